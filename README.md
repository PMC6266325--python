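# conntopo

Graph-topology analysis of DTI-derived structural brain connectomes:
weighted network construction, small-world and nodal metrics normalised
against matched random networks, hub detection, covariate-adjusted
permutation group inference, the Network-Based Statistic (NBS), and
clinical-score correlations — with a synthetic cohort generator that
plants known effects so every stage can be validated end to end.

## Who this is for

Researchers comparing whole-brain white-matter networks between a
patient group and controls (e.g. primary insomnia vs healthy sleepers),
starting from per-subject region-by-region matrices of streamline
counts (FN) and mean fractional anisotropy (FA) over an anatomical
parcellation such as AAL-90.

## The model in brief

Edge weights are `w_ij = FN_ij · FA_ij / ((vol_i + vol_j)/2)` with
connections below FN ≥ 3 removed. Each network is proportionally
thresholded over a sparsity grid (0.05–0.23, step 0.01) keeping edge
weights. Per threshold the pipeline computes Cp, Lp, Eg, Eloc and the
nodal metrics Ne, Bc, Dc; clustering and path length are normalised by
1,000 degree- and weight-matched random networks to give γ, λ and the
small-world index σ = γ/λ. Curves are summarised by their area under
the sparsity grid (AUC). Groups are compared by residualising on age,
sex and education and permuting group labels (10,000 permutations,
BH-FDR at q = 0.05); affected subnetworks are localised by the NBS
(primary p = 0.05, component-level FWER p ≤ 0.01); hubs are nodes one
SD above the mean nodal value; patient-unique hub metrics are
correlated with clinical scores (PSQI, ISI, SAS, SDS, duration) by
partial Spearman. Details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 24-region cohort in which patients carry a weakened
three-edge subnetwork, then run the full analysis:

```bash
conntopo simulate cohort/ --n-regions 24 --n-patients 10 --n-controls 10 \
    --lattice-neighbors 2 --planted-edge 1 2 --planted-edge 2 3 \
    --planted-edge 3 4 --planted-factor 0.5 --seed 3
conntopo run-all cohort/ results/ --sparsity-min 0.15 --sparsity-max 0.25 \
    --sparsity-step 0.05 --n-random 20 --n-perm 2000 --seed 7
```

`results/global_comparison.tsv` then contains (this exact output, given
these seeds):

```
metric	observed_diff	p	p_fdr	rejected
Cp	-0.0007359679009	0.6896551724	0.6896551724	False
Lp	7.952560788	0.3128435782	0.413376645	False
Eg	-8.101241746e-06	0.004997501249	0.02098950525	True
Eloc	-1.445321822e-05	0.05997001499	0.1049475262	False
gamma	0.0384146992	0.04897551224	0.1049475262	False
lambda	-0.006961838764	0.3543228386	0.413376645	False
sigma	0.03957704593	0.005997001499	0.02098950525	True
```

Read: after covariate adjustment and FDR, global efficiency `Eg` is
significantly *lower* in patients (adjusted-mean difference −8.1e-06 in
AUC units — small numbers because w = FN·FA/volume is itself small;
permutation p = 0.005), the expected integration loss from weakened
connections; σ is also flagged (here drifting upward — with 10+10
subjects and 20 random networks the normalised indices are noisy, which
is why the efficiency metrics are the primary readout). `components.tsv` localises it: the largest decreased NBS
component is exactly the planted chain R01.L–R01.R–R02.L–R02.R (3
edges, corrected p = 0.024 — significant at 0.05, though not at the
strict 0.01 default with only 10+10 subjects). `hubs.tsv`,
`hub_correlations.tsv` and `manifest.json` complete the outputs.

The same analysis runs on real data laid out as `atlas.tsv`,
`participants.tsv` and per-subject `<id>_FN.txt` / `<id>_FA.txt`
matrices (delimited text; see module docs in `conntopo/io.py`).

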