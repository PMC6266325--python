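# Methods

## Overview

`conntopo` analyses the topology of weighted structural brain networks
("connectomes") built from diffusion-MRI tractography. Its pipeline
mirrors a standard case-control connectome study: per-subject weighted
networks are built from streamline counts (FN) and mean fractional
anisotropy (FA) per region pair, graph metrics are computed across a
proportional-threshold (sparsity) grid and normalised against matched
random networks, groups are compared with covariate-adjusted permutation
tests under Benjamini-Hochberg FDR control, affected subnetworks are
localised with the Network-Based Statistic (NBS), hub regions are
identified, and nodal metrics of patient-unique hubs are correlated with
clinical scores. A synthetic cohort generator with planted ground truth
closes the loop for validation.

## Network construction

The edge weight between regions *i* and *j* is

    w_ij = FN_ij · FA_ij / ((vol_i + vol_j) / 2)

with connections below the streamline threshold (default FN ≥ 3) removed.
Volume normalisation uses the arithmetic mean of the two region volumes,
reading "average volume of the two connecting regions" literally.
Networks are then proportionally thresholded: at sparsity *s* the
`round(s·N(N−1)/2)` strongest edges are retained **with their weights**
(round half up; ties at the cutoff broken by lexicographic node order so
results are deterministic). Binary analysis is not offered. The default
grid is 0.05–0.23 in steps of 0.01 (19 thresholds).

Two admissibility rules bound the usable sparsity range: the analytic
mean degree `s·(N−1)` must exceed `log(N)` at the low end, and every
subject's small-world index σ must exceed 1.1 at the high end. The
logarithm base is configurable (natural by default) because the rule is
base-dependent in an interesting way at N = 90: `0.05·89 = 4.45` fails
against `ln 90 ≈ 4.4998` but passes against `log₁₀ 90 ≈ 1.954`. The
diagnostics table reports the rule in the configured base rather than
silently choosing.

## Graph metrics

All metrics operate on symmetric non-negative weight matrices with zero
diagonals. Topological distance along an edge is `1/w`, the standard
choice for FN·FA weights where stronger connections are "shorter".

* **Dc** — degree centrality: count of nonzero incident edges.
* **Lp** — characteristic path length: mean shortest-path distance over
  *reachable* pairs; the number of excluded (disconnected) pairs is
  reported. Efficiency metrics, which handle disconnection natively, are
  the primary integration measures.
* **Eg / Ne** — global and nodal efficiency: mean inverse distance over
  ordered pairs (unreachable pairs contribute 0). Eg is implemented as
  efficiency (mean inverse distance), the only internally consistent
  reading of its usual definition.
* **Cp** — Onnela weighted clustering: geometric-mean triangle intensity
  with weights scaled by the graph maximum, `2/(k(k−1)) Σ (ŵŵŵ)^{1/3}`;
  degree < 2 ⇒ 0. On binary graphs this reduces exactly to
  triangles / possible triangles.
* **Eloc** — local efficiency: global efficiency of the subgraph induced
  by a node's neighbours (computed with a dense Floyd-Warshall, which is
  faster than repeated sparse Dijkstra at these subgraph sizes).
* **Bc** — betweenness centrality (Brandes, via networkx) with `1/w`
  distances, unnormalised over unordered pairs: a star centre with *m*
  leaves scores C(*m*, 2).

**Matched random networks.** γ = Cp/⟨Cp_rand⟩ and λ = Lp/⟨Lp_rand⟩ are
normalised against an ensemble (default 1,000) of networks that preserve
the degree sequence exactly (degree-preserving double-edge swaps,
targeting 10× the edge count of successful swaps) and the edge-weight
multiset (weights reassigned to the rewired topology in random order).
Graphs admitting no swap (e.g. complete graphs) fall back to
weight-shuffled copies with a warning. The small-world index is
**σ = γ/λ**: a lattice-like network (γ > 1, λ ≈ 1) then gives σ > 1,
which is the criterion the field uses; the occasionally printed σ = λ/γ
is inconsistent with that criterion and is not used.

Curves over the sparsity grid are summarised per subject by the left
Riemann sum (AUC, `Σ value·step`); a fixed-sparsity summary is available
via `at_sparsity`.

**Hubs.** A node is a hub when its nodal value is at least one sample
standard deviation (ddof = 1) above the across-node mean; with zero SD
the hub set is empty. Hubs are detected on group-mean nodal values at a
reference sparsity (default 0.15), configurable; per-metric patient-only
("unique") hubs feed the clinical correlation stage.

## Group inference

**Residualise-then-permute.** Metric summaries are residualised on an
intercept plus age, sex and education by pooled OLS; the observed
statistic is the difference of adjusted group means; its two-sided
p-value comes from permuting group labels (10,000 by default) with the
add-one estimator `p = (1 + #extreme)/(n_perm + 1)`, which cannot return
zero. When the number of distinct label splits is at most `n_perm`, the
exact enumeration over all C(n, n_a) splits replaces sampling and
`p = #extreme/total`. This Freedman-Lane-style residualisation is the
simplest defensible reading of "adjusted ... as covariates" inside a
permutation framework.

FDR is Benjamini-Hochberg, applied within families: the 7 global
metrics; the N nodes of each nodal metric; and, for the hemisphere
analysis, the nodes within each hemisphere stratum (FDR re-applied per
stratum). Families are recorded in the run manifest. Both corrected and
uncorrected p-values are emitted.

**NBS.** Edges present in at least half the subjects of either group
(configurable) are tested with pooled-variance t statistics on
covariate-residualised weights (df = n − 2 − n_cov). The primary
threshold is the two-sided t quantile of an uncorrected p (default
0.05). Connected components of suprathreshold edges are extracted
separately for each direction; component size is the edge count
(extent). The null distribution records, per label permutation
(covariates stay with their subjects), the maximal component size over
both directions, so corrected component p-values are family-wise valid
for the two-direction family. The significance level for components
defaults to p ≤ 0.01.

**Clinical correlations.** Spearman correlations (midranks; p from the t
approximation) between patient-unique hub nodal metrics and clinical
scores (PSQI, ISI, SAS, SDS, disease duration), restricted to patients,
with covariates removed by the rank-after-residual convention:
residualise the raw values on intercept + covariates, then rank, with
df = n − 2 − n_cov. The alternative (rank first, then residualise the
ranks) is available behind `rank_first=True`. Missing scores are
excluded pairwise and the per-row n is reported. No multiplicity
correction is applied to this table by default.

## Synthetic cohorts

The generator emulates the *structure* of a two-group DTI cohort, not
its anatomy:

* **Backbone** — ring lattice with `k` neighbours per side (default 8)
  plus probabilistic rewiring (default 0.1), which guarantees the
  small-world regime with a single knob. Edge FN means decay with
  lattice distance (`base_fn_mean/d`, default 40 streamlines on nearest
  neighbours) so proportional thresholding retains local structure.
  Planted edges are never rewired; the template is guaranteed connected.
* **Subjects** — FN = template mean × multiplicative lognormal noise
  (CV default 0.25; mean-one parameterisation), rounded to non-negative
  integers, so FN is count-like and the FN ≥ 3 threshold stays
  meaningful. FA is drawn per edge from a truncated normal in (0, 1).
* **Planted effects** — patient FN multiplied by `planted_factor` on a
  chosen edge set and by `hub_factor` on edges incident to chosen nodes.
  The default configuration plants nothing: groups are exchangeable,
  which is the basis of all type-I-error checks.
* **Covariates and scores** — age, sex and education are drawn from the
  same distributions in both groups (matched in law; ranges typical of
  adult insomnia cohorts). Clinical scores are group-specific intercepts
  plus optional linear couplings to a nodal metric at the reference
  sparsity plus Gaussian noise; disease duration exists for patients
  only. Volumes are lognormal around 6,000 (arbitrary units) and shared
  between homologous left/right regions, whose labels alternate around
  the ring.

What the generator does **not** emulate: anatomical geometry and
distance-dependent connection probability, hemispheric modularity,
realistic FA spatial structure, head-motion or registration artefacts,
and site effects. Passing validation therefore demonstrates the
statistical machinery is correct and calibrated on exchangeable,
small-world, count-weighted networks — not that the pipeline is robust
to every property of real tractography data.

## Validation experiments and problem sizes

`conntopo.validation` packages the Monte-Carlo studies used by the test
suite and the reproduction script. Sizes were chosen so the whole suite
runs on one CPU in minutes:

* type-I calibration: 500 null cohorts of 30 regions, 10+10 subjects,
  grid 0.14–0.18 step 0.01, 2 matched random networks per graph, 1,000
  permutations per test;
* NBS: 300 null cohorts (30 regions, 20+20 subjects, 500 permutations)
  for family-wise error; 50 cohorts with an 8-edge chain weakened to 0.6
  for recovery (Jaccard ≥ 0.5 against the planted set);
* hub recovery: 100 cohorts of 90 regions, 12 patients, one node with
  1.5× incident strength, on a homogeneous anatomy (pure lattice, equal
  volumes) so the planted boost is the only node-level difference —
  with the default heterogeneous anatomy, baseline volume- and
  rewiring-driven strength variation dominates node ranking and the
  experiment would measure anatomy, not the detection rule;
* score-link recovery: one fixed 90-region template, 120 draws of 44
  patients; the SAS–Ne(target node) link is calibrated from a 1,200
  subject pilot on the same template to a population Spearman ρ ≈ 0.55,
  and the "true" ρ is measured empirically on the pilot rather than
  taken from the normal-theory conversion. Recovery means the patient
  estimate is within ±0.15 of that truth.

## Numerical choices and degenerate inputs

* Round half up for the retained-edge count K; deterministic tie-breaks
  everywhere (lexicographic edge order; component ordering by size then
  smallest node).
* All randomness flows from one master seed through
  `numpy.random.SeedSequence` spawns per stage; reruns are byte-identical
  (fixed float formats, sorted-key JSON, no timestamps).
* Disconnected graphs: Lp averages finite pairs (count reported);
  efficiencies treat unreachable pairs as zero contribution; a fully
  disconnected graph is an error for Lp.
* Sparsity requests beyond the achievable density retain all edges with
  a warning. Metrics that cannot be normalised (zero random-ensemble
  clustering) become NaN and are excluded from testing and FDR rather
  than propagating spurious p-values.
* Asymmetric input matrices (beyond 1e-8) are rejected; nonzero
  diagonals are zeroed with a logged warning.

## Known limitations

* The NBS permutation loop recomputes components per permutation in
  Python/scipy; at atlas scale with 10,000 permutations it is the
  slowest stage (minutes, not hours).
* The hemisphere analysis re-applies FDR within strata on the same
  per-node p-values used for the whole-brain analysis; it is a
  descriptive stratification, not an interaction test.
* `validate_sparsity_range` recomputes σ per subject per threshold when
  called standalone; the pipeline avoids the duplicate work by reusing
  the metric curves.
* Partial Spearman conventions (rank-after-residual vs residual-of-ranks)
  differ in small samples; both are offered, one is the default.
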