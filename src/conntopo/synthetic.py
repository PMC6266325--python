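"""Synthetic two-group cohorts of weighted small-world connectomes.

The generator emulates the structure of a DTI connectome study cohort so
that every downstream stage of the pipeline has a known ground truth:

* a group-level template built as a ring lattice (``k`` neighbours per
  side) with probabilistic rewiring — guaranteeing the small-world regime
  (gamma > 1, lambda close to 1) — whose streamline-count (FN) means decay
  with lattice distance;
* per-subject FN matrices = template means times multiplicative lognormal
  noise (count-like, so FN thresholding stays meaningful), rounded to
  integers; per-subject FA drawn from a truncated normal in (0, 1);
* planted group effects: patient FN multiplied by ``planted_factor`` on a
  chosen edge set and by ``hub_factor`` on edges incident to chosen hub
  nodes;
* clinical scores linearly linked (plus Gaussian noise) to a nodal metric
  of a chosen region at a reference sparsity, patients carrying the
  disease-range intercepts;
* covariates (age, sex, education) drawn from the same distribution in
  both groups, so the null configuration yields exchangeable groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import truncnorm

from . import build as _build
from . import metrics as _metrics
from . import io as _io

__all__ = [
    "ScoreLink",
    "SyntheticConfig",
    "ConnectomeTemplate",
    "generate_base_connectome",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "template_atlas",
]


@dataclass
class ScoreLink:
    """Linear coupling of one clinical score to a nodal metric.

    score = intercept(group) + slope * metric(target_node) + N(0, noise_sd)
    """

    target_node: int | None = None  # 0-based node index; None = no link
    target_metric: str = "Ne"
    slope: float = 0.0
    noise_sd: float = 1.0
    intercept_patient: float = 0.0
    intercept_control: float = 0.0
    patients_only: bool = False  # e.g. disease duration


def _default_score_links() -> dict[str, ScoreLink]:
    # intercepts/noise in the range of published insomnia cohorts
    return {
        "PSQI": ScoreLink(noise_sd=3.0, intercept_patient=16.5, intercept_control=2.3),
        "ISI": ScoreLink(noise_sd=3.5, intercept_patient=20.8, intercept_control=2.4),
        "SAS": ScoreLink(noise_sd=9.5, intercept_patient=47.4, intercept_control=30.0),
        "SDS": ScoreLink(noise_sd=9.8, intercept_patient=52.0, intercept_control=33.0),
        "duration": ScoreLink(
            noise_sd=10.0, intercept_patient=30.0, patients_only=True
        ),
    }


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort (defaults = null cohort)."""

    n_regions: int = 90
    n_per_group: tuple[int, int] = (44, 46)  # (patients, controls)
    lattice_neighbors: int = 8  # neighbours per side of the ring lattice
    rewire_prob: float = 0.1
    base_fn_mean: float = 40.0  # streamline-count mean on nearest edges
    fa_mean: float = 0.5
    fa_sd: float = 0.1
    volume_sd: float = 0.3  # lognormal sigma of region volumes (0 = equal)
    subject_noise_cv: float = 0.25  # CV of lognormal subject edge noise
    planted_edge_set: tuple[tuple[int, int], ...] = ()
    planted_factor: float = 1.0  # multiplies patient FN on planted edges
    planted_hub_nodes: tuple[int, ...] = ()
    hub_factor: float = 1.0  # multiplies patient FN on hub-incident edges
    score_links: dict[str, ScoreLink] = field(default_factory=_default_score_links)
    fn_threshold: int = 3
    ref_sparsity: float = 0.15  # sparsity at which score-linked metrics are taken
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.lattice_neighbors >= self.n_regions:
            raise ValueError("lattice_neighbors must satisfy 2k < n_regions")
        if min(self.n_per_group) < 2:
            raise ValueError("each group needs at least two subjects")
        if self.planted_factor <= 0 or self.hub_factor <= 0:
            raise ValueError("planted factors must be positive")
        if not 0 < self.fa_mean < 1:
            raise ValueError("fa_mean must lie in (0, 1)")


@dataclass
class ConnectomeTemplate:
    """Group-level template: edge FN/FA means, volumes, node identities."""

    fn_mean: np.ndarray
    fa_mean: np.ndarray
    volumes: np.ndarray
    abbreviations: list[str]
    hemispheres: list[str]


def _is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = connected_components(coo_matrix(adj), directed=False)
    return n_comp == 1


def generate_base_connectome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> ConnectomeTemplate:
    """Ring-lattice-plus-rewiring template with distance-decaying FN means.

    Edges planted via ``planted_edge_set`` are kept in the backbone (never
    rewired) so the planted effect always exists.  The template is
    guaranteed connected (rewiring is retried if it disconnects the graph).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, k = config.n_regions, config.lattice_neighbors
    planted = {tuple(sorted(e)) for e in config.planted_edge_set}

    base_edges: dict[tuple[int, int], float] = {}
    for d in range(1, k + 1):
        mean_d = config.base_fn_mean / d
        for i in range(n):
            j = (i + d) % n
            base_edges[tuple(sorted((i, j)))] = mean_d
    missing = planted - set(base_edges)
    if missing:
        raise ValueError(f"planted edges not in the lattice backbone: {sorted(missing)}")

    for _attempt in range(100):
        edges = dict(base_edges)
        for e in list(edges):
            if e in planted or rng.random() >= config.rewire_prob:
                continue
            mean_e = edges[e]
            i = e[0] if rng.random() < 0.5 else e[1]
            for _try in range(20):
                h = int(rng.integers(0, n))
                new = tuple(sorted((i, h)))
                if h != i and new not in edges:
                    del edges[e]
                    edges[new] = mean_e
                    break
        fn_mean = np.zeros((n, n))
        for (a, b), m in edges.items():
            fn_mean[a, b] = m
            fn_mean[b, a] = m
        if _is_connected(fn_mean > 0):
            break
    else:  # pragma: no cover - vanishingly unlikely with 2k neighbours
        raise RuntimeError("failed to generate a connected template")

    fa_mean = np.zeros((n, n))
    iu, ju = np.nonzero(np.triu(fn_mean, k=1))
    fa_vals = np.clip(rng.normal(config.fa_mean, config.fa_sd, iu.size), 0.05, 0.95)
    fa_mean[iu, ju] = fa_vals
    fa_mean[ju, iu] = fa_vals

    # homologous pairs share a volume; odd trailing region stands alone
    n_pairs = (n + 1) // 2
    pair_vol = rng.lognormal(np.log(6000.0), config.volume_sd, n_pairs)
    volumes = np.empty(n)
    abbreviations, hemispheres = [], []
    for p in range(n_pairs):
        for off, hemi in ((0, "L"), (1, "R")):
            node = 2 * p + off
            if node >= n:
                break
            volumes[node] = pair_vol[p]
            abbreviations.append(f"R{p + 1:02d}.{hemi}")
            hemispheres.append(hemi)
    return ConnectomeTemplate(fn_mean, fa_mean, volumes, abbreviations, hemispheres)


def generate_subject(
    template: ConnectomeTemplate,
    group: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    subject_id: str = "S000",
) -> _build.SubjectConnectome:
    """One subject's FN/FA matrices from the template plus planted effects."""
    n = template.fn_mean.shape[0]
    iu, ju = np.nonzero(np.triu(template.fn_mean, k=1))
    fn_mu = template.fn_mean[iu, ju].copy()

    cv = config.subject_noise_cv
    if cv > 0:
        s2 = np.log1p(cv * cv)
        noise = rng.lognormal(-s2 / 2.0, np.sqrt(s2), iu.size)
    else:
        noise = np.ones(iu.size)
    fn_edge = fn_mu * noise

    if group == "patient":
        if config.planted_factor != 1.0 and config.planted_edge_set:
            planted = {tuple(sorted(e)) for e in config.planted_edge_set}
            sel = np.array([(a, b) in planted for a, b in zip(iu, ju)])
            fn_edge[sel] *= config.planted_factor
        if config.hub_factor != 1.0 and config.planted_hub_nodes:
            hubs = set(config.planted_hub_nodes)
            sel = np.array([(a in hubs) or (b in hubs) for a, b in zip(iu, ju)])
            fn_edge[sel] *= config.hub_factor

    fn_edge = np.maximum(np.rint(fn_edge), 0.0)
    fa_mu = template.fa_mean[iu, ju]
    a = (0.0 - fa_mu) / config.fa_sd
    b = (1.0 - fa_mu) / config.fa_sd
    fa_edge = truncnorm.rvs(a, b, loc=fa_mu, scale=config.fa_sd, random_state=rng)

    fn = np.zeros((n, n))
    fa = np.zeros((n, n))
    fn[iu, ju] = fn_edge
    fn[ju, iu] = fn_edge
    fa[iu, ju] = fa_edge
    fa[ju, iu] = fa_edge
    subj = _build.SubjectConnectome(
        subject_id=subject_id, fn=fn, fa=fa, volumes=template.volumes.copy()
    )
    subj.build_weights(config.fn_threshold)
    return subj


def _nodal_metric_at_ref(
    subj: _build.SubjectConnectome, config: SyntheticConfig, metric: str
) -> np.ndarray:
    Wt = _build.threshold_by_sparsity(subj.weights, config.ref_sparsity)
    if metric == "Ne":
        return _metrics.nodal_efficiency(_metrics.shortest_path_matrix(Wt))
    if metric == "Dc":
        return _metrics.degree_centrality(Wt).astype(float)
    if metric == "Bc":
        return _metrics.betweenness_centrality(Wt)
    raise ValueError(f"unknown nodal metric {metric!r}")


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[_build.SubjectConnectome], pd.DataFrame, dict]:
    """Full cohort: subject connectomes, participants table, ground truth.

    Deterministic given ``config.seed``.  Clinical scores follow their
    configured links; covariates are drawn from identical distributions in
    both groups (matched in law).
    """
    ss = np.random.SeedSequence(config.seed)
    rng_template, rng_subj, rng_cov, rng_score = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    template = generate_base_connectome(config, rng_template)

    n_pat, n_con = config.n_per_group
    subjects: list[_build.SubjectConnectome] = []
    groups: list[str] = []
    ids: list[str] = []
    for g, count, prefix in (("patient", n_pat, "P"), ("control", n_con, "C")):
        for i in range(count):
            sid = f"{prefix}{i + 1:03d}"
            subjects.append(generate_subject(template, g, config, rng_subj, sid))
            groups.append(g)
            ids.append(sid)
    n_total = len(subjects)

    age = np.clip(rng_cov.normal(40.0, 10.0, n_total), 20.0, 65.0)
    sex = (rng_cov.random(n_total) < 0.45).astype(int)
    education = np.clip(rng_cov.normal(8.0, 4.0, n_total), 1.0, 20.0)

    need_metric = {
        lk.target_metric
        for lk in config.score_links.values()
        if lk.target_node is not None and lk.slope != 0.0
    }
    metric_cache: dict[str, np.ndarray] = {}
    for m in need_metric:
        metric_cache[m] = np.vstack(
            [_nodal_metric_at_ref(s, config, m) for s in subjects]
        )

    data: dict[str, object] = {
        "subject_id": ids,
        "group": groups,
        "age": np.round(age, 1),
        "sex": sex,
        "education": np.round(education, 1),
    }
    is_patient = np.array([g == "patient" for g in groups])
    for score, link in config.score_links.items():
        intercept = np.where(
            is_patient, link.intercept_patient, link.intercept_control
        ).astype(float)
        vals = intercept + rng_score.normal(0.0, link.noise_sd, n_total)
        if link.target_node is not None and link.slope != 0.0:
            vals = vals + link.slope * metric_cache[link.target_metric][:, link.target_node]
        vals = np.round(np.maximum(vals, 0.0), 2)
        out = vals.astype(object)
        if link.patients_only:
            out = np.where(is_patient, vals, np.nan)
        data[score] = out
    participants = pd.DataFrame(data)

    ground_truth = {
        "planted_edge_set": [list(map(int, e)) for e in config.planted_edge_set],
        "planted_factor": config.planted_factor,
        "planted_hub_nodes": list(map(int, config.planted_hub_nodes)),
        "hub_factor": config.hub_factor,
        "ref_sparsity": config.ref_sparsity,
        "score_links": {
            s: {
                "target_node": lk.target_node,
                "target_metric": lk.target_metric,
                "slope": lk.slope,
                "noise_sd": lk.noise_sd,
            }
            for s, lk in config.score_links.items()
        },
        "seed": config.seed,
    }
    return subjects, participants, ground_truth


def template_atlas(template: ConnectomeTemplate) -> _io.RegionAtlas:
    n = template.fn_mean.shape[0]
    return _io.RegionAtlas(
        index=np.arange(1, n + 1),
        abbreviation=list(template.abbreviations),
        name=[f"Synthetic region {i + 1}" for i in range(n)],
        hemisphere=list(template.hemispheres),
        volume=template.volumes.copy(),
    )


def write_cohort(config: SyntheticConfig, output_dir: str | Path) -> Path:
    """Emit the pipeline input layout: atlas, participants, matrices, truth."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, participants, truth = generate_cohort(config)
    template = generate_base_connectome(
        config, np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    )
    _io.write_region_atlas(template_atlas(template), out / "atlas.tsv")
    _io.write_participants(participants, out / "participants.tsv")
    for subj in subjects:
        _io.write_matrix(subj.fn, out / f"{subj.subject_id}_FN.txt")
        _io.write_matrix(subj.fa, out / f"{subj.subject_id}_FA.txt")
    (out / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return out
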