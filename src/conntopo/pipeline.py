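"""End-to-end orchestration: build -> metrics -> compare -> NBS -> correlate.

All randomness flows from the single master seed in :class:`RunConfig`,
split deterministically per stage with ``numpy.random.SeedSequence``, so a
rerun with the same inputs and configuration reproduces every output file
byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import build as _build
from . import corr as _corr
from . import io as _io
from . import metrics as _metrics
from . import nbs as _nbs
from . import stats as _stats
from .config import RunConfig

logger = logging.getLogger("conntopo")

__all__ = ["PipelineError", "run_pipeline", "compute_cohort_curves", "group_hubs"]

STAGES = ("load", "build", "metrics", "compare", "nbs", "correlate")


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def compute_cohort_curves(
    weight_matrices: list[np.ndarray],
    grid: np.ndarray,
    n_random: int,
    rng: np.random.Generator,
    nodal: bool = True,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Global and nodal metric curves for every subject over the grid.

    Returns ``(global_curves, nodal_curves)`` where ``global_curves[m]`` is
    (n_subjects, n_thresholds) and ``nodal_curves[m]`` is
    (n_subjects, n_thresholds, n_nodes).
    """
    n_subj = len(weight_matrices)
    n_thr = grid.size
    n_nodes = weight_matrices[0].shape[0]
    g_curves = {m: np.empty((n_subj, n_thr)) for m in _metrics.GLOBAL_METRIC_NAMES}
    n_curves = (
        {m: np.empty((n_subj, n_thr, n_nodes)) for m in _metrics.NODAL_METRIC_NAMES}
        if nodal
        else {}
    )
    for i, W in enumerate(weight_matrices):
        for j, s in enumerate(grid):
            Wt = _build.threshold_by_sparsity(W, float(s))
            gm = _metrics.graph_global_metrics(Wt, n_random, rng)
            for m in _metrics.GLOBAL_METRIC_NAMES:
                g_curves[m][i, j] = gm[m]
            if nodal:
                nm = _metrics.graph_nodal_metrics(Wt)
                for m in _metrics.NODAL_METRIC_NAMES:
                    n_curves[m][i, j] = nm[m]
    return g_curves, n_curves


def group_hubs(
    nodal_at_ref: dict[str, np.ndarray], is_patient: np.ndarray
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Hub sets per group and the patient-unique hubs per nodal metric.

    ``nodal_at_ref[m]`` is (n_subjects, n_nodes) at the reference sparsity.
    Hubs are detected on group-mean nodal values (mean + 1 SD rule).
    """
    hubs: dict[str, dict[str, np.ndarray]] = {}
    unique: dict[str, np.ndarray] = {}
    for m, vals in nodal_at_ref.items():
        pat = _metrics.detect_hubs(vals[is_patient].mean(axis=0))
        con = _metrics.detect_hubs(vals[~is_patient].mean(axis=0))
        hubs[m] = {"patient": pat, "control": con}
        unique[m] = np.setdiff1d(pat, con)
    return hubs, unique


def _stage(stage: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(
    config: RunConfig,
    input_dir: str | Path,
    output_dir: str | Path,
    stages: tuple[str, ...] = STAGES,
) -> int:
    """Run the full analysis on a cohort directory; returns 0 on success.

    ``input_dir`` must contain ``atlas.tsv``, ``participants.tsv`` and
    per-subject ``<id>_FN.txt`` / ``<id>_FA.txt`` matrices.  Result tables
    (TSV) and a JSON run manifest are written to ``output_dir``; output for
    a stage is written only when the stage is listed in ``stages`` (all by
    default; earlier stages are always computed as prerequisites).
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_metrics, rng_compare, rng_nbs = (np.random.default_rng(c) for c in ss.spawn(3))

    # -- load ---------------------------------------------------------------
    @_stage("load")
    def _load():
        atlas = _io.read_region_atlas(input_dir / "atlas.tsv")
        participants = _io.read_participants(input_dir / "participants.tsv")
        subjects = []
        for sid in participants["subject_id"]:
            for meas in ("FN", "FA"):
                path = input_dir / f"{sid}_{meas}.txt"
                if not path.exists():
                    raise FileNotFoundError(
                        f"missing {meas} matrix for subject {sid}: {path}"
                    )
            fn = _io.read_square_matrix(input_dir / f"{sid}_FN.txt", atlas.n_regions)
            fa = _io.read_square_matrix(input_dir / f"{sid}_FA.txt", atlas.n_regions)
            subjects.append(
                _build.SubjectConnectome(
                    subject_id=str(sid), fn=fn, fa=fa, volumes=atlas.volume
                )
            )
        return atlas, participants, subjects

    atlas, participants, subjects = _load()
    is_patient = (participants["group"] == "patient").to_numpy()
    covariates = participants[list(_stats.COVARIATE_COLUMNS)].to_numpy(dtype=float)

    # -- build --------------------------------------------------------------
    @_stage("build")
    def _build_stage():
        for subj in subjects:
            subj.build_weights(config.fn_threshold)
        return _build.build_sparsity_grid(
            config.sparsity_min, config.sparsity_max, config.sparsity_step
        )

    grid = _build_stage()
    weights = [s.weights for s in subjects]

    # -- metrics ------------------------------------------------------------
    @_stage("metrics")
    def _metrics_stage():
        g_curves, n_curves = compute_cohort_curves(
            weights, grid, config.n_random, rng_metrics
        )
        low, high, diag = _build.sparsity_admissibility(
            g_curves["sigma"], grid, atlas.n_regions, config.log_base_for_degree_rule
        )
        ref_j = int(np.argmin(np.abs(grid - config.ref_sparsity)))
        nodal_ref = {m: n_curves[m][:, ref_j, :] for m in n_curves}
        hubs, unique = group_hubs(nodal_ref, is_patient)
        return g_curves, n_curves, nodal_ref, hubs, unique, (low, high, diag)

    g_curves, n_curves, nodal_ref, hubs, unique_hubs, (low, high, diag) = _metrics_stage()

    if "metrics" in stages:
        _io.write_table(diag, output_dir / "sparsity_diagnostics.tsv")
        rows = []
        for i, sid in enumerate(participants["subject_id"]):
            for j, s in enumerate(grid):
                row = {"subject_id": sid, "sparsity": float(s)}
                row.update({m: g_curves[m][i, j] for m in _metrics.GLOBAL_METRIC_NAMES})
                rows.append(row)
        _io.write_table(pd.DataFrame(rows), output_dir / "global_metrics.tsv")
        nodal_rows = []
        for i, sid in enumerate(participants["subject_id"]):
            for j, s in enumerate(grid):
                for v in range(atlas.n_regions):
                    nodal_rows.append(
                        {
                            "subject_id": sid,
                            "sparsity": float(s),
                            "node": v + 1,
                            "label": atlas.abbreviation[v],
                            "Ne": n_curves["Ne"][i, j, v],
                            "Bc": n_curves["Bc"][i, j, v],
                            "Dc": n_curves["Dc"][i, j, v],
                        }
                    )
        _io.write_table(pd.DataFrame(nodal_rows), output_dir / "nodal_metrics.tsv")
        hub_rows = []
        for m, per_group in hubs.items():
            for grp, nodes in per_group.items():
                for v in nodes:
                    hub_rows.append(
                        {
                            "metric": m,
                            "group": grp,
                            "node": int(v) + 1,
                            "label": atlas.abbreviation[int(v)],
                            "unique_to_patients": bool(
                                grp == "patient" and v in unique_hubs[m]
                            ),
                        }
                    )
        _io.write_table(pd.DataFrame(
            hub_rows, columns=["metric", "group", "node", "label", "unique_to_patients"]
        ), output_dir / "hubs.tsv")

    # -- compare ------------------------------------------------------------
    @_stage("compare")
    def _compare_stage():
        primary, secondary = _stats.compare_global_metrics(
            g_curves, is_patient, covariates, grid,
            config.n_perm, config.fdr_q, rng_compare, config.at_sparsity,
        )
        nodal_cmp = _stats.compare_nodal_metrics(
            n_curves, is_patient, covariates, grid,
            config.n_perm, config.fdr_q, rng_compare, config.at_sparsity,
            node_labels=atlas.abbreviation,
        )
        hemi_tables, hemi_counts = _stats.hemisphere_analysis(
            nodal_cmp, atlas.hemisphere, config.fdr_q
        )
        return primary, secondary, nodal_cmp, hemi_tables, hemi_counts

    if "compare" in stages:
        primary, secondary, nodal_cmp, hemi_tables, hemi_counts = _compare_stage()
        _io.write_table(primary, output_dir / "global_comparison.tsv")
        _io.write_table(secondary, output_dir / "global_comparison_per_threshold.tsv")
        for m, df in nodal_cmp.items():
            _io.write_table(df, output_dir / f"nodal_comparison_{m}.tsv")
        for h, df in hemi_tables.items():
            _io.write_table(df, output_dir / f"hemisphere_{h}.tsv")
        _io.write_table(hemi_counts, output_dir / "hemisphere_summary.tsv")

    # -- nbs ----------------------------------------------------------------
    @_stage("nbs")
    def _nbs_stage():
        return _nbs.nbs_test(
            np.stack(weights), is_patient, covariates,
            n_perm=config.n_perm, primary_p=config.nbs_primary_p,
            corrected_p=config.nbs_corrected_p, rng=rng_nbs,
            mask_rule=config.nbs_mask_rule,
        )

    nbs_result = None
    if "nbs" in stages:
        nbs_result = _nbs_stage()
        comp_rows = []
        for cid, comp in enumerate(nbs_result.components, start=1):
            for a, b in comp.edges:
                comp_rows.append(
                    {
                        "component_id": cid,
                        "direction": comp.direction,
                        "region1": atlas.abbreviation[a],
                        "region2": atlas.abbreviation[b],
                        "size": comp.size,
                        "corrected_p": comp.p,
                        "significant": comp.p is not None
                        and comp.p <= config.nbs_corrected_p,
                    }
                )
        _io.write_table(
            pd.DataFrame(
                comp_rows,
                columns=["component_id", "direction", "region1", "region2",
                         "size", "corrected_p", "significant"],
            ),
            output_dir / "components.tsv",
        )
        _io.write_table(
            pd.DataFrame({"max_component_size": nbs_result.null_max_sizes}),
            output_dir / "nbs_null_distribution.tsv",
        )

    # -- correlate ----------------------------------------------------------
    @_stage("correlate")
    def _correlate_stage():
        pat = is_patient
        nodal_pat = {m: nodal_ref[m][pat] for m in nodal_ref}
        scores = participants.loc[pat, list(_io.SCORE_COLUMNS)].reset_index(drop=True)
        return _corr.correlate_hub_metrics(
            nodal_pat,
            {m: unique_hubs[m].tolist() for m in unique_hubs},
            scores,
            covariates[pat],
            node_labels=atlas.abbreviation,
        )

    if "correlate" in stages:
        hub_corr = _correlate_stage()
        _io.write_table(hub_corr, output_dir / "hub_correlations.tsv")

    manifest = {
        "config": config.to_dict(),
        "package": {"name": "conntopo", "version": __version__},
        "n_subjects": int(len(subjects)),
        "n_patients": int(is_patient.sum()),
        "n_regions": int(atlas.n_regions),
        "sparsity_grid": [float(s) for s in grid],
        "admissible_sparsity": {"low": low, "high": high},
        "fdr_families": {
            "global": "7 global metrics",
            "nodal": "all nodes within each nodal metric",
            "hemisphere": "nodes within each hemisphere stratum per metric",
        },
    }
    if nbs_result is not None:
        manifest["nbs"] = {
            "t_threshold": nbs_result.t_threshold,
            "n_components": len(nbs_result.components),
            "n_significant": len(nbs_result.significant),
        }
    _io.write_manifest(manifest, output_dir / "manifest.json")
    logger.info("pipeline complete: %s", output_dir)
    return 0
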