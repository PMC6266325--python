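"""Reading and writing of atlas tables, participants tables and matrices.

File conventions
----------------
* Region atlas: TSV with header ``index, abbreviation, name, hemisphere,
  volume``; the hemisphere may be omitted and is then inferred from the
  ``.L``/``.R`` abbreviation suffix.
* Participants: TSV with header; required columns ``subject_id, group,
  age, sex, education``; optional clinical columns ``PSQI, ISI, SAS, SDS,
  duration`` (blank = missing, excluded pairwise downstream).  Group
  labels other than ``patient``/``control`` can be declared in a leading
  comment line, e.g. ``# group_map: PI=patient HC=control``.
* Matrices: dense whitespace- or comma-delimited text, one file per
  subject per measure (``<subject_id>_FN.txt`` / ``<subject_id>_FA.txt``).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("conntopo")

__all__ = [
    "RegionAtlas",
    "read_region_atlas",
    "write_region_atlas",
    "read_square_matrix",
    "write_matrix",
    "read_participants",
    "write_participants",
    "write_table",
    "write_manifest",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ("PSQI", "ISI", "SAS", "SDS", "duration")


@dataclass
class RegionAtlas:
    """Node identities of the parcellation: 1..N contiguous indices."""

    index: np.ndarray  # 1-based node ids
    abbreviation: list[str]
    name: list[str]
    hemisphere: list[str]  # 'L' or 'R'
    volume: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.abbreviation)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index,
                "abbreviation": self.abbreviation,
                "name": self.name,
                "hemisphere": self.hemisphere,
                "volume": self.volume,
            }
        )


def _infer_hemisphere(abbrev: str) -> str:
    if abbrev.endswith(".L"):
        return "L"
    if abbrev.endswith(".R"):
        return "R"
    raise ValueError(f"cannot infer hemisphere from abbreviation {abbrev!r}")


def read_region_atlas(path: str | Path) -> RegionAtlas:
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"index", "abbreviation", "name", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"atlas table missing columns: {sorted(missing)}")
    idx = df["index"].astype(int).to_numpy()
    n = len(idx)
    if sorted(idx.tolist()) != list(range(1, n + 1)):
        raise ValueError("atlas indices must be contiguous 1..N without gaps or duplicates")
    order = np.argsort(idx)
    df = df.iloc[order].reset_index(drop=True)
    abbrev = [a.strip() for a in df["abbreviation"]]
    if "hemisphere" in df.columns and df["hemisphere"].notna().all() and \
            all(str(h).strip() for h in df["hemisphere"]):
        hemi = [str(h).strip().upper() for h in df["hemisphere"]]
        bad = [h for h in hemi if h not in ("L", "R")]
        if bad:
            raise ValueError(f"unparseable hemisphere labels: {sorted(set(bad))}")
    else:
        hemi = [_infer_hemisphere(a) for a in abbrev]
    volume = df["volume"].astype(float).to_numpy()
    if np.any(volume <= 0):
        raise ValueError("region volumes must be positive")
    return RegionAtlas(
        index=np.arange(1, n + 1),
        abbreviation=abbrev,
        name=[str(x).strip() for x in df["name"]],
        hemisphere=hemi,
        volume=volume,
    )


def write_region_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    write_table(atlas.to_frame(), path)


def read_square_matrix(path: str | Path, n: int) -> np.ndarray:
    """Dense n-by-n matrix from delimited text; symmetry enforced (1e-8)."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        M = np.loadtxt(path, delimiter=delimiter)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in matrix file {path}") from exc
    M = np.atleast_2d(M)
    if M.shape != (n, n):
        raise ValueError(f"matrix in {path} has shape {M.shape}, expected ({n}, {n})")
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError(f"matrix in {path} is not symmetric within 1e-8")
    if np.any(np.diagonal(M) != 0):
        logger.warning("matrix %s has nonzero diagonal; forcing to zero", path)
        M = M.copy()
        np.fill_diagonal(M, 0.0)
    return M


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    M = np.asarray(M)
    if np.issubdtype(M.dtype, np.integer) or np.all(M == np.rint(M)):
        np.savetxt(path, M.astype(int), fmt="%d", delimiter="\t")
    else:
        # %.17g preserves doubles exactly (lossless round trip)
        np.savetxt(path, M, fmt="%.17g", delimiter="\t")


def _parse_group_map(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#\s*group_map\s*:\s*(.*)", line.strip())
            if m:
                for pair in re.split(r"[,;\s]+", m.group(1)):
                    if "=" in pair:
                        raw, canon = pair.split("=", 1)
                        mapping[raw.strip().lower()] = canon.strip().lower()
    return mapping


def read_participants(path: str | Path) -> pd.DataFrame:
    """Participants table with canonical 'patient'/'control' group labels."""
    path = Path(path)
    group_map = _parse_group_map(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip() for c in df.columns]
    required = ["subject_id", "group", "age", "sex", "education"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"participants table missing columns: {missing}")
    groups = df["group"].astype(str).str.strip().str.lower()
    groups = groups.map(lambda g: group_map.get(g, g))
    unknown = sorted(set(groups) - {"patient", "control"})
    if unknown:
        raise ValueError(
            f"unknown group labels {unknown}; declare a '# group_map:' header line"
        )
    df["group"] = groups
    counts = df["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least two subjects in each of two groups")
    for col in ("age", "education"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise ValueError(f"covariate column {col!r} contains non-finite values")
    if not df["sex"].isin([0, 1]).all():
        raise ValueError("sex must be coded 0/1")
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    write_table(df, path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Stable TSV writer (fixed float format, LF line endings)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
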