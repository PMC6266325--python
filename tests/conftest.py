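from pathlib import Path

import numpy as np
import pytest

from conntopo.config import RunConfig
from conntopo.synthetic import SyntheticConfig, write_cohort


def random_weighted_graph(
    n: int,
    rng: np.random.Generator,
    density: float = 0.5,
    dyadic: bool = False,
) -> np.ndarray:
    """Random symmetric zero-diagonal weight matrix.

    With ``dyadic=True`` weights come from {1, 1/2, 1/4, 1/8} so that path
    lengths (sums of inverse weights) are exact in floating point and
    shortest-path ties are counted identically by any algorithm.
    """
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    if dyadic:
        w = 2.0 ** -rng.integers(0, 4, iu.size)
    else:
        w = 0.1 + 0.9 * rng.random(iu.size)
    vals = np.where(present, w, 0.0)
    W[iu, ju] = vals
    W[ju, iu] = vals
    return W


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory) -> Path:
    """A small synthetic cohort on disk in the pipeline input layout."""
    out = tmp_path_factory.mktemp("cohort") / "in"
    cfg = SyntheticConfig(
        n_regions=30,
        n_per_group=(6, 6),
        lattice_neighbors=3,
        subject_noise_cv=0.3,
        planted_edge_set=((0, 1), (1, 2), (2, 3)),
        planted_factor=0.6,
        seed=42,
    )
    write_cohort(cfg, out)
    return out


@pytest.fixture(scope="session")
def fast_run_config() -> RunConfig:
    return RunConfig(
        sparsity_min=0.12,
        sparsity_max=0.20,
        sparsity_step=0.02,
        n_random=4,
        n_perm=200,
        seed=7,
    )
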