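"""Run configuration for the connectome analysis pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """Parameters governing one end-to-end analysis run.

    Defaults follow the study conditions: FN threshold 3 streamlines,
    sparsity grid 0.05-0.23 in steps of 0.01, 1,000 matched random
    networks, 10,000 permutations, BH-FDR at q = 0.05, NBS primary
    p = 0.05 and corrected p = 0.01.
    """

    fn_threshold: int = 3
    sparsity_min: float = 0.05
    sparsity_max: float = 0.23
    sparsity_step: float = 0.01
    n_random: int = 1000
    n_perm: int = 10000
    fdr_q: float = 0.05
    nbs_primary_p: float = 0.05
    nbs_corrected_p: float = 0.01
    seed: int = 0
    log_base_for_degree_rule: str = "natural"
    # sparsity at which hubs are detected and hub-score correlations taken
    ref_sparsity: float = 0.15
    # NBS edge mask: connection present in >= this fraction of either group
    nbs_mask_rule: float = 0.5
    # summarise metric curves by AUC (None) or at a fixed sparsity
    at_sparsity: float | None = None
    # nodal metric used for the synthetic score link and hub correlations
    hub_metric: str = "Ne"

    def __post_init__(self) -> None:
        if not (0 < self.sparsity_min <= self.sparsity_max < 1):
            raise ValueError("require 0 < sparsity_min <= sparsity_max < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if self.fn_threshold < 0:
            raise ValueError("fn_threshold must be >= 0")
        for name in ("n_random", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.fdr_q < 1 and 0 < self.nbs_primary_p < 1
                and 0 < self.nbs_corrected_p < 1):
            raise ValueError("significance levels must lie in (0, 1)")
        if self.log_base_for_degree_rule not in ("natural", "base10"):
            raise ValueError("log_base_for_degree_rule must be 'natural' or 'base10'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
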