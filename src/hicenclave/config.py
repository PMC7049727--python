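"""Run configuration shared by the CLI and `run_pipeline`."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .matrix import DEFAULT_LAMBDA_GRID


@dataclass
class RunConfig:
    """Parameters of one per-chromosome run.

    Defaults reproduce the method's stated constants: five 2-means
    seedings per bisection and 500 random clusterings for the VI null.
    """

    resolution: int = 50_000
    chrom: str = "chr1"
    master_seed: int = 1234
    kr_tol: float = 1e-8
    kr_max_iter: int = 1000
    boxcox_grid: tuple[float, float, float] = (-2.0, 2.0, 0.05)
    n_seedings: int = 5
    null_draws: int = 500
    fdr_level: float = 0.05
    paths: dict = field(default_factory=dict)

    def lambda_grid(self) -> np.ndarray:
        lo, hi, step = self.boxcox_grid
        if (lo, hi, step) == (-2.0, 2.0, 0.05):
            return DEFAULT_LAMBDA_GRID
        return np.round(np.arange(lo, hi + 1e-9, step), 10)

    def to_dict(self) -> dict:
        return asdict(self)
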