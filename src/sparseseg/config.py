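"""Run configuration shared by the CLI and scripted pipelines."""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

from .autogen import DEFAULT_GROWTH_THRESHOLD
from .solver import DEFAULT_BETA, DEFAULT_MAX_ITER, DEFAULT_REL_TOL

#: Growth thresholds outside this band tend to over-grow (low p_t,
#: multi-label claims) or suppress growth entirely (high p_t).
RECOMMENDED_PT_RANGE = (0.6, 0.9)


@dataclass
class RunConfig:
    """Pipeline parameters with their published defaults.

    beta : edge-weight sharpness for the walker graph (90).
    p_t : ESP growth threshold in (0, 1) (0.8); values outside
        [0.6, 0.9] trigger a warning.
    sigma : likelihood kernel width; None means estimate from seed
        contrast (0.5 * mean seed intensity difference).
    connectivity : 4/6 lattice connectivity; None means match the
        image dimensionality.
    rel_tol, max_iter : conjugate-gradient stopping rule (1e-6, 1000).
    """

    beta: float = DEFAULT_BETA
    p_t: float = DEFAULT_GROWTH_THRESHOLD
    sigma: float | None = None
    connectivity: int | None = None
    rel_tol: float = DEFAULT_REL_TOL
    max_iter: int = DEFAULT_MAX_ITER
    rng_seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        if not 0 < self.p_t < 1:
            raise ValueError(f"p_t must be in (0, 1), got {self.p_t}")
        lo, hi = RECOMMENDED_PT_RANGE
        if not lo <= self.p_t <= hi:
            warnings.warn(
                f"p_t={self.p_t} is outside the recommended range "
                f"[{lo}, {hi}]; growth may be unstable",
                stacklevel=2,
            )
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")

    def as_manifest(self) -> dict:
        return asdict(self)
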