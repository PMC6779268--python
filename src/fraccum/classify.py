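"""Direction classifier: sign-map voting over fractional cumulants.

For a candidate pair (X, Y) the classifier computes the cumulant map of the
normalized series, restricts it to an index window, and sums the cumulants
weighted by the trained ternary sign maps.  A non-negative sum is evidence
that the pair matches the trained X -> Y pattern; a negative sum, its
mirror image Y -> X.  The "weighted" variant passes each cumulant through
the discount f(x) = log(cosh(max(x, 0))) so that hard-to-estimate
high-index cumulants contribute less.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .moments import fractional_cumulants, normalize_series
from .train import SignMaps

__all__ = [
    "Direction",
    "DirectionDecision",
    "ClassifierConfig",
    "discount",
    "window_mask",
    "classify_pair",
    "statistic_from_map",
]


class Direction(enum.IntEnum):
    X_TO_Y = 1
    Y_TO_X = -1

    def flipped(self) -> "Direction":
        return Direction(-int(self))


@dataclass(frozen=True)
class DirectionDecision:
    """Signed voting statistic and the verdict it implies (>= 0 -> X->Y)."""

    statistic: float
    verdict: Direction

    @classmethod
    def from_statistic(cls, statistic: float) -> "DirectionDecision":
        if statistic == 0.0:
            warnings.warn(
                "voting statistic is exactly zero; resolving tie as X->Y",
                stacklevel=3,
            )
        verdict = Direction.X_TO_Y if statistic >= 0 else Direction.Y_TO_X
        return cls(statistic=float(statistic), verdict=verdict)


@dataclass(frozen=True)
class ClassifierConfig:
    """Trained maps plus the voting window and weighting switches.

    Defaults are the tuned weighted configuration (2.1, 3.7); the tuned
    unweighted window is (2.4, 1.7).  ``window_mode`` selects between the
    triangle constraint k + l <= ind_max (default) and the box constraint
    max(k, l) <= ind_max.
    """

    sign_maps: SignMaps
    ind_r_max: float = 2.1
    ind_i_max: float = 3.7
    weighted: bool = True
    cov_weighted: bool = False
    min_index: float = 0.1
    window_mode: str = "triangle"
    min_length: int = 50

    def __post_init__(self) -> None:
        kmax = float(self.sign_maps.grid.k_values[-1])
        for name, val in (("ind_r_max", self.ind_r_max), ("ind_i_max", self.ind_i_max)):
            if not 0 < val <= 2 * kmax:
                raise ValueError(f"{name} must lie within the grid range")
        if self.window_mode not in ("triangle", "max"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")


def discount(x):
    """f(x) = log(cosh(max(x, 0))), evaluated overflow-safely.

    Zero for x <= 0, asymptotically x - log 2 for large x.
    """
    m = np.maximum(np.asarray(x, dtype=float), 0.0)
    out = m + np.log1p(np.exp(-2.0 * m)) - np.log(2.0)
    if np.isscalar(x):
        return float(out)
    return out


def window_mask(grid, ind_max: float, min_index: float = 0.1, mode: str = "triangle"):
    """Boolean cell mask for the voting window (k, l >= min_index)."""
    k = grid.k_values
    kk, ll = np.meshgrid(k, k, indexing="ij")
    base = (kk >= min_index - 1e-9) & (ll >= min_index - 1e-9)
    if mode == "triangle":
        return base & (kk + ll <= ind_max + 1e-9)
    return base & (np.maximum(kk, ll) <= ind_max + 1e-9)


def statistic_from_map(cmap, cfg: ClassifierConfig) -> float:
    """Voting sum over a precomputed cumulant map (no covariance factor)."""
    sm = cfg.sign_maps
    if not np.allclose(sm.grid.k_values, cmap.grid.k_values):
        raise ValueError("sign maps and cumulant map use different grids")
    mask_r = window_mask(cmap.grid, cfg.ind_r_max, cfg.min_index, cfg.window_mode)
    mask_i = window_mask(cmap.grid, cfg.ind_i_max, cfg.min_index, cfg.window_mode)
    g = discount if cfg.weighted else (lambda v: v)
    total = float(
        np.sum(sm.sr[mask_r] * g(cmap.cr[mask_r]))
        + np.sum(sm.si[mask_i] * g(cmap.ci[mask_i]))
    )
    return total


def classify_pair(x, y, cfg: ClassifierConfig) -> DirectionDecision:
    """Decide the direction of the connection between two raw series."""
    xn = normalize_series(np.asarray(getattr(x, "values", x), dtype=float))
    yn = normalize_series(np.asarray(getattr(y, "values", y), dtype=float))
    if xn.size != yn.size:
        raise ValueError("series must have equal length")
    if xn.size < cfg.min_length:
        raise ValueError(f"need at least {cfg.min_length} samples")
    cmap = fractional_cumulants(xn, yn, cfg.sign_maps.grid)
    stat = statistic_from_map(cmap, cfg)
    if cfg.cov_weighted:
        stat *= float(np.mean(xn * yn))
    return DirectionDecision.from_statistic(stat)
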