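"""Fractional complex moments and cumulants of normalized time series.

A normalized (mean 0, variance 1) series contains negative samples, so
non-integer powers are complex.  Powers of negative bases use the principal
branch ``(-a)^k = a^k exp(i pi k)`` (a > 0), which makes the moment curve
continuous in k and cross the real axis at every integer order.

The pairwise "fractional cumulant" map

    C_kl = (1/N) sum_i ( x_i^k y_i^l - x_i^l y_i^k )

is exactly antisymmetric in (k, l) and quantifies directional asymmetry
between the distributions of the two series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MomentGrid",
    "MomentCurve",
    "CumulantMap",
    "DegenerateSeriesError",
    "normalize_series",
    "complex_power",
    "power_matrix",
    "fractional_moments",
    "fractional_cumulants",
]

#: tolerances for accepting a series as "normalized"
_MEAN_TOL = 1e-8
_VAR_TOL = 1e-6


class DegenerateSeriesError(ValueError):
    """Raised for constant (zero-variance) input series."""


@dataclass(frozen=True)
class MomentGrid:
    """Ordered grid of moment orders k (default 0.0 ... 5.0, step 0.1)."""

    k_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)
    )

    def __post_init__(self) -> None:
        k = np.asarray(self.k_values, dtype=float)
        if k.ndim != 1 or k.size < 2:
            raise ValueError("grid must be a 1-D array with at least two orders")
        if np.any(np.diff(k) <= 0):
            raise ValueError("grid orders must be strictly increasing")
        if k[0] < 0:
            raise ValueError("moment orders must be non-negative")
        object.__setattr__(self, "k_values", k)

    def __len__(self) -> int:
        return self.k_values.size

    def index_of(self, k: float) -> int:
        idx = int(np.argmin(np.abs(self.k_values - k)))
        if abs(self.k_values[idx] - k) > 1e-9:
            raise KeyError(f"order {k} not on grid")
        return idx


def default_grid() -> MomentGrid:
    return MomentGrid()


@dataclass(frozen=True)
class MomentCurve:
    """Complex moment value per grid order, for a series of length n."""

    values: np.ndarray  # complex, shape (len(grid),)
    grid: MomentGrid
    n: int

    def at(self, k: float) -> complex:
        return complex(self.values[self.grid.index_of(k)])


@dataclass(frozen=True)
class CumulantMap:
    """Antisymmetric complex map C[a, b] = C_{k_a, k_b} over a shared grid.

    Node order matters: the first series is "X", the second "Y"; swapping
    them negates the whole map.
    """

    values: np.ndarray  # complex, shape (nk, nk)
    grid: MomentGrid
    labels: tuple[str, str] = ("x", "y")

    @property
    def cr(self) -> np.ndarray:
        """Real component (Cr)."""
        return self.values.real

    @property
    def ci(self) -> np.ndarray:
        """Imaginary component (Ci)."""
        return self.values.imag

    def at(self, k: float, l: float) -> complex:
        return complex(self.values[self.grid.index_of(k), self.grid.index_of(l)])


def _as_array(ts) -> np.ndarray:
    """Accept a plain array or anything exposing ``.values`` (TimeSeries)."""
    if hasattr(ts, "values") and not isinstance(ts, np.ndarray):
        ts = ts.values
    arr = np.asarray(ts, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D series")
    if not np.all(np.isfinite(arr)):
        raise ValueError("series contains non-finite values")
    return arr


def normalize_series(ts):
    """Shift/scale to mean 0 and population (1/N) variance 1.

    Returns the same kind of object it was given: a bare ndarray for array
    input, or a new TimeSeries for TimeSeries input.
    """
    arr = _as_array(ts)
    if arr.size < 2:
        raise ValueError("need at least two samples to normalize")
    sd = arr.std()  # population convention, ddof=0
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSeriesError("constant series cannot be normalized")
    out = (arr - arr.mean()) / sd
    if hasattr(ts, "values") and not isinstance(ts, np.ndarray):
        import dataclasses

        return dataclasses.replace(ts, values=out)
    return out


def is_normalized(arr: np.ndarray) -> bool:
    arr = np.asarray(arr, dtype=float)
    return bool(
        abs(arr.mean()) <= _MEAN_TOL and abs(arr.var() - 1.0) <= _VAR_TOL
    )


def complex_power(x, k: float):
    """Principal-branch power: x >= 0 -> x^k, x < 0 -> |x|^k exp(i pi k).

    0^0 is 1 by convention.  Scalar in -> scalar out; array in -> array out.
    """
    if k < 0:
        raise ValueError("order k must be non-negative")
    arr = np.asarray(x, dtype=float)
    phase = np.where(arr < 0, np.exp(1j * np.pi * k), 1.0 + 0j)
    out = np.abs(arr) ** k * phase
    if np.isscalar(x) or arr.ndim == 0:
        return complex(out)
    return out


def power_matrix(arr: np.ndarray, grid: MomentGrid) -> np.ndarray:
    """P[a, i] = arr[i] ** k_a (principal branch), shape (nk, N).

    Vectorized through exp(k * (log|x| + i*pi*[x<0])); zero samples are
    patched afterwards (0^k = 0 for k > 0, 0^0 = 1).
    """
    arr = np.asarray(arr, dtype=float)
    k = grid.k_values
    zero = arr == 0.0
    safe = np.where(zero, 1.0, arr)
    logz = np.log(np.abs(safe)) + 1j * np.pi * (safe < 0)
    P = np.exp(np.multiply.outer(k, logz))
    if zero.any():
        P[:, zero] = 0.0
        zi = np.where(zero)[0]
        for a in np.where(k == 0.0)[0]:
            P[a, zi] = 1.0
    return P


def fractional_moments(ts, grid: MomentGrid | None = None) -> MomentCurve:
    """Moment curve M_k = (1/N) sum_i x_i^k over the grid.

    The input must already be normalized (mean 0, variance 1); this is
    checked, not silently fixed.
    """
    arr = _as_array(ts)
    grid = grid or default_grid()
    if not is_normalized(arr):
        raise ValueError("input series must be normalized to mean 0, variance 1")
    P = power_matrix(arr, grid)
    return MomentCurve(values=P.mean(axis=1), grid=grid, n=arr.size)


def fractional_cumulants(
    x, y, grid: MomentGrid | None = None, labels: tuple[str, str] = ("x", "y")
) -> CumulantMap:
    """Full antisymmetric cumulant map for a pair of normalized series."""
    ax, ay = _as_array(x), _as_array(y)
    if ax.size != ay.size:
        raise ValueError(f"length mismatch: {ax.size} vs {ay.size}")
    grid = grid or default_grid()
    for name, arr in (("x", ax), ("y", ay)):
        if not is_normalized(arr):
            raise ValueError(f"series {name!r} must be normalized to mean 0, variance 1")
    Px = power_matrix(ax, grid)
    Py = power_matrix(ay, grid)
    G = Px @ Py.T
    C = (G - G.T) / ax.size
    return CumulantMap(values=C, grid=grid, labels=labels)
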