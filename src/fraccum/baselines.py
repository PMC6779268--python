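"""Reference pairwise direction methods used for comparison.

All methods share one convention: a signed statistic whose sign gives the
verdict (>= 0 -> X -> Y), wrapped in :class:`PairStatistic`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import Direction, discount
from .moments import DegenerateSeriesError, normalize_series

__all__ = [
    "PairStatistic",
    "patel_tau",
    "pw_lr_rskew",
    "granger_bivariate",
    "pdc_bivariate",
    "PAIR_METHODS",
]


@dataclass(frozen=True)
class PairStatistic:
    method: str
    statistic: float
    verdict: Direction

    @classmethod
    def from_statistic(cls, method: str, statistic: float) -> "PairStatistic":
        verdict = Direction.X_TO_Y if statistic >= 0 else Direction.Y_TO_X
        return cls(method=method, statistic=float(statistic), verdict=verdict)


def _pair(x, y, min_len=20):
    ax = np.asarray(getattr(x, "values", x), dtype=float)
    ay = np.asarray(getattr(y, "values", y), dtype=float)
    if ax.ndim != 1 or ay.ndim != 1:
        raise ValueError("expected 1-D series")
    if ax.size != ay.size:
        raise ValueError("series must have equal length")
    if ax.size < min_len:
        raise ValueError(f"need at least {min_len} samples")
    return ax, ay


# ---------------------------------------------------------------------------
# Patel's tau
# ---------------------------------------------------------------------------


def _patel_rescale(v: np.ndarray) -> np.ndarray:
    """Map to [0, 1]: <=10th pct -> 0, >=90th pct -> 1, linear between."""
    lo, hi = np.percentile(v, [10, 90])
    if hi <= lo:
        raise DegenerateSeriesError("series is flat between the 10th and 90th percentile")
    return np.clip((v - lo) / (hi - lo), 0.0, 1.0)


def patel_tau(x, y, n_thresholds: int = 99) -> PairStatistic:
    """Difference of conditional activation probabilities, integrated over
    all binarization thresholds.

    After rescaling both series to [0, 1], each threshold theta on a dense
    grid in (0, 1) binarizes them; the per-threshold statistic is
    P(Y1 | X1) - P(X1 | Y1) and the final statistic is the average over
    thresholds where both conditionals are defined.  A positive value
    means the Y events engulf the X events, i.e. evidence for X -> Y.
    """
    ax, ay = _pair(x, y)
    zx = _patel_rescale(ax)
    zy = _patel_rescale(ay)
    thetas = np.arange(1, n_thresholds + 1) / (n_thresholds + 1)
    bx = zx[None, :] > thetas[:, None]
    by = zy[None, :] > thetas[:, None]
    n_x = bx.sum(axis=1).astype(float)
    n_y = by.sum(axis=1).astype(float)
    n_xy = (bx & by).sum(axis=1).astype(float)
    valid = (n_x > 0) & (n_y > 0)
    if not valid.any():
        return PairStatistic.from_statistic("patel_tau", 0.0)
    tau = n_xy[valid] / n_x[valid] - n_xy[valid] / n_y[valid]
    return PairStatistic.from_statistic("patel_tau", float(tau.mean()))


# ---------------------------------------------------------------------------
# PW-LR r-skew
# ---------------------------------------------------------------------------


def pw_lr_rskew(x, y) -> PairStatistic:
    """Covariance-weighted robust-skewness likelihood-ratio approximation.

    statistic = corr(x, y) * mean( g(x) y - x g(y) ),  g(u) = log cosh(max(u, 0)),

    on normalized series.  Constant prefactors of the likelihood-ratio
    derivation are dropped: they are positive and do not affect the sign,
    which alone determines the verdict.
    """
    ax, ay = _pair(x, y)
    xn = normalize_series(ax)
    yn = normalize_series(ay)
    rho = float(np.mean(xn * yn))
    asym = float(np.mean(discount(xn) * yn - xn * discount(yn)))
    return PairStatistic.from_statistic("pw_lr_rskew", rho * asym)


# ---------------------------------------------------------------------------
# bivariate Granger causality (OLS, lag 1 by default)
# ---------------------------------------------------------------------------


def _lagged_design(series_list, lag):
    """Design matrix [1, s1_{t-1..t-lag}, s2_{t-1..t-lag}, ...] and row count."""
    T = series_list[0].size
    rows = T - lag
    cols = [np.ones(rows)]
    for s in series_list:
        for r in range(1, lag + 1):
            cols.append(s[lag - r : T - r])
    return np.column_stack(cols)


def _ols_rss(X, yv):
    coef, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient regressors in Granger fit")
    resid = yv - X @ coef
    return float(resid @ resid)


def _gc_one_direction(source, target, lag):
    yv = target[lag:]
    restricted = _lagged_design([target], lag)
    full = _lagged_design([target, source], lag)
    rss_r = _ols_rss(restricted, yv)
    rss_f = _ols_rss(full, yv)
    if rss_f <= 0:
        raise ValueError("degenerate residuals in Granger fit")
    return float(np.log(rss_r / rss_f))


def granger_bivariate(x, y, lag: int = 1) -> PairStatistic:
    """Difference of directed log residual-variance ratios, lag-1 OLS."""
    ax, ay = _pair(x, y, min_len=10 * lag + 1)
    gc_xy = _gc_one_direction(ax, ay, lag)
    gc_yx = _gc_one_direction(ay, ax, lag)
    return PairStatistic.from_statistic("granger", gc_xy - gc_yx)


# ---------------------------------------------------------------------------
# bivariate partial directed coherence
# ---------------------------------------------------------------------------


def _fit_var(z: np.ndarray, order: int) -> np.ndarray:
    """OLS VAR fit; returns coefficient matrices, shape (order, n, n).

    Convention: z_t = sum_r A_r z_{t-r} + e_t with A_r[i, j] the effect of
    node j (lagged) on node i.
    """
    T, n = z.shape
    rows = T - order
    X = [np.ones(rows)]
    for r in range(1, order + 1):
        X.append(z[order - r : T - r])
    X = np.column_stack(X)
    Y = z[order:]
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient regressors in VAR fit")
    A = np.empty((order, n, n))
    for r in range(order):
        A[r] = coef[1 + r * n : 1 + (r + 1) * n].T
    return A


def _var_stable(A: np.ndarray, rtol: float = 1e-2) -> bool:
    # near-unit-root fits are routine on smooth, highly autocorrelated BOLD;
    # only clearly explosive fits are rejected
    order, n, _ = A.shape
    companion = np.zeros((order * n, order * n))
    companion[:n] = np.concatenate(list(A), axis=1)
    if order > 1:
        companion[n:, : (order - 1) * n] = np.eye((order - 1) * n)
    return bool(np.all(np.abs(np.linalg.eigvals(companion)) < 1.0 + rtol))


def pdc_spectrum(A: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """PDC(f)[i, j]: column-normalized |Abar_ij(f)|, shape (nf, n, n)."""
    order, n, _ = A.shape
    out = np.empty((freqs.size, n, n))
    for fi, f in enumerate(freqs):
        abar = np.eye(n, dtype=complex)
        for r in range(1, order + 1):
            abar -= A[r - 1] * np.exp(-2j * np.pi * f * r)
        mag = np.abs(abar)
        denom = np.sqrt((mag**2).sum(axis=0))
        out[fi] = mag / denom
    return out


def pdc_bivariate(
    x, y, order: int = 1, band: tuple[float, float] = (0.0, 0.5), n_freqs: int = 64
) -> PairStatistic:
    """Band-averaged PDC asymmetry of a bivariate VAR fit.

    ``band`` is in normalized frequency (0.5 = Nyquist); the default
    averages the whole band.  statistic = <PDC(x->y)> - <PDC(y->x)>.
    """
    ax, ay = _pair(x, y, min_len=10 * order + 1)
    z = np.column_stack([ax, ay])
    A = _fit_var(z, order)
    if not _var_stable(A):
        raise ValueError("fitted VAR model is unstable")
    freqs = np.linspace(band[0], band[1], n_freqs)
    pdc = pdc_spectrum(A, freqs)
    stat = float(pdc[:, 1, 0].mean() - pdc[:, 0, 1].mean())
    return PairStatistic.from_statistic("pdc", stat)


#: name -> callable(x, y) registry for the comparison harness
PAIR_METHODS = {
    "patel_tau": patel_tau,
    "pw_lr_rskew": pw_lr_rskew,
    "granger": granger_bivariate,
    "pdc": pdc_bivariate,
}
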