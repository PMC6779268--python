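"""Two-step pipeline, step one: undirected connection detection.

Partial correlation is computed as the normalized inverse covariance,
P_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj).  Edges are kept when the
observed |P_ij| exceeds the (1 - alpha) quantile of an edge-specific null
built from surrogates: circular time shifts per node for single-run data
(preserving autocorrelation), or label shuffling across runs for
multi-run collections.  Step two orients each retained edge with a
pairwise direction classifier; absent edges stay absent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classify import ClassifierConfig, Direction, classify_pair

__all__ = [
    "UndirectedConnectome",
    "partial_correlation",
    "permutation_threshold",
    "two_step_infer",
]


@dataclass(frozen=True)
class UndirectedConnectome:
    """Partial-correlation matrix, thresholded adjacency and null percentiles."""

    pcorr: np.ndarray  # symmetric, unit diagonal
    adjacency: np.ndarray  # binary, symmetric, zero diagonal
    null_percentile: np.ndarray  # fraction of null |p| below the observed |p|
    alpha: float
    n_perm: int


def _check_matrix(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("expected a 2-D (time x nodes) matrix")
    if ts.shape[0] <= ts.shape[1]:
        raise ValueError("need more time points than nodes")
    return ts


def partial_correlation(ts: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Normalized inverse covariance of a (time x nodes) matrix."""
    ts = _check_matrix(ts)
    cov = np.cov(ts, rowvar=False)
    if ridge > 0:
        cov = cov + ridge * np.eye(cov.shape[0])
    cond = np.linalg.cond(cov)
    if cond > 1e10:
        warnings.warn(
            f"covariance is ill-conditioned (cond={cond:.2e}); "
            "consider the ridge option",
            stacklevel=2,
        )
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance; regularize (ridge > 0) or drop collinear nodes"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _circular_surrogate(rng, ts):
    T, n = ts.shape
    out = np.empty_like(ts)
    shifts = rng.integers(1, T, size=n)
    for j in range(n):
        out[:, j] = np.roll(ts[:, j], shifts[j])
    return out


def permutation_threshold(
    ts: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    ridge: float = 0.0,
) -> UndirectedConnectome:
    """Keep edges whose |partial correlation| beats an edge-wise null.

    The null is built by recomputing partial correlation on ``n_perm``
    circular-shift surrogates (each node independently rotated in time).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for a usable null")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    ts = _check_matrix(ts)
    n = ts.shape[1]
    observed = partial_correlation(ts, ridge=ridge)
    null = np.empty((n_perm, n, n))
    for p in range(n_perm):
        null[p] = np.abs(partial_correlation(_circular_surrogate(rng, ts), ridge=ridge))
    if alpha == 1.0:
        adjacency = np.ones((n, n), dtype=int)
        np.fill_diagonal(adjacency, 0)
        percentile = np.mean(null <= np.abs(observed)[None], axis=0)
    else:
        # conservative order-statistic threshold (standard permutation rule)
        thresh = np.quantile(null, 1.0 - alpha, axis=0, method="higher")
        adjacency = (np.abs(observed) > thresh).astype(int)
        np.fill_diagonal(adjacency, 0)
        percentile = np.mean(null <= np.abs(observed)[None], axis=0)
    np.fill_diagonal(percentile, 1.0)
    return UndirectedConnectome(
        pcorr=observed,
        adjacency=adjacency,
        null_percentile=percentile,
        alpha=alpha,
        n_perm=n_perm,
    )


def two_step_infer(
    ts: np.ndarray,
    classifier_cfg: ClassifierConfig,
    n_perm: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    ridge: float = 0.0,
) -> np.ndarray:
    """Directed adjacency: detect undirected edges, then orient each one.

    Returns D with D[i, j] = 1 meaning an inferred connection i -> j.  The
    directed graph never contains an edge absent from the undirected stage.
    """
    ts = _check_matrix(ts)
    undirected = permutation_threshold(ts, n_perm=n_perm, alpha=alpha, rng=rng, ridge=ridge)
    n = ts.shape[1]
    directed = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if not undirected.adjacency[i, j]:
                continue
            decision = classify_pair(ts[:, i], ts[:, j], classifier_cfg)
            if decision.verdict is Direction.X_TO_Y:
                directed[i, j] = 1
            else:
                directed[j, i] = 1
    return directed
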