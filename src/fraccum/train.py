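"""Supervised training of sign maps and discriminability maps.

The trained classifier state is nothing more than the per-cell majority
sign of the cumulant maps over many simulated realizations of a known
upstream -> downstream connection.  Discriminability scores each cell by
how far the "connection" distribution of its cumulant sticks out of the
"no connection" null distribution (kernel-smoothed 95th/5th percentile
exceedance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from . import __version__ as _pkg_version
from .dcm_sim import simulate_two_node_batch
from .moments import MomentGrid, default_grid, fractional_cumulants, normalize_series

__all__ = [
    "SignMaps",
    "DiscriminabilityMap",
    "collect_cumulant_samples",
    "train_sign_maps",
    "discriminability",
    "tune_window",
    "load_default_sign_maps",
]


@dataclass(frozen=True)
class SignMaps:
    """Ternary majority-sign maps for the real (sr) and imaginary (si) parts."""

    sr: np.ndarray  # int8, values in {-1, 0, +1}, shape (nk, nk)
    si: np.ndarray
    grid: MomentGrid
    n_sims: int
    connection_weight: float

    def to_json(self) -> str:
        payload = {
            "format": "fraccum-sign-maps",
            "version": _pkg_version,
            "grid": [float(k) for k in self.grid.k_values],
            "n_sims": int(self.n_sims),
            "connection_weight": float(self.connection_weight),
            "sr": self.sr.astype(int).tolist(),
            "si": self.si.astype(int).tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SignMaps":
        payload = json.loads(text)
        if payload.get("format") != "fraccum-sign-maps":
            raise ValueError("not a sign-maps file")
        return cls(
            sr=np.asarray(payload["sr"], dtype=np.int8),
            si=np.asarray(payload["si"], dtype=np.int8),
            grid=MomentGrid(np.asarray(payload["grid"], dtype=float)),
            n_sims=int(payload["n_sims"]),
            connection_weight=float(payload["connection_weight"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SignMaps":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class DiscriminabilityMap:
    """Per-cell exceedance fractions in [0, 1] (real and imaginary parts)."""

    dr: np.ndarray
    di: np.ndarray
    grid: MomentGrid


def _default_sim_factory(duration: float, fs: float):
    def factory(rng, n_sims, weight):
        return simulate_two_node_batch(rng, n_sims, weight, duration=duration, fs=fs)

    return factory


def collect_cumulant_samples(
    n_sims: int,
    weight: float,
    rng: np.random.Generator,
    grid: MomentGrid | None = None,
    duration: float = 600.0,
    fs: float = 200.0,
    sim_factory=None,
    batch_size: int = 100,
) -> np.ndarray:
    """Stack of cumulant maps, shape (n_sims, nk, nk) complex.

    Each map comes from an independent two-node simulation with connection
    ``weight`` from the upstream to the downstream node (weight 0 gives the
    null condition).  Simulations run in chunks of ``batch_size`` to bound
    memory.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    grid = grid or default_grid()
    factory = sim_factory or _default_sim_factory(duration, fs)
    nk = len(grid)
    out = np.empty((n_sims, nk, nk), dtype=complex)
    done = 0
    while done < n_sims:
        chunk = min(batch_size, n_sims - done)
        bold_up, bold_down = factory(rng, chunk, weight)
        for i in range(chunk):
            try:
                x = normalize_series(bold_up[i])
                y = normalize_series(bold_down[i])
                out[done + i] = fractional_cumulants(x, y, grid).values
            except Exception as exc:  # annotate with the failing simulation index
                raise RuntimeError(f"simulation {done + i} failed: {exc}") from exc
        done += chunk
    return out


def _majority_sign(component_samples: np.ndarray) -> np.ndarray:
    """Per-cell majority sign over axis 0; exact ties (incl. all-zero) -> 0."""
    n_pos = (component_samples > 0).sum(axis=0)
    n_neg = (component_samples < 0).sum(axis=0)
    return np.sign(n_pos - n_neg).astype(np.int8)


def train_sign_maps(
    n_sims: int = 1000,
    weight: float = 0.9,
    rng: np.random.Generator | None = None,
    grid: MomentGrid | None = None,
    duration: float = 600.0,
    fs: float = 200.0,
    sim_factory=None,
    samples: np.ndarray | None = None,
) -> SignMaps:
    """Majority-sign maps from repeated simulations of a known connection.

    Pass ``samples`` (as returned by :func:`collect_cumulant_samples`) to
    reuse precomputed maps, e.g. when discriminability needs the same draw.
    """
    grid = grid or default_grid()
    if samples is None:
        rng = rng if rng is not None else np.random.default_rng()
        samples = collect_cumulant_samples(
            n_sims, weight, rng, grid, duration=duration, fs=fs, sim_factory=sim_factory
        )
    return SignMaps(
        sr=_majority_sign(samples.real),
        si=_majority_sign(samples.imag),
        grid=grid,
        n_sims=samples.shape[0],
        connection_weight=weight,
    )


# ---------------------------------------------------------------------------
# discriminability
# ---------------------------------------------------------------------------


def _silverman_bw(vals: np.ndarray) -> float:
    sd = vals.std(ddof=1)
    iqr = np.subtract(*np.percentile(vals, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        return 1e-12
    return 0.9 * spread * vals.size ** (-0.2)


def _kde_cdf(vals: np.ndarray, bw: float, t: np.ndarray) -> np.ndarray:
    """Gaussian-kernel-smoothed empirical CDF evaluated at points t."""
    return ndtr((t[:, None] - vals[None, :]) / bw).mean(axis=1)


def _kde_quantile(vals: np.ndarray, q: float) -> float:
    bw = _silverman_bw(vals)
    lo = vals.min() - 5 * bw
    hi = vals.max() + 5 * bw
    t = np.linspace(lo, hi, 513)
    cdf = _kde_cdf(vals, bw, t)
    return float(np.interp(q, cdf, t))


def _cell_discriminability(null_vals: np.ndarray, conn_vals: np.ndarray) -> float:
    if np.ptp(null_vals) == 0 and np.ptp(conn_vals) == 0:
        return 0.0
    if conn_vals.mean() >= 0:
        q = _kde_quantile(null_vals, 0.95)
        bw = _silverman_bw(conn_vals)
        return float(1.0 - _kde_cdf(conn_vals, bw, np.array([q]))[0])
    q = _kde_quantile(null_vals, 0.05)
    bw = _silverman_bw(conn_vals)
    return float(_kde_cdf(conn_vals, bw, np.array([q]))[0])


def discriminability(
    null_samples: np.ndarray, conn_samples: np.ndarray, grid: MomentGrid | None = None
) -> DiscriminabilityMap:
    """Kernel-smoothed tail-exceedance map.

    ``null_samples`` and ``conn_samples`` are stacks of cumulant maps
    (n, nk, nk), complex, from the no-connection and connection conditions.
    Per cell and component: the fraction of connection-condition samples
    beyond the null's 95th percentile (below the 5th when the connection
    mean is negative).
    """
    null_samples = np.asarray(null_samples)
    conn_samples = np.asarray(conn_samples)
    if null_samples.shape[0] < 50 or conn_samples.shape[0] < 50:
        raise ValueError("need at least 50 samples per condition")
    if null_samples.shape[1:] != conn_samples.shape[1:]:
        raise ValueError("sample stacks must share the grid shape")
    nk = null_samples.shape[1]
    grid = grid or default_grid()
    if len(grid) != nk:
        raise ValueError("grid size does not match sample stack")
    dr = np.zeros((nk, nk))
    di = np.zeros((nk, nk))
    for a in range(nk):
        for b in range(nk):
            if a == b:
                continue
            dr[a, b] = _cell_discriminability(
                null_samples[:, a, b].real, conn_samples[:, a, b].real
            )
            di[a, b] = _cell_discriminability(
                null_samples[:, a, b].imag, conn_samples[:, a, b].imag
            )
    return DiscriminabilityMap(dr=dr, di=di, grid=grid)


# ---------------------------------------------------------------------------
# window / cutoff tuning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TuneResult:
    best_ind_r: float
    best_ind_i: float
    best_cutoff: float
    weighted: bool
    best_score: float
    surface: list  # (ind_r, ind_i, cutoff, weighted, score) tuples


def tune_window(
    sign_maps: SignMaps,
    disc_map: DiscriminabilityMap | None,
    evaluator,
    cutoffs=(0.0,),
    index_grid=None,
    weighted_options=(False, True),
) -> TuneResult:
    """Exhaustive search over cutoff and (IndR_max, IndI_max) windows.

    ``evaluator(cfg)`` must return a grand-mean success rate for a
    :class:`~fraccum.classify.ClassifierConfig`; the argmax configuration
    plus the full performance surface are returned.
    """
    from .classify import ClassifierConfig

    if index_grid is None:
        index_grid = [(r, i) for r in (1.1, 2.1, 3.1) for i in (1.1, 2.1, 3.1)]
    if len(index_grid) == 0 or len(cutoffs) == 0:
        raise ValueError("index_grid and cutoffs must be non-empty")
    surface = []
    best = None
    for weighted in weighted_options:
        for cutoff in cutoffs:
            sm = sign_maps
            if cutoff > 0:
                if disc_map is None:
                    raise ValueError("a discriminability map is required for cutoff > 0")
                keep_r = disc_map.dr >= cutoff
                keep_i = disc_map.di >= cutoff
                sm = SignMaps(
                    sr=np.where(keep_r, sign_maps.sr, 0).astype(np.int8),
                    si=np.where(keep_i, sign_maps.si, 0).astype(np.int8),
                    grid=sign_maps.grid,
                    n_sims=sign_maps.n_sims,
                    connection_weight=sign_maps.connection_weight,
                )
            for ind_r, ind_i in index_grid:
                cfg = ClassifierConfig(
                    sign_maps=sm, ind_r_max=ind_r, ind_i_max=ind_i, weighted=weighted
                )
                score = float(evaluator(cfg))
                surface.append((ind_r, ind_i, cutoff, weighted, score))
                if best is None or score > best[-1]:
                    best = (ind_r, ind_i, cutoff, weighted, score)
    return TuneResult(
        best_ind_r=best[0],
        best_ind_i=best[1],
        best_cutoff=best[2],
        weighted=best[3],
        best_score=best[4],
        surface=surface,
    )


def load_default_sign_maps() -> SignMaps:
    """Sign maps shipped with the package (regenerable via the CLI)."""
    from importlib import resources

    text = resources.files("fraccum.data").joinpath("sign_maps.json").read_text()
    return SignMaps.from_json(text)
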