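"""Generative forward model for synthetic BOLD from directed neuronal graphs.

Neuronal dynamics are linear, ``dz/dt = r (A z + u(t)) + sigma(t)`` with
``A[i, j]`` the weight of the connection j -> i (diagonal = negative
self-inhibition) and r the neural rate constant (default 20/s, i.e. a
50 ms neuronal lag).  Background noise sigma(t) enters the derivative
unscaled, the convention of the benchmark generative model.  Each node's neuronal state drives a Balloon-Windkessel
hemodynamic cascade (vasodilatory signal s, inflow f, volume v,
deoxyhemoglobin q) whose positive states are integrated in log space for
stability; the BOLD readout is

    y = V0 * (k1 (1 - q) + k2 (1 - q / v) + k3 (1 - v)),
    k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.

Inputs u(t) are binary on/off trains switched by a two-state Markov process
(per-second rates), scaled by a per-node magnitude; background neuronal
noise sigma(t) is optional white or scale-free (1/f) noise of a requested
variance.  Everything is an explicit Euler pass at dt = 1/fs and is fully
reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "TimeSeries",
    "HemoParams",
    "DCMConfig",
    "SimulationResult",
    "load_hemo_priors",
    "sample_hemo_params",
    "sample_input_process",
    "generate_pink_noise",
    "simulate_network",
    "simulate_two_node_batch",
    "two_node_adjacency",
]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


class SimulationError(RuntimeError):
    """Numerical failure during forward integration."""


@dataclass(frozen=True)
class TimeSeries:
    """One node's sampled signal with its sampling rate."""

    values: np.ndarray
    fs: float
    node_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class HemoParams:
    """Balloon-Windkessel parameters for a single node."""

    kappa: float  # vasodilatory signal decay (1/s)
    gamma: float  # flow autoregulation (1/s)
    tau: float  # mean transit time (s)
    alpha: float  # Grubb vessel stiffness exponent
    e0: float  # resting oxygen extraction fraction
    v0: float = 0.02  # resting venous volume fraction

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "alpha", "e0", "v0"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"hemodynamic parameter {name} must be > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.e0 < 1:
            raise ConfigurationError("e0 must lie in (0, 1)")


def load_hemo_priors(path: str | None = None) -> dict:
    """Load the hemodynamic prior table (packaged default or a user file)."""
    if path is None:
        text = resources.files("fraccum.data").joinpath("hemo_priors.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    priors = yaml.safe_load(text)
    for name, spec in priors.items():
        if spec["var"] < 0:
            raise ConfigurationError(f"prior variance for {name} must be >= 0")
    return priors


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled truncated normal; degenerate sd -> constant mean."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out >= high)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out >= high)
        tries += 1
        if tries > 1000:
            raise ConfigurationError("prior truncation rejects almost all samples")
    return out


def sample_hemo_params(
    rng: np.random.Generator, n_nodes: int, priors: dict | None = None
) -> list[HemoParams]:
    """Independent per-node draws from the (truncated) empirical priors."""
    if n_nodes < 1:
        raise ConfigurationError("n_nodes must be >= 1")
    priors = priors or load_hemo_priors()
    draws = {}
    for name, spec in priors.items():
        if spec["var"] < 0:
            raise ConfigurationError(f"prior variance for {name} must be >= 0")
        draws[name] = _truncated_normal(
            rng, spec["mean"], np.sqrt(spec["var"]), spec["low"], spec["high"], n_nodes
        )
    return [
        HemoParams(**{name: float(draws[name][i]) for name in draws})
        for i in range(n_nodes)
    ]


# ---------------------------------------------------------------------------
# input and noise processes
# ---------------------------------------------------------------------------


def _binary_markov_batch(rng, shape, n_steps, p_on_off, p_off_on, initial="off"):
    """Vectorized two-state Markov chains.

    ``p_on_off``/``p_off_on`` are per-step switch probabilities broadcastable
    to ``shape``; returns a {0,1} array of shape ``shape + (n_steps,)``.
    """
    p_on_off = np.clip(np.broadcast_to(p_on_off, shape), 0.0, 1.0)
    p_off_on = np.clip(np.broadcast_to(p_off_on, shape), 0.0, 1.0)
    out = np.empty(shape + (n_steps,), dtype=np.float64)
    if initial == "off":
        state = np.zeros(shape, dtype=bool)
    elif initial == "on":
        state = np.ones(shape, dtype=bool)
    else:
        raise ConfigurationError(f"unknown initial state {initial!r}")
    u = rng.random(shape + (n_steps,))
    for t in range(n_steps):
        out[..., t] = state
        p_switch = np.where(state, p_on_off, p_off_on)
        state = state ^ (u[..., t] < p_switch)
    return out


def sample_input_process(
    rng: np.random.Generator,
    fs: float,
    duration: float,
    magnitude: float | None = None,
    rate_on_off: float | None = None,
    rate_off_on: float | None = None,
    gamma_shape: float = 1.0,
    gamma_scale: float = 1.0,
    node_id: str | None = None,
) -> TimeSeries:
    """Binary Poisson-switching input train scaled by its magnitude.

    Magnitude and the two per-second switch rates default to independent
    Gamma(shape=1, scale=1) draws (mean 1, variance 1); pass explicit values
    to pin any of them.  Switching is realized as per-step Bernoulli
    transitions with probability rate/fs.
    """
    if fs <= 0 or duration <= 0:
        raise ConfigurationError("fs and duration must be positive")
    m = rng.gamma(gamma_shape, gamma_scale) if magnitude is None else float(magnitude)
    r_on = rng.gamma(gamma_shape, gamma_scale) if rate_on_off is None else float(rate_on_off)
    r_off = rng.gamma(gamma_shape, gamma_scale) if rate_off_on is None else float(rate_off_on)
    if m < 0 or r_on < 0 or r_off < 0:
        raise ConfigurationError("magnitude and rates must be non-negative")
    n_steps = int(round(duration * fs))
    states = _binary_markov_batch(rng, (), n_steps, r_on / fs, r_off / fs)
    return TimeSeries(values=m * states, fs=fs, node_id=node_id)


def _pink_noise_batch(rng, shape, n, variance):
    """Spectrally shaped 1/f noise, exact target variance per series."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^{-1/2} => PSD ~ 1/f
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    target = np.sqrt(np.broadcast_to(np.asarray(variance, float), shape))
    return pink / sd * target[..., None] if shape else pink / sd * np.sqrt(variance)


def generate_pink_noise(
    rng: np.random.Generator, n: int, variance: float, fs: float = 1.0
) -> TimeSeries:
    """Zero-mean noise with PSD ~ 1/f, rescaled to the exact target variance."""
    if n < 16:
        raise ConfigurationError("need n >= 16 samples for spectral shaping")
    if variance < 0:
        raise ConfigurationError("variance must be >= 0")
    if variance == 0:
        return TimeSeries(values=np.zeros(n), fs=fs, node_id="pink")
    values = _pink_noise_batch(rng, (), n, variance)
    values = values - values.mean()
    # re-impose the exact variance after demeaning
    values *= np.sqrt(variance) / values.std()
    return TimeSeries(values=values, fs=fs, node_id="pink")


# ---------------------------------------------------------------------------
# configuration and integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DCMConfig:
    """Full description of one forward simulation.

    ``adjacency[i, j]`` is the weight of connection j -> i; the diagonal
    holds (negative) self-inhibition.  ``input_magnitude`` and
    ``input_switch_rates`` may be None, in which case they are drawn per
    node from Gamma(1, 1) at simulation time.
    """

    adjacency: np.ndarray
    fs: float = 200.0
    duration: float = 600.0
    input_magnitude: np.ndarray | None = None  # (n,)
    input_switch_rates: np.ndarray | None = None  # (n, 2): on->off, off->on per s
    noise_variance: np.ndarray | float = 0.0  # per node or scalar
    noise_kind: str = "none"  # none | white | pink
    neural_rate: float = 20.0  # 1/s; 20 -> 50 ms neuronal lag
    base_switch_rates: tuple[float, float] = (0.4, 0.1)  # on->off, off->on (1/s)
    seed: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ConfigurationError("adjacency must be a square matrix")
        if np.any(np.diag(A) >= 0):
            raise ConfigurationError("adjacency diagonal must be negative (stable self-decay)")
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        if self.noise_kind not in ("none", "white", "pink"):
            raise ConfigurationError(f"unknown noise_kind {self.noise_kind!r}")
        if np.any(np.asarray(self.noise_variance, float) < 0):
            raise ConfigurationError("noise_variance must be >= 0")
        if self.neural_rate <= 0:
            raise ConfigurationError("neural_rate must be positive")
        if self.neural_rate / self.fs >= 2.0:
            raise ConfigurationError("neural_rate too fast for the Euler step (rate/fs >= 2)")
        object.__setattr__(self, "adjacency", A)
        if self.input_magnitude is not None:
            m = np.asarray(self.input_magnitude, dtype=float)
            if m.shape != (A.shape[0],):
                raise ConfigurationError("input_magnitude must have one entry per node")
            object.__setattr__(self, "input_magnitude", m)
        if self.input_switch_rates is not None:
            r = np.asarray(self.input_switch_rates, dtype=float)
            if r.shape != (A.shape[0], 2):
                raise ConfigurationError("input_switch_rates must be (n_nodes, 2)")
            object.__setattr__(self, "input_switch_rates", r)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_steps(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class SimulationResult:
    """BOLD, neuronal states and inputs of one simulation (time x nodes)."""

    bold: np.ndarray
    neuronal: np.ndarray
    inputs: np.ndarray
    noise: np.ndarray
    fs: float
    config: DCMConfig
    hemo: list[HemoParams]

    def bold_series(self, node: int) -> TimeSeries:
        return TimeSeries(values=self.bold[:, node], fs=self.fs, node_id=f"node{node}")


def two_node_adjacency(weight: float, self_inhibition: float = -1.0) -> np.ndarray:
    """Adjacency for upstream node 0 driving downstream node 1."""
    return np.array([[self_inhibition, 0.0], [weight, self_inhibition]])


def _hemo_arrays(hemo_list, batch_shape):
    """Stack per-node HemoParams into broadcastable arrays of shape (..., n)."""
    names = ("kappa", "gamma", "tau", "alpha", "e0", "v0")
    out = {}
    for name in names:
        vals = np.array([[getattr(h, name) for h in row] for row in hemo_list])
        out[name] = np.broadcast_to(vals, batch_shape + (vals.shape[-1],)).astype(float)
    return out


_LOG_FLOOR = np.log(1e-2)
_LOG_CAP = np.log(1e3)


def _integrate(adjacency, drive, noise, hemo, fs, neural_rate=20.0, check_every=200):
    """Euler pass of the neuronal + hemodynamic system.

    ``drive`` (B, T, n) holds the exogenous inputs, which are scaled by the
    neural rate like the recurrent term; ``noise`` (same shape, or None)
    enters the derivative unscaled.  ``hemo`` is a dict of arrays
    broadcastable to (B, n).  Returns (bold, neuronal), both (B, T, n).
    Hemodynamic states f, v, q are integrated in log space so they remain
    positive.
    """
    B, T, n = drive.shape
    dt = 1.0 / fs
    A = np.asarray(adjacency, dtype=float)
    kappa, gamma_, tau = hemo["kappa"], hemo["gamma"], hemo["tau"]
    alpha, e0, v0 = hemo["alpha"], hemo["e0"], hemo["v0"]
    inv_alpha = 1.0 / alpha
    k1 = 7.0 * e0
    k2 = 2.0
    k3 = 2.0 * e0 - 0.2

    z = np.zeros((B, n))
    s = np.zeros((B, n))
    lf = np.zeros((B, n))
    lv = np.zeros((B, n))
    lq = np.zeros((B, n))
    bold = np.empty((B, T, n))
    neuronal = np.empty((B, T, n))

    for t in range(T):
        neuronal[:, t] = z
        f = np.exp(lf)
        v = np.exp(lv)
        q = np.exp(lq)
        bold[:, t] = v0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))

        ffv = v ** (inv_alpha - 1.0)  # outflow v^{1/alpha} / v
        ex = 1.0 - (1.0 - e0) ** (1.0 / f)  # oxygen extraction E(f)
        dz = neural_rate * (z @ A.T + drive[:, t])
        if noise is not None:
            dz = dz + noise[:, t]
        ds = z - kappa * s - gamma_ * (f - 1.0)
        dlf = s / f
        dlv = (f - ffv * v) / (tau * v)
        dlq = (f * ex / (e0 * q) - ffv) / tau

        z = z + dt * dz
        s = s + dt * ds
        # keep flow/volume/deoxy inside the physical domain of the balloon
        # model: large transients can push f through zero in the linear
        # formulation, so the log-states saturate at 1e-2..1e3 of baseline
        lf = np.clip(lf + dt * dlf, _LOG_FLOOR, _LOG_CAP)
        lv = np.clip(lv + dt * dlv, _LOG_FLOOR, _LOG_CAP)
        lq = np.clip(lq + dt * dlq, _LOG_FLOOR, _LOG_CAP)

        if (t % check_every == check_every - 1 or t == T - 1) and not (
            np.all(np.isfinite(z)) and np.all(np.isfinite(lq))
        ):
            raise SimulationError(f"non-finite state at or before step {t}")
    return bold, neuronal


def _make_drive(rng, cfg_like, B):
    """Inputs and noise for B independent realizations of one configuration.

    Returns (inputs, noise), each (B, T, n).  Magnitudes and switch rates
    are drawn per realization/node from Gamma(1, 1) when unspecified.
    """
    n, T, fs = cfg_like.n_nodes, cfg_like.n_steps, cfg_like.fs
    if cfg_like.input_magnitude is None:
        mag = rng.gamma(1.0, 1.0, (B, n))
    else:
        mag = np.broadcast_to(cfg_like.input_magnitude, (B, n)).copy()
    if cfg_like.input_switch_rates is None:
        # one Gamma(1, 1) frequency multiplier per input train, applied to the
        # bursty base rates: switching frequency is marginalized across
        # realizations while the on/off duty ratio stays benchmark-like
        # (short on-bursts, long off-periods)
        freq = rng.gamma(1.0, 1.0, (B, n, 1))
        rates = freq * np.asarray(cfg_like.base_switch_rates)
    else:
        rates = np.broadcast_to(cfg_like.input_switch_rates, (B, n, 2)).copy()
    states = _binary_markov_batch(
        rng, (B, n), T, rates[..., 0] / fs, rates[..., 1] / fs
    )
    inputs = np.swapaxes(states * mag[..., None], 1, 2)  # (B, T, n)

    var = np.broadcast_to(np.asarray(cfg_like.noise_variance, float), (n,))
    if cfg_like.noise_kind == "none" or np.all(var == 0):
        noise = np.zeros((B, T, n))
    elif cfg_like.noise_kind == "white":
        noise = rng.standard_normal((B, n, T)) * np.sqrt(var)[None, :, None]
        noise = np.swapaxes(noise, 1, 2)
    else:  # pink
        pink = _pink_noise_batch(rng, (B, n), T, var[None, :])
        noise = np.swapaxes(pink, 1, 2)
    return inputs, noise


def simulate_network(
    config: DCMConfig,
    hemo: list[HemoParams] | None = None,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Forward-simulate one network; reproducible from (config, seed)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if hemo is None:
        hemo = sample_hemo_params(rng, config.n_nodes)
    if len(hemo) != config.n_nodes:
        raise ConfigurationError("need one HemoParams per node")
    inputs, noise = _make_drive(rng, config, B=1)
    hemo_arr = _hemo_arrays([hemo], (1,))
    bold, neuronal = _integrate(
        config.adjacency, inputs, noise, hemo_arr, config.fs, config.neural_rate
    )
    return SimulationResult(
        bold=bold[0],
        neuronal=neuronal[0],
        inputs=inputs[0],
        noise=noise[0],
        fs=config.fs,
        config=config,
        hemo=hemo,
    )


def simulate_two_node_batch(
    rng: np.random.Generator,
    n_sims: int,
    weight: float,
    duration: float = 600.0,
    fs: float = 200.0,
    input_magnitude: np.ndarray | None = None,
    noise_variance: np.ndarray | float = 0.0,
    noise_kind: str = "none",
    self_inhibition: float = -1.0,
    neural_rate: float = 20.0,
    priors: dict | None = None,
    resample_degenerate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch of independent two-node simulations (node 0 -> node 1).

    Hemodynamic parameters, input magnitudes and switch rates are drawn
    independently per realization and node.  Returns ``(bold_up, bold_down)``
    arrays of shape (n_sims, T); used for classifier training and the
    robustness grids, where per-realization Python overhead would dominate.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be >= 1")
    cfg = DCMConfig(
        adjacency=two_node_adjacency(weight, self_inhibition),
        fs=fs,
        duration=duration,
        input_magnitude=input_magnitude,
        noise_variance=noise_variance,
        noise_kind=noise_kind,
        neural_rate=neural_rate,
    )
    priors = priors or load_hemo_priors()

    def run(batch):
        hemo_rows = [sample_hemo_params(rng, 2, priors) for _ in range(batch)]
        hemo_arr = _hemo_arrays(hemo_rows, (batch,))
        inputs, noise = _make_drive(rng, cfg, B=batch)
        bold, _ = _integrate(cfg.adjacency, inputs, noise, hemo_arr, fs, neural_rate)
        return bold

    bold = run(n_sims)
    if resample_degenerate:
        # a tiny fraction of switch-rate draws never turn the input on,
        # leaving a flat BOLD; replace those realizations with fresh draws
        for _ in range(50):
            flat = bold.std(axis=1).min(axis=1) < 1e-12
            if not flat.any():
                break
            bold[flat] = run(int(flat.sum()))
        else:
            raise SimulationError("could not draw non-degenerate realizations")
    return bold[:, :, 0], bold[:, :, 1]
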