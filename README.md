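# fraccum

Pairwise effective-connectivity inference for fMRI-style BOLD time series,
based on fractional complex moments of the signal distributions combined
into antisymmetric cumulants.

A normalized series x̂ (mean 0, variance 1) has complex fractional moments
`M_k = (1/N) Σ x̂_i^k` (principal branch for negative samples). For a pair
(X, Y) the fractional cumulants

```
C_kl = (1/N) Σ ( x̂_i^k ŷ_i^l − x̂_i^l ŷ_i^k )
```

form an antisymmetric complex map over a (k, l) grid (default 0.0–5.0,
step 0.1). A supervised classifier compares the sign pattern of this map
against ternary *sign maps* trained on many forward simulations of a known
upstream → downstream connection: each cell votes for X→Y when its sign
matches the trained pattern, optionally discounted through
`f(x) = log cosh(max(x, 0))`, and the sign of the voting sum is the
verdict.

The package contains:

- `fraccum.dcm_sim` — generative forward model (linear neuronal dynamics
  with 50 ms lag + Balloon–Windkessel hemodynamics per node, hemodynamic
  parameters sampled from empirical priors, binary Poisson-switching
  inputs, optional white/pink background neuronal noise). Fully
  reproducible from a seed; a vectorized batch path
  (`simulate_two_node_batch`) backs training and the grid experiments.
- `fraccum.moments` — normalization, complex powers, fractional moment
  curves and cumulant maps.
- `fraccum.train` — sign-map training (majority sign over simulations),
  kernel-smoothed discriminability maps, and window/cutoff tuning.
- `fraccum.classify` — the voting classifier (weighted / unweighted,
  index windows, optional covariance weighting).
- `fraccum.connectome` — two-step pipeline: partial correlation
  (normalized inverse covariance) with per-edge permutation thresholding,
  then pairwise orientation of the detected edges.
- `fraccum.baselines` — Patel's tau (threshold-integrated), PW-LR r-skew,
  bivariate lag-1 Granger causality, bivariate PDC.
- `fraccum.experiments` — success rates, per-cumulant scoring, z-scores,
  and the two robustness grids (background-noise variance and input
  strength sweeps over [0.2, 5.0]).
- `fraccum.io` / `fraccum.cli` — delimited-text and benchmark-MAT
  readers/writers and the umbrella CLI.

Trained sign maps are shipped as package data
(`src/fraccum/data/sign_maps.json`, regenerable with the CLI) together
with the hemodynamic prior table (`hemo_priors.yaml`).

## CLI

All commands share a global `--seed`; identical invocations are
bit-reproducible.

```bash
# forward-simulate a configured network to TSV (+ JSON metadata sidecar)
fraccum --seed 1 simulate --config sim.yaml --out bold.tsv

# train sign maps (defaults mirror the full protocol: 1000 sims, 10 min)
fraccum --seed 1 train --n-sims 500 --duration 240 --out maps.json

# cumulant map of a two-column file as (k, l, Re, Im) CSV
fraccum cumulants --input bold.tsv --out cumulants.csv

# direction verdicts (JSON lines; packaged maps by default)
fraccum classify --input bold.tsv --weighted

# two-step pipeline: detect undirected edges, orient them
fraccum --seed 1 connectome --input bold.tsv --alpha 0.05 --out adjacency.csv

# baseline comparison on every node pair
fraccum compare --input bold.tsv --out edges.csv

# robustness grids (one CSV per method)
fraccum --seed 1 grid --mode noise --n-real 50 --out-prefix results/grid
```

A simulation config is YAML, e.g.

```yaml
adjacency: [[-1.0, 0.0], [0.9, -1.0]]   # row receives from column
fs: 200.0
duration: 600.0
input_magnitude: [1.0, 1.0]             # omit to sample Gamma(1,1) per node
noise_kind: pink
noise_variance: [0.5, 0.5]
```

The time-series text format is a header row of node labels and one row
per time point.

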