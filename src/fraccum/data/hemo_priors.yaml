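# Empirical priors of the Balloon-Windkessel hemodynamic parameters
# (means and prior variances of the canonical bilinear DCM formulation).
# Draws are truncated-normal, constrained to `low`/`high`.
kappa:   {mean: 0.65, var: 0.015,  low: 1.0e-3, high: .inf}   # signal decay, 1/s
gamma:   {mean: 0.41, var: 0.002,  low: 1.0e-3, high: .inf}   # autoregulation, 1/s
tau:     {mean: 0.98, var: 0.0568, low: 1.0e-3, high: .inf}   # transit time, s
alpha:   {mean: 0.32, var: 0.0015, low: 1.0e-3, high: 0.999}  # vessel stiffness
e0:      {mean: 0.34, var: 0.0024, low: 1.0e-3, high: 0.999}  # resting O2 extraction
v0:      {mean: 0.02, var: 0.0,    low: 1.0e-6, high: 1.0}    # resting blood volume
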