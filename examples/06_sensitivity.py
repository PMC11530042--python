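"""Sensitivity of predicted concentrations to half-life and diffusivities.

50 log-normal scaling factors per parameter, thinned to the 0–100th
percentiles in steps of 10 (11 runs); each run re-simulates the bone-plate
scenario and the index = output %-change / input %-change is evaluated at
several times. Positive indices mean the output moves with the parameter.
"""

from vancoelute import (
    default_prior,
    default_sensitivity_config,
    percentile_factors,
    run_sensitivity,
    sample_scaling_factors,
)

cfg = default_sensitivity_config()
for name in ("half_life", "D_tissue", "D_cortical"):
    prior = default_prior(name, cfg)
    factors = percentile_factors(sample_scaling_factors(prior, n=50, seed=1))
    run = run_sensitivity(cfg, prior, factors, output_times=[1.0, 24.0])
    print(f"{name:12s} mean index at 1 h: {run.indices_at(1.0).mean():+.3f}; "
          f"at 24 h: {run.indices_at(24.0).mean():+.3f}; "
          f"R^2(24 h) = {run.regression['r2'].iloc[-1]:.3f} "
          f"(adj {run.regression['adj_r2'].iloc[-1]:.3f})")
# Half-life indices are positive and grow with time (clearance compounds);
# diffusivity indices are negative (faster spread dilutes the local
# concentration). Close R² vs adjusted R² says fewer points would suffice.
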