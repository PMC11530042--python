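# Methods

## Model and assumptions

The package models local antibiotic delivery as one-phase Fickian diffusion
with spatially uniform first-order elimination. The governing balance per
grid cell combines Fick's second law with a clearance sink derived from the
half-life law `m(t) = m0·(½)^(t/t_half)`:

    ∂C/∂t = ∇·(D ∇C) − (ln 2 / t_half)·C

Assumptions worth keeping in mind:

* **No binding kinetics.** Vancomycin adsorption to hydroxyapatite is not
  modelled; in dense mineralised bone this can retard penetration beyond
  what pure diffusion predicts.
* **Uniform clearance.** Elimination is a volumetric first-order sink with a
  single half-life everywhere; real perfusion is spatially heterogeneous,
  and multi-exponential elimination (distribution + terminal phases) is out
  of scope.
* **Equal-concentration interfaces.** Layer boundaries (cortical/cancellous,
  coating/medium) carry no interfacial resistance; the concentration is
  continuous and flux is conserved across them.
* **Reduced geometry.** The bone plate's two release directions are two
  independent 1-D stacks sharing the release flux (split fraction is a
  config knob, default 0.5 — the true partition depends on plate geometry
  that a 1-D model cannot resolve). The agar plate is a thin 2-D fluid
  layer of uniform depth.

## Numerical scheme

Fully explicit cell-centred finite differences; every right-hand-side term
uses the state at time *t*.

* **Face diffusivities** are harmonic means of the adjacent cells'. The
  harmonic mean is the unique choice that conserves flux across a layer
  interface with contrasting D while keeping concentration continuous;
  arithmetic averaging overestimates interface flux.
* **Stability.** The time step must satisfy `Δt ≤ Δx²/(6·D)` (checked per
  cell; the default step is 0.9× the bound). Violations raise a
  `StabilityError` before any NaN can propagate, and any genuinely negative
  or non-finite state raises a `SolverFault` with the offending cell and
  time. Under the bound the scheme is positivity-preserving (the 6 in the
  denominator gives a 3× margin over the 1-D positivity limit, so boundary
  terms cannot break it); negatives at rounding level (≲1e-9 relative) are
  clamped to zero.
* **Dirichlet/sink boundaries** are imposed at the cell *face* via a
  ghost-value flux `2D(C − V)/Δx`. Pinning the boundary cell's centre
  instead would shift the effective domain edge by Δx/2 and, for an
  initially loaded slab, delete one cell of mass at t=0; the face form is
  second-order accurate and keeps the mass ledger exact. Verified against
  the erfc closed form (≤0.02% at the default resolution) and the slab
  release series (≤0.6%).
* **Clearance discretisation.** The default per-step increment is
  `Δt·(ln½/t_half)·C·0.5^(Δt/t_half)`, an explicit-Euler form of the
  half-life law with a sub-step attenuation factor; it converges to exact
  exponential elimination as Δt→0 (0.14% error at six half-lives with
  Δt = 0.004 h, t_half = 4 h — decay-accuracy tests use steps of this order
  because the error grows roughly linearly in Δt). An exact multiplicative
  mode (`C ← C·0.5^(Δt/t_half)`) is available via
  `ClearanceSpec(mode="exact")`.
* **Mass ledger.** Every run tracks initial, influx, cleared, Dirichlet
  outflux and stored mass; closure `initial + influx = stored + cleared +
  outflux` is exact to rounding (≈1e-14 relative) because each term
  accumulates exactly what the update applied. Ledger closure is the
  solver's primary self-check and is asserted on every scenario.

Canonical units are mm / h / µg with concentration in µg/mL; because µg/mL
is per cm³, terms converting fluxes or cell masses to concentrations carry a
single factor of 1000 (`vancoelute.units`).

## Parameters and defaults

| parameter | default | unit | basis |
|---|---|---|---|
| D0 (vancomycin in water, 37 °C) | 2.83e-6 | cm²/s | literature value |
| δ, φ, τ cortical | 0.84, 0.05, 1.10 | – | reported bone structure |
| δ, φ, τ cancellous | 0.96, 0.95, 1.10 | – | reported (φ high end, low bone mass) |
| D_eff cortical / cancellous | 1.081e-7 / 2.346e-6 | cm²/s | computed via D0·δ·φ/τ |
| D tissue | 2.08e-6 | cm²/s | approximated by agar diffusivity |
| D agar | 0.72 | mm²/h | reported agar measurement |
| half-life | 4 (adults 4–6) | h | human pharmacokinetics; "disabled" = no clearance (never t_half = 0) |
| MIC / toxicity | 2 / 1000 | µg/mL | S. aureus MIC; host-cell viability threshold |
| coating load / area | 5000 µg / 900 mm² | | assumption (documented, not measured) |
| release curve | k·t^0.5, 95% at 21 d | | synthetic stand-in (below) |
| bone stack | 3.5 + 14 + 3.5 | mm | human cortical/cancellous anatomy |
| tissue window | 3 (height 10) | mm | infections arise near the plate |
| rat stack | 0.7 + 2.6 + 0.7 | mm | assumption at rat-tibia scale |
| rat dose | 10 | µg | assumption; outputs are linear in dose |

The printed effective diffusivities found elsewhere for these structural
parameters are not consistent with D0·δ·φ/τ; this package always computes
D_eff from the formula, and any layer's D can be overridden in the config's
transport block (explicit unit tags) when a directly measured value is
preferred. Similarly, 0.72 mm²/h and 2.08e-6 cm²/s differ by 4%; the agar
scenario uses the former, the tissue default the latter, both overridable.

**In-vitro slab geometry.** The release experiment is simulated as a slab
with an *effective* diffusion length of 20.8 mm so that, at the free-water
diffusivity, 95% of the load leaves in ~21 days — matching the observed
release duration. This is a kinetic surrogate, not a physical coating
thickness: the real double-layer coating is far thinner and correspondingly
less permeable, and only the product D/L² is identifiable from a release
curve.

## Synthetic data

The measured cumulative-release dataset and the in-vivo concentration table
the pipeline would consume are not distributable, so `vancoelute.synthetic`
generates stand-ins:

* release curves: Korsmeyer–Peppas with n = 0.5 (Fickian), k set for 95%
  release at 21 days, no burst; optional relative/absolute Gaussian noise,
  re-monotonised by running maximum (cumulative data cannot decrease);
* in-vivo-like series: a simulated truth curve sampled at sparse times with
  Gaussian noise;
* `gen_fixture_suite`: all four scenario configs at test resolution plus a
  noisy release profile, from which the whole pipeline runs offline.

Every generator is a pure function of (parameters, seed). What passing tests
show is therefore internal consistency — solver vs closed forms, recovery of
known parameters from noisy synthetic data, qualitative pharmacokinetic
shapes — not agreement with any particular coating's measured kinetics:
absolute concentrations scale with the assumed load and split, and real
assay noise is not Gaussian-i.i.d.

## Sensitivity workflow

One parameter at a time: 50 multiplicative factors from a log-normal centred
on 1 (log-sd per parameter from the spread of literature values, shipped in
`DEFAULT_LOG_SD`), thinned to nearest-rank percentiles 0,10,…,100 (11 runs),
each run re-simulating the bone-plate scenario. Indices are
output %-change / input %-change per output time (1, 6, 12, 24 h default),
plus a linear regression of output on input change with R² and adjusted R²
(when they agree closely the point count could be thinned further, e.g. to
eight).

Two design choices were genuinely open:

* **Output metric.** With sealed (no-gradient) outer boundaries the
  domain-average concentration is *exactly* independent of every
  diffusivity — total mass obeys a closed balance of influx and uniform
  first-order clearance — so diffusivity sensitivities would be
  identically zero. The sweep therefore uses a sink at the far tissue
  boundary (drug carried away beyond the 3 mm window, the physically
  sensible picture for perfused tissue; `default_sensitivity_config()`)
  and, for cortical parameters, averages over the near half of the
  plate-side cortical layer, where cortical transport actually governs the
  signal within 24 h.
* **Porosity factors** scale the layer's effective diffusivity directly
  (D_eff ∝ φ) rather than φ itself, so large factors cannot push φ past 1.

Observed behaviour at defaults: half-life indices positive, ≈0.09 at 1 h
rising to ≈0.5 at 24 h (clearance compounds over time; at steady state with
a constant flux the index tends to 1); tissue-diffusivity indices negative
(≈−0.6 at 24 h); cortical-diffusivity indices negative and small (the dense
layer passes little mass on this horizon). A release-amplitude factor has
index exactly 1 at all times — the model is linear — which doubles as a
workflow self-check.

## Degenerate inputs and tie-breaks

* `half_life = None` disables clearance (a literal zero would mean
  instantaneous elimination, the opposite of the intended "no clearance").
* Release profiles must be non-decreasing with `t0 = 0`; fluxes beyond the
  last sample are zero (exhausted reservoir). Flux evaluation at a sample
  point takes the right-hand segment.
* Percentile selection is nearest-rank (`np.percentile(...,
  method="nearest")`), so selected factors are actual sample members.
* A scaling factor of exactly 1 is excluded from index tables (0/0).
* The agar runner refuses a domain whose boundary ring reaches the MIC —
  the inhibition area would be truncated — and the inhibition area counts
  non-source cells at or above the MIC plus (by default) the source
  footprint, since measured inhibition zones include the substrate.

## Problem sizes

Packaged "default" resolutions use production grids (e.g. tissue Δx =
0.1 mm, agar 70×70 at Δx = 1 mm); the "test" resolution coarsens cells
2–2.5× and shortens horizons, which keeps every scenario deterministic and
each full-suite run in tens of seconds while leaving all qualitative
behaviour and every oracle contract intact (grid-refinement tests verify
convergence between the two). Sensitivity sweeps run at test resolution:
11 runs per parameter, ~2 s each set.

## Known limitations

* 1-D/thin-2-D geometry only: no screw holes, plate curvature, or 3-D
  effects; the tissue/bone flux split is an assumption, not a prediction.
* No advection or perfusion; clearance is the only elimination route.
* Quantitative outputs (peak concentration, inhibition area) inherit the
  synthetic release curve's assumed load; treat them as scenario
  illustrations, while the oracle-checked solver behaviour, conservation,
  qualitative shapes and sensitivity structure are the tested claims.
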