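# vancoelute

Finite-difference modelling of **local vancomycin delivery** from
antibiotic-coated bone implants: how fast does the drug leave a poly(L-lactic
acid) (PLLA) coating, where does it go in layered tissue and bone, is the
concentration high enough to kill *S. aureus* (MIC 2 µg/mL) without harming
host cells (toxicity threshold 1,000 µg/mL), and which input parameters
actually matter?

The package is aimed at people modelling controlled-release antibiotic
systems — it trades CFD machinery for a transparent, fully testable explicit
scheme with an exact mass ledger.

## Model

Transport is Fickian diffusion with first-order (half-life) clearance. On a
cell-centred grid (index 0 at the release surface) the explicit update per
cell is

```
C_i(t+Δt) = C_i(t) + (Δt/Δx²)·[D_{i+½}(C_{i+1}−C_i) − D_{i−½}(C_i−C_{i−1})]
            + Δt·(ln½/t_half)·C_i(t)·0.5^(Δt/t_half)
```

with a prescribed mass flux `J_in(t)` (derived from a cumulative release
curve, e.g. Korsmeyer–Peppas `M_t/M_∞ = k·tⁿ`), held-value (sink) faces, or
sealed faces at the boundaries, and the stability bound `Δt ≤ Δx²/(6·D)`.
Diffusivity in bone is extrapolated from the free-water value via the
porous-media reduction `D_eff = D0·δ·φ/τ` (constrictivity, porosity,
tortuosity). Four packaged scenarios exercise the model end to end:
in-vitro release (slab → sink), agar-plate inhibition zone (2-D thin layer),
rat-tibia bolus validation, and the human bone-plate delivery system
(tissue side + cortical/cancellous/cortical bone side). A sensitivity module
sweeps log-normal parameter factors and reports
`index = output %-change / input %-change`.

## Worked example

```python
import numpy as np
from vancoelute import default_config, run_human_bone_plate, one_sample_t_test

res = run_human_bone_plate(default_config("human_bone_plate", "test"))
i = int(np.argmax(res.tissue_avg))
print(f"tissue peak {res.tissue_avg[i]:.2f} ug/mL at {res.tissue.times[i]:.2f} h")
print(res.zone_map('bone').areas)
print(one_sample_t_test(12.97, 1.30, 3, 15.43))
```

prints

```
tissue peak 52.53 ug/mL at 4.01 h
{'sub_MIC': 18.5, 'effective': 2.5, 'toxic': 0.0}
TTestResult(t=-3.2775730666303358, df=2, p=0.08182531826548452)
```

The tissue-average concentration peaks a few hours after implantation (well
above the MIC, far below toxicity) and then declines as clearance overtakes
the fading release. On the bone side the dense cortical layer keeps most of
the stack sub-MIC while the region next to the plate stays effective. The
t-test compares a simulated inhibition area (15.43 cm²) with the measured
12.97 ± 1.30 cm² over n=3 agar plates: p = 0.082 > 0.05, i.e. consistent.

The `examples/` directory has one short script per capability (effective
diffusivity, release→flux conversion, each scenario, sensitivity); each
prints its numbers with a line on what they mean. A thin CLI mirrors the
library: `vancoelute run|sensitivity|synth --help`.

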