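"""Parameter sensitivity-analysis workflow.

The pipeline mirrors a one-at-a-time multiplicative design: draw random
scaling factors for one parameter from a log-normal centred on 1 (log-sd from
literature spread), keep the 0th–100th percentiles in steps of 10 (11 runs),
re-simulate the bone-plate scenario for each, and report

    sensitivity index = output % change / input % change

per output time, together with a linear regression of output change on input
change (R² and adjusted R²; when the two agree closely the design can be
thinned to fewer points).

The output metric is the average concentration over the region each parameter
governs: the whole tissue domain for tissue-side parameters (with a sink at
the far tissue boundary so transport out of the 3 mm window is represented),
and the near half of the plate-side cortical layer for cortical parameters.
With no-gradient boundaries everywhere, a domain average would be exactly
independent of any diffusivity (mass conservation plus uniform first-order
clearance), so the sink is what lets diffusivity changes show up — see
docs/methods.md.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .postprocess import average_concentration
from .scenarios import default_config, run_human_bone_plate

#: default log-space standard deviations, from the spread of literature values
DEFAULT_LOG_SD = {
    "D_tissue": 0.18,  # ~±20% reported variation of agar/tissue diffusivity
    "D_cortical": 0.30,  # wide: structural extrapolation, porosity ranges
    "half_life": 0.20,  # 4–6 h in healthy adults
    "porosity_cortical": 0.30,
    "porosity_cancellous": 0.08,  # 0.75–0.95 reported range
    "release_amplitude": 0.10,
}

_PARAM_NAMES = tuple(DEFAULT_LOG_SD)


@dataclass(frozen=True)
class ParamPrior:
    """Multiplicative prior for one parameter: base value and log-space sd."""

    name: str
    base: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.name not in _PARAM_NAMES:
            raise ValidationError(
                f"unknown parameter {self.name!r}; expected one of {_PARAM_NAMES}"
            )
        if not self.base > 0:
            raise ValidationError("base must be > 0")
        if self.log_sd < 0:
            raise ValidationError("log_sd must be >= 0")


def default_prior(name: str, cfg: dict | None = None) -> ParamPrior:
    """Prior with the scenario's base value and the documented default log-sd."""
    cfg = cfg or default_config("human_bone_plate", "test")
    bases = {
        "D_tissue": float(cfg["transport"]["tissue"]["D"]),
        "D_cortical": 1.0,  # multiplicative on the effective cortical D
        "half_life": float(cfg["clearance"]["half_life_h"]),
        "porosity_cortical": float(cfg["transport"]["cortical"]["phi"]),
        "porosity_cancellous": float(cfg["transport"]["cancellous"]["phi"]),
        "release_amplitude": float(cfg["source"]["total_load_ug"]),
    }
    if name not in bases:
        raise ValidationError(f"unknown parameter {name!r}")
    return ParamPrior(name=name, base=bases[name], log_sd=DEFAULT_LOG_SD[name])


@dataclass
class SensitivityRun:
    """Batch result: tidy table plus regression summary per output time."""

    param: str
    factors: np.ndarray
    output_times: np.ndarray
    baseline: np.ndarray  # metric at output_times, factor = 1
    table: pd.DataFrame  # factor, input_pct, time_h, output, output_pct, index
    regression: pd.DataFrame = field(default=None)  # time_h, slope, r2, adj_r2

    def indices_at(self, t: float) -> np.ndarray:
        sel = self.table[np.isclose(self.table["time_h"], t)]
        return sel["index"].to_numpy()

    @property
    def can_reduce_points(self) -> bool:
        """True when adjusted R² tracks R² closely (≤0.01 apart) at every time."""
        return bool((self.regression["r2"] - self.regression["adj_r2"] <= 0.01).all())


def sample_scaling_factors(prior: ParamPrior, n: int = 50, seed: int = 0) -> np.ndarray:
    """n multiplicative factors, log-normal about 1 with the prior's log-sd.

    Deterministic per seed; sd = 0 degenerates to all ones.
    """
    if prior.log_sd < 0:
        raise ValidationError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(0.0, prior.log_sd, size=n))


def percentile_factors(
    factors: np.ndarray, percentiles: np.ndarray | None = None
) -> np.ndarray:
    """Empirical percentiles (nearest-rank) of the sampled factors, sorted.

    Default percentiles are 0, 10, …, 100; includes the sample min and max.
    """
    factors = np.asarray(factors, dtype=float)
    if percentiles is None:
        percentiles = np.arange(0, 101, 10)
    percentiles = np.asarray(percentiles, dtype=float)
    if factors.size < percentiles.size:
        raise ValidationError(
            f"need at least {percentiles.size} factors, got {factors.size}"
        )
    return np.sort(np.percentile(factors, percentiles, method="nearest"))


def sensitivity_index(output_pct: float, input_pct: float) -> float:
    """Signed ratio output%/input%; undefined (error) at input 0."""
    if input_pct == 0:
        raise ValidationError("input change percentage is 0; index undefined")
    return output_pct / input_pct


# ---------------------------------------------------------------------------
# applying a factor to a scenario config

_METRIC_REGION = {
    "D_tissue": ("tissue", None),
    "half_life": ("tissue", None),
    "release_amplitude": ("tissue", None),
    "D_cortical": ("bone", "cortical_near_half"),
    "porosity_cortical": ("bone", "cortical_near_half"),
    "porosity_cancellous": ("bone", "cancellous"),
}


def apply_factor(cfg: dict, name: str, factor: float) -> dict:
    """Config copy with one parameter scaled multiplicatively by ``factor``.

    Porosity factors are applied to the layer's effective diffusivity (D_eff
    is proportional to φ), which sidesteps unphysical φ > 1 at large factors.
    """
    if factor <= 0:
        raise ValidationError("factor must be > 0")
    out = copy.deepcopy(cfg)
    tr = out["transport"]
    if name == "D_tissue":
        tr["tissue"]["D"] = float(tr["tissue"]["D"]) * factor
    elif name in ("D_cortical", "porosity_cortical"):
        _scale_material(tr["cortical"], factor)
    elif name == "porosity_cancellous":
        _scale_material(tr["cancellous"], factor)
    elif name == "half_life":
        out["clearance"]["half_life_h"] = float(out["clearance"]["half_life_h"]) * factor
    elif name == "release_amplitude":
        out["source"]["total_load_ug"] = float(out["source"]["total_load_ug"]) * factor
    else:
        raise ValidationError(f"unknown parameter {name!r}")
    return out


def _scale_material(mat: dict, factor: float) -> None:
    if "D" in mat:
        mat["D"] = float(mat["D"]) * factor
    else:
        # D_eff ∝ D0; scale D0 so δ, φ, τ stay within their physical ranges
        mat["D0"] = float(mat["D0"]) * factor


def _metric(cfg: dict, name: str, output_times: np.ndarray) -> np.ndarray:
    res = run_human_bone_plate(cfg)
    side, region = _METRIC_REGION[name]
    sim = res.tissue if side == "tissue" else res.bone
    if region is None:
        series = average_concentration(sim)
    elif region == "cortical_near_half":
        sl = sim.grid.layer_cells("cortical_near")
        half = max(1, (sl.stop - sl.start) // 2)
        series = average_concentration(sim, slice(sl.start, sl.start + half))
    else:
        series = average_concentration(sim, sim.grid.layer_cells(region))
    return np.interp(output_times, sim.times, series)


def run_sensitivity(
    cfg: dict,
    prior: ParamPrior,
    factors: np.ndarray,
    output_times: np.ndarray | None = None,
) -> SensitivityRun:
    """One simulation per scaling factor; indices and regression vs baseline.

    Factors equal to 1 (no input change) are excluded from the index table.
    The scenario is the bone-plate delivery system; start from
    :func:`default_sensitivity_config`, which enables the far-tissue sink
    (see module docstring for why).
    """
    if output_times is None:
        output_times = np.array([1.0, 6.0, 12.0, 24.0])
    output_times = np.asarray(output_times, dtype=float)
    cfg = copy.deepcopy(cfg)
    baseline = _metric(cfg, prior.name, output_times)
    if np.any(baseline <= 0):
        raise ValidationError("baseline metric is not positive at all output times")

    rows = []
    for f in np.asarray(factors, dtype=float):
        if abs(f - 1.0) < 1e-12:
            continue  # 0/0 index undefined
        out = _metric(apply_factor(cfg, prior.name, f), prior.name, output_times)
        input_pct = (f - 1.0) * 100.0
        for t, y, y0 in zip(output_times, out, baseline):
            output_pct = (y - y0) / y0 * 100.0
            rows.append(
                {
                    "param": prior.name,
                    "factor": f,
                    "input_pct": input_pct,
                    "time_h": t,
                    "output": y,
                    "output_pct": output_pct,
                    "index": sensitivity_index(output_pct, input_pct),
                }
            )
    table = pd.DataFrame(rows).sort_values(["time_h", "factor"]).reset_index(drop=True)

    reg_rows = []
    for t in output_times:
        sub = table[np.isclose(table["time_h"], t)]
        x = sub["input_pct"].to_numpy()
        y = sub["output_pct"].to_numpy()
        n = x.size
        if n >= 3:
            fit = stats.linregress(x, y)
            slope = float(fit.slope)
            r2 = float(fit.rvalue**2)
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        else:  # too few points for a meaningful fit; report the raw slope
            slope = float(y[-1] / x[-1])
            r2 = adj = float("nan")
        reg_rows.append({"time_h": t, "slope": slope, "r2": r2, "adj_r2": adj})
    regression = pd.DataFrame(reg_rows)

    return SensitivityRun(
        param=prior.name,
        factors=np.asarray(factors, dtype=float),
        output_times=output_times,
        baseline=baseline,
        table=table,
        regression=regression,
    )


def default_sensitivity_config() -> dict:
    """Bone-plate config at sweep resolution with the far-tissue sink."""
    cfg = default_config("human_bone_plate", "test")
    cfg["geometry"]["tissue"]["far_boundary"] = "sink"
    return cfg
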