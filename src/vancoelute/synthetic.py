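"""Synthetic inputs: noisy release measurements, in-vivo-like concentration
series, full scenario fixture suites, and the parameter-recovery fits that
close the loop on them.

The real release dataset the pipeline consumes (the coating's cumulative
release curve) comes from a separate wet-lab study and is not shipped; the
generators here emulate it — a Korsmeyer–Peppas curve (Fickian n = 0.5,
~3-week duration, no initial burst) plus assay-like noise — so every stage is
testable without external data. Each generator is a pure function of its
parameters and an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import release as rel
from .errors import ValidationError
from .scenarios import SCENARIOS, default_config, save_config


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description.

    ``gaussian_relative`` scales the signal by (1 + ε), ``gaussian_absolute``
    adds ε, with ε ~ N(0, magnitude²). Deterministic per seed.
    """

    kind: str = "gaussian_relative"
    magnitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"gaussian_relative", "gaussian_absolute"}:
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValidationError("noise magnitude must be >= 0")


def _apply_noise(values: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.magnitude == 0:
        return values.copy()
    eps = rng.normal(0.0, noise.magnitude, size=values.shape)
    if noise.kind == "gaussian_relative":
        return values * (1.0 + eps)
    return values + eps


def gen_release_measurements(
    profile: rel.ReleaseProfile, noise: NoiseSpec
) -> rel.ReleaseProfile:
    """Noisy version of a cumulative release curve, as an assay would see it.

    Noise is applied pointwise, then the curve is re-monotonised by running
    maximum (cumulative data cannot decrease), pinned to 0 at t=0 and clipped
    to [0, 1] for fraction profiles.
    """
    rng = np.random.default_rng(noise.seed)
    noisy = _apply_noise(profile.cumulative, noise, rng)
    noisy[0] = 0.0
    noisy = np.maximum.accumulate(noisy)
    noisy = np.clip(noisy, 0.0, 1.0 if profile.is_fraction else None)
    return rel.ReleaseProfile(
        times=profile.times.copy(),
        cumulative=noisy,
        total_load=profile.total_load,
        coating_area=profile.coating_area,
        is_fraction=profile.is_fraction,
        meta={**profile.meta, "noise": noise.kind, "noise_magnitude": noise.magnitude},
    )


def gen_invivo_series(
    truth_times: np.ndarray,
    truth_values: np.ndarray,
    noise: NoiseSpec,
    sampling_times: np.ndarray,
) -> pd.DataFrame:
    """Sampled, noised concentration time series (µg/mL) from a truth curve.

    Emulates sparse in-vivo measurements: the truth series is interpolated at
    the sampling times, then noised. Sampling times outside the simulated
    horizon are an error.
    """
    truth_times = np.asarray(truth_times, dtype=float)
    truth_values = np.asarray(truth_values, dtype=float)
    sampling_times = np.asarray(sampling_times, dtype=float)
    if np.any(sampling_times < truth_times[0]) or np.any(sampling_times > truth_times[-1]):
        raise ValidationError("sampling times outside the simulated horizon")
    rng = np.random.default_rng(noise.seed)
    truth = np.interp(sampling_times, truth_times, truth_values)
    measured = _apply_noise(truth, noise, rng)
    return pd.DataFrame(
        {
            "time_h": sampling_times,
            "concentration_ugml": measured,
            "truth_ugml": truth,
        }
    )


def gen_fixture_suite(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write all four scenario configs (test resolution) plus a synthetic
    release profile into ``out_dir``; returns the paths.

    Different seeds perturb the release-profile measurements, not the config
    structure, so suites are structurally identical across seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    truth = rel.default_release_profile()
    noisy = gen_release_measurements(truth, NoiseSpec(magnitude=0.02, seed=seed))
    profile_path = out / "release_profile.tsv"
    rel.write_release_profile(noisy, profile_path)
    paths["release_profile"] = profile_path

    for name in SCENARIOS:
        cfg = default_config(name, resolution="test")
        cfg["run"]["seed"] = seed
        if cfg.get("source", {}).get("kind") == "peppas":
            cfg["source"] = {"kind": "file", "path": str(profile_path), **(
                {"split_to_tissue": cfg["source"]["split_to_tissue"]}
                if "split_to_tissue" in cfg["source"]
                else {}
            )}
        p = out / f"{name}.yaml"
        save_config(cfg, p)
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# parameter-recovery fits


def fit_half_life(times: np.ndarray, values: np.ndarray) -> float:
    """Least-squares half-life (h) from a decay-phase concentration series.

    Fits ln C against t; t_half = -ln 2 / slope. Non-positive samples are
    dropped; requires at least 3 usable points and a negative slope.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = values > 0
    if ok.sum() < 3:
        raise ValidationError("need at least 3 positive samples to fit a half-life")
    slope, _ = np.polyfit(times[ok], np.log(values[ok]), 1)
    if slope >= 0:
        raise ValidationError("series is not decaying; cannot fit a half-life")
    return float(-np.log(2.0) / slope)


def fit_release_exponent(
    profile: rel.ReleaseProfile, frac_min: float = 0.1, frac_cap: float = 0.6
) -> tuple[float, float]:
    """Korsmeyer–Peppas (k, n) by log-log regression on the early curve.

    Only samples with ``frac_min`` ≤ fraction ≤ ``frac_cap`` enter the fit:
    the power law holds before the curve saturates, and very small fractions
    carry outsized relative measurement noise. Returns (k, n).
    """
    frac = profile.cumulative if profile.is_fraction else profile.cumulative_mass / profile.total_load
    ok = (frac >= frac_min) & (frac <= frac_cap) & (profile.times > 0)
    if ok.sum() < 3:
        raise ValidationError("not enough early-curve samples to fit the exponent")
    n, logk = np.polyfit(np.log(profile.times[ok]), np.log(frac[ok]), 1)
    return float(np.exp(logk)), float(n)
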