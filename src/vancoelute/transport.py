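"""Derived transport parameters for drug diffusion in porous bone.

Vancomycin diffusivity has been measured in free water but not in bone, so the
bone value is extrapolated from the free-water coefficient and the structural
descriptors of the porous matrix — constrictivity δ (pore narrowing), porosity
φ (accessible volume fraction) and tortuosity τ (path lengthening):

    D_eff = D0 · δ · φ / τ

the standard porous-media reduction: δ and φ shrink the accessible flux,
τ lengthens the diffusion path. Cortical bone (φ ≈ 0.05) is nearly
impermeable next to cancellous bone (φ ≈ 0.95).

This module also houses the stability bound for the explicit scheme,
Δt ≤ Δx²/(6 D), the Courant–Friedrichs–Lewy-type rule used to pick the time
step.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: free-water diffusion coefficient of vancomycin at 37 °C (cm²/s)
D0_WATER_CM2_S = 2.83e-6

#: structural descriptors of human bone used as defaults throughout
DEFAULT_BONE_PARAMS = {
    "cortical": {"D0": D0_WATER_CM2_S, "delta": 0.84, "phi": 0.05, "tau": 1.10},
    "cancellous": {"D0": D0_WATER_CM2_S, "delta": 0.96, "phi": 0.95, "tau": 1.10},
}


@dataclass(frozen=True)
class TransportParams:
    """Porous-medium descriptors for one material.

    Parameters
    ----------
    D0 : float
        Free-medium diffusion coefficient (cm²/s).
    delta : float
        Constrictivity factor δ, in (0, 1].
    phi : float
        Porosity φ, in (0, 1].
    tau : float
        Tortuosity factor τ, ≥ 1.
    """

    D0: float
    delta: float
    phi: float
    tau: float

    def __post_init__(self) -> None:
        if not self.D0 > 0:
            raise ValidationError(f"D0 must be > 0, got {self.D0}")
        if not 0 < self.delta <= 1:
            raise ValidationError(f"delta must be in (0, 1], got {self.delta}")
        if not 0 < self.phi <= 1:
            raise ValidationError(f"phi must be in (0, 1], got {self.phi}")
        if not self.tau >= 1:
            raise ValidationError(f"tau must be >= 1, got {self.tau}")


@dataclass(frozen=True)
class StepConstraint:
    """Explicit-scheme stability record: dt_max = dx²/(6·D)."""

    dx: float  # mm
    D: float  # mm²/h
    dt_max: float  # h


def effective_diffusivity(params: TransportParams) -> float:
    """Effective diffusivity D_eff = D0·δ·φ/τ, in the units of ``params.D0``.

    Strictly positive and never larger than D0 (δ, φ ≤ 1, τ ≥ 1).
    """
    return params.D0 * params.delta * params.phi / params.tau


def max_stable_timestep(dx: float, D: float) -> float:
    """Largest stable time step Δt = Δx²/(6·D) for the explicit scheme.

    Parameters are in canonical units (dx mm, D mm²/h); the result is hours.
    """
    if not dx > 0:
        raise ValidationError(f"dx must be > 0, got {dx}")
    if D == 0:
        raise ValidationError("no diffusion; time step unconstrained")
    if not D > 0:
        raise ValidationError(f"D must be > 0, got {D}")
    return dx * dx / (6.0 * D)


def step_constraint(dx: float, D: float) -> StepConstraint:
    """Bundle dx, D and the resulting stability bound."""
    return StepConstraint(dx=dx, D=D, dt_max=max_stable_timestep(dx, D))
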