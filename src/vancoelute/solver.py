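"""Explicit finite-difference diffusion with first-order (half-life) clearance.

The transient drug balance over each grid cell is Fick's second law plus a
clearance sink. On a cell-centred 1-D grid (index 0 at the release surface)
the fully explicit update is

    C_i(t+Δt) = C_i(t) + (Δt/Δx²)·[D_{i+½}(C_{i+1}−C_i) − D_{i−½}(C_i−C_{i−1})]
                + Δt·(ln½ / t_half)·C_i(t)·0.5^(Δt/t_half)

with boundary cells receiving either a prescribed mass flux J_in(t), a
held-value (Dirichlet/sink) face, or a zero-flux face. Face diffusivities are
the harmonic mean of the adjacent cells', which conserves flux across layer
interfaces while keeping the concentration continuous there. Stability
requires Δt ≤ Δx²/(6·D) (checked; violation raises, never NaNs).

The clearance increment mirrors the discrete half-life bookkeeping
m_t = m_0·(½)^{t/t_half} applied per element; as Δt→0 it converges to exact
exponential elimination, and an exact multiplicative mode
(C ← C·0.5^{Δt/t_half}) is available via ``ClearanceSpec(mode="exact")``.

Every run maintains a mass ledger (initial, influx, cleared, boundary
outflux, stored) whose closure is the solver's primary self-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import SolverFault, StabilityError, ValidationError
from .units import UG_PER_ML_PER_UG_PER_MM3 as _KC

_NEG_TOL = 1e-9  # relative; below this a negative state is a solver fault


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous layer of a 1-D stack."""

    name: str
    length: float  # mm
    D: float  # mm²/h
    porosity: float | None = None  # metadata only

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValidationError(f"layer {self.name}: length must be > 0")
        if not self.D > 0:
            raise ValidationError(f"layer {self.name}: D must be > 0")


class Grid1D:
    """Cell-centred 1-D grid over an ordered stack of layers.

    Cell 0 sits at the release surface; cell centres are at (i+½)·Δx. Each
    layer must contain an integer number of cells.
    """

    def __init__(
        self,
        layers: Sequence[LayerSpec],
        dx: float,
        cross_section_area: float = 1.0,
    ) -> None:
        if not dx > 0:
            raise ValidationError(f"dx must be > 0, got {dx}")
        if not cross_section_area > 0:
            raise ValidationError("cross_section_area must be > 0")
        if not layers:
            raise ValidationError("at least one layer required")
        self.dx = float(dx)
        self.layers = tuple(layers)
        self.cross_section_area = float(cross_section_area)
        cell_D: list[float] = []
        self._layer_slices: dict[str, slice] = {}
        start = 0
        for layer in layers:
            n_f = layer.length / dx
            n = round(n_f)
            if abs(n_f - n) > 1e-9 * max(1.0, n_f) or n < 1:
                raise ValidationError(
                    f"layer {layer.name}: length {layer.length} mm is not an "
                    f"integer number of cells of dx={dx} mm"
                )
            cell_D.extend([layer.D] * n)
            self._layer_slices[layer.name] = slice(start, start + n)
            start += n
        self.cell_D = np.array(cell_D, dtype=float)
        self.n_cells = self.cell_D.size
        # harmonic-mean diffusivity on interior faces: conserves flux across
        # layer interfaces with contrasting D
        dl, dr = self.cell_D[:-1], self.cell_D[1:]
        self.face_D = 2.0 * dl * dr / (dl + dr)

    @property
    def length(self) -> float:
        return self.n_cells * self.dx

    @property
    def cell_centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx

    @property
    def cell_volume(self) -> float:
        """Volume of one cell (mm³)."""
        return self.dx * self.cross_section_area

    def layer_cells(self, name: str) -> slice:
        """Slice of cell indices belonging to a named layer."""
        return self._layer_slices[name]

    def max_stable_dt(self) -> float:
        """Δx²/(6·D) with the largest cell diffusivity."""
        return self.dx**2 / (6.0 * float(self.cell_D.max()))


@dataclass
class Grid2D:
    """Uniform rectangular grid for thin-layer (plate) diffusion.

    ``thickness`` is the depth (mm) of the fluid layer; concentrations are
    volumetric (µg/mL) in that layer. ``source_mask`` marks the cells of the
    releasing footprint.
    """

    dx: float  # mm
    nx: int
    ny: int
    D: float  # mm²/h
    thickness: float = 4.0  # mm
    source_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.nx > 0 and self.ny > 0):
            raise ValidationError("dx, nx, ny must be positive")
        if not (self.D > 0 and self.thickness > 0):
            raise ValidationError("D and thickness must be positive")
        if self.source_mask is not None:
            self.source_mask = np.asarray(self.source_mask, dtype=bool)
            if self.source_mask.shape != (self.ny, self.nx):
                raise ValidationError("source_mask shape must be (ny, nx)")

    def max_stable_dt(self) -> float:
        return self.dx**2 / (6.0 * self.D)

    @property
    def cell_volume(self) -> float:
        return self.dx * self.dx * self.thickness


# ---------------------------------------------------------------------------
# boundary conditions and clearance


@dataclass(frozen=True)
class BoundaryCondition:
    """One end of the 1-D domain.

    kinds: ``flux_in`` (prescribed mass flux, µg·mm⁻²·h⁻¹), ``dirichlet``
    (value held at the boundary face; ``sink`` is dirichlet 0), ``no_flux``
    and ``symmetric`` (synonymous in 1-D).
    """

    kind: str
    flux_fn: Callable[[float], float] | None = None
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"flux_in", "dirichlet", "no_flux", "symmetric"}:
            raise ValidationError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "flux_in" and self.flux_fn is None:
            raise ValidationError("flux_in boundary requires flux_fn")


def flux_in(flux_fn: Callable[[float], float]) -> BoundaryCondition:
    return BoundaryCondition("flux_in", flux_fn=flux_fn)


def sink() -> BoundaryCondition:
    """Perfect sink: concentration held at 0 at the boundary face."""
    return BoundaryCondition("dirichlet", value=0.0)


def dirichlet(value: float) -> BoundaryCondition:
    return BoundaryCondition("dirichlet", value=value)


def no_flux() -> BoundaryCondition:
    return BoundaryCondition("no_flux")


def symmetric() -> BoundaryCondition:
    return BoundaryCondition("symmetric")


@dataclass(frozen=True)
class ClearanceSpec:
    """First-order elimination with half-life t_half (h); None = disabled.

    mode "incremental" applies the explicit per-step increment
    Δt·(ln½/t_half)·C·0.5^(Δt/t_half); mode "exact" multiplies by
    0.5^(Δt/t_half). Both converge to exponential elimination as Δt→0.
    """

    half_life: float | None = None
    mode: str = "incremental"

    def __post_init__(self) -> None:
        if self.half_life is not None and not self.half_life > 0:
            raise ValidationError("half_life must be > 0 when enabled")
        if self.mode not in {"incremental", "exact"}:
            raise ValidationError(f"unknown clearance mode {self.mode!r}")

    @property
    def enabled(self) -> bool:
        return self.half_life is not None


def decay_increment(
    C: float | np.ndarray, dt: float, clearance: ClearanceSpec
) -> float | np.ndarray:
    """Per-step clearance increment (≤ 0) added to the concentration.

    Incremental mode: Δt·(ln 0.5 / t_half)·C·0.5^(Δt/t_half).
    Exact mode: C·(0.5^(Δt/t_half) − 1).
    Returns 0 when clearance is disabled.
    """
    if not dt > 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    if not clearance.enabled:
        return np.zeros_like(C) if isinstance(C, np.ndarray) else 0.0
    th = clearance.half_life
    if clearance.mode == "exact":
        return C * (0.5 ** (dt / th) - 1.0)
    return dt * (math.log(0.5) / th) * C * 0.5 ** (dt / th)


# ---------------------------------------------------------------------------
# results


@dataclass
class MassLedger:
    """Cumulative mass bookkeeping (µg) for one run."""

    initial: float = 0.0
    influx: float = 0.0
    cleared: float = 0.0
    outflux: float = 0.0  # net mass removed through dirichlet faces
    stored: float = 0.0

    def closure_error(self) -> float:
        """Relative residual of initial + influx = stored + cleared + outflux."""
        residual = self.initial + self.influx - self.stored - self.cleared - self.outflux
        scale = max(
            abs(self.initial) + abs(self.influx),
            abs(self.stored) + abs(self.cleared) + abs(self.outflux),
            1e-300,
        )
        return abs(residual) / scale


@dataclass
class SimResult:
    """Recorded snapshots plus the final mass ledger of one simulation."""

    times: np.ndarray  # recorded instants (h)
    states: np.ndarray  # (n_times, n_cells) or (n_times, ny, nx), µg/mL
    ledger: MassLedger
    grid: Grid1D | Grid2D
    stored_series: np.ndarray = field(default=None)  # µg at each recorded time

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def mass_balance(result: SimResult) -> dict:
    """Ledger report: influx, cleared, outflux, stored and relative closure."""
    led = result.ledger
    return {
        "initial_ug": led.initial,
        "influx_ug": led.influx,
        "cleared_ug": led.cleared,
        "outflux_ug": led.outflux,
        "stored_ug": led.stored,
        "closure_error": led.closure_error(),
    }


# ---------------------------------------------------------------------------
# 1-D stepping


def _check_state(C: np.ndarray, t: float) -> None:
    if not np.all(np.isfinite(C)):
        raise SolverFault(f"non-finite concentration at t={t:.6g} h")
    scale = max(1.0, float(C.max(initial=0.0)))
    if float(C.min(initial=0.0)) < -_NEG_TOL * scale:
        i = int(np.argmin(C))
        raise SolverFault(
            f"negative concentration {C[i]:.3e} µg/mL in cell {i} at t={t:.6g} h"
        )


def _require_stable(dt: float, dt_max: float) -> None:
    if dt > dt_max * (1.0 + 1e-12):
        raise StabilityError(
            f"dt={dt:.6g} h exceeds the stability bound dx^2/(6 D)={dt_max:.6g} h; "
            "reduce dt or coarsen the grid"
        )


def step_1d(
    C: np.ndarray,
    t: float,
    grid: Grid1D,
    left: BoundaryCondition,
    right: BoundaryCondition,
    clearance: ClearanceSpec,
    dt: float,
) -> tuple[np.ndarray, dict]:
    """Advance one explicit step; returns (new state, step mass deltas in µg).

    All right-hand-side terms use the state at time ``t`` (fully explicit).
    """
    _require_stable(dt, grid.max_stable_dt())
    if C.shape != (grid.n_cells,):
        raise ValidationError("state size does not match grid")
    dx = grid.dx
    area = grid.cross_section_area
    vol = grid.cell_volume

    new = C.copy()
    # interior diffusive exchange, flux form (exactly conservative)
    if grid.n_cells > 1:
        F = grid.face_D * (C[1:] - C[:-1]) / dx  # µg/mL · mm/h, toward lower i
        new[:-1] += (dt / dx) * F
        new[1:] -= (dt / dx) * F

    deltas = {"influx": 0.0, "cleared": 0.0, "outflux": 0.0}

    for bc, idx, d_cell in ((left, 0, grid.cell_D[0]), (right, -1, grid.cell_D[-1])):
        if bc.kind == "flux_in":
            j = float(bc.flux_fn(t))
            if j < 0:
                raise ValidationError(f"boundary flux must be >= 0, got {j} at t={t}")
            new[idx] += (dt / dx) * j * _KC  # J µg/mm²/h → µg/mL rate
            deltas["influx"] += area * j * dt
        elif bc.kind == "dirichlet":
            # value held at the boundary FACE (ghost-cell form): one-sided
            # flux 2 D (C - V) / dx leaves through the face
            fb = 2.0 * d_cell * (bc.value - C[idx]) / dx
            new[idx] += (dt / dx) * fb
            deltas["outflux"] -= area * fb * dt / _KC
        # no_flux / symmetric: nothing to do

    if clearance.enabled:
        inc = decay_increment(C, dt, clearance)
        new += inc
        deltas["cleared"] += float(-inc.sum()) * vol / _KC

    _check_state(new, t + dt)
    np.clip(new, 0.0, None, out=new)  # scrub roundoff-level negatives
    return new, deltas


def simulate_1d(
    grid: Grid1D,
    left: BoundaryCondition,
    right: BoundaryCondition,
    clearance: ClearanceSpec,
    t_end: float,
    dt: float | None = None,
    record_every: float | None = None,
    init: np.ndarray | float = 0.0,
) -> SimResult:
    """Run the explicit scheme from t=0 to t_end, recording snapshots.

    ``dt=None`` picks 0.9× the stability bound. Snapshots are stored at t=0,
    then at the first step crossing each multiple of ``record_every``, and at
    t_end; recorded times are the actual step times. Deterministic for fixed
    inputs.
    """
    if not t_end > 0:
        raise ValidationError("t_end must be > 0")
    dt_max = grid.max_stable_dt()
    if dt is None:
        dt = 0.9 * dt_max
    _require_stable(dt, dt_max)
    if record_every is None:
        record_every = t_end

    C = np.full(grid.n_cells, float(init)) if np.ndim(init) == 0 else np.array(init, dtype=float)
    if C.shape != (grid.n_cells,):
        raise ValidationError("init size does not match grid")
    if np.any(C < 0):
        raise ValidationError("initial concentrations must be >= 0")

    vol = grid.cell_volume
    ledger = MassLedger(initial=float(C.sum()) * vol / _KC)
    times = [0.0]
    states = [C.copy()]
    stored = [ledger.initial]

    n_steps = int(math.ceil(t_end / dt - 1e-12))
    next_record = record_every
    t = 0.0
    for k in range(n_steps):
        step_dt = min(dt, t_end - t)
        if step_dt <= 0:
            break
        try:
            C, deltas = step_1d(C, t, grid, left, right, clearance, step_dt)
        except (SolverFault, StabilityError) as exc:
            raise type(exc)(f"{exc} (while stepping t={t:.6g} h)") from exc
        ledger.influx += deltas["influx"]
        ledger.cleared += deltas["cleared"]
        ledger.outflux += deltas["outflux"]
        t += step_dt
        if t + 1e-12 >= next_record or k == n_steps - 1:
            times.append(t)
            states.append(C.copy())
            stored.append(float(C.sum()) * vol / _KC)
            while next_record <= t + 1e-12:
                next_record += record_every

    ledger.stored = float(C.sum()) * vol / _KC
    return SimResult(
        times=np.array(times),
        states=np.array(states),
        ledger=ledger,
        grid=grid,
        stored_series=np.array(stored),
    )


# ---------------------------------------------------------------------------
# 2-D stepping (thin fluid layer, uniform D, 5-point Laplacian)


def step_2d(
    C: np.ndarray,
    t: float,
    grid: Grid2D,
    source_flux_fn: Callable[[float], float] | None,
    clearance: ClearanceSpec,
    dt: float,
) -> tuple[np.ndarray, dict]:
    """One explicit 2-D step with no-flux (symmetric) outer boundaries.

    ``source_flux_fn(t)`` is the mass flux (µg·mm⁻²·h⁻¹) entering the fluid
    layer over the source footprint; it is converted to a concentration rate
    by the layer thickness.
    """
    _require_stable(dt, grid.max_stable_dt())
    if C.shape != (grid.ny, grid.nx):
        raise ValidationError("state shape does not match grid")
    pad = np.pad(C, 1, mode="edge")  # zero-gradient outer boundary
    lap = (
        pad[1:-1, 2:] + pad[1:-1, :-2] + pad[2:, 1:-1] + pad[:-2, 1:-1] - 4.0 * C
    )
    new = C + grid.D * dt / grid.dx**2 * lap

    deltas = {"influx": 0.0, "cleared": 0.0, "outflux": 0.0}
    if source_flux_fn is not None:
        if grid.source_mask is None or not grid.source_mask.any():
            raise ValidationError("source flux given but source_mask is empty")
        j = float(source_flux_fn(t))
        if j < 0:
            raise ValidationError(f"source flux must be >= 0, got {j} at t={t}")
        new[grid.source_mask] += dt * j * _KC / grid.thickness
        deltas["influx"] += j * dt * float(grid.source_mask.sum()) * grid.dx**2

    if clearance.enabled:
        inc = decay_increment(C, dt, clearance)
        new += inc
        deltas["cleared"] += float(-inc.sum()) * grid.cell_volume / _KC

    _check_state(new, t + dt)
    np.clip(new, 0.0, None, out=new)
    return new, deltas


def simulate_2d(
    grid: Grid2D,
    source_flux_fn: Callable[[float], float] | None,
    clearance: ClearanceSpec,
    t_end: float,
    dt: float | None = None,
    record_every: float | None = None,
    init: np.ndarray | float = 0.0,
) -> SimResult:
    """2-D analogue of :func:`simulate_1d` (see there for conventions)."""
    if not t_end > 0:
        raise ValidationError("t_end must be > 0")
    dt_max = grid.max_stable_dt()
    if dt is None:
        dt = 0.9 * dt_max
    _require_stable(dt, dt_max)
    if record_every is None:
        record_every = t_end

    if np.ndim(init) == 0:
        C = np.full((grid.ny, grid.nx), float(init))
    else:
        C = np.array(init, dtype=float)
    if C.shape != (grid.ny, grid.nx):
        raise ValidationError("init shape does not match grid")

    vol = grid.cell_volume
    ledger = MassLedger(initial=float(C.sum()) * vol / _KC)
    times = [0.0]
    states = [C.copy()]
    stored = [ledger.initial]

    n_steps = int(math.ceil(t_end / dt - 1e-12))
    next_record = record_every
    t = 0.0
    for k in range(n_steps):
        step_dt = min(dt, t_end - t)
        if step_dt <= 0:
            break
        C, deltas = step_2d(C, t, grid, source_flux_fn, clearance, step_dt)
        ledger.influx += deltas["influx"]
        ledger.cleared += deltas["cleared"]
        t += step_dt
        if t + 1e-12 >= next_record or k == n_steps - 1:
            times.append(t)
            states.append(C.copy())
            stored.append(float(C.sum()) * vol / _KC)
            while next_record <= t + 1e-12:
                next_record += record_every

    ledger.stored = float(C.sum()) * vol / _KC
    return SimResult(
        times=np.array(times),
        states=np.array(states),
        ledger=ledger,
        grid=grid,
        stored_series=np.array(stored),
    )
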