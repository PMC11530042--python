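"""Derived quantities and validation statistics.

Averages over regions, classification of the domain against the MIC
(minimum inhibitory concentration, 2 µg/mL for S. aureus) and the toxicity
threshold (1,000 µg/mL), the predicted inhibition area of an agar-plate
simulation, and the one-sample t-test used to compare a simulated inhibition
area with the experimentally measured one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .solver import Grid2D, SimResult

MIC_UG_ML = 2.0
TOXICITY_UG_ML = 1000.0

ZONE_SUB_MIC = 0
ZONE_EFFECTIVE = 1
ZONE_TOXIC = 2


@dataclass
class ZoneMap:
    """Per-cell therapeutic classification of a concentration field.

    ``classes`` holds 0 = sub-MIC (C < MIC), 1 = effective
    (MIC ≤ C ≤ toxicity), 2 = toxic (C > toxicity). ``areas`` maps class name
    to area (cm², 2-D fields) or volume (mm³, 1-D stacks).
    """

    classes: np.ndarray
    areas: dict
    mic: float
    toxicity: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def average_concentration(
    result: SimResult, region: slice | np.ndarray | None = None
) -> np.ndarray:
    """Volume-weighted mean concentration (µg/mL) at each recorded time.

    ``region`` selects cells (slice or index/bool array over the flattened
    grid); None averages the whole domain. Cells are uniform, so the
    volume-weighted mean is the arithmetic mean over the selected cells.
    """
    states = result.states.reshape(result.states.shape[0], -1)
    n = states.shape[1]
    if region is None:
        sel = states
    else:
        idx = np.arange(n)[region]
        if idx.size == 0:
            raise ValidationError("region selects no cells")
        sel = states[:, idx]
    return sel.mean(axis=1)


def inhibition_area(
    field: np.ndarray,
    grid: Grid2D,
    mic: float = MIC_UG_ML,
    include_source: bool = True,
) -> float:
    """Predicted inhibition area (cm²) of a 2-D field.

    Counts cells outside the source footprint with C ≥ MIC, times dx²; when
    ``include_source`` is set (default) the source footprint itself is added,
    matching the convention in which the measured inhibition zone includes
    the substrate. Returns cm².
    """
    if not np.all(np.isfinite(field)):
        raise ValidationError("field contains non-finite values")
    mask = grid.source_mask
    above = field >= mic
    if mask is not None:
        outside = above & ~mask
        n = int(outside.sum())
        if include_source:
            n += int(mask.sum())
    else:
        n = int(above.sum())
    return n * grid.dx**2 / 100.0  # mm² → cm²


def classify_zones(
    field: np.ndarray,
    mic: float = MIC_UG_ML,
    toxicity: float = TOXICITY_UG_ML,
    cell_measure: float = 1.0,
) -> ZoneMap:
    """Partition a field into sub-MIC / effective / toxic classes.

    ``cell_measure`` is the area or volume of one cell in the caller's
    preferred unit; ``areas`` reports the per-class totals in that unit.
    """
    if not mic < toxicity:
        raise ValidationError("MIC must be below the toxicity threshold")
    field = np.asarray(field)
    classes = np.full(field.shape, ZONE_EFFECTIVE, dtype=np.int8)
    classes[field < mic] = ZONE_SUB_MIC
    classes[field > toxicity] = ZONE_TOXIC
    areas = {
        "sub_MIC": float((classes == ZONE_SUB_MIC).sum()) * cell_measure,
        "effective": float((classes == ZONE_EFFECTIVE).sum()) * cell_measure,
        "toxic": float((classes == ZONE_TOXIC).sum()) * cell_measure,
    }
    return ZoneMap(classes=classes, areas=areas, mic=mic, toxicity=toxicity)


def one_sample_t_test(mean: float, sd: float, n: int, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test from summary statistics.

    t = (mean − mu0) / (sd/√n), df = n − 1, p from the t distribution.
    """
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if not sd > 0:
        raise ValidationError(f"sd must be > 0, got {sd}")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)
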