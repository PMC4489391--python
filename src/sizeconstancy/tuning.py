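"""Static tuning-curve families.

Three cell populations feed the model:

* **Disparity-selective cells** (V1, five classes).  Tuned excitatory (TE)
  cells are single Gaussians peaking near zero disparity.  Tuned-near (TN)
  and near (NE) cells peak at crossed (negative) disparity and carry a
  suppressive Gaussian lobe displaced toward uncrossed disparities; tuned-far
  (TF) and far (FA) cells mirror this with the lobe displaced toward crossed
  disparities:

      a(delta) = A1 exp(-(delta - d_i)^2 / s_i^2)
               - A2 exp(-(delta - (d_i +/- s_i/2))^2 / s_i^2) + A3

  Tuned-inhibitory cells are omitted: their responses are equivalent to TE
  cells with negative readout weights.

* **Vergence cells** (frontal eye fields), logistic in vergence angle:
  ``z(v) = 1 / (1 + exp(-(v - v_i) / T_i))``.

* **Size-tuned cells** (V1), Gaussians over angular size whose amplitude is
  multiplied by a distance-dependent gain:
  ``s(beta) = K * exp(-(beta - b_i)^2 / s_i^2)``.

Negative disparity responses (possible from the subtracted lobe) are clipped
at zero by default, since downstream they stand for firing rates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "DisparityClass",
    "DISPARITY_CLASS_RANGES",
    "ZERO_PEAK_WIDTH_DEG",
    "DisparityCell",
    "VergenceCell",
    "SizeCell",
    "SizeScalingKind",
    "disparity_response",
    "vergence_response",
    "size_response",
    "width_for_preferred_disparity",
    "default_disparity_population",
    "default_vergence_population",
    "population_to_records",
]


class DisparityClass(str, Enum):
    """Disparity-cell taxonomy (tuned-inhibitory cells excluded)."""

    TE = "TE"  # tuned excitatory: peak at/near zero disparity
    TN = "TN"  # tuned near: peak at crossed disparity
    TF = "TF"  # tuned far: peak at uncrossed disparity
    NE = "NE"  # near: broad response over crossed disparities
    FA = "FA"  # far: broad response over uncrossed disparities


#: Admissible preferred-disparity range (degrees) per class.
DISPARITY_CLASS_RANGES: dict[DisparityClass, tuple[float, float]] = {
    DisparityClass.TN: (-4.0, -1.5),
    DisparityClass.NE: (-4.0, -1.5),
    DisparityClass.TE: (-1.5, 1.5),
    DisparityClass.TF: (1.5, 4.0),
    DisparityClass.FA: (1.5, 4.0),
}

#: Tuning width used for cells whose peak lies within 10 arcmin of zero.
ZERO_PEAK_WIDTH_DEG = 10.0 / 60.0


@dataclass(frozen=True)
class DisparityCell:
    """One disparity-selective unit.

    ``amplitudes`` are the (A1, A2, A3) response constants: primary Gaussian
    height, suppressive-lobe height and additive baseline.  TE cells have a
    single Gaussian, so A2 = A3 = 0 is enforced.
    """

    cell_class: DisparityClass
    preferred_disparity: float  # degrees
    width: float  # degrees
    amplitudes: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        a1, a2, a3 = self.amplitudes
        if a1 <= 0:
            raise ValueError(f"A1 must be > 0, got {a1}")
        lo, hi = DISPARITY_CLASS_RANGES[self.cell_class]
        if not lo <= self.preferred_disparity <= hi:
            raise ValueError(
                f"{self.cell_class.value} preferred disparity must lie in "
                f"[{lo}, {hi}] deg, got {self.preferred_disparity}"
            )
        if self.cell_class is DisparityClass.TE and (a2 != 0 or a3 != 0):
            raise ValueError("TE cells are single Gaussians: A2 and A3 must be 0")


@dataclass(frozen=True)
class VergenceCell:
    """One vergence-selective unit: logistic with midpoint ``threshold`` and
    steepness set by ``slope`` (degrees; smaller = steeper)."""

    threshold: float  # degrees
    slope: float  # degrees

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


class SizeScalingKind(str, Enum):
    """Distance dependence of a size-tuned cell's response amplitude."""

    INDEPENDENT = "independent"
    FARNESS = "farness"
    NEARNESS = "nearness"


@dataclass(frozen=True)
class SizeCell:
    """One size-tuned unit: Gaussian over angular size (degrees), with the
    distance-gain behaviour named by ``scaling_kind``."""

    preferred_size: float  # degrees, within [0, 3.2]
    width: float  # degrees
    scaling_kind: SizeScalingKind = SizeScalingKind.INDEPENDENT
    scaling_constant: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.preferred_size <= 3.2:
            raise ValueError(
                f"preferred size must lie in [0, 3.2] deg, got {self.preferred_size}"
            )
        if self.width <= 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if self.scaling_constant <= 0:
            raise ValueError(f"scaling constant must be > 0, got {self.scaling_constant}")


# -- responses ---------------------------------------------------------------


def _lobe_center(cell: DisparityCell) -> float:
    """Centre of the suppressive Gaussian lobe.

    Displaced toward uncrossed disparities for near-type cells and toward
    crossed disparities for far-type cells, producing the push–pull
    asymmetry of the two class families.
    """
    if cell.cell_class in (DisparityClass.TN, DisparityClass.NE):
        return cell.preferred_disparity + cell.width / 2.0
    if cell.cell_class in (DisparityClass.TF, DisparityClass.FA):
        return cell.preferred_disparity - cell.width / 2.0
    raise ValueError("TE cells have no suppressive lobe")


def disparity_response(
    cell: DisparityCell, delta: float | np.ndarray, clip_negative: bool = True
) -> float | np.ndarray:
    """Response of a disparity cell at disparity ``delta`` (degrees).

    Evaluates the class-appropriate (difference-of-)Gaussian profile; by
    default the result is clipped at zero, as it models a firing rate.
    Accepts scalars or arrays.
    """
    delta = np.asarray(delta, dtype=float)
    a1, a2, a3 = cell.amplitudes
    s2 = cell.width**2
    r = a1 * np.exp(-((delta - cell.preferred_disparity) ** 2) / s2)
    if cell.cell_class is not DisparityClass.TE:
        r = r - a2 * np.exp(-((delta - _lobe_center(cell)) ** 2) / s2) + a3
    if clip_negative:
        r = np.maximum(r, 0.0)
    return float(r) if r.ndim == 0 else r


def vergence_response(cell: VergenceCell, v: float | np.ndarray) -> float | np.ndarray:
    """Logistic response in (0, 1), strictly increasing in vergence."""
    v = np.asarray(v, dtype=float)
    r = expit((v - cell.threshold) / cell.slope)
    return float(r) if r.ndim == 0 else r


def size_response(
    cell: SizeCell, beta: float | np.ndarray, scale: float = 1.0
) -> float | np.ndarray:
    """Distance-scaled size response ``scale * exp(-(beta - b_i)^2 / s_i^2)``.

    The gain ``scale`` multiplies the whole curve, so the peak position and
    width never change with distance.
    """
    if scale < 0:
        raise ValueError(f"scale must be >= 0, got {scale}")
    beta = np.asarray(beta, dtype=float)
    r = scale * np.exp(-((beta - cell.preferred_size) ** 2) / cell.width**2)
    return float(r) if r.ndim == 0 else r


# -- default populations -----------------------------------------------------


def width_for_preferred_disparity(preferred_deg: float) -> float:
    """Tuning width rule: the width equals ``|preferred disparity|`` except
    within 10 arcmin of zero, where it is pinned to 10 arcmin."""
    if abs(preferred_deg) < ZERO_PEAK_WIDTH_DEG:
        return ZERO_PEAK_WIDTH_DEG
    return abs(preferred_deg)

# Base amplitude shape (A1, A2, A3) before peak normalization.  The 0.5
# suppressive lobe and 0.1 baseline give the push-pull profile with a
# below-baseline dip on the anti-preferred side.
_BASE_AMPLITUDES = {
    DisparityClass.TE: (1.0, 0.0, 0.0),
    DisparityClass.TN: (1.0, 0.5, 0.1),
    DisparityClass.NE: (1.0, 0.5, 0.1),
    DisparityClass.TF: (1.0, 0.5, 0.1),
    DisparityClass.FA: (1.0, 0.5, 0.1),
}

_CLASS_ORDER = (
    DisparityClass.TE,
    DisparityClass.TN,
    DisparityClass.TF,
    DisparityClass.NE,
    DisparityClass.FA,
)


def _normalize_peak(cell: DisparityCell, grid_step: float = 0.01) -> DisparityCell:
    """Rescale (A1, A2, A3) jointly so the cell's maximum response is 1 on a
    dense disparity grid over [-4, 4] degrees."""
    grid = np.arange(-4.0, 4.0 + grid_step / 2, grid_step)
    peak = float(np.max(disparity_response(cell, grid, clip_negative=False)))
    a1, a2, a3 = cell.amplitudes
    return replace(cell, amplitudes=(a1 / peak, a2 / peak, a3 / peak))


def default_disparity_population(n: int = 40) -> list[DisparityCell]:
    """Disparity population tiling the five class ranges.

    Cells are allocated as evenly as possible across the classes (8 per
    class at the default n=40), with preferred disparities evenly spaced
    within each class range, widths from
    :func:`width_for_preferred_disparity`, and amplitudes normalized so
    every cell peaks at 1 (within grid resolution).
    """
    if n < 5:
        raise ValueError(f"need at least one cell per class (n >= 5), got n={n}")
    counts = {c: n // 5 for c in _CLASS_ORDER}
    for c in _CLASS_ORDER[: n % 5]:
        counts[c] += 1
    cells: list[DisparityCell] = []
    for cls in _CLASS_ORDER:
        lo, hi = DISPARITY_CLASS_RANGES[cls]
        k = counts[cls]
        prefs = np.linspace(lo, hi, k) if k > 1 else np.array([(lo + hi) / 2.0])
        for p in prefs:
            cell = DisparityCell(
                cell_class=cls,
                preferred_disparity=float(p),
                width=width_for_preferred_disparity(float(p)),
                amplitudes=_BASE_AMPLITUDES[cls] if cls is not DisparityClass.TE else (1.0, 0.0, 0.0),
            )
            cells.append(_normalize_peak(cell))
    return cells


def default_vergence_population(
    n: int = 5, vergence_range: tuple[float, float] = (1.0, 15.0), slope: float = 0.75
) -> list[VergenceCell]:
    """``n`` logistic vergence cells with thresholds evenly spaced over the
    working vergence range and a common slope (degrees).

    At zero disparity the distance readout is spanned by the vergence
    curves alone, so the default slope is chosen steep enough that five
    sigmoids resolve the rapid near-range portion of the distance law.
    """
    if n < 1:
        raise ValueError(f"need at least one vergence cell, got n={n}")
    lo, hi = vergence_range
    thresholds = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    return [VergenceCell(threshold=float(t), slope=slope) for t in thresholds]


def population_to_records(cells: Sequence[DisparityCell]) -> list[dict]:
    """Serializable summary of a disparity population (for config round-trips
    and CSV export)."""
    return [
        {
            "cell_class": c.cell_class.value,
            "preferred_disparity": c.preferred_disparity,
            "width": c.width,
            "a1": c.amplitudes[0],
            "a2": c.amplitudes[1],
            "a3": c.amplitudes[2],
        }
        for c in cells
    ]
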