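"""Distance-scaled size tuning and topographic shunting dynamics.

**Distance scaling.**  Each size-tuned cell carries a gain ``K(d)`` set by
its scaling kind: distance-independent cells keep ``K = C``; farness cells
have ``K = C * d`` (response grows with viewing distance); nearness cells
have ``K = C / d`` (response shrinks with viewing distance).  The gain
multiplies the cell's Gaussian size tuning, so peak position and width are
distance-invariant — only the amplitude changes.

**Topographic map.**  Size-tuned cells are laid out along a 1-D axis with
preferred angular size non-decreasing, a proxy for cortical eccentricity
(larger perceived sizes engage more eccentric retinotopic loci).  Cells
interact through Gaussian excitatory and broader inhibitory kernels over
preferred-size difference (centre–surround), with self-connections zeroed.

**Shunting dynamics.**  Each cell's activity obeys the membrane equation

    dS_i/dt = -B1_i * S_i + (B2 - S_i) * sum_k I_k s_ki
                          - (B3 + S_i) * sum_k I_k s'_ki

so excitation drives activity toward the ceiling ``B2``, inhibition toward
``-B3``, and activity decays at rate ``B1``; the decay rate may itself be
scaled by the distance estimate of the current stimulus (farness-like decay
modulation).  Activities therefore remain in ``[-B3, B2]`` for any input.
A literal mode with the excitatory term entering negatively is provided for
comparison only; it makes excitatory input suppressive and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .tuning import SizeCell, SizeScalingKind, size_response

__all__ = [
    "ScalingFunction",
    "distance_scale",
    "TopographicMap",
    "default_size_map",
    "scaled_size_tuning",
    "interaction_kernels",
    "StimulusEvent",
    "StimulusProtocol",
    "ShuntingConfig",
    "Integrator",
    "ShuntingInstabilityError",
    "shunting_equilibrium",
    "simulate_dynamics",
    "roi_timecourses",
]


@dataclass(frozen=True)
class ScalingFunction:
    """Distance-scaling rule ``K(d)`` of a size-tuned cell.

    ``literal_nearness`` switches nearness cells to the gain ``K = d``
    (increasing with distance).  That variant is kept for comparison only:
    it contradicts the defining property of nearness cells (response
    decreasing with viewing distance), which the default ``K = C / d``
    implements.
    """

    kind: SizeScalingKind
    constant: float = 1.0
    literal_nearness: bool = False

    def __post_init__(self) -> None:
        if self.constant <= 0:
            raise ValueError(f"scaling constant must be > 0, got {self.constant}")


def distance_scale(f: ScalingFunction, d: float) -> float:
    """Gain ``K(d)`` for viewing distance ``d`` (metres, > 0)."""
    if d <= 0:
        raise ValueError(f"viewing distance must be > 0 m, got {d}")
    if f.kind is SizeScalingKind.INDEPENDENT:
        return f.constant
    if f.kind is SizeScalingKind.FARNESS:
        return f.constant * d
    if f.literal_nearness:
        return d
    return f.constant / d


def _cell_scaling(cell: SizeCell, literal_nearness: bool = False) -> ScalingFunction:
    return ScalingFunction(
        kind=cell.scaling_kind,
        constant=cell.scaling_constant,
        literal_nearness=literal_nearness,
    )


@dataclass(frozen=True)
class TopographicMap:
    """1-D eccentricity-ordered sheet of size-tuned cells.

    ``cells`` must be ordered by non-decreasing preferred size (neighbouring
    cells prefer similar angular sizes).  The interaction kernel widths are
    in degrees of preferred-size difference; the inhibitory surround must be
    broader than the excitatory centre.
    """

    cells: tuple[SizeCell, ...]
    excitatory_kernel_width: float = 0.2
    inhibitory_kernel_width: float = 0.6

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", tuple(self.cells))
        prefs = [c.preferred_size for c in self.cells]
        if any(b < a for a, b in zip(prefs, prefs[1:])):
            raise ValueError("cells must be ordered by non-decreasing preferred size")
        if self.excitatory_kernel_width <= 0 or self.inhibitory_kernel_width <= 0:
            raise ValueError("kernel widths must be > 0")
        if self.inhibitory_kernel_width <= self.excitatory_kernel_width:
            raise ValueError(
                "inhibitory kernel must be broader than excitatory (centre-surround)"
            )

    @property
    def preferred_sizes(self) -> np.ndarray:
        return np.array([c.preferred_size for c in self.cells])

    def with_kernel_widths(self, excitatory: float, inhibitory: float) -> "TopographicMap":
        return replace(
            self, excitatory_kernel_width=excitatory, inhibitory_kernel_width=inhibitory
        )


def default_size_map(
    n_cells: int = 61,
    size_range: tuple[float, float] = (0.0, 3.2),
    tuning_width: float = 0.4,
    scaling_kind: SizeScalingKind = SizeScalingKind.FARNESS,
    scaling_constant: float = 1.0,
    excitatory_kernel_width: float = 0.2,
    inhibitory_kernel_width: float = 0.6,
) -> TopographicMap:
    """Evenly tiled topographic map over the angular-size working range
    [0, 3.2] degrees, all cells of one scaling kind."""
    if n_cells < 2:
        raise ValueError(f"need at least 2 cells, got {n_cells}")
    prefs = np.linspace(size_range[0], size_range[1], n_cells)
    cells = tuple(
        SizeCell(
            preferred_size=float(b),
            width=tuning_width,
            scaling_kind=scaling_kind,
            scaling_constant=scaling_constant,
        )
        for b in prefs
    )
    return TopographicMap(
        cells=cells,
        excitatory_kernel_width=excitatory_kernel_width,
        inhibitory_kernel_width=inhibitory_kernel_width,
    )


def scaled_size_tuning(
    topo: TopographicMap,
    beta: float | np.ndarray,
    d: float,
    literal_nearness: bool = False,
) -> np.ndarray:
    """Population response to angular size ``beta`` at viewing distance ``d``.

    Element ``i`` is ``K_i(d) * exp(-(beta - b_i)^2 / s_i^2)`` with each
    cell's own scaling function.  For scalar ``beta`` the result has shape
    (n_cells,); for an array of sizes, (len(beta), n_cells).
    """
    gains = np.array(
        [distance_scale(_cell_scaling(c, literal_nearness), d) for c in topo.cells]
    )
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    resp = np.column_stack(
        [size_response(c, beta_arr, scale=g) for c, g in zip(topo.cells, gains)]
    )
    return resp[0] if np.isscalar(beta) or np.asarray(beta).ndim == 0 else resp


def interaction_kernels(topo: TopographicMap) -> tuple[np.ndarray, np.ndarray]:
    """Excitatory and inhibitory connection matrices ``(s_ki, s'_ki)``.

    Gaussian in the preferred-size difference with the map's configured
    widths (same functional form as the size tuning curves); the inhibitory
    surround is broader.  Self-connections (k == i) are zeroed.
    """
    if len(topo.cells) < 2:
        raise ValueError("interaction kernels need at least 2 cells")
    prefs = topo.preferred_sizes
    diff2 = (prefs[:, None] - prefs[None, :]) ** 2
    exc = np.exp(-diff2 / topo.excitatory_kernel_width**2)
    inh = np.exp(-diff2 / topo.inhibitory_kernel_width**2)
    np.fill_diagonal(exc, 0.0)
    np.fill_diagonal(inh, 0.0)
    return exc, inh


# -- stimulus protocol -------------------------------------------------------


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation epoch.

    ``amplitude_factor`` multiplies the protocol amplitude (e.g. 0.5 for an
    afterimage-like second presentation).
    """

    onset: float  # seconds
    offset: float  # seconds
    angular_size: float  # degrees (retinal)
    viewing_distance: float  # metres
    amplitude_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(f"event offset {self.offset} must exceed onset {self.onset}")
        if self.viewing_distance <= 0:
            raise ValueError("viewing distance must be > 0")
        if self.angular_size < 0:
            raise ValueError("angular size must be >= 0")


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-ordered, non-overlapping stimulus events.

    ``size_distance_scaling`` applies the size–distance invariance scaling
    to the drive: the population input is centred on the *perceived* angular
    size ``angular_size * d / d_ref`` rather than the retinal size, with
    ``d_ref`` the reference distance (defaults to the first event's
    distance).  A stimulus of fixed retinal size seen farther away therefore
    drives more eccentric (larger-preferred-size) cells maximally.
    """

    events: tuple[StimulusEvent, ...]
    amplitude: float = 1.0
    size_distance_scaling: bool = True
    reference_distance: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if not self.events:
            raise ValueError("protocol needs at least one event")
        for a, b in zip(self.events, self.events[1:]):
            if b.onset < a.offset:
                raise ValueError(
                    f"events overlap or are out of order: {a.offset} > {b.onset}"
                )
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")

    @property
    def duration(self) -> float:
        return self.events[-1].offset


# -- shunting dynamics -------------------------------------------------------


class Integrator(str, Enum):
    EULER = "euler"
    RK4 = "rk4"


class ShuntingInstabilityError(RuntimeError):
    """Raised when the integration leaves the shunting bounds (dt too large)."""


@dataclass(frozen=True)
class ShuntingConfig:
    """Shunting-equation parameters.

    ``decay`` is the baseline decay rate B1 (1/s) before distance scaling;
    when ``decay_distance_scaling`` is on, the effective decay during a
    stimulus is ``B1 * decay_scaling_constant * d_hat`` (farness-like
    modulation by the distance estimate).  ``excitatory_ceiling`` (B2) and
    ``inhibitory_floor`` (B3) bound activity in [-B3, B2]; the defaults
    B2 = 1, B3 = 0 keep activities non-negative.  ``literal_sign`` restores
    the variant with a negative excitatory term (comparison only).
    """

    decay: float = 1.0  # B1, 1/s
    excitatory_ceiling: float = 1.0  # B2
    inhibitory_floor: float = 0.0  # B3
    dt: float = 0.005  # s
    relaxation_tail: float = 1.0  # s simulated after the last offset
    integrator: Integrator = Integrator.RK4
    decay_distance_scaling: bool = True
    decay_scaling_constant: float = 1.0
    literal_sign: bool = False

    def __post_init__(self) -> None:
        if self.excitatory_ceiling <= 0:
            raise ValueError("B2 (excitatory ceiling) must be > 0")
        if self.inhibitory_floor < 0:
            raise ValueError("B3 (inhibitory floor) must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")


def shunting_equilibrium(
    cfg: ShuntingConfig,
    excitation: np.ndarray,
    inhibition: np.ndarray,
    decay: float | None = None,
) -> np.ndarray:
    """Closed-form steady state under constant input:
    ``S* = (B2 E - B3 H) / (B1 + E + H)`` per cell."""
    b1 = cfg.decay if decay is None else decay
    e = np.asarray(excitation, dtype=float)
    h = np.asarray(inhibition, dtype=float)
    return (cfg.excitatory_ceiling * e - cfg.inhibitory_floor * h) / (b1 + e + h)


def _event_drive(
    topo: TopographicMap,
    protocol: StimulusProtocol,
    event: StimulusEvent,
    d_hat: float,
    d_hat_ref: float,
) -> np.ndarray:
    """Stimulus input vector I_k for one event: protocol amplitude times the
    distance-scaled size tuning, centred on the perceived size when the
    size-distance scaling is enabled."""
    beta = event.angular_size
    if protocol.size_distance_scaling:
        beta = event.angular_size * d_hat / d_hat_ref
    return (
        protocol.amplitude
        * event.amplitude_factor
        * scaled_size_tuning(topo, float(beta), d_hat)
    )


def simulate_dynamics(
    topo: TopographicMap,
    cfg: ShuntingConfig,
    protocol: StimulusProtocol,
    d_source: Callable[[StimulusEvent], float] | None = None,
    initial_state: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the distance-dependent shunting equations over the protocol.

    ``d_source`` maps each event to the distance estimate fed back to the
    map (defaults to the event's physical viewing distance, i.e. a veridical
    estimate).  Returns ``(times, activity)`` with ``activity`` of shape
    (n_times, n_cells); ``times[0] = 0`` holds the initial state and the
    simulation runs ``relaxation_tail`` seconds past the last offset.

    Raises :class:`ShuntingInstabilityError` if any activity leaves
    ``[-B3 - 1e-6, B2 + 1e-6]``, and ValueError if the Euler stability bound
    ``dt * (B1 + E + H) < 1`` is violated.
    """
    if d_source is None:
        d_source = lambda ev: ev.viewing_distance

    exc_k, inh_k = interaction_kernels(topo)
    n = len(topo.cells)
    b2, b3 = cfg.excitatory_ceiling, cfg.inhibitory_floor

    # reference distance estimate for the perceived-size drive centre
    if protocol.reference_distance is not None:
        ref_event = replace(
            protocol.events[0], viewing_distance=protocol.reference_distance
        )
        d_hat_ref = d_source(ref_event)
    else:
        d_hat_ref = d_source(protocol.events[0])

    # piecewise-constant per-event drives and effective decay rates
    segments = []  # (onset, offset, E, H, b1_eff)
    for ev in protocol.events:
        d_hat = d_source(ev)
        drive = _event_drive(topo, protocol, ev, d_hat, d_hat_ref)
        e_vec = exc_k @ drive
        h_vec = inh_k @ drive
        b1 = cfg.decay
        if cfg.decay_distance_scaling:
            b1 = cfg.decay * cfg.decay_scaling_constant * d_hat
        segments.append((ev.onset, ev.offset, e_vec, h_vec, b1))

    duration = protocol.duration + cfg.relaxation_tail
    n_steps = int(round(duration / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    activity = np.zeros((n_steps + 1, n))
    s = (
        np.zeros(n)
        if initial_state is None
        else np.array(initial_state, dtype=float)
    )
    activity[0] = s

    zero = np.zeros(n)
    exc_sign = -1.0 if cfg.literal_sign else 1.0

    def drive_at(t: float) -> tuple[np.ndarray, np.ndarray, float]:
        for onset, offset, e_vec, h_vec, b1 in segments:
            if onset <= t < offset:
                return e_vec, h_vec, b1
        return zero, zero, cfg.decay

    def rhs(state: np.ndarray, e: np.ndarray, h: np.ndarray, b1: float) -> np.ndarray:
        return -b1 * state + exc_sign * (b2 - state) * e - (b3 + state) * h

    tol = 1e-6
    for step in range(n_steps):
        t = times[step]
        e, h, b1 = drive_at(t)  # input held constant across the step
        if cfg.integrator is Integrator.EULER:
            gain = cfg.dt * (b1 + e + h)
            if np.any(gain >= 1.0):
                raise ValueError(
                    "Euler stability bound dt*(B1 + E + H) < 1 violated "
                    f"(max {float(np.max(gain)):.3f}); reduce dt"
                )
            s = s + cfg.dt * rhs(s, e, h, b1)
        else:
            k1 = rhs(s, e, h, b1)
            k2 = rhs(s + 0.5 * cfg.dt * k1, e, h, b1)
            k3 = rhs(s + 0.5 * cfg.dt * k2, e, h, b1)
            k4 = rhs(s + cfg.dt * k3, e, h, b1)
            s = s + cfg.dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not cfg.literal_sign and (
            np.any(s > b2 + tol) or np.any(s < -b3 - tol)
        ):
            raise ShuntingInstabilityError(
                f"activity left [-B3, B2] at t={t + cfg.dt:.3f}s; reduce dt"
            )
        activity[step + 1] = s
    return times, activity


def roi_timecourses(activity: np.ndarray, n_rois: int = 5) -> np.ndarray:
    """Mean activity per contiguous eccentricity band.

    Splits the cell axis (ordered by preferred size, the eccentricity proxy)
    into ``n_rois`` contiguous bands and averages within each.  Returns an
    array of shape (n_times, n_rois), ROI 1 the least eccentric band.
    """
    activity = np.asarray(activity, dtype=float)
    n_cells = activity.shape[1]
    if n_rois < 1 or n_rois > n_cells:
        raise ValueError(f"n_rois must be in [1, {n_cells}], got {n_rois}")
    bands = np.array_split(np.arange(n_cells), n_rois)
    return np.column_stack([activity[:, b].mean(axis=1) for b in bands])
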