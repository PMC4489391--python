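"""Gain-field distance network: MT basis layer and trained LIP readout.

Each MT unit multiplies one disparity tuning curve by one vergence sigmoid,

    B_i(delta, v) = a_i(delta) * z_i(v),

so the basis set is the full Cartesian product of the two populations (the
default 40 x 5 populations give 200 gain-modulated units).  The LIP distance
estimate is the linear readout

    D(delta, v) = sum_i w_i * B_i(delta, v),

whose weights are found with the delta rule — online stochastic gradient
descent on squared error against a perceived-distance teaching signal
evaluated over a (vergence, disparity) training grid.  Because the readout
is linear in the weights, batch least squares over the same design matrix is
the natural oracle: the delta rule's grid RMSE converges toward (and can
never beat) the least-squares RMSE.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import (
    DEFAULT_CORRECTION,
    DEFAULT_INTEROCULAR_DISTANCE,
    MIN_OBJECT_ANGLE_DEG,
    DisparityCorrection,
    ViewingGeometry,
    perceived_distance,
)
from .tuning import (
    DisparityCell,
    VergenceCell,
    default_disparity_population,
    default_vergence_population,
    disparity_response,
    population_to_records,
    vergence_response,
)

__all__ = [
    "TrainingConfig",
    "TrainingDivergenceError",
    "DistanceNetwork",
    "make_training_grid",
    "perceived_distance_teacher",
    "basis_activation",
    "readout_distance",
    "train_readout",
    "least_squares_weights",
    "relative_rmse",
]

logger = logging.getLogger(__name__)


class TrainingDivergenceError(RuntimeError):
    """Raised when delta-rule training diverges (learning rate too large)."""


@dataclass
class TrainingConfig:
    """Delta-rule training settings.

    ``learning_rate`` must respect the online stability bound
    eta < 2 / max ||B(sample)||^2; the default is safe for the default
    populations.  ``max_distance`` caps the teaching signal so near-singular
    geometry (object angle -> 0) does not dominate the squared-error loss.
    """

    learning_rate: float = 0.03
    epochs: int = 400
    seed: int = 0
    vergence_range: tuple[float, float] = (1.0, 15.0)
    disparity_range: tuple[float, float] = (-4.0, 4.0)
    grid_points: int = 30
    max_distance: float = 20.0
    target_rel_rmse: float = 0.05
    ridge: float = 0.0  # optional Tikhonov term for ill-conditioned bases

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def make_training_grid(cfg: TrainingConfig) -> np.ndarray:
    """(n_samples, 2) array of (vergence, disparity) pairs, the product grid
    intersected with the valid-geometry domain (object angle > 0)."""
    v = np.linspace(*cfg.vergence_range, cfg.grid_points)
    d = np.linspace(*cfg.disparity_range, cfg.grid_points)
    vv, dd = np.meshgrid(v, d, indexing="ij")
    pts = np.column_stack([vv.ravel(), dd.ravel()])
    valid = pts[:, 0] - pts[:, 1] > MIN_OBJECT_ANGLE_DEG
    return pts[valid]


def perceived_distance_teacher(
    grid: np.ndarray,
    max_distance: float = 20.0,
    interocular: float = DEFAULT_INTEROCULAR_DISTANCE,
    correction: DisparityCorrection = DEFAULT_CORRECTION,
) -> np.ndarray:
    """Perceived-distance teaching signal over the grid, capped at
    ``max_distance`` metres."""
    out = np.empty(len(grid))
    for i, (v, d) in enumerate(grid):
        g = ViewingGeometry(vergence=float(v), disparity=float(d), interocular_distance=interocular)
        out[i] = min(perceived_distance(g, correction), max_distance)
    return out


@dataclass
class DistanceNetwork:
    """MT basis set plus the LIP readout weight vector.

    The basis is ordered disparity-major: unit ``i * n_vergence + j`` pairs
    disparity cell ``i`` with vergence cell ``j``.  ``training_log`` holds
    (epoch, grid RMSE in metres) pairs appended by :func:`train_readout`.
    """

    disparity_population: list[DisparityCell] = field(default_factory=default_disparity_population)
    vergence_population: list[VergenceCell] = field(default_factory=default_vergence_population)
    weights: np.ndarray | None = None
    training_log: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.disparity_population or not self.vergence_population:
            raise ValueError("both populations must be non-empty")
        if self.weights is None:
            self.weights = np.zeros(self.n_basis)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_basis,):
                raise ValueError(
                    f"weights must have length {self.n_basis}, got {self.weights.shape}"
                )

    @property
    def n_basis(self) -> int:
        return len(self.disparity_population) * len(self.vergence_population)

    # convenience wrappers around the module-level functions
    def activation(self, delta: float, v: float) -> np.ndarray:
        return basis_activation(self, delta, v)

    def readout(self, delta: float, v: float) -> float:
        return readout_distance(self, delta, v)

    def design_matrix(self, grid: np.ndarray) -> np.ndarray:
        """(n_samples, n_basis) matrix of basis activations over the grid of
        (vergence, disparity) pairs."""
        a = np.column_stack(
            [disparity_response(c, grid[:, 1]) for c in self.disparity_population]
        )  # (n, n_disp)
        z = np.column_stack(
            [vergence_response(c, grid[:, 0]) for c in self.vergence_population]
        )  # (n, n_verg)
        return np.einsum("ni,nj->nij", a, z).reshape(len(grid), -1)

    def save_weights(self, path: str | Path) -> None:
        """Serialize the weight vector (with the generating population
        configuration) to a JSON document."""
        doc = {
            "weights": list(map(float, self.weights)),
            "disparity_population": population_to_records(self.disparity_population),
            "vergence_population": [
                {"threshold": c.threshold, "slope": c.slope} for c in self.vergence_population
            ],
            "training_log": [[int(e), float(r)] for e, r in self.training_log],
        }
        Path(path).write_text(json.dumps(doc, indent=2))


def basis_activation(net: DistanceNetwork, delta: float, v: float) -> np.ndarray:
    """MT activation vector at one (disparity, vergence) input: the outer
    product of disparity responses and vergence gates, flattened
    disparity-major."""
    a = np.array([disparity_response(c, delta) for c in net.disparity_population])
    z = np.array([vergence_response(c, v) for c in net.vergence_population])
    return np.outer(a, z).ravel()


def readout_distance(net: DistanceNetwork, delta: float, v: float) -> float:
    """LIP distance estimate (metres): inner product of the weights with the
    basis activation.  An untrained (all-zero) network returns 0 with a
    warning."""
    if not np.any(net.weights):
        logger.warning("readout from untrained network (all-zero weights); returning 0")
    return float(net.weights @ basis_activation(net, delta, v))


def train_readout(
    net: DistanceNetwork,
    cfg: TrainingConfig,
    teacher: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> DistanceNetwork:
    """Train the readout weights with the online delta rule.

    Samples are shuffled every epoch with the seeded generator and weights
    updated per sample, ``w <- w + eta * (teacher - w.B) * B``.  If
    ``teacher``/``grid`` are omitted, the perceived-distance teaching signal
    over the config's grid is used.  The per-epoch grid RMSE is appended to
    ``net.training_log``.  Raises :class:`TrainingDivergenceError` if the
    RMSE grows tenfold within ten epochs.
    """
    if grid is None:
        grid = make_training_grid(cfg)
    if teacher is None:
        teacher = perceived_distance_teacher(grid, max_distance=cfg.max_distance)
    teacher = np.asarray(teacher, dtype=float)
    if len(teacher) != len(grid):
        raise ValueError("teacher and grid lengths differ")
    if not np.all(np.isfinite(teacher)):
        raise ValueError("teacher contains non-finite values")

    X = net.design_matrix(grid)
    w = net.weights.copy()
    rng = np.random.default_rng(cfg.seed)
    n = len(grid)
    order = np.arange(n)

    def grid_rmse(wv: np.ndarray) -> float:
        return float(np.sqrt(np.mean((X @ wv - teacher) ** 2)))

    start_epoch = net.training_log[-1][0] if net.training_log else 0
    recent: list[float] = []
    for epoch in range(1, cfg.epochs + 1):
        rng.shuffle(order)
        for k in order:
            x = X[k]
            err = teacher[k] - x @ w
            w += cfg.learning_rate * (err * x - cfg.ridge * w)
        rmse = grid_rmse(w)
        net.training_log.append((start_epoch + epoch, rmse))
        recent.append(rmse)
        if len(recent) > 10:
            recent.pop(0)
        if not np.isfinite(rmse) or (len(recent) == 10 and rmse > 10.0 * recent[0]):
            raise TrainingDivergenceError(
                f"grid RMSE grew to {rmse:.3g} (10-epoch baseline {recent[0]:.3g}); "
                "reduce the learning rate"
            )
    net.weights = w
    return net


def relative_rmse(predicted: np.ndarray, target: np.ndarray) -> float:
    """Range-normalized RMSE (NRMSE): RMSE divided by the target's spread.

    The teaching signal spans roughly two orders of magnitude in metres
    (tens of centimetres at large object angles up to the capped maximum),
    so normalizing by the mean or RMS would let the near-singular corner of
    the domain dominate the score; normalizing by ``max - min`` is the
    standard NRMSE convention for wide-range targets.
    """
    predicted = np.asarray(predicted, dtype=float)
    target = np.asarray(target, dtype=float)
    spread = float(np.max(target) - np.min(target))
    if spread <= 0:
        raise ValueError("target has zero spread; relative RMSE undefined")
    return float(np.sqrt(np.mean((predicted - target) ** 2)) / spread)


def least_squares_weights(
    net: DistanceNetwork, grid: np.ndarray, teacher: np.ndarray
) -> tuple[np.ndarray, float]:
    """Batch least-squares oracle over the same basis: returns the optimal
    weights and their grid RMSE (the floor for the delta rule)."""
    X = net.design_matrix(grid)
    w, *_ = np.linalg.lstsq(X, np.asarray(teacher, dtype=float), rcond=None)
    rmse = float(np.sqrt(np.mean((X @ w - teacher) ** 2)))
    return w, rmse
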