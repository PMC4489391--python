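"""Fit-quality measures between an empirical curve and a simulated curve.

Three scalar measures compare a reference time course ``F`` (e.g. a BOLD
signal change) with a simulated one ``S``:

* ``cca`` — cosine of the correlation angle, ``<F, S> / (||F|| ||S||)``;
  1 when the curves are positive scalar multiples of each other.
* ``drms`` — difference in root mean square,
  ``RMS(F - S) / (RMS(F) + RMS(S))``; 0 iff the curves are identical.
* ``pearson_r`` — the product-moment correlation coefficient.

Confidence intervals are obtained by a seeded percentile bootstrap over
time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "CurvePair",
    "cca",
    "rms",
    "drms",
    "pearson_r",
    "bootstrap_ci",
    "compare_curves",
]


@dataclass(frozen=True)
class CurvePair:
    """Equal-length reference (``F``) and candidate (``S``) sample vectors."""

    reference: np.ndarray
    candidate: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.reference, dtype=float)
        s = np.asarray(self.candidate, dtype=float)
        if f.ndim != 1 or s.ndim != 1:
            raise ValueError("curves must be one-dimensional")
        if len(f) != len(s):
            raise ValueError(f"curve lengths differ: {len(f)} vs {len(s)}")
        if len(f) < 2:
            raise ValueError("curves must have at least 2 samples")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(s))):
            raise ValueError("curves must be finite")
        object.__setattr__(self, "reference", f)
        object.__setattr__(self, "candidate", s)


def _as_pair(p: CurvePair | tuple) -> CurvePair:
    return p if isinstance(p, CurvePair) else CurvePair(*p)


def cca(p: CurvePair) -> float:
    """Cosine of the correlation angle between the two curves, in [-1, 1]."""
    p = _as_pair(p)
    nf = np.linalg.norm(p.reference)
    ns = np.linalg.norm(p.candidate)
    if nf == 0 or ns == 0:
        raise ValueError("cca undefined for a zero-norm curve")
    return float(np.dot(p.reference, p.candidate) / (nf * ns))


def rms(x: np.ndarray) -> float:
    """Root mean square, ``sqrt(mean(x^2))``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty vector is undefined")
    return float(np.sqrt(np.mean(x**2)))


def drms(p: CurvePair) -> float:
    """Normalized RMS difference, ``RMS(F-S) / (RMS(F) + RMS(S))``."""
    p = _as_pair(p)
    denom = rms(p.reference) + rms(p.candidate)
    if denom == 0:
        raise ValueError("drms undefined when both curves are identically zero")
    return float(rms(p.reference - p.candidate) / denom)


def pearson_r(p: CurvePair) -> float:
    """Pearson product-moment correlation coefficient, in [-1, 1].

    Defined as the covariance of the two curves over the product of their
    standard deviations; undefined (raises) if either curve has zero
    variance.
    """
    p = _as_pair(p)
    if np.var(p.reference) == 0 or np.var(p.candidate) == 0:
        raise ValueError("pearson_r undefined for a zero-variance curve")
    return float(np.corrcoef(p.reference, p.candidate)[0, 1])


def bootstrap_ci(
    metric: Callable[[CurvePair], float],
    p: CurvePair,
    n_resamples: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile-bootstrap confidence interval over time points.

    Resamples (F_t, S_t) pairs with replacement; resamples on which the
    metric is undefined (e.g. zero variance) are skipped.
    """
    p = _as_pair(p)
    rng = np.random.default_rng(seed)
    n = len(p.reference)
    values = []
    for _ in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(metric(CurvePair(p.reference[idx], p.candidate[idx])))
        except ValueError:
            continue
    if not values:
        raise ValueError("metric undefined on every bootstrap resample")
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_curves(
    reference: np.ndarray,
    candidate: np.ndarray,
    n_resamples: int = 10_000,
    seed: int = 0,
    with_ci: bool = True,
) -> dict:
    """All three measures (and bootstrap CIs for cca/drms) as a dict."""
    p = CurvePair(np.asarray(reference), np.asarray(candidate))
    out: dict = {"cca": cca(p), "drms": drms(p), "pearson_r": pearson_r(p)}
    if with_ci:
        out["cca_ci95"] = bootstrap_ci(cca, p, n_resamples=n_resamples, seed=seed)
        out["drms_ci95"] = bootstrap_ci(drms, p, n_resamples=n_resamples, seed=seed + 1)
    return out
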