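"""Forward model for two-channel phagocytosis flow cytometry.

A macrophage exposed to fluorescent targets (e.g. DIO-labelled platelets)
receives ``n`` adsorption "hits" with ``n ~ Poisson(m)``, where ``m`` is the
*functional* target:macrophage ratio.  Each adsorbed target is independently
internalized with probability ``p``.  A cell is adsorption-positive (quadrants
2+3 of the two-channel plot) iff at least one hit remains on the surface.
Among adsorption-negative cells, each internalized target shifts the cell's
log fluorescence in the uptake channel by ``alpha`` negative-control log-SD
units, so the fraction of an ``n``-hit, fully-internalized population above a
gate placed at the negative-control log mean is ``Phi(n * alpha)``.

The module maps a parameter point ``(m, p, alpha)`` plus negative-control
statistics to predicted quadrant fractions and predicted uptake-channel
histograms.  All log-domain quantities use natural log internally; since
``alpha`` and the gate are expressed in SD-normalized log units, results are
invariant to the log base used upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "NegativeControlStats",
    "ParamPoint",
    "QuadrantFractions",
    "PredictedHistogram",
    "DEFAULT_N_MAX",
    "M_BOUND",
    "ALPHA_BOUND",
    "poisson_pmf",
    "prob_any_hit",
    "prob_all_internalized",
    "predicted_q23",
    "predicted_q1",
    "predicted_quadrants",
    "predicted_histogram",
]

#: Default truncation of the Poisson hit count.  At the scan bound m < 6.5 the
#: cumulative probability of 12 or fewer hits still exceeds 0.98, so the
#: truncated sums are accurate to ~2% in the worst case and far better for
#: typical m ~ 2.
DEFAULT_N_MAX = 12

#: Scan-side upper bound on the functional ratio; beyond this the n <= 12
#: truncation sheds too much Poisson mass.
M_BOUND = 6.5

#: Scan-side upper bound on the per-target fluorescence shift.  Larger shifts
#: produce visibly multimodal adsorption-negative histograms, which typical
#: assays do not show.
ALPHA_BOUND = 4.5


class ConfigError(ValueError):
    """Invalid configuration (grid, truncation, histogram setup)."""


@dataclass(frozen=True)
class NegativeControlStats:
    """Log-domain location/scale of the negative-control uptake channel.

    Parameters
    ----------
    log_mean : float
        Mean of the log-transformed uptake fluorescence of the negative
        control (macrophages without targets).  Any fixed log base; the
        package uses natural log throughout.
    log_sd : float
        Standard deviation of the same, strictly positive.
    n_events : int
        Number of control events the statistics were computed from.
    """

    log_mean: float
    log_sd: float
    n_events: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_mean):
            raise ValueError("log_mean must be finite")
        if not (self.log_sd > 0):
            raise ValueError(f"log_sd must be > 0, got {self.log_sd}")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class ParamPoint:
    """One (m, p, alpha) triple.

    ``m`` is the functional target:macrophage ratio (Poisson mean of the hit
    count), ``p`` the probability that any single adsorbed target is
    internalized, ``alpha`` the mean log-fluorescence shift per internalized
    target in units of the negative-control log SD.  The forward model
    tolerates any ``m > 0`` and ``alpha >= 0``; the scan bounds
    (``m < 6.5``, ``alpha <= 4.5``) are enforced by the grid, not here.
    """

    m: float
    p: float
    alpha: float

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError(f"m must be > 0, got {self.m}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (self.alpha >= 0):
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class QuadrantFractions:
    """Observed or predicted quadrant fractions.

    ``q1`` is the fraction of cells that are adsorption-marker negative with
    uptake fluorescence above the negative-control mean; ``q23`` is the
    fraction that is adsorption-marker positive (quadrants 2 and 3 pooled —
    the model never splits them).  The remainder ``1 - q1 - q23`` sits below
    the gate in the marker-negative half.
    """

    q1: float
    q23: float

    def __post_init__(self) -> None:
        if self.q1 < 0 or self.q23 < 0:
            raise ValueError("quadrant fractions must be nonnegative")
        if self.q1 + self.q23 > 1.0 + 1e-9:
            raise ValueError(f"q1 + q23 = {self.q1 + self.q23} exceeds 1")


@dataclass(frozen=True)
class PredictedHistogram:
    """Predicted adsorption-negative uptake histogram as a normal mixture.

    ``component_densities[n]`` is the weighted density of the population that
    received ``n`` hits and internalized all of them; ``total_density`` is the
    elementwise sum.  Weights are renormalized over the adsorption-negative
    population so the curve overlays an observed marker-negative histogram.
    """

    grid: np.ndarray
    component_densities: np.ndarray  # shape (n_max + 1, len(grid))
    total_density: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total_density is None:
            object.__setattr__(
                self, "total_density", self.component_densities.sum(axis=0)
            )


def _check_m(m: float) -> None:
    if not (m > 0):
        raise ValueError(f"m must be > 0, got {m}")


def poisson_pmf(n: int, m: float) -> float:
    """P(hit count = n) under Poisson adsorption with functional ratio ``m``.

    Returns ``exp(-m) * m**n / n!``.
    """
    _check_m(m)
    if n < 0 or int(n) != n:
        raise ValueError(f"hit count n must be a nonnegative integer, got {n}")
    return float(stats.poisson.pmf(int(n), m))


def prob_any_hit(m: float) -> float:
    """Probability of receiving at least one adsorption hit: ``1 - exp(-m)``."""
    _check_m(m)
    return -math.expm1(-m)


def prob_all_internalized(n: int, p: float) -> float:
    """Probability that all ``n`` adsorbed targets were internalized: ``p**n``.

    Internalization is assumed independent per hit, with probability ``p``
    regardless of how many targets the cell carries.
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"hit count n must be a nonnegative integer, got {n}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    return float(p) ** int(n)


def _check_n_max(n_max: int) -> None:
    if n_max < 1:
        raise ConfigError(f"n_max must be >= 1, got {n_max}")


def predicted_q23(params: ParamPoint, n_max: int = DEFAULT_N_MAX) -> float:
    """Predicted adsorption-positive fraction (quadrants 2+3).

    Sum over n = 1..n_max of ``P(n; m) * (1 - p**n)``: a cell lands in Q2+3
    iff it received at least one hit and failed to internalize all of them.
    As n_max grows this converges from below to the closed form
    ``1 - exp(-m * (1 - p))`` (the surviving surface hits are themselves
    Poisson with mean ``m * (1 - p)``).
    """
    _check_n_max(n_max)
    n = np.arange(1, n_max + 1)
    pois = stats.poisson.pmf(n, params.m)
    return float(np.sum(pois * (1.0 - params.p ** n)))


def q23_closed_form(m: float, p: float) -> float:
    """Untruncated adsorption-positive fraction, ``1 - exp(-m (1 - p))``."""
    _check_m(m)
    return -math.expm1(-m * (1.0 - p))


def predicted_q1(params: ParamPoint, n_max: int = DEFAULT_N_MAX) -> float:
    """Predicted fraction in quadrant 1 (marker-negative, above the gate).

    Sum over n = 0..n_max of ``P(n; m) * p**n * Phi(n * alpha)``: the weight
    of the n-hit, fully-internalized population times the fraction of its
    normal log-FI distribution (mean shifted by ``n * alpha`` control SDs)
    lying above the gate at the negative-control log mean.  The n = 0 term is
    the half of the true negatives above the gate, ``exp(-m) / 2``.
    """
    _check_n_max(n_max)
    n = np.arange(0, n_max + 1)
    pois = stats.poisson.pmf(n, params.m)
    above_gate = stats.norm.sf(-n * params.alpha)  # Phi(n * alpha)
    return float(np.sum(pois * params.p ** n * above_gate))


def predicted_quadrants(
    params: ParamPoint, n_max: int = DEFAULT_N_MAX
) -> QuadrantFractions:
    """Predicted (q1, q23) at one parameter point."""
    return QuadrantFractions(
        q1=predicted_q1(params, n_max), q23=predicted_q23(params, n_max)
    )


def predicted_histogram(
    params: ParamPoint,
    neg: NegativeControlStats,
    grid: np.ndarray,
    n_max: int = DEFAULT_N_MAX,
) -> PredictedHistogram:
    """Predicted uptake-channel log-FI histogram of adsorption(−) cells.

    Component ``n`` is a normal density with mean
    ``neg.log_mean + n * alpha * neg.log_sd`` and SD ``neg.log_sd``,
    weighted by ``P(n; m) * p**n`` and renormalized over the total
    adsorption(−) weight so that the mixture integrates to 1 and is directly
    comparable to an observed marker-negative histogram.
    """
    _check_n_max(n_max)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ConfigError("histogram grid must be non-empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ConfigError("histogram grid must be strictly increasing")

    n = np.arange(0, n_max + 1)
    weights = stats.poisson.pmf(n, params.m) * params.p ** n
    total_weight = weights.sum()
    if total_weight <= 0:
        raise ConfigError("no adsorption-negative weight at these parameters")
    weights = weights / total_weight

    means = neg.log_mean + n * params.alpha * neg.log_sd
    comps = weights[:, None] * stats.norm.pdf(
        grid[None, :], loc=means[:, None], scale=neg.log_sd
    )
    return PredictedHistogram(grid=grid, component_densities=comps)
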