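"""Per-cell Monte Carlo generator for two-channel phagocytosis assays.

Emulates the generative assumptions of the forward model at event level so
gating, fitting and parameter recovery can be exercised without cytometer
data:

* hit count ``n ~ Poisson(m)`` (untruncated — truncation is a fitting-side
  approximation only);
* each hit internalized independently with probability ``p``, so
  ``k | n ~ Binomial(n, p)``;
* uptake-channel log FI normal with mean ``log_mean + k * alpha * log_sd``
  and SD ``log_sd`` (each internalized target shifts the cell by ``alpha``
  control SDs; surface-retained targets contribute nothing here — their dye
  is read out in Q2+3 membership, which pools all marker-positive cells);
* adsorption-marker log FI a two-component normal: baseline for cells with
  no surface target, shifted by ``marker_shift`` SDs for cells retaining at
  least one (the model treats marker positivity as binary, so any clean
  separation suffices).

Event tables are pandas DataFrames; ``to_event_table`` exports linear scale
values (exponentiated natural-log FI) in the shape the IO module ingests,
optionally with a negative baseline offset to exercise the correction path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import NegativeControlStats, ParamPoint, QuadrantFractions

__all__ = [
    "SimConfig",
    "simulate",
    "simulate_negative_control",
    "events_to_observed",
    "to_event_table",
]

EVENT_COLUMNS = [
    "n_hits",
    "k_internalized",
    "uptake_log_fi",
    "marker_log_fi",
    "adsorption_positive",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated assay condition.

    ``marker_shift`` is the separation (in marker-channel log SDs) between
    marker-negative and marker-positive cells; the default 6 SDs makes the
    vertical gate unambiguous, matching how a bright adsorption antibody
    (e.g. PE-anti-CD61) behaves.  ``seed`` is mandatory: simulations are
    never silently nondeterministic.
    """

    truth: ParamPoint
    neg: NegativeControlStats
    n_cells: int
    seed: int
    marker_neg_log_mean: float = 3.0
    marker_log_sd: float = 0.5
    marker_shift: float = 6.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (self.marker_log_sd > 0):
            raise ValueError("marker_log_sd must be > 0")


def _marker_channel(
    rng: np.random.Generator, config: SimConfig, positive: np.ndarray
) -> np.ndarray:
    loc = config.marker_neg_log_mean + positive * config.marker_shift * config.marker_log_sd
    return rng.normal(loc, config.marker_log_sd)


def simulate(config: SimConfig) -> pd.DataFrame:
    """Simulate one assay condition; returns one row per macrophage.

    Columns: ``n_hits``, ``k_internalized``, ``uptake_log_fi``,
    ``marker_log_fi``, ``adsorption_positive``.  Bitwise reproducible for a
    fixed config.
    """
    rng = np.random.default_rng(config.seed)
    n = rng.poisson(config.truth.m, size=config.n_cells)
    k = rng.binomial(n, config.truth.p)
    positive = k < n
    uptake = rng.normal(
        config.neg.log_mean + k * config.truth.alpha * config.neg.log_sd,
        config.neg.log_sd,
    )
    marker = _marker_channel(rng, config, positive)
    return pd.DataFrame(
        {
            "n_hits": n,
            "k_internalized": k,
            "uptake_log_fi": uptake,
            "marker_log_fi": marker,
            "adsorption_positive": positive,
        }
    )


def simulate_negative_control(
    neg: NegativeControlStats,
    n_cells: int,
    seed: int,
    marker_neg_log_mean: float = 3.0,
    marker_log_sd: float = 0.5,
) -> pd.DataFrame:
    """Simulate a macrophages-only well: zero hits, baseline channels."""
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = np.random.default_rng(seed)
    zeros = np.zeros(n_cells, dtype=int)
    return pd.DataFrame(
        {
            "n_hits": zeros,
            "k_internalized": zeros,
            "uptake_log_fi": rng.normal(neg.log_mean, neg.log_sd, size=n_cells),
            "marker_log_fi": rng.normal(marker_neg_log_mean, marker_log_sd, size=n_cells),
            "adsorption_positive": np.zeros(n_cells, dtype=bool),
        }
    )


def events_to_observed(events: pd.DataFrame, gates) -> QuadrantFractions:
    """Quadrant fractions of a simulated event table under a gate set.

    Applies exactly the same rule as the IO module's quadrant counter —
    Q2+3 is everything above the marker threshold, Q1 is marker-negative and
    above the uptake threshold — so recovery tests and real-data analyses
    share one definition.
    """
    marker_pos = events["marker_log_fi"].to_numpy() > gates.marker_threshold
    above = events["uptake_log_fi"].to_numpy() > gates.uptake_threshold
    n = len(events)
    if n == 0:
        raise ValueError("empty event table")
    q23 = marker_pos.mean()
    q1 = (~marker_pos & above).mean()
    return QuadrantFractions(q1=float(q1), q23=float(q23))


def to_event_table(
    events: pd.DataFrame,
    source_id: str = "sim",
    baseline_offset: float = 0.0,
):
    """Convert simulated log-FI events to a linear-scale event table.

    Exponentiates the natural-log channels into scale values; a negative
    ``baseline_offset`` is added to both channels to mimic the cytometer's
    automated baseline correction producing negative scale values, so the
    IO-side correction path can be exercised end to end.
    """
    from .flow_io import EventTable  # local import to avoid a cycle

    return EventTable(
        uptake_fi=np.exp(events["uptake_log_fi"].to_numpy()) + baseline_offset,
        marker_fi=np.exp(events["marker_log_fi"].to_numpy()) + baseline_offset,
        source_id=source_id,
    )
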