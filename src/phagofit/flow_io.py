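"""Ingest, baseline-correct, log-transform and gate flow-cytometry exports.

Event tables are two-channel CSV exports of scale values (one row per event,
columns ``uptake_fi`` and ``marker_fi``).  Cytometers' automated baseline
correction can yield negative scale values; these are repaired per file by
adding a constant equal to the magnitude of the lowest value (plus a small
epsilon so the minimum stays strictly positive and log-transformable).  All
log transforms are natural log; every downstream quantity (alpha, the gate,
residuals) is defined in SD-normalized log units, so the base is immaterial.

Gating convention: the horizontal (uptake) gate sits at the negative
control's log mean, placing 50% of the control population in quadrant 1; the
vertical (marker) gate sits at a high quantile (default 0.995) of the
control's marker channel.  Quadrants 2 and 3 are always pooled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ConfigError, NegativeControlStats, QuadrantFractions

__all__ = [
    "EventTable",
    "GateSet",
    "DataError",
    "read_event_csv",
    "write_event_csv",
    "baseline_correct",
    "log_transform",
    "negative_stats",
    "derive_gates",
    "observed_quadrants",
    "observed_histogram",
]

#: Added on top of the |min| shift so the corrected minimum is strictly
#: positive (the raw rule would leave a zero, which the log transform cannot
#: take).  One scale unit is far below any real signal.
BASELINE_EPSILON = 1.0


class DataError(ValueError):
    """Malformed or degenerate event data."""


@dataclass(frozen=True)
class EventTable:
    """Per-event linear scale values for the two channels of one file."""

    uptake_fi: np.ndarray
    marker_fi: np.ndarray
    source_id: str = ""
    corrections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        u = np.asarray(self.uptake_fi, dtype=float)
        m = np.asarray(self.marker_fi, dtype=float)
        if u.size == 0:
            raise DataError(f"empty event table {self.source_id!r}")
        if u.shape != m.shape:
            raise DataError("channel lengths differ")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(m))):
            raise DataError("non-finite scale values")
        object.__setattr__(self, "uptake_fi", u)
        object.__setattr__(self, "marker_fi", m)

    def __len__(self) -> int:
        return self.uptake_fi.size


@dataclass(frozen=True)
class GateSet:
    """Log-domain quadrant thresholds with provenance."""

    uptake_threshold: float
    marker_threshold: float
    control_id: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.uptake_threshold) and np.isfinite(self.marker_threshold)):
            raise DataError("gate thresholds must be finite")

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2)


def read_event_csv(path) -> EventTable:
    """Read a headered CSV export with ``uptake_fi`` and ``marker_fi`` columns."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"uptake_fi", "marker_fi"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return EventTable(
        uptake_fi=df["uptake_fi"].to_numpy(float),
        marker_fi=df["marker_fi"].to_numpy(float),
        source_id=path.name,
    )


def write_event_csv(table: EventTable, path) -> None:
    pd.DataFrame(
        {"uptake_fi": table.uptake_fi, "marker_fi": table.marker_fi}
    ).to_csv(path, index=False)


def _correct_channel(values: np.ndarray, epsilon: float) -> tuple[np.ndarray, float]:
    lo = values.min()
    if lo > 0:
        return values, 0.0
    shift = -lo + epsilon
    return values + shift, float(shift)


def baseline_correct(table: EventTable, epsilon: float = BASELINE_EPSILON) -> EventTable:
    """Shift non-positive channels of one file into the positive domain.

    Each channel with a minimum <= 0 is shifted by ``|min| + epsilon``; an
    all-positive channel is left untouched.  The applied constants are
    recorded in ``corrections`` for the provenance log.  The correction is
    per file: two files with different minima receive different constants.
    Idempotent — a corrected table passes through unchanged.
    """
    for name, values in (("uptake_fi", table.uptake_fi), ("marker_fi", table.marker_fi)):
        if np.ptp(values) == 0:
            raise DataError(
                f"{table.source_id!r}: channel {name} is constant (no dynamic range)"
            )
    u, su = _correct_channel(table.uptake_fi, epsilon)
    m, sm = _correct_channel(table.marker_fi, epsilon)
    corrections = dict(table.corrections)
    if su or sm:
        corrections.update({"uptake_shift": su, "marker_shift": sm})
    return replace(table, uptake_fi=u, marker_fi=m, corrections=corrections)


def log_transform(table: EventTable) -> tuple[np.ndarray, np.ndarray]:
    """Natural-log channels of a corrected (all-positive) table."""
    if table.uptake_fi.min() <= 0 or table.marker_fi.min() <= 0:
        raise DataError(
            f"{table.source_id!r}: non-positive scale values; run baseline_correct first"
        )
    return np.log(table.uptake_fi), np.log(table.marker_fi)


def negative_stats(control: EventTable) -> NegativeControlStats:
    """Log-domain mean and SD of the control's uptake channel.

    The mean of the logs is the log of the geometric mean, which is where
    the uptake gate is placed.  Fewer than 30 events triggers an
    unstable-SD warning.
    """
    log_u, _ = log_transform(control)
    if log_u.std() == 0:
        raise DataError(f"{control.source_id!r}: zero variance in uptake channel")
    if len(control) < 30:
        warnings.warn(
            f"{control.source_id!r}: only {len(control)} control events; "
            "SD estimate is unstable",
            stacklevel=2,
        )
    return NegativeControlStats(
        log_mean=float(log_u.mean()),
        log_sd=float(log_u.std(ddof=1)) if len(control) > 1 else float(log_u.std()),
        n_events=len(control),
    )


def derive_gates(control: EventTable, marker_quantile: float = 0.995) -> GateSet:
    """Derive quadrant gates from a negative control.

    The uptake threshold is the control's log mean (geometric-mean position),
    so 50% of a lognormal control sits above it; the marker threshold is the
    ``marker_quantile`` of the control's log marker channel.
    """
    if not (0.5 < marker_quantile < 1.0):
        raise ConfigError(
            f"marker_quantile must be in (0.5, 1), got {marker_quantile}"
        )
    log_u, log_m = log_transform(control)
    return GateSet(
        uptake_threshold=float(log_u.mean()),
        marker_threshold=float(np.quantile(log_m, marker_quantile)),
        control_id=control.source_id,
    )


def observed_quadrants(table: EventTable, gates: GateSet) -> QuadrantFractions:
    """Observed quadrant fractions of a corrected table.

    Q2+3 pools every marker-positive event; Q1 is marker-negative with
    uptake above the gate.  Fractions are of total events, so
    ``q1 + q23 + remainder == 1`` exactly.
    """
    log_u, log_m = log_transform(table)
    marker_pos = log_m > gates.marker_threshold
    q23 = float(marker_pos.mean())
    q1 = float((~marker_pos & (log_u > gates.uptake_threshold)).mean())
    return QuadrantFractions(q1=q1, q23=q23)


def observed_histogram(
    table: EventTable, gates: GateSet, bins=50
) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram of log uptake FI for marker-negative events.

    Returns ``(bin_centers, density)`` normalized to integrate to 1,
    directly overlayable on a predicted adsorption(−) histogram.
    """
    if np.isscalar(bins):
        if bins < 2:
            raise ConfigError("need at least 2 histogram bins")
    elif len(np.atleast_1d(bins)) < 3:
        raise ConfigError("need at least 2 histogram bins")
    log_u, log_m = log_transform(table)
    neg = log_u[log_m <= gates.marker_threshold]
    if neg.size == 0:
        raise DataError("no marker-negative events to histogram")
    density, edges = np.histogram(neg, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
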