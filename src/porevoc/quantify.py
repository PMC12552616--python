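"""Ratiometric quantification of analytes from labeled event streams.

Each analyte's event-formation rate v_on is measured against the shared open
time (all association clocks run in parallel while the cysteine is free) and
inverted through the bimolecular law ``C_tot = v_on / k_on`` using the
calibration k_on of that analyte.  Because the observed k_on is defined
against the *total* concentration, no hydration correction is needed at
quantification time; reporting in terms of free aldehyde via k_on' is a
presentation choice, not a different estimate.

Recordings whose mixture changes mid-experiment (solution replacement) are
analysed per segment with the replacement times taken as known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytes import AnalyteSpec, ValidationError
from .detect import EventTable

__all__ = [
    "ConcentrationEstimate",
    "quantify",
    "ratio_profile",
    "concentration_ratio",
]

_MIN_EVENTS_WARN = 20


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Total concentration of one analyte recovered from event rates."""

    analyte: str
    concentration: float  # mM
    stderr: float         # mM
    n_events: int
    v_on: float           # s^-1, as used
    k_on: float           # mM^-1 s^-1, as used
    upper95: float | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0.0:
            raise ValidationError("concentration must be >= 0")


def _calibration_kon(calibration) -> dict[str, float]:
    out: dict[str, float] = {}
    if isinstance(calibration, Mapping):
        items = calibration.items()
        for name, value in items:
            out[name] = value.k_on_obs if isinstance(
                value, AnalyteSpec) else float(value)
    else:
        for spec in calibration:
            out[spec.name] = spec.k_on_obs
    return out


def quantify(
    events: EventTable | pd.DataFrame,
    calibration,
    duration: float | None = None,
    dead_time: float = 5e-4,
) -> dict[str, ConcentrationEstimate]:
    """Per-analyte total concentrations from a labeled event table.

    ``calibration`` supplies k_on per analyte: a sequence of AnalyteSpec, or
    a mapping name -> AnalyteSpec | k_on.  Every calibrated analyte gets an
    estimate (zero events give 0 mM with a rule-of-three upper bound); event
    labels missing from the calibration raise an error.
    """
    if isinstance(events, EventTable):
        df = events.events
        duration = events.duration if duration is None else duration
    else:
        df = events
        if duration is None:
            raise ValidationError(
                "recording duration required with a bare event frame")
    kon = _calibration_kon(calibration)
    labels = df["label"].astype(str)
    if (labels == "").any():
        raise ValidationError("all events must be labeled before quantify")
    unknown = sorted(set(labels) - set(kon))
    if unknown:
        raise ValidationError(
            f"event labels missing from the calibration: {unknown}")

    open_time = duration - float(df["duration_s"].sum())
    if open_time <= 0.0:
        raise ValidationError("no open time in the recording")
    out: dict[str, ConcentrationEstimate] = {}
    for name, k in kon.items():
        n = int((labels == name).sum())
        if k <= 0.0:
            raise ValidationError(f"{name}: calibration k_on must be > 0")
        exposure = open_time - n * dead_time
        v_on = n / exposure
        if n == 0:
            out[name] = ConcentrationEstimate(
                analyte=name, concentration=0.0, stderr=0.0, n_events=0,
                v_on=0.0, k_on=k, upper95=3.0 / (open_time * k))
            continue
        conc = v_on / k
        # delta method: Var(n/T/k) = n / (T k)^2 for a Poisson count
        stderr = np.sqrt(n) / (exposure * k)
        out[name] = ConcentrationEstimate(
            analyte=name, concentration=conc, stderr=stderr, n_events=n,
            v_on=v_on, k_on=k)
    return out


def concentration_ratio(
    a: ConcentrationEstimate, b: ConcentrationEstimate
) -> tuple[float, float]:
    """Ratio a/b with first-order propagated standard error."""
    if b.concentration <= 0.0:
        return float("inf"), float("nan")
    r = a.concentration / b.concentration
    if a.concentration <= 0.0:
        return 0.0, float("nan")
    se = r * np.sqrt((a.stderr / a.concentration) ** 2
                     + (b.stderr / b.concentration) ** 2)
    return r, se


def ratio_profile(
    segments: Sequence[tuple[tuple[float, float], EventTable | pd.DataFrame]],
    calibration,
    reference: str | None = None,
    dead_time: float = 5e-4,
) -> pd.DataFrame:
    """Per-segment concentrations and ratios across a segmented recording.

    ``segments`` holds ``((t_start, t_end), events)`` pairs, ordered and
    non-overlapping; ratios are reported against ``reference`` (default: the
    first calibrated analyte).  Empty segments are flagged in the output, not
    dropped.
    """
    kon = _calibration_kon(calibration)
    names = sorted(kon)
    if reference is None:
        reference = names[0]
    if reference not in kon:
        raise ValidationError(f"reference {reference!r} not calibrated")
    prev_end = None
    rows = []
    for i, ((t0, t1), events) in enumerate(segments):
        if t1 <= t0:
            raise ValidationError(f"segment {i}: end before start")
        if prev_end is not None and t0 < prev_end - 1e-12:
            raise ValidationError("segments must be ordered, non-overlapping")
        prev_end = t1
        df = events.events if isinstance(events, EventTable) else events
        estimates = quantify(df, kon, duration=t1 - t0, dead_time=dead_time)
        for name in names:
            est = estimates[name]
            if 0 < est.n_events < _MIN_EVENTS_WARN:
                warnings.warn(
                    f"segment {i}: only {est.n_events} events for {name}; "
                    "ratio will be noisy", stacklevel=2)
            ratio, ratio_se = concentration_ratio(est, estimates[reference])
            rows.append({
                "segment": i, "t_start_s": t0, "t_end_s": t1,
                "analyte": name, "n_events": est.n_events,
                "concentration_mm": est.concentration,
                "stderr_mm": est.stderr,
                "ratio_to_reference": ratio,
                "ratio_stderr": ratio_se,
                "reference": reference,
                "empty_segment": len(df) == 0,
            })
    return pd.DataFrame(rows)
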