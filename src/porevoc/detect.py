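"""Idealization of two-level traces and per-event feature extraction.

The chemistry guarantees a two-level alternating signal (one reactive
cysteine), so threshold-crossing segmentation on an analysis-filtered copy of
the trace is sufficient: no hidden-Markov idealization is attempted.

Detection pipeline:

1. low-pass the trace again at ``analysis_filter_cutoff`` (default 1 kHz,
   between the display and acquisition bandwidths);
2. rough open-level estimate = median of the filtered trace (valid while
   blockades occupy < 50% of the time);
3. samples whose like-signed ratio to the rough baseline falls below
   ``threshold_pct`` are blockade candidates; runs shorter than the dead time
   are treated as missed events;
4. the baseline is re-estimated as the median of the *raw* open samples away
   from any candidate transition, and per-event features are computed from
   raw samples with filter-rise margins excluded.

Features per event: ``ires_pct`` (mean blockade current as % of the estimated
open current), ``duration_s``, and ``rms_noise_pa`` (standard deviation of
the within-event samples about the event mean).  Events too short to yield
features are kept and flagged, never silently dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .analytes import ConfigError, ValidationError
from .simulate import DwellSequence, Trace, filter_sigma_samples

__all__ = [
    "IdealizationConfig",
    "EventTable",
    "BaselineError",
    "estimate_baseline",
    "idealize",
    "extract_features",
    "match_events",
    "MatchResult",
    "split_levels",
    "write_events",
    "read_events",
]

EVENT_COLUMNS = ["start_s", "duration_s", "ires_pct", "rms_noise_pa",
                 "flag", "label"]


class BaselineError(RuntimeError):
    """The open-pore level could not be estimated from the trace."""


def _analysis_lowpass(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-approximating linear-phase low-pass: three cascaded boxcars.

    The boxcar width is chosen so the cascade's impulse response has standard
    deviation ``sigma`` samples; runs in O(n) independent of the bandwidth.
    """
    w = int(round(math.sqrt(4.0 * sigma * sigma + 1.0)))
    w = max(w + (w + 1) % 2, 3)  # odd, >= 3, keeps the filter linear-phase
    a = uniform_filter1d(np.asarray(x, dtype=float), w, mode="nearest")
    b = uniform_filter1d(a, w, mode="nearest", output=np.empty_like(a))
    uniform_filter1d(b, w, mode="nearest", output=a)
    return a


@dataclass(frozen=True)
class IdealizationConfig:
    """Detection settings.

    ``threshold_pct`` is the decision level in ires% units: samples whose
    ratio to the baseline (x100) falls below it belong to a blockade.  The
    default sits halfway between the open level (100) and the shallowest
    adduct level of the reference pore (98.7), maximizing the margin for the
    closest level.
    """

    analysis_filter_cutoff: float = 1_000.0
    threshold_pct: float = 99.35
    dead_time: float = 5e-4
    baseline_window: float = 0.1
    margin_time_constants: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_pct < 100.0):
            raise ConfigError(
                f"threshold_pct must be in (0, 100), got {self.threshold_pct}")
        if self.dead_time < 0.0:
            raise ConfigError("dead_time must be >= 0")
        if (self.analysis_filter_cutoff > 0.0
                and self.dead_time < 2.0 / self.analysis_filter_cutoff):
            warnings.warn(
                "dead_time below 2/analysis_filter_cutoff: dwells near the "
                "dead time will be distorted by the analysis filter",
                stacklevel=2)

    @classmethod
    def for_levels(cls, levels: Sequence[float],
                   **overrides) -> "IdealizationConfig":
        """Place the threshold halfway between open and the shallowest level."""
        levels = list(levels)
        if not levels:
            raise ConfigError("need at least one expected level")
        threshold = (100.0 + max(levels)) / 2.0
        if threshold <= min(levels):
            raise ConfigError(
                f"threshold {threshold} not above the deepest level "
                f"{min(levels)}")
        return cls(threshold_pct=threshold, **overrides)


@dataclass
class EventTable:
    """Detected blockade events plus the trace-level context."""

    events: pd.DataFrame
    open_current: float
    duration: float
    sampling_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                self.events[col] = "" if col in ("flag", "label") else np.nan
        starts = self.events["start_s"].to_numpy()
        if starts.size > 1 and np.any(np.diff(starts) < 0):
            raise ValidationError("events must be time-ordered")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def ok(self) -> pd.DataFrame:
        """Feature-complete events."""
        return self.events[self.events["flag"] == "ok"]

    def labeled(self, labels: Sequence[str]) -> "EventTable":
        events = self.events.copy()
        events["label"] = list(labels)
        return replace(self, events=events)


def _segment(trace: Trace, config: IdealizationConfig):
    """Shared first pass: filter, rough baseline, candidate runs, margins."""
    cur = trace.current
    if cur.size == 0:
        raise ValidationError("empty trace")
    if config.analysis_filter_cutoff > 0.0:
        sigma = filter_sigma_samples(trace.sampling_rate,
                                     config.analysis_filter_cutoff)
        filt = _analysis_lowpass(cur, sigma)
    else:
        sigma = 0.0
        filt = cur
    rough = float(np.median(filt))
    if rough == 0.0:
        raise BaselineError("median current is zero; no open level found")
    # a blockade reduces the current magnitude: compare like-signed values
    thr_abs = rough * config.threshold_pct / 100.0
    blocked = (filt > thr_abs) if rough < 0.0 else (filt < thr_abs)

    def _runs(mask):
        flips = np.flatnonzero(np.diff(mask))
        edges = np.concatenate(([0], flips + 1, [mask.size]))
        return edges[:-1], edges[1:], mask[edges[:-1]]

    dead = int(round(config.dead_time * trace.sampling_rate))
    run_starts, run_ends, run_blocked = _runs(blocked)
    # merge sub-dead-time open gaps between blockades: a single-sample noise
    # excursion above threshold must not split one adduct dwell in two
    gaps = (~run_blocked & (run_ends - run_starts < max(dead, 1))
            & (run_starts > 0) & (run_ends < blocked.size))
    if gaps.any():
        for s, e in zip(run_starts[gaps], run_ends[gaps]):
            blocked[s:e] = True
        run_starts, run_ends, run_blocked = _runs(blocked)

    keep = run_blocked & ((run_ends - run_starts) >= max(dead, 1))
    ev_starts = run_starts[keep]
    ev_ends = run_ends[keep]

    margin = int(math.ceil(config.margin_time_constants * sigma))
    # open mask for baseline: away from ANY candidate blockade (kept or not)
    open_mask = ~blocked
    if margin > 0:
        bad = np.zeros(cur.size, dtype=bool)
        for s, e in zip(run_starts[run_blocked], run_ends[run_blocked]):
            bad[max(0, s - margin):min(cur.size, e + margin)] = True
        open_mask &= ~bad
    return ev_starts, ev_ends, open_mask, margin


def estimate_baseline(trace: Trace,
                      config: IdealizationConfig | None = None) -> float:
    """Robust (median-based) open-pore current estimate, pA."""
    config = config or IdealizationConfig()
    _, _, open_mask, _ = _segment(trace, config)
    n_needed = int(config.baseline_window * trace.sampling_rate)
    if open_mask.sum() < max(n_needed, 1):
        raise BaselineError(
            "not enough open-level samples to estimate the baseline "
            f"({int(open_mask.sum())} found)")
    return float(np.median(trace.current[open_mask]))


def extract_features(window: np.ndarray,
                     baseline: float) -> tuple[float, float]:
    """(ires_pct, rms_noise_pa) from the usable samples of one event."""
    window = np.asarray(window, dtype=float)
    if window.size < 3:
        raise ValidationError(
            "event has fewer than 3 usable samples; features undefined")
    ires = float(np.mean(window) / baseline * 100.0)
    rms = float(np.std(window, ddof=1))
    return ires, rms


def idealize(trace: Trace,
             config: IdealizationConfig | None = None) -> EventTable:
    """Threshold-crossing idealization of a two-level trace."""
    config = config or IdealizationConfig()
    ev_starts, ev_ends, open_mask, margin = _segment(trace, config)
    n_needed = int(config.baseline_window * trace.sampling_rate)
    if open_mask.sum() < max(n_needed, 1):
        raise BaselineError("trace is (almost) fully blockaded")
    baseline = float(np.median(trace.current[open_mask]))

    fs = trace.sampling_rate
    rows = []
    cur = trace.current
    for s, e in zip(ev_starts, ev_ends):
        lo, hi = s + margin, e - margin
        if hi - lo >= 3:
            ires, rms = extract_features(cur[lo:hi], baseline)
            flag = "ok"
        else:
            ires, rms, flag = np.nan, np.nan, "short"
        rows.append((s / fs, (e - s) / fs, ires, rms, flag, ""))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventTable(events=events, open_current=baseline,
                      duration=trace.duration, sampling_rate=fs,
                      meta=dict(trace.meta))


@dataclass
class MatchResult:
    """Greedy interval matching of detected events to ground-truth dwells."""

    matches: pd.DataFrame   # truth_idx, det_idx, overlap_s, truth_duration_s
    misses: pd.DataFrame    # unmatched truth adduct dwells
    false_positives: pd.DataFrame  # unmatched detected events

    @property
    def recall(self) -> float:
        n = len(self.matches) + len(self.misses)
        return len(self.matches) / n if n else float("nan")

    @property
    def precision(self) -> float:
        n = len(self.matches) + len(self.false_positives)
        return len(self.matches) / n if n else float("nan")

    def miss_rate_by_duration(self, bins: Sequence[float]) -> pd.Series:
        truth = pd.concat([
            self.matches.assign(missed=0)[["truth_duration_s", "missed"]],
            self.misses.rename(
                columns={"duration_s": "truth_duration_s"}).assign(
                missed=1)[["truth_duration_s", "missed"]],
        ])
        grouped = truth.groupby(
            pd.cut(truth["truth_duration_s"], bins), observed=False)
        return grouped["missed"].mean()


def match_events(detected: EventTable, truth: DwellSequence,
                 min_overlap: float = 0.5) -> MatchResult:
    """Match detected events to true adduct dwells by >=50% interval overlap.

    Overlap is measured relative to the shorter of the two intervals; each
    dwell and each event is used at most once (greedy, longest overlap first).
    """
    truth_df = truth.adducts()
    det = detected.events
    t_start = truth_df["start_s"].to_numpy()
    t_end = t_start + truth_df["duration_s"].to_numpy()
    d_start = det["start_s"].to_numpy()
    d_end = d_start + det["duration_s"].to_numpy()

    pairs = []
    j0 = 0
    for i in range(len(truth_df)):
        j = j0
        while j < len(det) and d_end[j] <= t_start[i]:
            j += 1
        j0 = j
        while j < len(det) and d_start[j] < t_end[i]:
            ov = min(t_end[i], d_end[j]) - max(t_start[i], d_start[j])
            shorter = min(t_end[i] - t_start[i], d_end[j] - d_start[j])
            if shorter > 0 and ov / shorter >= min_overlap:
                pairs.append((ov, i, j))
            j += 1
    pairs.sort(reverse=True)
    used_t: set[int] = set()
    used_d: set[int] = set()
    rows = []
    for ov, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        rows.append((i, j, ov, t_end[i] - t_start[i]))
    matches = pd.DataFrame(
        rows, columns=["truth_idx", "det_idx", "overlap_s",
                       "truth_duration_s"])
    misses = truth_df[~truth_df.index.isin(used_t)].reset_index(drop=True)
    fps = det[~det.index.isin(used_d)].reset_index(drop=True)
    return MatchResult(matches=matches, misses=misses, false_positives=fps)


def split_levels(ires_values: Sequence[float], n_levels: int = 2,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cluster event residual levels into ``n_levels`` groups.

    Returns (sorted group means descending, per-event group assignment by
    that order).  Used to measure diastereomer level splits.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(ires_values, dtype=float).reshape(-1, 1)
    if x.size < n_levels:
        raise ValidationError("fewer events than requested levels")
    km = KMeans(n_clusters=n_levels, n_init=10, random_state=seed).fit(x)
    order = np.argsort(-km.cluster_centers_.ravel())
    means = km.cluster_centers_.ravel()[order]
    remap = np.empty_like(order)
    remap[order] = np.arange(n_levels)
    return means, remap[km.labels_]


def write_events(table: EventTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# open_current_pa: {table.open_current!r}\n")
        fh.write(f"# duration_s: {table.duration!r}\n")
        fh.write(f"# sampling_rate_hz: {table.sampling_rate!r}\n")
        table.events[EVENT_COLUMNS].to_csv(fh, sep="\t", index=False,
                                           float_format="%.17g")


def read_events(path: str | Path) -> EventTable:
    from .simulate import _read_header

    with open(path) as fh:
        meta = _read_header(fh)
        df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                         na_values=[""], dtype={"flag": str, "label": str},
                         float_precision="round_trip")
    for col in ("flag", "label"):
        if col in df.columns:
            df[col] = df[col].fillna("")
        else:
            df[col] = ""
    return EventTable(
        events=df,
        open_current=float(meta.get("open_current_pa", "nan")),
        duration=float(meta.get("duration_s", "nan")),
        sampling_rate=float(meta.get("sampling_rate_hz", "nan")),
    )
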