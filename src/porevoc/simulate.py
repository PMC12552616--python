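"""Synthetic single-channel recordings of covalent aldehyde sensing.

The latent signal is a two-state alternating renewal process: the pore is
either open or carries one hemithioacetal adduct (a single reactive cysteine
forbids double occupancy).  From the open state the waiting time is
exponential with total rate ``sum_i k_on_obs,i * C_i`` over all analytes in
the mixture; the entering analyte is drawn proportionally to its rate and the
diastereomer by its branching fraction; the adduct dwell is exponential with
that diastereomer's ``k_off``.  Concentrations are piecewise constant in time
(solution replacement); by memorylessness a segment boundary simply truncates
the running clock and re-draws it with the new rates.

Rendering places the open dwells at the open-pore current I_P and adduct
dwells at ``ires_pct/100 * I_P`` (plus one Gaussian level offset per
blockade, the slow event-to-event level jitter), applies a linear-phase
Gaussian FIR standing in for the acquisition 10 kHz low-pass Bessel filter,
and adds white Gaussian noise of configurable RMS after filtering.
Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .analytes import (
    AnalyteSpec,
    ConfigError,
    MixtureSpec,
    PoreSpec,
    ValidationError,
)

__all__ = [
    "Segment",
    "SimulationScenario",
    "Dwell",
    "DwellSequence",
    "Trace",
    "sample_dwells",
    "render_trace",
    "simulate_trace",
    "sample_labeled_events",
    "write_trace",
    "read_trace",
    "write_dwells",
    "read_dwells",
]

# -3 dB point of a Gaussian filter: sigma_t = sqrt(ln 2) / (2 pi f_c).
GAUSSIAN_SIGMA_FACTOR = math.sqrt(math.log(2.0)) / (2.0 * math.pi)

_STAGES = {"dwells": 1, "noise": 2, "events": 3, "split": 4, "model": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from one global seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STAGES[stage]])


def filter_sigma_samples(sampling_rate: float, cutoff: float) -> float:
    """Gaussian kernel width (samples) with a -3 dB point at ``cutoff``."""
    return GAUSSIAN_SIGMA_FACTOR * sampling_rate / cutoff


def _smoothed_steps(level_pa: np.ndarray, counts: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Piecewise-constant signal with Gaussian-filtered level transitions.

    Exact closed form of the Gaussian FIR response to a step train: the
    filtered signal equals the raw one away from transitions, and each
    transition contributes its step scaled by the Gaussian CDF within a
    +-5 sigma window.  Equivalent to convolving the full trace but O(events)
    instead of O(samples x taps).
    """
    out = np.repeat(np.asarray(level_pa, dtype=float), counts)
    if sigma <= 0.0 or level_pa.size < 2:
        return out
    n = out.size
    r = int(math.ceil(5.0 * sigma))
    offsets = np.arange(-r, r)
    blend = ndtr((offsets + 0.5) / sigma) - (offsets >= 0)
    bounds = np.cumsum(counts)[:-1]
    deltas = np.diff(level_pa)
    idx = bounds[:, None] + offsets[None, :]
    contrib = deltas[:, None] * blend[None, :]
    valid = (idx >= 0) & (idx < n)
    np.add.at(out, idx[valid], contrib[valid])
    return out


@dataclass(frozen=True)
class Segment:
    duration: float
    mixture: MixtureSpec

    def __post_init__(self) -> None:
        if not (self.duration > 0.0 and math.isfinite(self.duration)):
            raise ValidationError(
                f"segment duration must be positive and finite, "
                f"got {self.duration!r}")


@dataclass(frozen=True)
class SimulationScenario:
    """Pore + time-segmented mixture + acquisition parameters + seed."""

    pore: PoreSpec
    segments: tuple[Segment, ...]
    sampling_rate: float = 50_000.0
    filter_cutoff: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValidationError("scenario needs at least one segment")
        if not self.sampling_rate > 2.0 * self.filter_cutoff:
            raise ValidationError(
                "sampling_rate must exceed twice the filter cutoff "
                f"({self.sampling_rate} <= 2 x {self.filter_cutoff})")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def level_map(self) -> dict[tuple[str, str], float]:
        """(analyte, diastereomer) -> residual level (ires %)."""
        out: dict[tuple[str, str], float] = {}
        for seg in self.segments:
            for analyte in seg.mixture.analytes:
                for d in analyte.diastereomers:
                    out[(analyte.name, d.label)] = d.ires_pct
        return out

    def scenario_hash(self) -> str:
        doc = {
            "pore": [self.pore.name, self.pore.open_current,
                     self.pore.potential, self.pore.rms_noise],
            "segments": [
                [seg.duration,
                 sorted((a.name, c, a.khyd, a.k_on_obs,
                         [[d.label, d.ires_pct, d.k_off, d.fraction]
                          for d in a.diastereomers])
                        for a, c in seg.mixture.components)]
                for seg in self.segments],
            "sampling_rate": self.sampling_rate,
            "filter_cutoff": self.filter_cutoff,
            "seed": self.seed,
        }
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Dwell:
    state: str  # "open" | "adduct"
    analyte: str | None
    diastereomer: str | None
    start: float
    duration: float


@dataclass(frozen=True)
class DwellSequence:
    """Ground-truth alternating state intervals (latent Markov path)."""

    dwells: tuple[Dwell, ...]
    total_duration: float
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "dwells", tuple(self.dwells))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "state": [d.state for d in self.dwells],
            "analyte": [d.analyte or "" for d in self.dwells],
            "diastereomer": [d.diastereomer or "" for d in self.dwells],
            "start_s": [d.start for d in self.dwells],
            "duration_s": [d.duration for d in self.dwells],
        })

    def adducts(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["state"] == "adduct"].reset_index(drop=True)

    def opens(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["state"] == "open"].reset_index(drop=True)


@dataclass
class Trace:
    """A sampled current recording plus provenance metadata."""

    current: np.ndarray  # pA
    sampling_rate: float
    potential: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.size and not np.all(np.isfinite(self.current)):
            raise ValidationError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate


def _segment_channels(mixture: MixtureSpec):
    """Flatten a mixture into association channels with per-channel rates."""
    names, dias, rates, koffs = [], [], [], []
    for analyte, conc in mixture.components:
        v_on = analyte.k_on_obs * conc
        if v_on <= 0.0:
            continue
        for d in analyte.diastereomers:
            if d.fraction <= 0.0:
                continue
            names.append(analyte.name)
            dias.append(d.label)
            rates.append(v_on * d.fraction)
            koffs.append(d.k_off)
    return names, dias, np.asarray(rates), np.asarray(koffs)


def sample_dwells(scenario: SimulationScenario) -> DwellSequence:
    """Sample the latent alternating open/adduct dwell sequence."""
    rng = stage_rng(scenario.seed, "dwells")
    dwells: list[Dwell] = []
    t = 0.0
    # pending dwell accumulates across segment boundaries (state persists).
    p_state, p_analyte, p_dia, p_start, p_dur = "open", None, None, 0.0, 0.0

    def flush() -> None:
        nonlocal p_dur
        if p_dur > 0.0:
            dwells.append(Dwell(p_state, p_analyte, p_dia, p_start, p_dur))

    for seg in scenario.segments:
        names, dias, rates, koffs = _segment_channels(seg.mixture)
        total_on = float(rates.sum())
        probs = rates / total_on if total_on > 0.0 else None
        seg_end = t + seg.duration
        while t < seg_end:
            if p_state == "open":
                if total_on <= 0.0:
                    p_dur += seg_end - t
                    t = seg_end
                    break
                tau = rng.exponential(1.0 / total_on)
                if t + tau >= seg_end:
                    p_dur += seg_end - t
                    t = seg_end
                    break
                p_dur += tau
                t += tau
                flush()
                i = int(rng.choice(len(rates), p=probs))
                p_state, p_analyte, p_dia = "adduct", names[i], dias[i]
                p_start, p_dur = t, 0.0
                k_off = koffs[i]
            else:
                tau = rng.exponential(1.0 / k_off)
                if t + tau >= seg_end:
                    p_dur += seg_end - t
                    t = seg_end
                    break
                p_dur += tau
                t += tau
                flush()
                p_state, p_analyte, p_dia = "open", None, None
                p_start, p_dur = t, 0.0
        # an adduct spanning the boundary keeps its own k_off (memoryless
        # truncation: the residual dwell is re-drawn with the same rate)
    flush()
    return DwellSequence(tuple(dwells), scenario.total_duration,
                         scenario.seed)


def render_trace(dwells: DwellSequence,
                 scenario: SimulationScenario) -> Trace:
    """Render a dwell sequence to a filtered, noisy, sampled current trace."""
    if abs(dwells.total_duration - scenario.total_duration) > 1e-9:
        raise ValidationError(
            "dwell sequence duration does not match the scenario")
    fs = scenario.sampling_rate
    n_total = int(round(dwells.total_duration * fs))
    levels_pct = scenario.level_map()
    i_p = scenario.pore.open_current

    ends = np.cumsum([d.duration for d in dwells.dwells])
    bounds = np.round(ends * fs).astype(np.int64)
    bounds[-1] = n_total
    counts = np.diff(np.concatenate(([0], bounds)))
    level_pa = np.array([
        i_p if d.state == "open"
        else levels_pct[(d.analyte, d.diastereomer)] / 100.0 * i_p
        for d in dwells.dwells])
    rng = stage_rng(scenario.seed, "noise")
    if scenario.pore.level_jitter_pct > 0.0:
        # slow level fluctuations: one offset per blockade, not per sample
        adduct = np.array([d.state == "adduct" for d in dwells.dwells])
        jitter = rng.standard_normal(level_pa.size) * (
            scenario.pore.level_jitter_pct / 100.0 * i_p)
        level_pa = np.where(adduct, level_pa + jitter, level_pa)

    sigma = filter_sigma_samples(fs, scenario.filter_cutoff)
    current = _smoothed_steps(level_pa, counts, sigma)
    if scenario.pore.rms_noise > 0.0:
        current += rng.standard_normal(n_total) * scenario.pore.rms_noise
    meta = {
        "seed": scenario.seed,
        "scenario_hash": scenario.scenario_hash(),
        "filter_cutoff_hz": scenario.filter_cutoff,
        "pore": scenario.pore.name,
    }
    return Trace(current=current, sampling_rate=fs,
                 potential=scenario.pore.potential, meta=meta)


def simulate_trace(
        scenario: SimulationScenario) -> tuple[DwellSequence, Trace]:
    dwells = sample_dwells(scenario)
    return dwells, render_trace(dwells, scenario)


def sample_labeled_events(
    analytes: Sequence[AnalyteSpec],
    n_per_class: int,
    pore: PoreSpec,
    seed: int,
    dead_time: float = 5e-4,
    sampling_rate: float = 50_000.0,
    analysis_filter_cutoff: float = 1_000.0,
    margin_time_constants: float = 3.0,
) -> pd.DataFrame:
    """Draw labeled blockade events directly from the generative model.

    Event durations follow the detected-dwell law (exponential with the
    diastereomer's ``k_off``, left-truncated at the dead time); the residual
    level of each event is the configured ires% plus the per-event level
    jitter plus the sampling error of a mean over the event's usable samples
    under white baseline noise, and the
    within-event RMS feature follows the matching chi distribution.  This is
    the renderer+detector noise model without paying for a full 50 kHz trace,
    and is what the classifier is trained and evaluated on.
    """
    rng = stage_rng(seed, "events")
    margin = int(math.ceil(margin_time_constants * filter_sigma_samples(
        sampling_rate, analysis_filter_cutoff)))
    min_samples = 2 * margin + 3  # below this the detector flags the event
    sd_scale = 100.0 * pore.rms_noise / abs(pore.open_current)

    frames = []
    for analyte in analytes:
        fracs = np.array([d.fraction for d in analyte.diastereomers])
        choice = rng.choice(len(fracs), size=n_per_class, p=fracs)
        koffs = np.array([d.k_off for d in analyte.diastereomers])[choice]
        levels = np.array(
            [d.ires_pct for d in analyte.diastereomers])[choice]
        dlabels = np.array(
            [d.label for d in analyte.diastereomers])[choice]
        # left-truncated exponential == dead_time + exponential
        durations = dead_time + rng.exponential(1.0 / koffs)
        # feature-complete events only: re-draw those too short to measure
        short = np.round(durations * sampling_rate) < min_samples
        while short.any():
            durations[short] = dead_time + rng.exponential(
                1.0 / koffs[short])
            short = np.round(durations * sampling_rate) < min_samples
        usable = np.round(durations * sampling_rate) - 2 * margin
        ires = (levels
                + rng.standard_normal(n_per_class) * pore.level_jitter_pct
                + rng.standard_normal(n_per_class) * (
                    sd_scale / np.sqrt(usable)))
        rms = pore.rms_noise * np.sqrt(
            rng.chisquare(usable - 1) / (usable - 1))
        frames.append(pd.DataFrame({
            "ires_pct": ires,
            "duration_s": durations,
            "rms_noise_pa": rms,
            "label": analyte.name,
            "diastereomer": dlabels,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# File formats: CSV traces with '#'-prefixed header, TSV dwell tables.

def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace; ``.csv`` text format or ``.npz`` compact binary."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, current_pa=trace.current,
                 sampling_rate_hz=trace.sampling_rate,
                 potential_mv=trace.potential,
                 meta=json.dumps(trace.meta))
        return
    with open(path, "w") as fh:
        fh.write("# porevoc_trace: 1\n")
        fh.write(f"# sampling_rate_hz: {trace.sampling_rate!r}\n")
        fh.write(f"# potential_mv: {trace.potential!r}\n")
        for key, value in trace.meta.items():
            fh.write(f"# {key}: {value}\n")
        pd.DataFrame({"current_pa": trace.current}).to_csv(
            fh, index=False, float_format="%.17g")


def _read_header(fh) -> dict[str, str]:
    meta: dict[str, str] = {}
    pos = fh.tell()
    line = fh.readline()
    while line.startswith("#"):
        body = line[1:].strip()
        if ":" in body:
            key, _, value = body.partition(":")
            meta[key.strip()] = value.strip()
        pos = fh.tell()
        line = fh.readline()
    fh.seek(pos)
    return meta


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            return Trace(current=data["current_pa"],
                         sampling_rate=float(data["sampling_rate_hz"]),
                         potential=float(data["potential_mv"]),
                         meta=json.loads(str(data["meta"])))
    with open(path) as fh:
        meta = _read_header(fh)
        if "sampling_rate_hz" not in meta:
            raise ConfigError(f"{path}: missing sampling_rate_hz header")
        body = pd.read_csv(fh, float_precision="round_trip")
    if body.empty:
        raise ConfigError(f"{path}: trace file holds no samples")
    if "current_pa" not in body.columns:
        raise ConfigError(f"{path}: missing current_pa column")
    current = body["current_pa"].to_numpy(dtype=float)
    if not np.all(np.isfinite(current)):
        raise ConfigError(f"{path}: trace contains NaN/inf samples")
    sampling_rate = float(meta.pop("sampling_rate_hz"))
    potential = float(meta.pop("potential_mv", "0"))
    meta.pop("porevoc_trace", None)
    return Trace(current=current, sampling_rate=sampling_rate,
                 potential=potential, meta=meta)


def write_dwells(dwells: DwellSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_duration_s: {dwells.total_duration!r}\n")
        fh.write(f"# seed: {dwells.seed}\n")
        dwells.to_frame().to_csv(fh, sep="\t", index=False,
                                 float_format="%.17g")


def read_dwells(path: str | Path) -> DwellSequence:
    with open(path) as fh:
        meta = _read_header(fh)
        df = pd.read_csv(fh, sep="\t", keep_default_na=False,
                         float_precision="round_trip")
    dwells = tuple(
        Dwell(state=row.state,
              analyte=row.analyte or None,
              diastereomer=str(row.diastereomer) or None,
              start=float(row.start_s),
              duration=float(row.duration_s))
        for row in df.itertuples())
    return DwellSequence(dwells,
                         float(meta.get("total_duration_s", "nan")),
                         int(meta.get("seed", "0")))
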