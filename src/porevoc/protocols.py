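"""Standard desk-scale characterization protocols.

Each function builds a recording scenario from the packaged reference fixture
((AG)6(AG-T115C)), runs the relevant slice of the pipeline
(simulate -> idealize -> estimate) and returns the recovered quantities.
They mirror the bench characterization workflows: single-analyte level and
kinetics runs, a concentration series for the bimolecular constant, a
diastereomer-split measurement, a two-analyte ratiometric run, and the
multi-aldehyde classification benchmark.

Recording lengths and concentrations are chosen so each protocol collects the
event count its estimate needs (a few hundred) within minutes of simulated
recording; they are stated per protocol below.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .analytes import correct_kon
from .classify import evaluate, stratified_split, train
from .config import Fixture, load_fixture
from .detect import EventTable, IdealizationConfig, idealize, split_levels
from .kinetics import estimate_koff, estimate_von, fit_kon
from .quantify import quantify
from .simulate import (
    Segment,
    SimulationScenario,
    sample_labeled_events,
    simulate_trace,
)

__all__ = [
    "single_analyte_recording",
    "butanal_kinetics",
    "level_recovery",
    "heptanal_diastereomer_split",
    "propanal_kon_series",
    "mixture_quantification",
    "classification_benchmark",
]

REFERENCE_FIXTURE = "ag_t115c"

STRAIGHT_CHAIN = ("ethanal", "propanal", "butanal", "pentanal",
                  "hexanal", "heptanal", "octanal")


def _fixture(fixture: Fixture | str | None) -> Fixture:
    if isinstance(fixture, Fixture):
        return fixture
    return load_fixture(fixture or REFERENCE_FIXTURE)


def single_analyte_recording(
    analyte: str,
    concentration: float,
    duration: float,
    seed: int,
    fixture: Fixture | str | None = None,
) -> tuple[SimulationScenario, EventTable]:
    """Simulate and idealize one single-analyte recording."""
    fx = _fixture(fixture)
    scenario = SimulationScenario(
        pore=fx.pore,
        segments=(Segment(duration, fx.mixture({analyte: concentration})),),
        seed=seed)
    _, trace = simulate_trace(scenario)
    config = IdealizationConfig.for_levels(fx.analyte(analyte).levels)
    return scenario, idealize(trace, config)


def butanal_kinetics(seed: int, concentration: float = 3.0,
                     duration: float = 600.0) -> dict:
    """10-minute butanal run: event count, adduct lifetime, v_on, baseline.

    At 3 mM the fixture kinetics give an expected ~500 events in 10 min.
    """
    _, table = single_analyte_recording("butanal", concentration, duration,
                                        seed)
    k_off = estimate_koff(table)
    v_on = estimate_von(table)
    return {
        "n_events": len(table),
        "lifetime_ms": 1000.0 / k_off.value,
        "k_off": k_off,
        "v_on": v_on,
        "baseline_pa": table.open_current,
    }


def level_recovery(analyte: str, concentration: float, duration: float,
                   seed: int) -> dict:
    """Mean recovered residual level (ires %) for one analyte."""
    _, table = single_analyte_recording(analyte, concentration, duration,
                                        seed)
    ok = table.ok
    return {
        "mean_ires_pct": float(ok["ires_pct"].mean()),
        "sd_ires_pct": float(ok["ires_pct"].std()),
        "n_events": len(table),
        "baseline_pa": table.open_current,
    }


def heptanal_diastereomer_split(seed: int, concentration: float = 3.0,
                                duration: float = 480.0,
                                min_duration: float = 5e-3) -> dict:
    """Separation between the two heptanal adduct levels.

    Events of at least ``min_duration`` are clustered into two groups on
    their residual level (events shorter than ~5 ms average too few samples
    for their level error to stay well below the ~0.3% split).
    """
    _, table = single_analyte_recording("heptanal", concentration, duration,
                                        seed)
    ok = table.ok
    ires = ok.loc[ok["duration_s"] >= min_duration, "ires_pct"]
    means, assignment = split_levels(ires, n_levels=2)
    counts = np.bincount(assignment, minlength=2)
    return {
        "delta_ires_pct": float(means[0] - means[1]),
        "level_a_pct": float(means[0]),
        "level_b_pct": float(means[1]),
        "n_events_per_level": counts.tolist(),
    }


def propanal_kon_series(
    seed: int,
    concentrations: Sequence[float] = (3.0, 5.8, 8.5, 11.0),
    duration: float = 240.0,
) -> dict:
    """Bimolecular constant from a propanal concentration series.

    One recording per concentration; v_on per recording; origin-constrained
    weighted slope; hydration correction with the fixture K_hyd.
    """
    fx = _fixture(None)
    series = []
    for i, conc in enumerate(concentrations):
        _, table = single_analyte_recording("propanal", conc, duration,
                                            seed + 7919 * (i + 1))
        series.append((conc, estimate_von(table)))
    fit = fit_kon(series)
    khyd = fx.analyte("propanal").khyd
    return {
        "k_on": fit.estimate.value,
        "k_on_stderr": fit.estimate.stderr,
        "k_on_prime": correct_kon(fit.estimate.value, khyd),
        "khyd": khyd,
        "n_dwells": fit.estimate.n_dwells,
        "diagnostics": fit.diagnostics,
    }


def mixture_quantification(
    seed: int,
    concentrations: Mapping[str, float] | None = None,
    duration: float = 600.0,
    use_true_labels: bool = False,
) -> dict:
    """End-to-end two-analyte quantification (butanal + pentanal).

    Defaults to 4 mM butanal and 2 mM pentanal so that several hundred
    events accrue in the 10-minute recording.  Events are labeled by a
    Gaussian baseline classifier trained on single-analyte event sets sampled
    from the calibration fixture, then inverted to concentrations through the
    calibrated k_on of each analyte.
    """
    fx = _fixture(None)
    concentrations = dict(concentrations or {"butanal": 4.0, "pentanal": 2.0})
    scenario = SimulationScenario(
        pore=fx.pore,
        segments=(Segment(duration, fx.mixture(concentrations)),),
        seed=seed)
    dwells, trace = simulate_trace(scenario)
    levels = [lv for (name, _), lv in scenario.level_map().items()]
    table = idealize(trace, IdealizationConfig.for_levels(levels))

    specs = {name: fx.analyte(name) for name in concentrations}
    ok = table.ok.copy()
    if use_true_labels:
        from .detect import match_events

        result = match_events(table, dwells)
        truth = dwells.adducts()
        labels = {int(r.det_idx): truth.loc[int(r.truth_idx), "analyte"]
                  for r in result.matches.itertuples()}
        ok["label"] = [labels.get(i, "") for i in ok.index]
        ok = ok[ok["label"] != ""]
    else:
        training = sample_labeled_events(
            list(specs.values()), 500, fx.pore, seed=seed + 1)
        model = train(training, kind="gaussian", seed=seed + 1)
        ok["label"] = model.predict(ok)

    estimates = quantify(ok, specs, duration=duration)
    errors = {
        name: abs(est.concentration - concentrations[name])
        / concentrations[name] * 100.0
        for name, est in estimates.items()
    }
    return {
        "estimates": estimates,
        "true_mm": concentrations,
        "relative_error_pct": errors,
        "max_relative_error_pct": max(errors.values()),
        "n_events": len(table),
    }


def classification_benchmark(
    seed: int,
    n_per_class: int = 1000,
    kind: str = "forest",
    analytes: Sequence[str] = STRAIGHT_CHAIN,
    test_fraction: float = 0.3,
) -> dict:
    """Multi-aldehyde identification accuracy on sampled labeled events.

    ~1000 events per straight-chain aldehyde are drawn from the fixture
    levels, dwell kinetics and noise model; a stratified split holds out 30%
    for testing; the classifier is scored as the fraction of correctly
    classified test events.
    """
    fx = _fixture(None)
    events = sample_labeled_events(
        [fx.analyte(a) for a in analytes], n_per_class, fx.pore, seed=seed)
    train_df, test_df = stratified_split(events, test_fraction, seed=seed)
    model = train(train_df, kind=kind, seed=seed)
    cm_test = evaluate(model, test_df)
    cm_train = evaluate(model, train_df)
    return {
        "test_accuracy_pct": 100.0 * cm_test.accuracy,
        "train_accuracy_pct": 100.0 * cm_train.accuracy,
        "confusion": cm_test.counts,
        "n_test": len(test_df),
    }
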