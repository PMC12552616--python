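import numpy as np
import pytest
from scipy import stats

import porevoc as pv
from porevoc.analytes import ConfigError, ValidationError
from porevoc.simulate import Dwell, DwellSequence

from conftest import make_scenario


class TestSampleDwells:
    def test_zero_concentration_gives_single_open_dwell(self, ag):
        scen = make_scenario(ag, {"butanal": 0.0}, 30.0, seed=1)
        dwells = pv.sample_dwells(scen)
        assert len(dwells.dwells) == 1
        only = dwells.dwells[0]
        assert only.state == "open" and only.duration == 30.0

    def test_alternation_and_tiling(self, ag):
        scen = make_scenario(ag, {"heptanal": 3.0}, 200.0, seed=2)
        dwells = pv.sample_dwells(scen).dwells
        states = [d.state for d in dwells]
        assert all(a != b for a, b in zip(states, states[1:]))
        assert dwells[0].start == 0.0
        for a, b in zip(dwells, dwells[1:]):
            assert b.start == pytest.approx(a.start + a.duration, abs=1e-12)
        total = dwells[-1].start + dwells[-1].duration
        assert total == pytest.approx(200.0, abs=1e-9)

    def test_expected_event_count_butanal(self, ag):
        # renewal theory: 600 s / (1/0.93 + 0.130) ~ 497 cycles
        scen = make_scenario(ag, {"butanal": 3.0}, 600.0, seed=4)
        n = len(pv.sample_dwells(scen).adducts())
        assert 497 - 3 * np.sqrt(497) < n < 497 + 3 * np.sqrt(497)

    def test_competing_analytes_match_two_clock_oracle(self, ag):
        # package: thinning of the total association rate
        scen = make_scenario(ag, {"butanal": 5.0, "pentanal": 5.0 * 0.31 /
                                  (3 * 0.29)}, 2200.0, seed=5)
        adducts = pv.sample_dwells(scen).adducts()
        v_b = 0.31 * 5.0
        v_p = v_b / 3.0
        n = len(adducts)
        assert n >= 2000
        frac = (adducts["analyte"] == "butanal").mean()

        # oracle: two independent exponential clocks, winner takes the event
        rng = np.random.default_rng(99)
        wins = (rng.exponential(1 / v_b, size=n)
                < rng.exponential(1 / v_p, size=n)).mean()

        p = v_b / (v_b + v_p)  # 0.75
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 3 * se
        assert abs(wins - p) < 3 * se

    def test_dwell_distributions_are_exponential(self, ag):
        # KS at alpha 0.01 against the configured rates, n >= 5000
        scen = make_scenario(ag, {"propanal": 5.8}, 4200.0, seed=6)
        df = pv.sample_dwells(scen).to_frame().iloc[1:-1]
        opens = df[df["state"] == "open"]["duration_s"]
        adducts = df[df["state"] == "adduct"]["duration_s"]
        assert len(opens) >= 5000 and len(adducts) >= 5000
        v_on = 0.294 * 5.8
        k_off = 8.8
        assert stats.kstest(opens, "expon", args=(0, 1 / v_on)).pvalue > 0.01
        assert stats.kstest(adducts, "expon",
                            args=(0, 1 / k_off)).pvalue > 0.01
        # means within 3 standard errors
        assert abs(opens.mean() - 1 / v_on) < 3 * opens.std() / np.sqrt(
            len(opens))
        assert abs(adducts.mean() - 1 / k_off) < 3 * adducts.std() / np.sqrt(
            len(adducts))

    def test_segment_change_rescales_event_rate(self, ag):
        scen = pv.SimulationScenario(
            pore=ag.pore,
            segments=(pv.Segment(300.0, ag.mixture({"butanal": 2.0})),
                      pv.Segment(300.0, ag.mixture({"butanal": 8.0}))),
            seed=7)
        adducts = pv.sample_dwells(scen).adducts()
        n1 = (adducts["start_s"] < 300.0).sum()
        n2 = (adducts["start_s"] >= 300.0).sum()
        assert n2 > 2.5 * n1  # fourfold concentration, minus occupancy loss

    def test_determinism(self, ag):
        scen = make_scenario(ag, {"butanal": 3.0}, 20.0, seed=8)
        d1, t1 = pv.simulate_trace(scen)
        d2, t2 = pv.simulate_trace(scen)
        assert d1.dwells == d2.dwells
        assert np.array_equal(t1.current, t2.current)
        d3 = pv.sample_dwells(make_scenario(ag, {"butanal": 3.0}, 20.0,
                                            seed=9))
        assert d3.dwells != d1.dwells


class TestRenderTrace:
    def _dwells(self):
        return DwellSequence((
            Dwell("open", None, None, 0.0, 0.4),
            Dwell("adduct", "butanal", "A", 0.4, 0.2),
            Dwell("open", None, None, 0.6, 0.4),
        ), 1.0, seed=0)

    def test_noiseless_two_level_plateaus_exact(self, ag, quiet_pore):
        scen = make_scenario(ag, {"butanal": 3.0}, 1.0, seed=0,
                             pore=quiet_pore)
        trace = pv.render_trace(self._dwells(), scen)
        fs = scen.sampling_rate
        open_plateau = trace.current[1000:int(0.38 * fs)]
        adduct_plateau = trace.current[int(0.42 * fs):int(0.58 * fs)]
        assert np.allclose(open_plateau, -129.0)
        assert np.allclose(adduct_plateau, 0.979 * -129.0)

    def test_ires_scale_invariance(self, ag, quiet_pore):
        from dataclasses import replace

        scen1 = make_scenario(ag, {"butanal": 3.0}, 1.0, seed=0,
                              pore=quiet_pore)
        scen2 = make_scenario(ag, {"butanal": 3.0}, 1.0, seed=0,
                              pore=replace(quiet_pore, open_current=-258.0))
        t1 = pv.render_trace(self._dwells(), scen1)
        t2 = pv.render_trace(self._dwells(), scen2)
        assert np.allclose(t2.current, 2.0 * t1.current)

    def test_noise_rms_as_configured(self, ag):
        scen = make_scenario(ag, {"butanal": 0.0}, 2.0, seed=3)
        trace = pv.render_trace(pv.sample_dwells(scen), scen)
        assert np.std(trace.current) == pytest.approx(1.0, rel=0.05)

    def test_trace_length(self, ag):
        scen = make_scenario(ag, {"butanal": 3.0}, 2.5, seed=3)
        _, trace = pv.simulate_trace(scen)
        assert trace.current.size == round(2.5 * scen.sampling_rate)


class TestTraceIO:
    def test_csv_roundtrip_lossless(self, ag, tmp_path):
        scen = make_scenario(ag, {"butanal": 3.0}, 0.2, seed=3)
        _, trace = pv.simulate_trace(scen)
        path = tmp_path / "trace.csv"
        pv.write_trace(trace, path)
        back = pv.read_trace(path)
        assert np.array_equal(back.current, trace.current)
        assert back.sampling_rate == trace.sampling_rate
        assert back.potential == trace.potential
        assert back.meta["scenario_hash"] == trace.meta["scenario_hash"]

    def test_npz_roundtrip(self, ag, tmp_path):
        scen = make_scenario(ag, {"butanal": 3.0}, 0.2, seed=3)
        _, trace = pv.simulate_trace(scen)
        path = tmp_path / "trace.npz"
        pv.write_trace(trace, path)
        back = pv.read_trace(path)
        assert np.array_equal(back.current, trace.current)

    def test_empty_trace_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("# sampling_rate_hz: 50000\ncurrent_pa\n")
        with pytest.raises(ConfigError):
            pv.read_trace(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("current_pa\n-129.0\n")
        with pytest.raises(ConfigError):
            pv.read_trace(path)

    def test_nan_samples_rejected(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("# sampling_rate_hz: 50000\n# potential_mv: -50\n"
                        "current_pa\n-129.0\nnan\n")
        with pytest.raises(ConfigError):
            pv.read_trace(path)

    def test_dwell_table_roundtrip(self, ag, tmp_path):
        scen = make_scenario(ag, {"heptanal": 3.0}, 30.0, seed=3)
        dwells = pv.sample_dwells(scen)
        path = tmp_path / "dwells.tsv"
        from porevoc.simulate import read_dwells, write_dwells

        write_dwells(dwells, path)
        back = read_dwells(path)
        assert back.dwells == dwells.dwells


class TestLabeledEventSampler:
    def test_shapes_labels_and_determinism(self, ag):
        analytes = [ag.analyte("butanal"), ag.analyte("pentanal")]
        ev1 = pv.sample_labeled_events(analytes, 200, ag.pore, seed=5)
        ev2 = pv.sample_labeled_events(analytes, 200, ag.pore, seed=5)
        assert ev1.equals(ev2)
        assert ev1["label"].value_counts().to_dict() == {
            "butanal": 200, "pentanal": 200}
        assert (ev1["duration_s"] >= 5e-4).all()
        assert (ev1["rms_noise_pa"] > 0).all()

    def test_levels_near_configured(self, ag):
        ev = pv.sample_labeled_events([ag.analyte("hexanal")], 500, ag.pore,
                                      seed=6)
        assert ev["ires_pct"].mean() == pytest.approx(96.1, abs=0.02)

    def test_durations_track_koff(self, ag):
        ev = pv.sample_labeled_events([ag.analyte("ethanal")], 2000, ag.pore,
                                      seed=7)
        # truncated exponential: mean = dead_time + 1/k_off
        assert ev["duration_s"].mean() == pytest.approx(
            5e-4 + 1 / 9.4, rel=0.1)


def test_scenario_validation(ag):
    with pytest.raises(ValidationError):
        pv.SimulationScenario(pore=ag.pore, segments=(), seed=0)
    with pytest.raises(ValidationError):
        make_scenario(ag, {"butanal": 1.0}, -5.0, seed=0)
    with pytest.raises(ValidationError):
        pv.SimulationScenario(
            pore=ag.pore,
            segments=(pv.Segment(1.0, ag.mixture({"butanal": 1.0})),),
            sampling_rate=15_000.0, filter_cutoff=10_000.0, seed=0)
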