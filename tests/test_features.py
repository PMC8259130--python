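"""Waveform features (T1, T2, N, speed), gating, and sort metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from besselflow import (
    GateSpec,
    ObjectSpec,
    ScenePlan,
    SortReport,
    apply_gate_and_score,
    compute_T1,
    compute_T2_profile,
    count_positive_peaks,
    detect_events,
    estimate_noise_sigma,
    estimate_speed,
    extract_features,
    otsu_threshold,
    synthesize_waveform,
    valley_threshold,
)


def single_event(rec):
    events = detect_events(rec)
    assert len(events) == 1
    return events[0]


class TestEstimateSpeed:
    @pytest.mark.parametrize("v", [10.0, 15.0, 20.0, 25.0])
    def test_speed_recovered_across_range(self, bead_record_factory, v):
        rec = bead_record_factory(diameter=10.0, speed=v)
        ev = single_event(rec)
        got = estimate_speed(rec, ev)
        # one-sample timing error on a 20 um baseline
        dt_rel = rec.params.dt / (rec.params.led_separation_object / (v / 100.0))
        assert got == pytest.approx(v, rel=max(2 * dt_rel, 1e-3))

    def test_none_when_dips_missing(self, bead_record_factory):
        rec = bead_record_factory(diameter=10.0, speed=20.0)
        ev = single_event(rec)
        assert estimate_speed(rec, ev, min_depth=0.9) is None


class TestComputeT1:
    def test_duration_matches_size_over_speed(self, bead_record_factory):
        rec = bead_record_factory(diameter=15.0, speed=20.0)
        ev = single_event(rec)
        sigma = estimate_noise_sigma(rec)
        t1, span = compute_T1(rec, ev, sigma)
        # (15 + 1.5 slit) um / 0.2 um/us = 82.5 us
        assert t1 == pytest.approx(82.5, abs=2 * rec.params.scan_period)
        assert span[0] >= ev.first_scan and span[1] <= ev.last_scan

    def test_halving_speed_doubles_t1(self, bead_record_factory):
        sigma = 0.0
        t = {}
        for v in (10.0, 20.0):
            rec = bead_record_factory(diameter=15.0, speed=v)
            t[v], _ = compute_T1(rec, single_event(rec), sigma)
        assert t[10.0] == pytest.approx(2 * t[20.0], rel=0.05)

    def test_none_when_nothing_qualifies(self, bead_record_factory):
        rec = bead_record_factory(diameter=10.0)
        ev = single_event(rec)
        t1, span = compute_T1(rec, ev, sigma=10.0)  # absurd noise level
        assert t1 is None and span is None


class TestComputeT2:
    @pytest.mark.parametrize("d", [7.0, 10.0, 15.0])
    def test_width_tracks_diameter(self, bead_record_factory, d):
        rec = bead_record_factory(diameter=d, speed=20.0)
        ev = single_event(rec)
        _, t2max = compute_T2_profile(rec, ev, sigma=estimate_noise_sigma(rec))
        w = t2max * rec.params.scan_speed
        assert w == pytest.approx(d, abs=2 * rec.params.pitch)

    def test_profile_peaks_at_widest_section(self, bead_record_factory):
        rec = bead_record_factory(diameter=15.0, speed=20.0)
        ev = single_event(rec)
        widths, t2max = compute_T2_profile(rec, ev, sigma=0.0)
        assert widths.max() == t2max
        i = int(np.argmax(widths))
        # widest section sits mid-transit, away from the window edges
        assert 0.2 * len(widths) < i < 0.8 * len(widths)

    def test_speed_invariance_of_width(self, bead_record_factory):
        w = []
        for v in (10.0, 25.0):
            rec = bead_record_factory(diameter=10.0, speed=v)
            _, t2max = compute_T2_profile(rec, single_event(rec), sigma=0.0)
            w.append(t2max * rec.params.scan_speed)
        assert w[0] == pytest.approx(w[1], rel=0.05)


class TestCountPositivePeaks:
    def test_smooth_dark_bead_has_none(self, bead_record_factory):
        rec = bead_record_factory(diameter=10.0, bright_spot=False)
        ev = single_event(rec)
        assert count_positive_peaks(rec, ev, sigma=0.0) == 0

    def test_bright_centre_registers(self, comb, acq_quiet):
        spec = ObjectSpec(
            kind="bead", diameter=10.0, speed=20.0, arrival_time=600.0,
            bright_spot=True, center_transmission=1.25,
        )
        rec = synthesize_waveform(ScenePlan(objects=[spec], seed=0), comb, acq_quiet, seed=0)
        ev = single_event(rec)
        assert count_positive_peaks(rec, ev, sigma=0.0) >= 1

    def test_correlates_with_granule_count(self, comb, acq_quiet):
        counts, truth = [], []
        rng = np.random.default_rng(7)
        for i in range(50):
            n_g = int(rng.integers(0, 13))
            spec = ObjectSpec(
                kind="cell", diameter=13.0, speed=20.0, arrival_time=600.0,
                n_granules=n_g, granule_contrast=0.4, granule_diameter=2.0,
                seed=int(rng.integers(0, 2**31)),
            )
            rec = synthesize_waveform(
                ScenePlan(objects=[spec], seed=i), comb, acq_quiet, seed=i
            )
            ev = single_event(rec)
            sigma = estimate_noise_sigma(rec)
            _, span = compute_T1(rec, ev, sigma)
            counts.append(count_positive_peaks(rec, ev, sigma, scan_span=span))
            truth.append(n_g)
        rho = stats.spearmanr(truth, counts).statistic
        assert rho > 0.8


class TestDerivedFeatures:
    def test_length_is_speed_invariant(self, bead_record_factory):
        L = []
        for v in (10.0, 15.0, 20.0, 25.0):
            rec = bead_record_factory(diameter=10.0, speed=v)
            df = extract_features(rec, detect_events(rec))
            L.append(float(df["L_um"].iloc[0]))
        assert np.std(L) / np.mean(L) < 0.03

    def test_speed_correction_shrinks_spread(self, comb, acq_quiet):
        """Raw T1 varies strongly with the flow speed; T1 * v does not."""
        rng = np.random.default_rng(3)
        t1s, Ls = [], []
        for i in range(12):
            v = float(rng.uniform(10.0, 25.0))
            spec = ObjectSpec(kind="bead", diameter=10.0, speed=v, arrival_time=600.0)
            rec = synthesize_waveform(
                ScenePlan(objects=[spec], seed=i), comb, acq_quiet, seed=i
            )
            df = extract_features(rec, detect_events(rec))
            t1s.append(float(df["T1_us"].iloc[0]))
            Ls.append(float(df["L_um"].iloc[0]))
        cv_raw = np.std(t1s) / np.mean(t1s)
        cv_corr = np.std(Ls) / np.mean(Ls)
        assert cv_corr < cv_raw / 5

    def test_feature_frame_schema_and_truth_match(self, bead_record_factory):
        rec = bead_record_factory(diameter=10.0, speed=20.0)
        df = extract_features(rec, detect_events(rec))
        for col in ("T1_us", "T2_max_us", "n_pos_peaks", "speed_cm_s",
                    "L_um", "W_um", "size_product_um2", "Nv",
                    "truth_label", "truth_index", "reason"):
            assert col in df.columns
        assert df["truth_index"].iloc[0] == 0
        assert df["reason"].iloc[0] == ""


class TestGating:
    def _frame(self, values, labels):
        return pd.DataFrame(
            {"x": values, "truth_label": labels, "reason": [""] * len(values)}
        )

    def test_contains_is_closed_interval(self):
        gate = GateSpec(bounds={"x": (1.0, 2.0)})
        df = self._frame([0.5, 1.0, 1.5, 2.0, 2.5], ["a"] * 5)
        assert gate.contains(df).tolist() == [False, True, True, True, False]

    def test_missing_axis_raises_with_available_names(self):
        gate = GateSpec(bounds={"nope": (0.0, 1.0)})
        with pytest.raises(KeyError, match="nope"):
            gate.contains(self._frame([1.0], ["a"]))

    def test_degenerate_gate_rejected(self):
        with pytest.raises(ValueError):
            GateSpec(bounds={"x": (2.0, 2.0)})
        with pytest.raises(ValueError):
            GateSpec(bounds={})

    def test_purity_yield_arithmetic(self):
        # 124 targets + 4 contaminants sorted out of 128 targets present
        df = self._frame(
            [1.5] * 124 + [1.6] * 4 + [0.5] * 4 + [0.2] * 368,
            ["t"] * 124 + ["b"] * 4 + ["t"] * 4 + ["b"] * 368,
        )
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (1.0, 2.0)}), "t")
        assert rep.true_positive == 124 and rep.false_positive == 4
        assert rep.purity_percent == pytest.approx(100 * 124 / 128)
        assert round(rep.purity_percent) == 97
        assert rep.yield_percent == pytest.approx(100 * 124 / 128)

    def test_second_worked_example(self):
        df = self._frame(
            [1.5] * 248 + [1.6] * 5 + [0.5] * 5 + [0.2] * 295,
            ["t"] * 248 + ["b"] * 5 + ["t"] * 5 + ["b"] * 295,
        )
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (1.0, 2.0)}), "t")
        assert round(rep.purity_percent) == 98

    def test_perfect_gate_gives_infinite_enrichment(self):
        df = self._frame([1.5] * 10 + [0.1] * 500, ["t"] * 10 + ["b"] * 500)
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (1.0, 2.0)}), "t")
        assert rep.purity_percent == 100.0
        assert np.isinf(rep.enrichment)
        assert rep.to_dict()["enrichment"] is None

    def test_enrichment_odds_ratio(self):
        # before: 20 targets vs 1000 background; sorted: 19 TP, 1 FP
        df = self._frame(
            [1.5] * 19 + [1.5] + [0.1] + [0.1] * 999,
            ["t"] * 19 + ["b"] + ["t"] + ["b"] * 999,
        )
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (1.0, 2.0)}), "t")
        assert rep.enrichment == pytest.approx((19 / 1) / (20 / 1000))

    def test_all_pass_gate_recovers_mixture_proportion(self):
        df = self._frame([1.0] * 30 + [1.0] * 70, ["t"] * 30 + ["b"] * 70)
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (0.0, 2.0)}), "t")
        assert rep.purity_percent == pytest.approx(30.0)
        assert rep.yield_percent == 100.0

    def test_invalid_events_never_sort(self):
        df = pd.DataFrame(
            {
                "x": [1.5, 1.5],
                "truth_label": ["t", "t"],
                "reason": ["", "speed_unavailable"],
            }
        )
        rep = apply_gate_and_score(df, GateSpec(bounds={"x": (1.0, 2.0)}), "t")
        assert rep.true_positive == 1 and rep.false_negative == 1

    def test_idempotent_and_order_independent(self, rng):
        x = np.r_[rng.normal(1.0, 0.1, 50), rng.normal(3.0, 0.1, 50)]
        labels = ["a"] * 50 + ["b"] * 50
        df = self._frame(list(x), labels)
        gate = GateSpec(bounds={"x": (2.0, 4.0)})
        r1 = apply_gate_and_score(df, gate, "b")
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        r2 = apply_gate_and_score(shuffled, gate, "b")
        assert r1.to_dict() == r2.to_dict()
        r3 = apply_gate_and_score(df, gate, "b")
        assert r1.to_dict() == r3.to_dict()


class TestThresholds:
    def test_valley_separates_two_modes(self, rng):
        x = np.r_[rng.normal(10.0, 0.5, 300), rng.normal(20.0, 0.5, 300)]
        thr = valley_threshold(x)
        assert 12.0 < thr < 18.0

    def test_valley_rejects_unimodal(self, rng):
        with pytest.raises(ValueError):
            valley_threshold(np.full(100, 5.0) + rng.normal(0, 1e-9, 100))

    def test_otsu_separates_two_modes(self, rng):
        x = np.r_[rng.normal(10.0, 0.5, 300), rng.normal(20.0, 0.5, 300)]
        thr = otsu_threshold(x)
        assert 12.0 < thr < 18.0


class TestSortReportSerialization:
    def test_to_dict_round_numbers(self):
        rep = SortReport(
            target_label="t", true_positive=9, false_positive=1,
            false_negative=0, true_negative=90,
            n_target_before=9, n_background_before=91,
        )
        d = rep.to_dict()
        assert d["purity_percent"] == 90.0
        assert d["yield_percent"] == 100.0
        assert d["enrichment"] == pytest.approx(9 / (9 / 91))
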