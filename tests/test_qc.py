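import numpy as np
import pandas as pd
import pytest

from panelflow.chromio import AreaMatrix
from panelflow.panel import TransitionRole
from panelflow.qc import (
    FeatureTable,
    QcConfigError,
    correct_drift,
    detection_rate_filter,
    digestion_gate,
    mask_outliers,
    normalize_to_is,
    quantqual_ratio_check,
    run_qc_chain,
    subtract_blank,
)
from panelflow.simulate import ChromatogramSimSpec, simulate_chromatograms


def _areas(panel, samples, fill=1000.0):
    cols = [t.key for t in panel.transitions]
    values = pd.DataFrame(fill, index=samples, columns=cols)
    return values


def _runsheet(samples, roles=None):
    roles = roles or ["study"] * len(samples)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "injection_order": range(1, len(samples) + 1),
            "role": roles,
            "group": [None] * len(samples),
            "calibration_level": [None] * len(samples),
        }
    )


class TestDigestionGate:
    def test_zero_signal_sample_excluded(self, demo_panel):
        samples = [f"S{i}" for i in range(10)]
        values = _areas(demo_panel, samples)
        eno1_q = [
            t.key for t in demo_panel.transitions
            if t.protein_id == "ENO1" and t.role == TransitionRole.QUANTIFIER
        ]
        values.loc["S3", eno1_q] = 0.0
        kept, report = digestion_gate(AreaMatrix(values), demo_panel)
        assert kept.samples == [s for s in samples if s != "S3"]
        assert report.loc[report.sample_id == "S3", "excluded"].item()

    def test_all_samples_pass_is_identity(self, demo_panel):
        values = _areas(demo_panel, ["S1", "S2"])
        kept, _ = digestion_gate(AreaMatrix(values), demo_panel)
        pd.testing.assert_frame_equal(kept.values, values.astype(float))

    def test_all_fail_warns_and_empties(self, demo_panel):
        values = _areas(demo_panel, ["S1", "S2"], fill=0.0)
        with pytest.warns(UserWarning, match="every sample"):
            kept, _ = digestion_gate(AreaMatrix(values), demo_panel)
        assert kept.samples == []

    def test_missing_standard_column_is_config_error(self, demo_panel):
        values = _areas(demo_panel, ["S1"]).drop(
            columns=[t.key for t in demo_panel.transitions if t.protein_id == "ENO1"]
        )
        with pytest.raises(QcConfigError):
            digestion_gate(AreaMatrix(values), demo_panel)


class TestRatioCheck:
    def test_deviant_ratio_flagged(self, demo_panel):
        pep = demo_panel.peptides[0]
        qk = demo_panel.transition(pep, "quantifier").key
        lk = demo_panel.transition(pep, "qualifier").key
        samples = [f"S{i}" for i in range(7)]
        values = _areas(demo_panel, samples)
        values[qk] = 1000.0
        values[lk] = 200.0  # ratio 5.0 everywhere
        values.loc["S6", lk] = 600.0  # ratio 1.67: |1.67-5|/5 = 0.67 > 0.30
        flags = quantqual_ratio_check(AreaMatrix(values), demo_panel, tolerance=0.30)
        assert flags.loc["S6", pep]
        assert not flags.loc["S0", pep]

    def test_identical_ratios_no_flags(self, demo_panel):
        values = _areas(demo_panel, ["S1", "S2", "S3"])
        flags = quantqual_ratio_check(AreaMatrix(values), demo_panel, 0.30)
        assert not flags.to_numpy().any()

    def test_zero_qualifier_flagged(self, demo_panel):
        pep = demo_panel.peptides[0]
        lk = demo_panel.transition(pep, "qualifier").key
        values = _areas(demo_panel, ["S1", "S2", "S3"])
        values.loc["S1", lk] = 0.0
        flags = quantqual_ratio_check(AreaMatrix(values), demo_panel, 0.30)
        assert flags.loc["S1", pep]


class TestBlankSubtraction:
    def test_mean_blank_subtracted(self, demo_panel):
        key = demo_panel.transitions[0].key
        values = _areas(demo_panel, ["S1", "B1"])
        values.loc["S1", key] = 500.0
        values.loc["B1", key] = 100.0
        m = AreaMatrix(values, _runsheet(["S1", "B1"], ["study", "blank"]))
        out, _ = subtract_blank(m)
        assert out.values.loc["S1", key] == pytest.approx(400.0)

    def test_zero_blank_untouched(self, demo_panel):
        key = demo_panel.transitions[0].key
        values = _areas(demo_panel, ["S1", "B1"])
        values.loc["B1", :] = 0.0
        m = AreaMatrix(values, _runsheet(["S1", "B1"], ["study", "blank"]))
        out, _ = subtract_blank(m)
        assert out.values.loc["S1", key] == pytest.approx(1000.0)

    def test_floors_at_zero_with_report(self, demo_panel):
        key = demo_panel.transitions[0].key
        values = _areas(demo_panel, ["S1", "B1"])
        values.loc["S1", key] = 50.0
        values.loc["B1", key] = 100.0
        m = AreaMatrix(values, _runsheet(["S1", "B1"], ["study", "blank"]))
        out, report = subtract_blank(m)
        assert out.values.loc["S1", key] == 0.0
        assert {"sample_id": "S1", "transition_key": key} in report.to_dict("records")

    def test_no_blanks_is_warned_noop(self, demo_panel):
        values = _areas(demo_panel, ["S1"])
        m = AreaMatrix(values, _runsheet(["S1"]))
        with pytest.warns(UserWarning, match="blank"):
            out, _ = subtract_blank(m)
        pd.testing.assert_frame_equal(out.values, m.values)


class TestNormalizeToIs:
    def test_simple_ratio(self, demo_panel):
        prot = demo_panel.proteins[0]
        pk = demo_panel.transition(demo_panel.peptides_for(prot)[0], "quantifier").key
        aldoa_q = [
            t.key for t in demo_panel.transitions
            if t.protein_id == "ALDOA" and t.role == TransitionRole.QUANTIFIER
        ]
        values = _areas(demo_panel, ["S1"])
        values.loc["S1", pk] = 1000.0
        values.loc["S1", aldoa_q] = 500.0
        table = normalize_to_is(AreaMatrix(values), demo_panel, standard="ALDOA")
        assert table.values.loc["S1", prot] == pytest.approx(2.0)

    def test_invariant_to_per_sample_scaling(self, demo_panel):
        rng = np.random.default_rng(2)
        samples = ["S1", "S2", "S3"]
        values = _areas(demo_panel, samples) * rng.uniform(0.5, 2, (3, 1))
        values2 = values * np.array([[2.0], [5.0], [0.1]])  # per-sample global factor
        t1 = normalize_to_is(AreaMatrix(values), demo_panel, standard="ALDOA")
        t2 = normalize_to_is(AreaMatrix(values2), demo_panel, standard="ALDOA")
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_missing_standard_blanks_row(self, demo_panel):
        aldoa = [t.key for t in demo_panel.transitions if t.protein_id == "ALDOA"]
        values = _areas(demo_panel, ["S1", "S2"])
        values.loc["S1", aldoa] = np.nan
        table = normalize_to_is(AreaMatrix(values), demo_panel, standard="ALDOA")
        assert table.values.loc["S1"].isna().all()
        assert table.values.loc["S2"].notna().all()

    def test_unknown_standard_is_config_error(self, demo_panel):
        values = _areas(demo_panel, ["S1"])
        with pytest.raises(QcConfigError):
            normalize_to_is(AreaMatrix(values), demo_panel, standard="NOPE")


def _feature_table(values, order=None):
    meta = pd.DataFrame(index=values.index)
    meta["injection_order"] = order if order is not None else range(1, len(values) + 1)
    return FeatureTable(values, meta)


class TestDriftCorrection:
    def test_near_identity_without_drift(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(
            {"P1": 10 + rng.normal(0, 0.1, 40)}, index=[f"S{i}" for i in range(40)]
        )
        out = correct_drift(_feature_table(vals), frac=0.5)
        rel = (out.values["P1"] - vals["P1"]).abs() / vals["P1"]
        assert rel.max() < 0.05  # corrections stay within the noise scale

    def test_linear_drift_removed_and_cv_halved(self):
        n = 60
        order = np.arange(1, n + 1)
        drift = 1 + 0.3 * order / n
        vals = pd.DataFrame({"P1": 10.0 * drift}, index=[f"S{i}" for i in range(n)])
        out = correct_drift(_feature_table(vals, order), frac=0.5)
        slope_before = np.polyfit(order, vals["P1"], 1)[0]
        slope_after = np.polyfit(order, out.values["P1"], 1)[0]
        assert abs(slope_after) < abs(slope_before) / 10
        cv_before = vals["P1"].std() / vals["P1"].mean()
        cv_after = out.values["P1"].std() / out.values["P1"].mean()
        assert cv_after < cv_before / 2

    def test_mean_preserved(self):
        rng = np.random.default_rng(9)
        n = 50
        order = np.arange(1, n + 1)
        vals = pd.DataFrame(
            {"P1": 5 * (1 + 0.2 * order / n) + rng.normal(0, 0.2, n)},
            index=[f"S{i}" for i in range(n)],
        )
        out = correct_drift(_feature_table(vals, order), frac=0.5)
        assert out.values["P1"].mean() == pytest.approx(vals["P1"].mean(), rel=1e-6)

    def test_too_few_points_left_uncorrected(self):
        vals = pd.DataFrame({"P1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="too few"):
            out = correct_drift(_feature_table(vals), frac=0.5)
        pd.testing.assert_frame_equal(out.values, vals)


class TestOutlierMask:
    def test_hand_computed_mad_case(self):
        # {1..10, 1000}: median 6, MAD 3, threshold 10*3=30 → only 1000 masked
        vals = pd.DataFrame(
            {"P1": list(range(1, 11)) + [1000.0]},
            index=[f"S{i}" for i in range(11)],
        )
        out, report = mask_outliers(_feature_table(vals), k=10)
        assert np.isnan(out.values.loc["S10", "P1"])
        assert out.values["P1"].iloc[:10].notna().all()
        assert len(report) == 1 and report.iloc[0]["value"] == 1000.0

    def test_values_within_band_untouched(self):
        vals = pd.DataFrame({"P1": [1.0, 1.1, 0.9, 1.05]}, index=list("abcd"))
        out, report = mask_outliers(_feature_table(vals), k=10)
        pd.testing.assert_frame_equal(out.values, vals)
        assert report.empty

    def test_zero_mad_warns_and_skips(self):
        vals = pd.DataFrame({"P1": [2.0, 2.0, 2.0, 50.0]}, index=list("abcd"))
        # median 2, MAD 0 → rule undefined → nothing masked
        with pytest.warns(UserWarning, match="MAD"):
            out, report = mask_outliers(_feature_table(vals), k=10)
        pd.testing.assert_frame_equal(out.values, vals)

    def test_surviving_values_unchanged(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame({"P1": rng.lognormal(0, 0.3, 30)}, index=range(30))
        vals.iloc[0, 0] = 1e6
        out, _ = mask_outliers(_feature_table(vals), k=10)
        kept = out.values["P1"].notna()
        pd.testing.assert_series_equal(out.values.loc[kept, "P1"], vals.loc[kept, "P1"])


class TestChain:
    def test_full_chain_on_synthetic_batch(self, demo_panel, params):
        from panelflow.peaks import integrate_batch

        spec = ChromatogramSimSpec(
            panel=demo_panel, n_samples=12, n_blanks=2, noise_sd=0.02,
            rt_jitter_sd=0.02, drift_coefficient=0.3, blank_level=0.05, seed=21,
        )
        traces, runsheet, truth = simulate_chromatograms(spec)
        areas, _ = integrate_batch(traces, demo_panel, params, runsheet)
        table, reports = run_qc_chain(areas, demo_panel, params)
        # all study samples retained, standards dropped from columns
        assert len(table.samples) == 12
        assert "ENO1" not in table.proteins and "ALDOA" not in table.proteins
        assert (table.values.dropna() >= 0).all().all()
        # drift was multiplicative and shared: post-chain CV should be small
        cvs = table.values.std() / table.values.mean()
        assert cvs.max() < 0.15

    def test_rerun_changes_nothing_but_masks(self, demo_panel, params):
        rng = np.random.default_rng(8)
        samples = [f"S{i}" for i in range(20)]
        values = pd.DataFrame(
            rng.lognormal(np.log(1000), 0.2, (20, len(demo_panel.transitions))),
            index=samples,
            columns=[t.key for t in demo_panel.transitions],
        )
        m = AreaMatrix(values, _runsheet(samples))
        t1, _ = run_qc_chain(m, demo_panel, params, blank_subtraction=False)
        # feed normalized output areas back: IS ratios of ratios are unchanged
        t2, _ = run_qc_chain(m, demo_panel, params, blank_subtraction=False)
        pd.testing.assert_frame_equal(t1.values, t2.values)

    def test_detection_rate_filter(self):
        vals = pd.DataFrame(
            {"good": [1.0] * 10, "patchy": [1.0] * 5 + [np.nan] * 5},
            index=[f"S{i}" for i in range(10)],
        )
        table = _feature_table(vals)
        kept, dropped = detection_rate_filter(table, min_rate=0.8)
        assert kept.proteins == ["good"]
        assert dropped == ["patchy"]
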