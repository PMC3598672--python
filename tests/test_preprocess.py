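"""Preprocessing ladder: hand-arithmetic oracles for each step, QC attrition
monotonicity, normalization idempotence and scale invariance."""

import numpy as np
import pandas as pd
import pytest

from mirblood.preprocess import (
    CountMatrix,
    PreprocessError,
    content_normalize,
    filter_min_count,
    log2_transform,
    negative_background_threshold,
    positive_control_normalize,
    probe_background_correct,
    read_count_table,
    run_preprocess,
    QCReport,
)


def _matrix(rows: dict, classes: dict) -> CountMatrix:
    values = pd.DataFrame(rows).T
    values.columns = [f"s{i+1}" for i in range(values.shape[1])]
    return CountMatrix(values, pd.Series(classes))


class TestReadCountTable:
    def test_codeset_layout_tallies(self, tmp_path):
        n = {"endogenous": 734, "pos": 6, "neg": 8, "hk": 5}
        ids, classes = [], []
        for cls, k in n.items():
            ids += [f"{cls}_{i}" for i in range(k)]
            classes += [cls] * k
        df = pd.DataFrame({"probe_class": classes, "sA": 1, "sB": 2}, index=ids)
        df.index.name = "probe_id"
        path = tmp_path / "counts.csv"
        df.to_csv(path)
        cm = read_count_table(path)
        assert cm.class_counts() == n

    def test_negative_count_rejected(self, tmp_path):
        df = pd.DataFrame({"probe_class": ["endogenous"], "sA": [-1]}, index=["m1"])
        df.index.name = "probe_id"
        path = tmp_path / "bad.csv"
        df.to_csv(path)
        with pytest.raises(PreprocessError, match="m1"):
            read_count_table(path)

    def test_duplicate_probe_ids_rejected(self):
        values = pd.DataFrame([[1.0], [2.0]], index=["m1", "m1"], columns=["s1"])
        with pytest.raises(PreprocessError, match="duplicate"):
            CountMatrix(values, pd.Series(["endogenous", "endogenous"], index=["m1", "m1"]))

    def test_unknown_probe_class_rejected(self):
        values = pd.DataFrame([[1.0]], index=["m1"], columns=["s1"])
        with pytest.raises(PreprocessError, match="bogus"):
            CountMatrix(values, pd.Series(["bogus"], index=["m1"]))

    def test_rcc_like_dialect(self, tmp_path):
        text = (
            "<Header>\nversion,1\n"
            "<Code_Summary>\n"
            "CodeClass,Name,s1,s2\n"
            "Endogenous,miR-1,10,20\n"
            "Positive,POS_A,100,110\n"
            "Negative,NEG_1,2,3\n"
            "Housekeeping,ACTB,500,600\n"
        )
        path = tmp_path / "t.rcc"
        path.write_text(text)
        cm = read_count_table(path, dialect="rcc-like")
        assert cm.class_counts() == {"endogenous": 1, "pos": 1, "neg": 1, "hk": 1}
        assert cm.values.loc["miR-1", "s2"] == 20


class TestProbeBackgroundCorrect:
    def test_subtraction_and_floor(self, toy_counts):
        out = probe_background_correct(toy_counts, {"m1": 10.0, "m3": 11.0})
        assert out.values.loc["m1", "s1"] == 40.0  # 50 - 10
        assert out.values.loc["m3", "s1"] == 1.0  # 10 - 11 < 0 -> 1
        assert out.values.loc["m3", "s2"] == 1.0  # 12 - 11 >= 0 -> 1.0
        assert out.values.loc["m2", "s1"] == 200.0  # unlisted unchanged

    def test_empty_map_is_identity(self, toy_counts):
        out = probe_background_correct(toy_counts, {})
        pd.testing.assert_frame_equal(out.values, toy_counts.values)

    def test_unknown_probe_rejected(self, toy_counts):
        with pytest.raises(PreprocessError, match="nope"):
            probe_background_correct(toy_counts, {"nope": 1.0})


class TestPositiveControlNormalize:
    def test_mean_target_rule(self, toy_counts):
        # pos sums: s1 = 100, s2 = 200 -> factors 1.5 and 0.75, both sums 150
        qc = QCReport()
        out = positive_control_normalize(toy_counts, qc=qc)
        sums = out.of_class("pos").sum(axis=0)
        np.testing.assert_allclose(sums, 150.0, rtol=1e-9)
        assert qc.pos_scale_factors == {"s1": 1.5, "s2": 0.75}

    def test_equal_sums_give_unit_factors(self):
        cm = _matrix(
            {"m1": [5.0, 7.0], "POS_A": [100.0, 100.0]},
            {"m1": "endogenous", "POS_A": "pos"},
        )
        out = positive_control_normalize(cm)
        pd.testing.assert_frame_equal(out.values, cm.values)

    def test_idempotent(self, toy_counts):
        once = positive_control_normalize(toy_counts)
        twice = positive_control_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)

    def test_zero_positive_sum_rejected(self):
        cm = _matrix(
            {"m1": [5.0, 7.0], "POS_A": [0.0, 10.0]},
            {"m1": "endogenous", "POS_A": "pos"},
        )
        with pytest.raises(PreprocessError, match="s1"):
            positive_control_normalize(cm)


class TestNegativeBackgroundThreshold:
    def test_hand_arithmetic_threshold(self):
        # negatives 1..8: mean 4.5, sd 2.449 (n-1), T = 9.399
        rows = {f"NEG_{i}": [float(i)] for i in range(1, 9)}
        rows["keep"] = [10.0]
        rows["drop"] = [9.0]
        classes = {k: ("neg" if k.startswith("NEG") else "endogenous") for k in rows}
        out, detected = negative_background_threshold(CountMatrix(pd.DataFrame(rows).T, pd.Series(classes)))
        T = 4.5 + 2 * np.std(np.arange(1, 9), ddof=1)
        assert T == pytest.approx(9.39898, abs=1e-4)
        assert list(detected) == ["keep"]
        assert out.values.loc["keep"].iloc[0] == pytest.approx(10.0 - T)
        assert "drop" not in out.values.index

    def test_zero_negatives_keep_everything(self, toy_counts):
        out, detected = negative_background_threshold(toy_counts)
        assert set(detected) == {"m1", "m2", "m3"}
        pd.testing.assert_frame_equal(
            out.values.loc[["m1", "m2", "m3"]], toy_counts.values.loc[["m1", "m2", "m3"]]
        )

    def test_detection_is_all_samples_conjunction(self):
        rows = {"NEG_1": [2.0, 2.0], "NEG_2": [2.0, 2.0], "m": [100.0, 1.0]}
        classes = {"NEG_1": "neg", "NEG_2": "neg", "m": "endogenous"}
        cm = CountMatrix(pd.DataFrame(rows).T, pd.Series(classes))
        _, detected = negative_background_threshold(cm)
        assert len(detected) == 0  # positive in one sample, negative in the other

    def test_single_negative_rejected(self):
        cm = _matrix({"NEG_1": [1.0], "m": [5.0]}, {"NEG_1": "neg", "m": "endogenous"})
        with pytest.raises(PreprocessError):
            negative_background_threshold(cm)

    def test_detection_only_mode_keeps_counts(self):
        rows = {"NEG_1": [2.0], "NEG_2": [4.0], "m": [100.0]}
        classes = {"NEG_1": "neg", "NEG_2": "neg", "m": "endogenous"}
        cm = CountMatrix(pd.DataFrame(rows).T, pd.Series(classes))
        out, _ = negative_background_threshold(cm, subtract=False)
        assert out.values.loc["m"].iloc[0] == 100.0


class TestContentNormalize:
    def test_totals_equalized_to_mean(self):
        cm = _matrix(
            {"m1": [1000.0, 3000.0], "POS_A": [10.0, 10.0]},
            {"m1": "endogenous", "POS_A": "pos"},
        )
        out = content_normalize(cm, ["m1"])
        np.testing.assert_allclose(out.values.loc["m1"], 2000.0, rtol=1e-9)

    def test_controls_excluded_from_scaling_sum(self):
        cm = _matrix(
            {"m1": [100.0, 100.0], "POS_A": [50.0, 500.0]},
            {"m1": "endogenous", "POS_A": "pos"},
        )
        out = content_normalize(cm, ["m1"])  # detected totals equal -> identity
        pd.testing.assert_frame_equal(out.values, cm.values)

    def test_idempotent(self, toy_counts):
        once = content_normalize(toy_counts, ["m1", "m2"])
        twice = content_normalize(once, ["m1", "m2"])
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-9)

    def test_empty_detected_set_rejected(self, toy_counts):
        with pytest.raises(PreprocessError):
            content_normalize(toy_counts, [])


class TestFilterMinCount:
    def test_boundary_probe_retained(self):
        cm = _matrix({"m1": [100.0, 100.0]}, {"m1": "endogenous"})
        out = filter_min_count(cm, threshold=100.0)
        assert list(out.values.index) == ["m1"]

    def test_matches_brute_force_scan(self, rng):
        values = pd.DataFrame(
            rng.integers(50, 200, size=(5, 4)).astype(float),
            index=[f"m{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(4)],
        )
        cm = CountMatrix(values, pd.Series("endogenous", index=values.index))
        out = filter_min_count(cm, threshold=100.0)
        brute = [p for p in values.index if all(values.loc[p] >= 100.0)]
        assert list(out.values.index) == brute

    def test_mean_rule_flag(self):
        cm = _matrix({"m1": [90.0, 120.0]}, {"m1": "endogenous"})
        assert len(filter_min_count(cm, 100.0, rule="min").values) == 0
        assert len(filter_min_count(cm, 100.0, rule="mean").values) == 1

    def test_empty_result_warns_not_errors(self):
        cm = _matrix({"m1": [1.0, 1.0]}, {"m1": "endogenous"})
        with pytest.warns(UserWarning):
            out = filter_min_count(cm, threshold=100.0)
        assert len(out.values) == 0


class TestLog2Transform:
    @pytest.mark.parametrize("raw,expected", [(1024.0, 10.0), (0.0, 0.0), (1.0, 0.0)])
    def test_values_with_floor(self, raw, expected):
        cm = _matrix({"m1": [raw]}, {"m1": "endogenous"})
        assert log2_transform(cm).values.iloc[0, 0] == expected

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 2000, size=50))
        cm = CountMatrix(
            pd.DataFrame({"s1": x}, index=[f"m{i}" for i in range(50)]),
            pd.Series("endogenous", index=[f"m{i}" for i in range(50)]),
        )
        out = log2_transform(cm).values["s1"].to_numpy()
        assert (np.diff(out) >= 0).all()


class TestRunPreprocess:
    def test_qc_attrition_non_increasing(self, small_cohort):
        _, qc = run_preprocess(small_cohort.counts)
        retained = [s["endogenous_retained"] for s in qc.steps]
        assert retained == sorted(retained, reverse=True)

    def test_identity_config_equals_log2_of_content_normalized(self):
        # uniform controls: pos sums equal, negatives all zero -> only content
        # normalization and log2 act
        rows = {
            "m1": [200.0, 400.0],
            "m2": [600.0, 1200.0],
            "POS_A": [100.0, 100.0],
            "NEG_1": [0.0, 0.0],
            "NEG_2": [0.0, 0.0],
        }
        classes = {"m1": "endogenous", "m2": "endogenous", "POS_A": "pos",
                   "NEG_1": "neg", "NEG_2": "neg"}
        cm = CountMatrix(pd.DataFrame(rows).T, pd.Series(classes))
        expr, _ = run_preprocess(cm, min_count=100.0)
        endo = cm.values.loc[["m1", "m2"]]
        totals = endo.sum(axis=0)
        expected = np.log2(endo * (totals.mean() / totals))
        np.testing.assert_allclose(expr.values, expected, rtol=1e-9)

    def test_provenance_records_step_order(self, small_cohort):
        expr, _ = run_preprocess(small_cohort.counts)
        steps = [rec["step"] for rec in expr.provenance]
        assert steps[:6] == [
            "input",
            "probe_background_correct",
            "positive_control_normalize",
            "negative_background_threshold",
            "content_normalize",
            "filter_min_count",
        ]
        assert steps[-1] == "log2_transform"

    def test_sample_scale_invariance(self):
        # scaling one sample's raw counts by c > 0 leaves its expression
        # unchanged when the detected set is unchanged
        rng = np.random.default_rng(5)
        n_probes = 30
        rows = {f"m{i}": list(rng.integers(500, 2000, size=3).astype(float)) for i in range(n_probes)}
        for i, v in enumerate([10.0, 20.0, 40.0, 80.0, 160.0, 320.0]):
            rows[f"POS_{i}"] = [v, v, v]
        for i in range(8):
            rows[f"NEG_{i}"] = list(rng.integers(3, 9).astype(float) * np.ones(3))
        classes = {
            k: ("pos" if k.startswith("POS") else "neg" if k.startswith("NEG") else "endogenous")
            for k in rows
        }
        cm = CountMatrix(pd.DataFrame(rows).T, pd.Series(classes))
        expr1, qc1 = run_preprocess(cm, min_count=10.0)

        scaled = cm.copy()
        scaled.values.iloc[:, 1] *= 3.0
        expr2, qc2 = run_preprocess(scaled, min_count=10.0)
        assert qc1.retained("negative_background_threshold") == qc2.retained(
            "negative_background_threshold"
        )
        # both normalizations are ratio-based, but their cross-sample mean
        # *target* moves when one sample is rescaled: the result is identical
        # up to one global log2 constant, which cancels in any between-sample
        # or between-group statistic
        delta = (expr2.values - expr1.values).to_numpy()
        np.testing.assert_allclose(delta, delta.flat[0], atol=1e-9)

    def test_simulated_detected_set_matches_generator_construction(self, small_cohort):
        # brute-force recomputation of the detected set from the raw counts
        raw = small_cohort.counts
        corrected = positive_control_normalize(raw)
        neg = corrected.of_class("neg")
        T = neg.mean(axis=0) + 2 * neg.std(axis=0, ddof=1)
        endo = corrected.of_class("endogenous")
        brute = endo.index[((endo - T) >= 0).all(axis=1)]
        _, qc = run_preprocess(raw)
        assert qc.retained("negative_background_threshold") == len(brute)
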