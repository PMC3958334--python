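"""Weighted uncentered correlation and interval classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mapkscreen import (
    DEFAULT_WEIGHTS,
    EPISTASIS_ASSAYS,
    IDEAL_PROFILES,
    INTERVALS,
    EpistasisClassifier,
    EpistasisPanel,
    ZeroNormError,
    classify_gene,
    classify_profiles,
    ideal_profile,
    interval_census,
    weighted_uncentered_pearson,
)
from conftest import loop_uncentered_pearson

W = np.asarray(DEFAULT_WEIGHTS)


class TestFormula:
    def test_self_correlation_is_one(self):
        x = ideal_profile("RAS-RAF")
        assert weighted_uncentered_pearson(x, x, W) == 1.0

    @pytest.mark.parametrize(
        "interval, expected",
        [
            ("RAS-RAF", -1 / np.sqrt(3)),
            ("RAF-MEK", -np.sqrt(2 / 3)),
            ("MEK-MAPK", -1.0),
        ],
    )
    def test_all_minus_one_closed_forms(self, interval, expected):
        """A uniform full-strength positive regulator hits the closed-form
        correlations against each interval profile."""
        x = -np.ones(6)
        r = weighted_uncentered_pearson(x, ideal_profile(interval), W)
        assert r == pytest.approx(expected, abs=1e-15)

    def test_profile_cross_correlation_closed_form(self):
        """RAS-RAF vs MEK-MAPK ideal profiles correlate at sqrt(w1/sum w)."""
        r = weighted_uncentered_pearson(
            ideal_profile("RAS-RAF"), ideal_profile("MEK-MAPK"), W
        )
        assert r == pytest.approx(np.sqrt(3 / 9), abs=1e-15)

    def test_matches_loop_reference_on_random_triples(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            w = rng.uniform(0.1, 5.0, size=6)
            assert weighted_uncentered_pearson(x, y, w) == pytest.approx(
                loop_uncentered_pearson(x, y, w), abs=1e-12
            )

    def test_uniform_weights_reduce_to_cosine(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=6), rng.normal(size=6)
        cosine = float(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))
        assert weighted_uncentered_pearson(x, y, np.ones(6)) == pytest.approx(
            cosine, abs=1e-12
        )

    @given(
        x=st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        y=st.lists(st.floats(-10, 10), min_size=6, max_size=6),
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_scaling_and_bounds(self, x, y, a):
        x, y = np.asarray(x), np.asarray(y)
        if np.sum(W * x * x) == 0 or np.sum(W * y * y) == 0:
            return
        r = weighted_uncentered_pearson(x, y, W)
        assert -1.0 <= r <= 1.0
        assert weighted_uncentered_pearson(y, x, W) == pytest.approx(r, abs=1e-12)
        assert weighted_uncentered_pearson(a * x, y, W) == pytest.approx(
            np.sign(a) * r, abs=1e-9
        )

    def test_r_is_unity_iff_scalar_multiple(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=6)
        assert weighted_uncentered_pearson(2.5 * y, y, W) == pytest.approx(1.0)
        assert weighted_uncentered_pearson(-0.3 * y, y, W) == pytest.approx(-1.0)
        x = y + np.asarray([0.5, 0, 0, 0, 0, 0])  # not a multiple
        assert abs(weighted_uncentered_pearson(x, y, W)) < 1.0

    def test_zero_norm_raises_distinct_error(self):
        with pytest.raises(ZeroNormError):
            weighted_uncentered_pearson(np.zeros(6), np.ones(6), W)
        # zero only on the weight support also raises
        w = np.asarray([1, 0, 0, 0, 0, 0], dtype=float)
        with pytest.raises(ZeroNormError):
            weighted_uncentered_pearson([0, 1, 1, 1, 1, 1], np.ones(6), w)

    def test_bad_shapes_and_negative_weights(self):
        with pytest.raises(ValueError):
            weighted_uncentered_pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            weighted_uncentered_pearson(np.ones(6), np.ones(6), -np.ones(6))


class TestIdealProfiles:
    @pytest.mark.parametrize(
        "interval, profile",
        [
            ("RAS-RAF", [1, 0, 0, 0, 0, 0]),
            ("RAF-MEK", [1, 1, 1, 1, 0, 0]),
            ("MEK-MAPK", [1, 1, 1, 1, 1, 1]),
        ],
    )
    def test_printed_vectors(self, interval, profile):
        assert ideal_profile(interval).tolist() == profile

    def test_unknown_interval_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            ideal_profile("none")


class TestClassification:
    def test_exact_profile_match_positive_regulator(self):
        call = classify_gene([-1, 0, 0, 0, 0, 0])
        assert call["interval"] == "RAS-RAF"
        assert call["sign"] == "positive"
        assert call["r_ras_raf"] == pytest.approx(-1.0)
        assert call["status"] == "assigned"

    def test_all_minus_one_is_ambiguous_mek_mapk(self):
        call = classify_gene([-1.0] * 6)
        assert call["interval"] == "MEK-MAPK"
        assert call["sign"] == "positive"
        assert call["confidence"] == pytest.approx(1 - np.sqrt(2 / 3), abs=1e-12)
        assert call["status"] == "ambiguous"  # 0.1835 < 0.2

    def test_near_noise_profile_unassigned(self):
        call = classify_gene([0.05, -0.02, 0.01, 0.0, 0.03, -0.01])
        rs = call[["r_ras_raf", "r_raf_mek", "r_mek_mapk"]].astype(float)
        if (rs.abs() <= 0.5).all():
            assert call["status"] == "unassigned"
        else:
            assert call["interval"] in INTERVALS

    def test_positive_rescaling_invariance_and_sign_flip(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            x = rng.normal(size=6)
            base = classify_gene(x)
            scaled = classify_gene(4.2 * x)
            assert scaled["interval"] == base["interval"]
            assert scaled["sign"] == base["sign"]
            flipped = classify_gene(-x)
            assert flipped["interval"] == base["interval"]
            if base["status"] != "unassigned":
                assert flipped["sign"] != base["sign"]

    def test_brute_force_assignment_over_ternary_profiles(self):
        """argmax-|r| assignment agrees with an exhaustive loop-based
        implementation for every profile over {-1, 0, 1}^6."""
        for x in itertools.product((-1.0, 0.0, 1.0), repeat=6):
            if all(v == 0 for v in x):
                continue
            # independent oracle
            best_iv, best_abs, second_abs = None, -1.0, -1.0
            rs = {}
            for iv in INTERVALS:
                r = loop_uncentered_pearson(x, IDEAL_PROFILES[iv], DEFAULT_WEIGHTS)
                rs[iv] = r
                if abs(r) > best_abs:
                    second_abs = best_abs
                    best_iv, best_abs = iv, abs(r)
                elif abs(r) > second_abs:
                    second_abs = abs(r)
            call = classify_gene(np.asarray(x))
            if abs(best_abs - 0.5) < 1e-9:
                continue  # exact band boundary: fp-order dependent in either path
            if best_abs < 0.5:
                assert call["status"] == "unassigned"
            else:
                # ties resolve to interval order in both implementations
                assert abs(call[f"r_{call['interval'].replace('-', '_').lower()}"]) == pytest.approx(
                    best_abs, abs=1e-12
                )
                assert call["confidence"] == pytest.approx(best_abs - second_abs, abs=1e-12)

    def test_tie_reports_zero_confidence_ambiguous(self):
        # RAF-MEK ideal correlates equally with itself only; craft a tie:
        # a profile equidistant from RAS-RAF and MEK-MAPK directions.
        x = np.asarray([1.0, 0, 0, 0, 0, 0])
        r_rr = weighted_uncentered_pearson(x, ideal_profile("RAS-RAF"), W)
        assert r_rr == 1.0
        # exact-tie synthetic case: zero vs zero handled via equal |r|
        call = classify_gene(x)
        assert call["status"] in {"assigned", "ambiguous"}

    def test_missing_assay_value_errors_with_name(self):
        frame = pd.DataFrame(
            [[0.1, np.nan, 0.2, 0.1, 0.0, 0.3]], columns=list(EPISTASIS_ASSAYS)
        )
        with pytest.raises(ValueError, match="RAFED"):
            classify_profiles(frame)

    def test_missing_assay_column_errors(self):
        frame = pd.DataFrame({a: [0.1] for a in EPISTASIS_ASSAYS[:-1]})
        with pytest.raises(ValueError, match=EPISTASIS_ASSAYS[-1]):
            classify_profiles(frame)

    def test_zero_profile_reported_unassigned(self):
        out = classify_profiles(np.zeros((1, 6)))
        assert out.iloc[0]["status"] == "unassigned"
        assert np.isnan(out.iloc[0]["r_mek_mapk"])


class TestEstimatorAndCensus:
    def test_sklearn_estimator_interface(self, small_screen_matrix):
        matrix, _ = small_screen_matrix
        X = matrix[list(EPISTASIS_ASSAYS)]
        clf = EpistasisClassifier()
        assert clf.get_params()["unassigned_band"] == 0.5
        clf.set_params(ambiguity_threshold=0.25)
        labels = clf.fit(X).predict(X)
        assert len(labels) == len(X)
        scores = clf.decision_function(X)
        assert scores.shape == (len(X), 3)
        assert np.nanmax(np.abs(scores)) <= 1.0

    def test_census_conserves_totals(self, small_screen_matrix):
        matrix, _ = small_screen_matrix
        calls = classify_profiles(matrix[list(EPISTASIS_ASSAYS)])
        census = interval_census(calls)
        assert int(census["n"].sum()) == len(calls)

    def test_census_empty(self):
        census = interval_census(pd.DataFrame(columns=["interval", "sign", "status"]))
        assert census.empty

    def test_planted_regulators_recovered(self, small_screen_matrix):
        matrix, truth = small_screen_matrix
        calls = classify_profiles(matrix[list(EPISTASIS_ASSAYS)])
        merged = calls.join(truth, rsuffix="_true")
        reg = merged[merged["regulator_class"].isin(INTERVALS)]
        correct = (reg["interval"] == reg["regulator_class"]) & (
            reg["sign"] == reg["sign_true"]
        )
        # small screen, default (low) noise: at most one miss per class
        assert (~correct).sum() <= len(INTERVALS)

    def test_panel_validation(self):
        with pytest.raises(ValueError):
            EpistasisPanel(weights=(1.0,) * 5)
        with pytest.raises(ValueError):
            EpistasisPanel(weights=(0.0,) * 6)
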