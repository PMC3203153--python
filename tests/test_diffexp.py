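"""Detection filtering, normalization, direction calls and permutation FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import bundle_from_array
from mirreg.diffexp import (
    SamConfig,
    consistent_direction,
    detection_filter,
    log2_median_center,
    paired_deltas,
    percent_of,
    permutation_fdr,
    permutation_q_values,
    sam_paired_d,
    sam_s0,
)


class TestDetectionFilter:
    def test_undetected_everywhere_dropped(self):
        det = np.ones((3, 12), dtype=bool)
        det[1, :] = False
        bundle = bundle_from_array(np.ones((3, 12)), detection=det)
        out = detection_filter(bundle)
        assert out.feature_ids == ["G1", "G3"]

    def test_all_detected_identity(self):
        bundle = bundle_from_array(np.ones((4, 4)))
        out = detection_filter(bundle)
        assert out.feature_ids == bundle.feature_ids

    def test_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(3)
        det = rng.random((50, 12)) < 0.1
        bundle = bundle_from_array(np.ones((50, 12)), detection=det)
        expected = [f"G{i+1}" for i in range(50) if any(det[i])]
        assert detection_filter(bundle).feature_ids == expected


class TestLog2MedianCenter:
    def test_hand_arithmetic(self):
        # one column {2,4,16}: log2 {1,2,4}, median 2, centered {-1,0,2}
        vals = np.array([[2.0, 2.0], [4.0, 4.0], [16.0, 16.0]])
        bundle = bundle_from_array(vals)
        out = log2_median_center(bundle)
        assert np.allclose(out.values.iloc[:, 0], [-1.0, 0.0, 2.0])
        assert out.scale == "log2_centered"

    def test_constant_column_all_zero(self):
        bundle = bundle_from_array(np.full((3, 2), 7.0))
        out = log2_median_center(bundle)
        assert np.allclose(out.values.to_numpy(), 0.0)

    def test_every_column_median_zero(self):
        rng = np.random.default_rng(5)
        bundle = bundle_from_array(rng.lognormal(3, 1, (101, 12)))
        out = log2_median_center(bundle)
        assert np.allclose(out.values.median(axis=0), 0.0)

    def test_nonpositive_value_names_culprit(self):
        vals = np.ones((2, 2))
        vals[1, 1] = 0.0
        with pytest.raises(ValueError, match="G2"):
            log2_median_center(bundle_from_array(vals))


class TestConsistentDirection:
    def test_rule_application(self):
        # deltas per patient: +1, +2, +0.5 -> up, mean ~1.1667
        vals = np.array([[1.0, 2.0, 0.5, 0.0, 0.0, 0.0]])
        bundle = bundle_from_array(vals, scale="log2_centered")
        (res,) = consistent_direction(bundle)
        assert res.direction == "up"
        assert res.mean_delta == pytest.approx(3.5 / 3)

    def test_mixed_signs_none(self):
        vals = np.array([[1.0, -1.0, 1.0, 0.0, 0.0, 0.0]])
        bundle = bundle_from_array(vals, scale="log2_centered")
        assert consistent_direction(bundle)[0].direction == "none"

    def test_exact_zero_delta_breaks_consistency(self):
        vals = np.array([[1.0, 0.0, 1.0, 0.0, 0.0, 0.0]])
        bundle = bundle_from_array(vals, scale="log2_centered")
        assert consistent_direction(bundle)[0].direction == "none"

    def test_matches_brute_force_sign_scan(self):
        rng = np.random.default_rng(11)
        tumor = rng.normal(0, 1, (50, 6))
        normal = rng.normal(0, 1, (50, 6))
        bundle = bundle_from_array(np.hstack([tumor, normal]), scale="log2_centered")
        results = consistent_direction(bundle)
        for i, res in enumerate(results):
            deltas = tumor[i] - normal[i]
            if all(d > 0 for d in deltas):
                expected = "up"
            elif all(d < 0 for d in deltas):
                expected = "down"
            else:
                expected = "none"
            assert res.direction == expected
            assert res.mean_delta == pytest.approx(np.mean(deltas))

    def test_up_down_none_partition(self):
        rng = np.random.default_rng(12)
        bundle = bundle_from_array(rng.normal(0, 1, (200, 12)), scale="log2_centered")
        results = consistent_direction(bundle)
        assert len(results) == 200
        assert {r.direction for r in results} <= {"up", "down", "none"}


class TestSamPairedD:
    def test_zero_deltas(self):
        assert sam_paired_d(np.zeros(4), s0=0.1) == 0.0

    def test_hand_formula(self):
        # deltas {1,2,3}: mean 2, sd 1, se 1/sqrt(3), d = 2*sqrt(3)
        assert sam_paired_d(np.array([1.0, 2.0, 3.0]), s0=0.0) == pytest.approx(
            2 * np.sqrt(3)
        )

    def test_equals_one_sample_t_when_s0_zero(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        deltas = rng.normal(0.5, 1, 8)
        t, _ = stats.ttest_1samp(deltas, 0.0)
        assert sam_paired_d(deltas, s0=0.0) == pytest.approx(float(t))

    def test_abs_d_decreases_in_s0(self):
        deltas = np.array([0.5, 1.5, 1.0, 2.0])
        ds = [abs(sam_paired_d(deltas, s0)) for s0 in (0.0, 0.1, 0.5, 2.0)]
        assert ds == sorted(ds, reverse=True)
        assert len(set(ds)) == len(ds)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            sam_paired_d(np.array([1.0]), 0.1)
        with pytest.raises(ValueError, match="degenerate scatter"):
            sam_paired_d(np.array([1.0, 1.0, 1.0]), 0.0)


class TestPermutationFdr:
    def test_constant_zero_no_calls(self):
        bundle = bundle_from_array(np.zeros((10, 12)), scale="log2_centered")
        results = permutation_fdr(bundle, SamConfig(rng_seed=0))
        assert all(r.q_value == 1.0 for r in results)

    def test_planted_spike_attains_min_q(self):
        rng = np.random.default_rng(7)
        deltas = rng.normal(0, 1, (201, 6))
        deltas[0] += 10.0
        d, q = permutation_q_values(deltas, SamConfig(rng_seed=7))
        assert q[0] == min(q)
        assert abs(d[0]) == max(abs(d))

    def test_null_calibration_small(self):
        """Complete null: the fraction of q<0.1 calls stays at or below 0.1."""
        fracs = []
        for seed in range(5):
            deltas = np.random.default_rng(seed).normal(0, 1, (500, 6))
            _, q = permutation_q_values(deltas, SamConfig(rng_seed=seed))
            fracs.append((q < 0.1).mean())
        assert np.mean(fracs) <= 0.1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        deltas = rng.normal(0, 1, (50, 8))
        cfg = SamConfig(n_permutations=100, rng_seed=42)
        _, q1 = permutation_q_values(deltas, cfg)
        _, q2 = permutation_q_values(deltas, cfg)
        assert np.array_equal(q1, q2)

    def test_exhaustive_switch_logged(self, caplog):
        deltas = np.random.default_rng(0).normal(0, 1, (20, 4))
        with caplog.at_level("INFO"):
            permutation_q_values(deltas, SamConfig(n_permutations=1000))
        assert "exhaustive" in caplog.text

    def test_q_monotone_in_abs_d(self):
        deltas = np.random.default_rng(9).normal(0.2, 1, (100, 6))
        d, q = permutation_q_values(deltas, SamConfig(rng_seed=9))
        order = np.argsort(-np.abs(d))
        assert (np.diff(q[order]) >= 0).all()


class TestPercentOf:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (13, 581, 2.24),
            (48, 1297, 3.70),
            (0, 100, 0.00),
            (48841, 70320, 69.46),
            (48841, 77988, 62.63),
            (1, 8, 12.50),
        ],
    )
    def test_half_up_two_decimals(self, k, n, expected):
        assert percent_of(k, n) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent_of(1, 0)

    @given(st.integers(0, 10000), st.integers(1, 10000))
    @settings(max_examples=100, derandomize=True)
    def test_rounding_within_half_ulp(self, k, n):
        assert abs(percent_of(k, n) - 100 * k / n) <= 0.005 + 1e-9


def test_sam_s0_is_percentile_of_ses():
    rng = np.random.default_rng(0)
    deltas = rng.normal(0, 1, (100, 6))
    se = deltas.std(axis=1, ddof=1) / np.sqrt(6)
    assert sam_s0(deltas, 50.0) == pytest.approx(np.median(se))
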