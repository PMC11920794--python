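"""cis-DCO extraction, gamma fitting, bootstrap, and CoC behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meioscope import (
    bootstrap_shape,
    compare_distance_sets,
    compare_shape_distributions,
    compute_coc,
    extract_cis_dcos,
    fit_gamma,
    sample_expected_distances,
)


def _segments(states, bounds):
    """Segment table on one chromosome from states and (start, end) pairs."""
    return pd.DataFrame(
        {
            "individual": "i1",
            "chrom": "c1",
            "start": [b[0] for b in bounds],
            "end": [b[1] for b in bounds],
            "state": states,
            "n_markers": 50,
        }
    )


class TestCisDcoExtraction:
    def test_hand_computed_distance(self):
        segs = _segments(
            ["P1", "H", "P1"],
            [(0, 3_000_000), (3_000_000, 10_000_000), (10_000_000, 15_000_000)],
        )
        out = extract_cis_dcos(segs)
        assert len(out) == 1
        assert out["distance"].iloc[0] == pytest.approx(7_000_000)

    def test_mismatched_parentals_not_counted(self):
        segs = _segments(
            ["P1", "H", "P2"],
            [(0, 3_000_000), (3_000_000, 10_000_000), (10_000_000, 15_000_000)],
        )
        assert extract_cis_dcos(segs).empty

    def test_h_p_h_not_counted(self):
        segs = _segments(
            ["H", "P1", "H"],
            [(0, 3_000_000), (3_000_000, 10_000_000), (10_000_000, 15_000_000)],
        )
        assert extract_cis_dcos(segs).empty

    def test_single_segment(self):
        assert extract_cis_dcos(_segments(["P1"], [(0, 1_000_000)])).empty

    def test_five_segment_run_gives_two(self):
        bounds = [(k * 10, k * 10 + 10) for k in range(5)]
        segs = _segments(["P2", "H", "P2", "H", "P2"], bounds)
        assert len(extract_cis_dcos(segs)) == 2


class TestExpectedNull:
    def test_degenerate_midpoints_give_zero_distances(self, rng):
        with pytest.warns(UserWarning):
            out = sample_expected_distances(np.full(10, 5.0e6), 400, rng)
        assert out.size == 0

    def test_uniform_midpoints_triangular_mean(self):
        rng = np.random.default_rng(123)
        L = 30e6
        mids = rng.uniform(0, L, size=5_000)
        samples = [sample_expected_distances(mids, 400, rng).mean() for _ in range(100)]
        assert abs(np.mean(samples) - L / 3) / (L / 3) < 0.02

    def test_seed_determinism(self):
        mids = np.arange(100) * 1e5
        a = sample_expected_distances(mids, 400, np.random.default_rng(5))
        b = sample_expected_distances(mids, 400, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestGammaFit:
    def test_exponential_has_unit_shape(self):
        x = np.random.default_rng(1).exponential(2.0, size=10_000)
        fit = fit_gamma(x)
        assert abs(fit.shape - 1.0) < 0.05

    def test_parameter_recovery(self):
        x = np.random.default_rng(2).gamma(4.0, 0.5, size=10_000)  # rate 2
        fit = fit_gamma(x)
        assert 3.8 <= fit.shape <= 4.2
        assert 1.9 <= fit.rate <= 2.1

    def test_matches_scipy_mle(self):
        x = np.random.default_rng(3).gamma(2.5, 1.7, size=400)
        fit = fit_gamma(x)
        a_ref, _, scale_ref = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(a_ref, rel=1e-3)
        assert fit.rate == pytest.approx(1 / scale_ref, rel=1e-3)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_gamma(np.ones(9))

    def test_constant_sample_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            fit = fit_gamma(np.full(100, 3.0))
        assert fit.shape == 1e6

    def test_zeros_replaced(self):
        x = np.concatenate([np.zeros(5), np.random.default_rng(4).gamma(2, 1, 200)])
        fit = fit_gamma(x)
        assert np.isfinite(fit.loglik)


class TestBootstrap:
    def test_determinism_and_length(self):
        x = np.random.default_rng(5).gamma(4, 0.5, size=300)
        a = bootstrap_shape(x, iters=50, rng=np.random.default_rng(9))
        b = bootstrap_shape(x, iters=50, rng=np.random.default_rng(9))
        assert np.array_equal(a, b) and a.size == 50

    def test_consistency_with_point_estimate(self):
        x = np.random.default_rng(6).gamma(4, 0.5, size=500)
        boot = bootstrap_shape(x, iters=1000, rng=np.random.default_rng(7))
        assert abs(boot.mean() - fit_gamma(x).shape) / fit_gamma(x).shape < 0.10

    def test_single_iteration(self):
        x = np.random.default_rng(8).gamma(2, 1, size=100)
        assert bootstrap_shape(x, iters=1, rng=np.random.default_rng(0)).size == 1


class TestShapeComparison:
    def test_identical_constant_vectors(self):
        with pytest.warns(UserWarning):
            assert compare_shape_distributions(np.ones(10), np.ones(10)) == 1.0

    def test_separation(self):
        rng = np.random.default_rng(11)
        strong = bootstrap_shape(rng.gamma(5.0, 1.0, 500), iters=300, rng=rng)
        weak = bootstrap_shape(rng.exponential(1.0, 500), iters=300, rng=rng)
        assert compare_shape_distributions(strong, weak) < 0.001
        assert compare_shape_distributions(strong, weak, alternative="greater") < 0.001

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(2, 0.1, 200), rng.normal(2.05, 0.1, 200)
        assert compare_shape_distributions(a, b) == pytest.approx(
            compare_shape_distributions(b, a)
        )


class TestDistanceComparison:
    def test_identical_sets(self):
        x = np.arange(1.0, 50.0)
        assert compare_distance_sets(x, x) == pytest.approx(1.0, abs=0.05)

    def test_location_shift_detected(self):
        rng = np.random.default_rng(13)
        a = rng.gamma(3, 2e6, 100)
        assert compare_distance_sets(a, a + 5e6) < 0.01

    def test_single_observations_powerless(self):
        assert compare_distance_sets([1.0], [2.0]) == 1.0

    def test_paired_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_distance_sets([1, 2, 3], [1, 2], paired=True)

    def test_paired_shift_detected(self):
        rng = np.random.default_rng(14)
        a = rng.gamma(3, 1, 60)
        assert compare_distance_sets(a, a * 1.5, paired=True) < 0.01


class TestCoC:
    def test_observed_equals_expected_gives_unit_coc(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 20e6, 20_000)
        coc = compute_coc(x, x.copy())
        filled = coc.table.dropna(subset=["coc"])
        assert np.allclose(filled["coc"], 1.0)
        assert coc.mean_coc() == pytest.approx(1.0)

    def test_expected_rescaled_to_observed_total(self):
        rng = np.random.default_rng(16)
        coc = compute_coc(rng.uniform(0, 10e6, 500), rng.uniform(0, 10e6, 5_000))
        assert coc.table["expected"].sum() == pytest.approx(500)

    def test_empty_first_bin_gives_zero(self):
        obs = np.full(100, 5.0e6)
        exp = np.concatenate([np.full(50, 1.0e6), np.full(50, 5.0e6)])
        coc = compute_coc(obs, exp)
        assert coc.table["coc"].iloc[0] == 0.0

    def test_empty_observed_raises(self):
        with pytest.raises(ValueError):
            compute_coc(np.empty(0), np.ones(10))
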