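"""Statistical and structural properties of the meiosis simulator."""

import numpy as np
import pytest
from scipy import stats

from meioscope import (
    SimConfig,
    place_class1,
    place_class2,
    simulate_coverage,
    simulate_f2_population,
    simulate_seed_counts,
)
from meioscope.models import ChromosomeModel, SeedCounts
from meioscope.sim_meiosis import genotype_from_gametes, make_marker_map
from meioscope.ftl_rf import recombination_frequency

CHR20 = ChromosomeModel("c", 20_000_000, 10_000_000)


def _counts(chrom, mean, nu, n, seed):
    rng = np.random.default_rng(seed)
    return np.array([place_class1(chrom, mean, nu, rng).size for _ in range(n)])


class TestClass1Placement:
    def test_nu1_count_distribution_is_poisson(self):
        counts = _counts(CHR20, 2.0, 1.0, 10_000, 1)
        assert abs(counts.mean() - 2.0) < 0.06
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_nu1_positions_are_uniform(self):
        # a homogeneous Poisson process has i.i.d. uniform positions
        # conditional on the count
        rng = np.random.default_rng(2)
        pos = []
        while len(pos) < 10_000:
            pos.extend(place_class1(CHR20, 5.0, 1.0, rng))
        p = stats.kstest(np.array(pos[:10_000]) / CHR20.length, "uniform").pvalue
        assert p > 0.01

    def test_interference_underdisperses_counts(self):
        counts5 = _counts(CHR20, 2.0, 5.0, 10_000, 3)
        counts1 = _counts(CHR20, 2.0, 1.0, 10_000, 3)
        assert counts5.var() / counts5.mean() < 1.0
        # events are more evenly spread: larger nearest-neighbour distance
        rng5, rng1 = np.random.default_rng(4), np.random.default_rng(5)
        def mean_nn(nu, rng):
            nn = []
            for _ in range(2_000):
                pos = place_class1(CHR20, 2.0, nu, rng)
                if pos.size >= 2:
                    nn.extend(np.diff(pos))
            return np.mean(nn)
        assert mean_nn(5.0, rng5) > mean_nn(1.0, rng1)

    def test_dispersion_strictly_decreases_with_nu(self):
        ratios = []
        for nu in (1.0, 2.0, 5.0, 10.0):
            c = _counts(CHR20, 2.0, nu, 8_000, 6)
            ratios.append(c.var() / c.mean())
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    @pytest.mark.parametrize("nu", [0.5, 1.0, 5.0])
    def test_zero_mean_places_nothing(self, nu):
        rng = np.random.default_rng(7)
        for _ in range(50):
            assert place_class1(CHR20, 0.0, nu, rng).size == 0

    def test_positions_sorted_and_in_range(self):
        rng = np.random.default_rng(8)
        for nu in (0.7, 1.0, 3.0, 12.0):
            for _ in range(200):
                pos = place_class1(CHR20, 3.0, nu, rng)
                assert np.all(np.diff(pos) > 0)
                assert pos.size == 0 or (pos[0] >= 0 and pos[-1] < CHR20.length)

    def test_invalid_inputs_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            place_class1(CHR20, -1.0, 1.0, rng)
        with pytest.raises(ValueError):
            place_class1(CHR20, 1.0, 0.0, rng)


class TestClass2Placement:
    def test_terminal_confinement(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            pos = place_class2(CHR20, 4.0, rng, terminal_fraction=0.2)
            w = 0.1 * CHR20.length
            assert np.all((pos <= w) | (pos >= CHR20.length - w))

    def test_poisson_count(self):
        rng = np.random.default_rng(10)
        counts = np.array([place_class2(CHR20, 3.0, rng).size for _ in range(5_000)])
        assert abs(counts.mean() - 3.0) < 0.1


class TestF2Population:
    def test_forced_single_crossover_gives_one_transition(self):
        positions = np.arange(1, 20_000_000, 100_000)
        code = genotype_from_gametes(
            (np.array([10_000_000.0]), 0), (np.empty(0), 0), positions
        )
        changes = np.flatnonzero(np.diff(code))
        assert changes.size == 1
        assert positions[changes[0]] < 10_000_000 <= positions[changes[0] + 1]
        assert set(code) == {0, 1}  # P1 then H

    def test_expected_crossovers_per_individual(self):
        cfg = SimConfig(
            chromosomes=[CHR20], class1_mean=1.0, nu=1.0, class2_mean=1.0,
            geno_error_p=0.0, marker_spacing=100_000, seed=11,
        )
        _, record = simulate_f2_population(cfg, 500)
        per_ind = [
            sum(g.size for g in record.crossovers[(ind, "c")])
            for ind in record.individuals
        ]
        # two gametes x 2 bivalent COs x 1/2 chromatid transmission = 2
        assert abs(np.mean(per_ind) - 2.0) < 0.2

    def test_obligate_escape_yields_aneuploids(self):
        cfg = SimConfig(
            chromosomes=[CHR20], class1_mean=0.0, nu=1.0, class2_mean=0.0,
            obligate_escape_p=1.0, geno_error_p=0.0, marker_spacing=200_000, seed=12,
        )
        _, record = simulate_f2_population(cfg, 100)
        assert set(record.copy_number.values()) <= {1, 3}

    def test_no_escape_keeps_disomy(self, wt_population):
        _, _, record, _, _ = wt_population
        assert set(record.copy_number.values()) == {2}

    def test_seed_reproducibility(self):
        cfg = SimConfig(chromosomes=[CHR20], marker_spacing=100_000, seed=13)
        m1, r1 = simulate_f2_population(cfg, 20)
        m2, r2 = simulate_f2_population(cfg, 20)
        assert np.array_equal(m1.geno, m2.geno)
        assert np.array_equal(m1.qual, m2.qual)
        for key in r1.crossovers:
            for a, b in zip(r1.crossovers[key], r2.crossovers[key]):
                assert np.array_equal(a, b)

    def test_marker_map_spacing_and_order(self):
        rng = np.random.default_rng(14)
        markers = make_marker_map([CHR20], 50_000, rng)
        pos = markers["pos"].to_numpy()
        assert np.all(np.diff(pos) > 0)
        assert abs(np.diff(pos).mean() - 50_000) < 2_500
        assert np.diff(pos).max() < 2 * 50_000


class TestCoverage:
    def _record(self, copy):
        from meioscope.models import TrueMeiosisRecord

        return TrueMeiosisRecord(
            [CHR20], ["i1"], {("i1", "c"): [np.empty(0), np.empty(0)]}, {("i1", "c"): copy}
        )

    @pytest.mark.parametrize("copy,ratio", [(3, 1.5), (1, 0.5), (2, 1.0)])
    def test_noiseless_depth_matches_copy(self, copy, ratio):
        track = simulate_coverage(self._record(copy), base_depth=20.0, noise_sd=0.0)
        assert np.allclose(track["depth"], 20.0 * ratio)

    def test_windows_tile_chromosome(self):
        track = simulate_coverage(self._record(2), window_bp=100_000)
        assert track["start"].iloc[0] == 0
        assert track["end"].iloc[-1] == CHR20.length
        assert np.all(track["end"].to_numpy()[:-1] == track["start"].to_numpy()[1:])

    def test_mean_ratio_concentrates(self, rng):
        from meioscope.models import TrueMeiosisRecord

        inds = [f"i{k}" for k in range(200)]
        rec = TrueMeiosisRecord(
            [CHR20], inds,
            {(i, "c"): [np.empty(0), np.empty(0)] for i in inds},
            {(i, "c"): 2 for i in inds},
        )
        track = simulate_coverage(rec, base_depth=20.0, noise_sd=1.0, rng=rng)
        means = track.groupby("individual")["depth"].mean() / 20.0
        assert (np.abs(means - 1.0) < 0.05).mean() >= 0.99

    def test_bad_window_raises(self):
        with pytest.raises(ValueError):
            simulate_coverage(self._record(2), window_bp=0)


class TestSeedCounts:
    def test_zero_rf_gives_no_single_fluorescent(self, rng):
        for _ in range(20):
            c = simulate_seed_counts(0.0, 500, rng)
            assert c.n_green == 0 and c.n_red == 0

    def test_rf50_single_fraction(self, rng):
        c = simulate_seed_counts(50.0, 2_000_000, rng)
        assert abs((c.n_green + c.n_red) / c.n_total - 0.375) < 0.002

    def test_round_trip_at_subtelomeric_interval(self, rng):
        c = simulate_seed_counts(21.8, 4_000, rng)
        assert abs(recombination_frequency(c) - 21.8) < 1.0

    def test_invalid_rf_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_seed_counts(100.0, 100, rng)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(chromosomes=[CHR20], geno_error_p=1.5)
        with pytest.raises(ValueError):
            SimConfig(chromosomes=[CHR20], nu=0.0)

    def test_empty_marker_map_rejected(self):
        cfg = SimConfig(chromosomes=[CHR20], marker_spacing=100_000, seed=0)
        with pytest.raises(ValueError):
            simulate_f2_population(cfg, 0)
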