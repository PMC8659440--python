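"""Selector contracts: KS oracle equivalence, SPA projection oracle,
SFLA/VCPA/GA/IRIV behaviour and seed reproducibility."""

import numpy as np
import pytest

import teaspec as ts
from teaspec import selection as sel
from teaspec.synthetic import make_planted_spectra


def brute_force_kennard_stone(X, n_cal):
    """Independent max-min implementation using explicit pairwise loops."""
    X = np.asarray(X, float)
    n = len(X)
    d = np.array([[np.linalg.norm(X[i] - X[j]) for j in range(n)]
                  for i in range(n)])
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] > best[0]:
                best = (d[i, j], (i, j))
    picked = list(best[1])
    while len(picked) < n_cal:
        cand_best = (-1.0, None)
        for i in range(n):
            if i in picked:
                continue
            dmin = min(d[i, p] for p in picked)
            if dmin > cand_best[0]:
                cand_best = (dmin, i)
        picked.append(cand_best[1])
    return np.sort(picked)


class TestKennardStone:
    def test_collinear_points_pick_extremes(self):
        X = np.arange(10.0)[:, None]
        split = sel.kennard_stone(X, 0.4)
        assert {0, 9} <= set(split.calibration.tolist())

    def test_all_calibration_rejected(self):
        X = np.arange(10.0)[:, None]
        with pytest.raises(ts.ParameterError):
            sel.kennard_stone(X, 0.99)

    @pytest.mark.parametrize("n, frac", [(6, 0.5), (8, 0.75), (10, 0.6)])
    def test_matches_bruteforce_oracle(self, n, frac, rng):
        X = rng.normal(size=(n, 4))
        split = sel.kennard_stone(X, frac)
        oracle = brute_force_kennard_stone(X, int(round(frac * n)))
        np.testing.assert_array_equal(split.calibration, oracle)

    def test_partition_is_disjoint_and_complete(self, rng):
        X = rng.normal(size=(40, 5))
        split = sel.kennard_stone(X, 0.75)
        assert len(split.calibration) == 30
        union = np.union1d(split.calibration, split.prediction)
        np.testing.assert_array_equal(union, np.arange(40))


class TestSubsetFitness:
    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(30, 12))
        y = X[:, 2] - X[:, 7] + rng.normal(0, 0.1, 30)
        f1 = sel.SubsetFitness(X, y, seed=3)
        f2 = sel.SubsetFitness(X, y, seed=3)
        assert f1([1, 2, 7]) == f2([2, 7, 1])

    def test_informative_subset_scores_better(self, rng):
        X = rng.normal(size=(40, 12))
        y = X[:, 2] - X[:, 7] + rng.normal(0, 0.05, 40)
        f = sel.SubsetFitness(X, y, seed=0)
        assert f([2, 7]) < f([0, 1])

    def test_empty_subset_rejected(self, rng):
        f = sel.SubsetFitness(rng.normal(size=(20, 5)), rng.normal(size=20))
        with pytest.raises(ts.ParameterError):
            f([])


class TestSpa:
    def test_stepwise_argmax_matches_explicit_projections(self, rng):
        """Each greedy pick equals the argmax over explicitly computed
        orthogonal-complement projection norms on an 8x6 matrix."""
        X = rng.normal(size=(8, 6))
        for start in range(6):
            chain = sel.spa_chain(X, start, 4)
            for step in range(1, len(chain)):
                sub = chain[:step]
                Q, _ = np.linalg.qr(X[:, sub])
                norms = []
                for j in range(6):
                    if j in sub:
                        norms.append(-1.0)
                    else:
                        r = X[:, j] - Q @ (Q.T @ X[:, j])
                        norms.append(float(r @ r))
                assert chain[step] == int(np.argmax(norms))

    def test_recovers_columns_that_generate_response(self, rng):
        X = rng.normal(size=(40, 8))
        y = X[:, 2] - X[:, 5]
        result = sel.spa_select(X, y, kmin=1, kmax=5, seed=0)
        assert {2, 5} <= set(result.indices.tolist())
        assert result.fitness < 1e-8

    def test_duplicate_column_never_coselected(self, rng):
        X = rng.normal(size=(30, 6))
        X[:, 4] = X[:, 1]
        for start in range(6):
            chain = sel.spa_chain(X, start, 6)
            assert not ({1, 4} <= set(chain))

    def test_invalid_lengths_rejected(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        with pytest.raises(ts.ParameterError):
            sel.spa_select(X, y, kmin=5, kmax=3)


class TestSfla:
    @pytest.fixture()
    def planted(self):
        X, y = make_planted_spectra(80, 40, [5, 20, 33], seed=11)
        return X, y

    def test_seed_reproducibility(self, planted):
        X, y = planted
        kw = dict(memeplexes=3, frogs_per=4, iterations=8, seed=5)
        r1 = sel.sfla_select(X, y, **kw)
        r2 = sel.sfla_select(X, y, **kw)
        np.testing.assert_array_equal(r1.indices, r2.indices)
        assert r1.fitness_trace == r2.fitness_trace

    def test_trace_non_increasing(self, planted):
        X, y = planted
        r = sel.sfla_select(X, y, memeplexes=3, frogs_per=4, iterations=10,
                            seed=2)
        assert np.all(np.diff(r.fitness_trace) <= 0)

    def test_reported_fitness_reproducible(self, planted):
        X, y = planted
        r = sel.sfla_select(X, y, memeplexes=3, frogs_per=4, iterations=8,
                            seed=1)
        f = sel.SubsetFitness(X, y, folds=5, seed=1)
        assert f(r.indices) == pytest.approx(r.fitness)

    def test_population_too_small_rejected(self, planted):
        X, y = planted
        with pytest.raises(ts.ParameterError):
            sel.sfla_select(X, y, memeplexes=1, frogs_per=2)


class TestVcpa:
    def test_edf_schedule_closed_form(self):
        sched = sel.edf_schedule(100, 10, 10)
        expected = np.round(100 * 0.1 ** (np.arange(1, 11) / 10)).astype(int)
        np.testing.assert_array_equal(sched, expected)
        assert np.all(np.diff(sched) <= 0)
        assert sched[-1] == 10

    def test_bms_inclusion_frequency_near_half(self, rng):
        X, y = make_planted_spectra(60, 30, [3, 15], seed=0)
        n_bms = 400
        rng2 = np.random.default_rng(0)
        M = rng2.random((n_bms, 30)) < 0.5
        freq = M.mean(axis=0)
        sigma = np.sqrt(0.25 / n_bms)
        assert np.all(np.abs(freq - 0.5) < 3 * sigma + 0.02)

    def test_survivors_and_best_subset(self):
        X, y = make_planted_spectra(80, 40, [5, 20, 33], seed=3)
        r = sel.vcpa_select(X, y, n_bms=80, edf_loops=4, final_size=10, seed=3)
        assert r.survivors is not None and r.survivors.size == 10
        assert set(r.indices.tolist()) <= set(range(40))
        f = sel.SubsetFitness(X, y, seed=3)
        assert f(r.indices) == pytest.approx(r.fitness)

    def test_final_size_must_shrink(self):
        X, y = make_planted_spectra(40, 20, [3], seed=0)
        with pytest.raises(ts.ParameterError):
            sel.vcpa_select(X, y, final_size=20)


class TestRefinement:
    @pytest.fixture()
    def survivors_setup(self):
        X, y = make_planted_spectra(80, 30, [4, 12, 25], seed=9)
        fit = sel.SubsetFitness(X, y, seed=9)
        survivors = np.array([1, 4, 7, 12, 18, 25, 28])
        return X, y, fit, survivors

    def test_ga_fixed_point_without_variation(self, survivors_setup):
        """With no crossover or mutation and identical chromosomes, GA
        returns exactly the starting subset."""
        X, y, fit, survivors = survivors_setup
        chrom = np.zeros(survivors.size, bool)
        chrom[[0, 2, 5]] = True
        r = sel.refine_subset(X, y, survivors, "GA", fit,
                              {"generations": 5, "crossover": 0.0,
                               "mutation": 0.0, "initial": [chrom] * 6},
                              seed=0)
        np.testing.assert_array_equal(r.indices,
                                      np.sort(survivors[[0, 2, 5]]))

    def test_iriv_drops_harmful_collinear_band(self):
        """A band that duplicates an informative band plus strong noise is
        classified as interfering and eliminated in the first round."""
        drops = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 60
            X = rng.normal(size=(n, 8))
            y = X[:, 0] + X[:, 3] + rng.normal(0, 0.05, n)
            X[:, 6] = y + rng.normal(0, 3.0, n)   # noisy y-proxy: harmful
            fit = sel.SubsetFitness(X, y, seed=seed)
            r = sel.refine_subset(X, y, np.arange(8), "IRIV", fit,
                                  {"n_draws": 80, "max_rounds": 4}, seed=seed)
            drops += 6 not in r.indices
        assert drops >= 9

    def test_refined_fitness_not_worse_than_pool(self, survivors_setup):
        X, y, fit, survivors = survivors_setup
        full = fit(survivors)
        for mode, params in [("GA", {"population": 10, "generations": 10}),
                             ("IRIV", {"n_draws": 60, "max_rounds": 3})]:
            r = sel.refine_subset(X, y, survivors, mode, fit, params, seed=1)
            assert r.fitness <= full + 1e-12

    def test_empty_survivors_rejected(self, survivors_setup):
        X, y, fit, _ = survivors_setup
        with pytest.raises(ts.ParameterError):
            sel.refine_subset(X, y, np.array([], int), "GA", fit, {}, seed=0)


class TestSelectionResult:
    def test_json_round_trip(self, tmp_path, small_grid):
        r = sel.SelectionResult("SPA", np.array([3, 1, 5]),
                                small_grid.wavelengths_nm[[1, 3, 5]], 0.25,
                                [0.4, 0.3, 0.25], n_bands_total=80)
        p = tmp_path / "sel.json"
        r.to_json(p)
        back = sel.SelectionResult.from_json(p)
        np.testing.assert_array_equal(back.indices, [1, 3, 5])
        assert back.fitness == 0.25
        assert back.data_reduction_ratio == pytest.approx(1 - 3 / 80)
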