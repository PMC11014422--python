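import numpy as np
import pytest

from divsel.simulator import (
    DrawnParams,
    FixedParams,
    PopulationPair,
    _apply_breakpoints,
    fitness_vector,
    found_populations,
    migrate_swap,
    migration_generation,
    migration_times,
    recombine_offspring,
    reproduction_probabilities,
    run_simulation,
    sample_crossover_count,
    sample_crossovers,
    selection_generation,
)


class TestFixedParams:
    @pytest.mark.parametrize(
        "t_star,n_cycles,expected",
        [(5, 4, 19), (50, 4, 199), (50, 2, 99)],
    )
    def test_t_final(self, t_star, n_cycles, expected):
        fixed = FixedParams(
            r=3e-4, t_star=t_star, n_cycles=n_cycles, Ne=100, L=100, snp_spacing=165
        )
        assert fixed.t_final == expected

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(r=0.0),
            dict(r=1.0),
            dict(t_star=1),
            dict(n_cycles=0),
            dict(Ne=1),
            dict(L=1),
            dict(snp_spacing=0),
        ],
    )
    def test_invalid(self, kwargs):
        base = dict(r=3e-4, t_star=5, n_cycles=4, Ne=100, L=100, snp_spacing=165)
        base.update(kwargs)
        with pytest.raises(ValueError):
            FixedParams(**base)

    @pytest.mark.parametrize(
        "L,r,expected",
        [(100, 3.0e-4, 4.9497), (1500, 2.0e-5, 4.94998)],
    )
    def test_expected_crossovers(self, L, r, expected):
        fixed = FixedParams(r=r, t_star=5, n_cycles=4, Ne=100, L=L, snp_spacing=165)
        assert fixed.expected_crossovers == pytest.approx(expected, abs=1e-10)
        assert round(fixed.expected_crossovers, 2) == 4.95


class TestDrawnParams:
    def test_defaults_are_neutral(self):
        drawn = DrawnParams()
        assert drawn.n_selected == 0 and drawn.m == 0.0

    def test_alleles_default_to_one(self):
        drawn = DrawnParams(sel_loci=(3, 7), sel_coeffs=(0.1, -0.2))
        assert drawn.sel_alleles == (1, 1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sel_loci=(1, 1), sel_coeffs=(0.1, 0.1)),
            dict(sel_loci=(0,), sel_coeffs=(0.1,)),
            dict(sel_loci=(1,), sel_coeffs=()),
            dict(m=1.0),
            dict(m=-0.1),
            dict(sex=2),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            DrawnParams(**kwargs)


class TestCrossovers:
    def test_crossover_count_mean(self, rng):
        # Monte-Carlo mean of the binomial count within 3 SE of 4.95
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=100, L=100, snp_spacing=165)
        n = 20_000
        draws = np.array([sample_crossover_count(fixed, rng) for _ in range(n)])
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - 4.9497) < 3 * se

    def test_breakpoints_sorted_unique_in_range(self, rng):
        fixed = FixedParams(r=0.01, t_star=5, n_cycles=4, Ne=100, L=20, snp_spacing=10)
        for _ in range(200):
            bps = sample_crossovers(fixed, rng)
            assert np.all(np.diff(bps) > 0)
            if bps.size:
                assert bps.min() >= 1 and bps.max() <= fixed.L - 1

    def test_tiny_r_gives_empty_list(self, tiny_r_fixed, rng):
        for _ in range(50):
            assert sample_crossovers(tiny_r_fixed, rng).size == 0


class TestRecombination:
    def test_alternation_rule(self):
        p1 = np.zeros(6, dtype=np.uint8)
        p2 = np.ones(6, dtype=np.uint8)
        # single breakpoint after SNP 3 (1-based) -> 000111
        out = _apply_breakpoints(p1, p2, [3])
        assert out.tolist() == [0, 0, 0, 1, 1, 1]

    def test_double_breakpoint_alternates_back(self):
        p1 = np.zeros(6, dtype=np.uint8)
        p2 = np.ones(6, dtype=np.uint8)
        out = _apply_breakpoints(p1, p2, [2, 4])
        assert out.tolist() == [0, 0, 1, 1, 0, 0]

    def test_identical_parents(self, rng):
        p = rng.integers(0, 2, size=10).astype(np.uint8)
        out = recombine_offspring(p, p, [3, 7], rng)
        np.testing.assert_array_equal(out, p)

    def test_breakpoint_out_of_range(self):
        p = np.zeros(6, dtype=np.uint8)
        with pytest.raises(ValueError):
            _apply_breakpoints(p, p, [6])
        with pytest.raises(ValueError):
            _apply_breakpoints(p, p, [0])

    def test_empty_breakpoints_swap_frequency(self, rng):
        # offspring equals p1 or p2 with probability ~0.5 each
        p1 = np.zeros(4, dtype=np.uint8)
        p2 = np.ones(4, dtype=np.uint8)
        hits = sum(
            recombine_offspring(p1, p2, [], rng)[0] == 0 for _ in range(2000)
        )
        assert abs(hits / 2000 - 0.5) < 3 * 0.5 / np.sqrt(2000)

    def test_offspring_alleles_come_from_parents(self, rng):
        p1 = rng.integers(0, 2, size=12).astype(np.uint8)
        p2 = rng.integers(0, 2, size=12).astype(np.uint8)
        out = recombine_offspring(p1, p2, [4, 9], rng)
        assert np.all((out == p1) | (out == p2))


class TestFounding:
    def test_shape_and_binary(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng)
        assert pair.X.shape == pair.Y.shape == (small_fixed.Ne, small_fixed.L)
        assert set(np.unique(pair.X)) <= {0, 1}
        assert pair.t == 0

    def test_tiny_r_rows_constant(self, tiny_r_fixed, rng):
        pair = found_populations(tiny_r_fixed, rng)
        for M in (pair.X, pair.Y):
            assert np.all((M.min(axis=1) == M.max(axis=1)))

    def test_mean_frequency_half(self, rng):
        # symmetry of the uniform founding allele draw -> E[p] = 0.5
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=400, L=40, snp_spacing=165)
        n_rep = 200
        freqs = np.empty(n_rep)
        for i in range(n_rep):
            pair = found_populations(fixed, rng)
            freqs[i] = pair.X.mean()
        se = freqs.std(ddof=1) / np.sqrt(n_rep)
        assert abs(freqs.mean() - 0.5) < 3 * se

    def test_shared_ancestry_variant(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng, shared_ancestry=True)
        assert pair.X.shape == (small_fixed.Ne, small_fixed.L)


class TestFitness:
    def test_single_locus(self):
        pop = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        drawn = DrawnParams(sel_loci=(1,), sel_coeffs=(0.25,))
        np.testing.assert_allclose(
            fitness_vector(pop, drawn, "X"), [1.25, 1.0]
        )

    def test_two_loci_additive(self):
        pop = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        drawn = DrawnParams(sel_loci=(1, 2), sel_coeffs=(-0.025, -0.025))
        # (1 - 0.025) + (1 - 0.025) = 1.95 for the double carrier
        np.testing.assert_allclose(fitness_vector(pop, drawn, "X"), [1.95, 2.0])

    def test_population_y_neutral(self, rng):
        pop = rng.integers(0, 2, size=(20, 5)).astype(np.uint8)
        drawn = DrawnParams(sel_loci=(2, 4), sel_coeffs=(0.2, -0.2))
        omega = fitness_vector(pop, drawn, "Y")
        assert np.all(omega == omega[0])

    def test_empty_sum_convention(self, rng):
        pop = rng.integers(0, 2, size=(10, 4)).astype(np.uint8)
        omega = fitness_vector(pop, DrawnParams(), "X")
        np.testing.assert_allclose(omega, 1.0)

    def test_selected_allele_zero(self):
        pop = np.array([[0], [1]], dtype=np.uint8)
        drawn = DrawnParams(sel_loci=(1,), sel_coeffs=(0.1,), sel_alleles=(0,))
        np.testing.assert_allclose(fitness_vector(pop, drawn, "X"), [1.1, 1.0])


class TestSelectionGeneration:
    def test_probabilities_hand_computed(self):
        # Ne=2 with fitnesses (1.25, 1.0) -> p = (5/9, 4/9)
        np.testing.assert_allclose(
            reproduction_probabilities(np.array([1.25, 1.0])), [5 / 9, 4 / 9]
        )

    def test_probabilities_sum_to_one(self, rng):
        omega = rng.uniform(0.5, 2.0, size=100)
        assert reproduction_probabilities(omega).sum() == pytest.approx(1.0, abs=1e-12)

    def test_output_shape_and_source(self, small_fixed, rng):
        pop = rng.integers(0, 2, size=(small_fixed.Ne, small_fixed.L)).astype(np.uint8)
        drawn = DrawnParams(sel_loci=(3,), sel_coeffs=(0.25,))
        nxt = selection_generation(pop, drawn, "X", small_fixed, rng)
        assert nxt.shape == pop.shape
        # every offspring row is a copy of some parent row
        parents = {r.tobytes() for r in pop}
        assert all(r.tobytes() in parents for r in nxt)

    def test_neutral_resampling_is_unbiased(self, rng):
        # martingale property of multinomial resampling without selection
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=100, L=4, snp_spacing=165)
        pop = (rng.random((fixed.Ne, fixed.L)) < 0.3).astype(np.uint8)
        p_parent = pop.mean()
        n_rep = 600
        means = np.array(
            [
                selection_generation(pop, DrawnParams(), "X", fixed, rng).mean()
                for _ in range(n_rep)
            ]
        )
        se = means.std(ddof=1) / np.sqrt(n_rep)
        assert abs(means.mean() - p_parent) < 3 * se


class TestMigration:
    def test_swap_count(self, rng):
        Ne, L = 40, 6
        pair = PopulationPair(
            X=np.zeros((Ne, L), dtype=np.uint8),
            Y=np.ones((Ne, L), dtype=np.uint8),
            t=4,
        )
        X, Y = migrate_swap(pair, 0.5, rng)
        assert int(X.sum(axis=1).astype(bool).sum()) == round(Ne / 2)
        assert int((~Y.sum(axis=1).astype(bool)).sum()) == round(Ne / 2)

    def test_m_zero_no_swap(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng)
        X, Y = migrate_swap(pair, 0.0, rng)
        np.testing.assert_array_equal(X, pair.X)
        np.testing.assert_array_equal(Y, pair.Y)

    def test_asexual_reproduction_copies_rows(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng)
        drawn = DrawnParams(m=0.2, sex=0)
        nxt = migration_generation(pair, drawn, small_fixed, rng)
        assert nxt.t == pair.t + 1
        pool = {r.tobytes() for r in np.vstack([pair.X, pair.Y])}
        assert all(r.tobytes() in pool for r in nxt.X)

    def test_sexual_reproduction_shapes(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng)
        nxt = migration_generation(pair, DrawnParams(m=0.2, sex=1), small_fixed, rng)
        assert nxt.X.shape == pair.X.shape
        assert set(np.unique(nxt.X)) <= {0, 1}

    def test_m_too_large(self, small_fixed, rng):
        pair = found_populations(small_fixed, rng)
        with pytest.raises(ValueError):
            migrate_swap(pair, 0.999, rng)  # round(Ne*m) == Ne


class TestRunSimulation:
    def test_migration_schedule(self):
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=10, L=4, snp_spacing=165)
        assert migration_times(fixed) == [5, 10, 15]
        fixed2 = FixedParams(r=3e-4, t_star=50, n_cycles=2, Ne=10, L=4, snp_spacing=165)
        assert migration_times(fixed2) == [50]

    def test_halts_at_t_final(self, small_fixed, rng):
        pair = run_simulation(small_fixed, DrawnParams(), rng)
        assert pair.t == small_fixed.t_final == 19

    def test_generation_callback_sees_every_step(self, small_fixed, rng):
        seen = []
        run_simulation(small_fixed, DrawnParams(), rng, on_generation=lambda p: seen.append(p.t))
        assert seen == list(range(small_fixed.t_final + 1))

    def test_entries_stay_binary(self, small_fixed, rng):
        drawn = DrawnParams(sel_loci=(5,), sel_coeffs=(0.25,), m=0.2, sex=1)
        pair = run_simulation(small_fixed, drawn, rng)
        assert set(np.unique(pair.X)) <= {0, 1}
        assert set(np.unique(pair.Y)) <= {0, 1}

    def test_neutral_drift_preserves_mean(self, rng):
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=100, L=6, snp_spacing=165)
        n_rep = 200
        means = np.array(
            [run_simulation(fixed, DrawnParams(), rng).X.mean() for _ in range(n_rep)]
        )
        se = means.std(ddof=1) / np.sqrt(n_rep)
        assert abs(means.mean() - 0.5) < 3 * se

    def test_sel_locus_out_of_range(self, small_fixed, rng):
        drawn = DrawnParams(sel_loci=(small_fixed.L + 1,), sel_coeffs=(0.1,))
        with pytest.raises(ValueError):
            run_simulation(small_fixed, drawn, rng)

    def test_strong_selection_raises_frequency(self, rng):
        fixed = FixedParams(r=3e-4, t_star=5, n_cycles=4, Ne=300, L=3, snp_spacing=165)
        drawn = DrawnParams(sel_loci=(2,), sel_coeffs=(0.25,))
        final = run_simulation(fixed, drawn, rng)
        pX = final.X[:, 1].mean()
        pY = final.Y[:, 1].mean()
        assert pX > pY  # selection acts only in X
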