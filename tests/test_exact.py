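"""Phase-type IICR computation: generators, survival/density, closed forms."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from iicr import (
    SamplingScheme,
    add_population_split,
    beta_asymptote,
    build_pair_generator,
    exact_iicr,
    make_asymmetric_model,
    make_continent_island,
    make_custom_model,
    make_n_island,
    make_stepping_stone,
    nei_takahata_ne,
    nisland_iicr_closed_form,
    small_m_plateau,
    survival_and_density,
    survival_function,
)
from iicr.demography import Epoch
from iicr.exact import PairStateSpace, UnreachableCoalescenceError, alpha_companion


class TestPairGenerator:
    def test_state_count(self):
        for n in (1, 2, 5):
            space = PairStateSpace(n)
            assert space.n_states == n * (n + 1) // 2 + 1

    def test_two_island_rates(self):
        gen = build_pair_generator(make_n_island(2, 1).epochs[0])
        space = gen.space
        both0 = space.index(0, 0)
        apart = space.index(0, 1)
        assert gen.Q[both0, space.absorbing] == 1.0
        # two lineages each migrating at M/2 = 0.5
        assert gen.Q[both0, apart] == 1.0
        assert gen.Q[both0, both0] == -2.0

    def test_single_deme(self):
        gen = build_pair_generator(make_n_island(1, 0).epochs[0])
        assert gen.Q.shape == (2, 2)
        assert gen.Q[0, 1] == 1.0

    def test_deme_size_sets_coalescence_rate(self):
        gen = build_pair_generator(make_continent_island(10, 1.0).epochs[0])
        space = gen.space
        assert gen.Q[space.index(0, 0), space.absorbing] == pytest.approx(0.1)
        assert gen.Q[space.index(1, 1), space.absorbing] == 1.0

    @settings(deadline=None, max_examples=30)
    @given(
        n=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_rows_sum_to_zero_on_random_epochs(self, n, seed):
        rng = np.random.default_rng(seed)
        model = make_asymmetric_model(
            rng.uniform(0, 3, (n, n)), sizes=rng.uniform(0.2, 4, n)
        )
        gen = build_pair_generator(model.epochs[0])
        assert np.allclose(gen.Q.sum(axis=1), 0.0, atol=1e-12)
        off = gen.Q[~np.eye(gen.Q.shape[0], dtype=bool)]
        assert np.all(off >= 0)
        assert np.all(gen.Q[-1] == 0)


class TestSurvivalDensity:
    def test_panmictic_exponential(self, same_deme):
        model = make_n_island(1, 0)
        t = np.array([0.0, 0.5, 2.0])
        S, f = survival_and_density(model, same_deme, t)
        assert np.allclose(S, np.exp(-t), atol=1e-12)
        assert np.allclose(f, np.exp(-t), atol=1e-12)

    def test_instantaneous_rates_at_zero(self):
        model = make_continent_island(10, 1.0)
        S, f = survival_and_density(model, SamplingScheme(0, 0), 0.0)
        assert S == 1.0 and f == pytest.approx(0.1)  # 1/s of the continent
        S, f = survival_and_density(model, SamplingScheme(1, 1), 0.0)
        assert f == pytest.approx(1.0)
        _, f = survival_and_density(model, SamplingScheme(0, 1), 0.0)
        assert f == 0.0

    def test_two_island_matches_lumped_chain_oracle(self, same_deme):
        # independent oracle: expm of the 2-state lumped (same, different)
        # chain assembled by hand, not via the pair-state machinery
        n, M = 2, 1.0
        lumped = np.array([[-(1 + M), M], [M / (n - 1), -M / (n - 1)]])
        for t in (0.3, 1.0, 2.5):
            p = scipy.linalg.expm(lumped * t)[0]
            S_o, f_o = p.sum(), p[0]
            S, f = survival_and_density(make_n_island(n, M), same_deme, t)
            assert S == pytest.approx(S_o, rel=1e-12)
            assert f == pytest.approx(f_o, rel=1e-12)

    def test_survival_monotone_density_nonneg(self, diff_deme):
        model = make_stepping_stone((4,), 0.5)
        t = np.geomspace(1e-3, 50, 200)
        S, f = survival_and_density(model, diff_deme, t)
        assert np.all(np.diff(S) <= 1e-14)
        assert np.all(f >= 0)

    def test_density_integrates_to_one(self, same_deme):
        # total absorbed mass: 1 - S(T) -> 1 for irreducible models
        model = make_asymmetric_model([[0, 1.0], [0.1, 0]])
        S = survival_function(model, same_deme)
        assert S(np.array([3000.0]))[0] < 1e-8

    def test_unreachable_coalescence_raises(self):
        isolated = make_asymmetric_model([[0, 0.0], [0.0, 0]])
        with pytest.raises(UnreachableCoalescenceError):
            survival_and_density(isolated, SamplingScheme(0, 1), 1.0)
        # opt-in: survival never decays, density identically zero
        S, f = survival_and_density(
            isolated, SamplingScheme(0, 1), np.array([1.0, 10.0]),
            allow_infinite=True,
        )
        assert np.all(S == 1.0) and np.all(f == 0.0)


class TestExactIICR:
    def test_panmictic_constant(self, same_deme, log_grid):
        curve = exact_iicr(make_n_island(1, 0), same_deme, log_grid)
        assert np.allclose(curve.values, 1.0, atol=1e-12)
        assert curve.provenance == "exact"

    def test_recent_limit_is_local_deme_size(self, same_deme):
        grid = np.concatenate([[0.0], np.geomspace(1e-8, 1e-4, 5)])
        curve = exact_iicr(make_n_island(10, 0.1), same_deme, grid)
        assert curve.values[0] == 1.0
        assert np.allclose(curve.values[1:], 1.0, atol=1e-3)
        big = exact_iicr(make_continent_island(10, 1.0), SamplingScheme(0, 0),
                         np.array([0.0]))
        assert big.values[0] == 10.0

    def test_ancient_plateau_is_inverse_beta(self, same_deme):
        curve = exact_iicr(make_n_island(10, 0.1), same_deme, np.array([200.0]))
        assert curve.values[0] == pytest.approx(1 / beta_asymptote(10, 0.1),
                                                rel=1e-9)

    def test_different_deme_diverges_at_origin(self, diff_deme):
        grid = np.array([1e-8, 1e-6, 1e-4, 1e-2])
        curve = exact_iicr(make_n_island(5, 1.0), diff_deme, grid)
        assert np.all(np.diff(curve.values) < 0)  # grows toward t -> 0+
        assert curve.values[0] > 1e3
        at_zero = exact_iicr(make_n_island(5, 1.0), diff_deme,
                             np.array([0.0, 1.0]))
        assert np.isinf(at_zero.values[0])

    def test_time_shift_invariance_of_stationary_models(self, same_deme):
        """Duplicating a homogeneous epoch at t0 (a past sampling origin)
        leaves the curve unchanged."""
        base = make_n_island(3, 0.5)
        e = base.epochs[0]
        shifted = make_custom_model(
            [e, Epoch(0.7, e.deme_sizes, e.migration)]
        )
        grid = np.geomspace(1e-2, 50, 40)
        a = exact_iicr(base, same_deme, grid).values
        b = exact_iicr(shifted, same_deme, grid).values
        assert np.allclose(a, b, rtol=1e-10)


class TestClosedForm:
    @pytest.mark.parametrize("scheme", ["same", "different"])
    def test_matches_matrix_exponential(self, scheme, log_grid):
        model = make_n_island(4, 0.5)
        sampling = SamplingScheme(0, 0) if scheme == "same" else SamplingScheme(0, 1)
        a = exact_iicr(model, sampling, log_grid).values
        b = nisland_iicr_closed_form(4, 0.5, scheme, log_grid).values
        assert np.all(np.abs(a / b - 1) < 1e-10)

    def test_large_t_limit_is_inverse_beta(self):
        for n, M in [(2, 1.0), (10, 0.1), (5, 10.0)]:
            v = nisland_iicr_closed_form(n, M, "same", np.array([500 / M]))
            assert v.values[-1] == pytest.approx(1 / beta_asymptote(n, M), rel=1e-6)

    def test_same_deme_value_at_zero(self):
        v = nisland_iicr_closed_form(3, 1.0, "same", np.array([0.0, 1.0]))
        assert v.values[0] == 1.0

    def test_rejects_degenerate_parameters(self):
        with pytest.raises(ValueError):
            nisland_iicr_closed_form(1, 1.0, "same", np.array([1.0]))


class TestPrintedQuantities:
    def test_beta_values(self):
        assert beta_asymptote(2, 1) == pytest.approx(0.3819660112501051, abs=1e-12)
        assert beta_asymptote(10, 0.1) == pytest.approx(0.010091657394063258,
                                                        abs=1e-12)
        # M -> inf: beta -> 1/n, so the plateau N/beta -> nN
        assert beta_asymptote(2, 1e6) == pytest.approx(0.5, abs=1e-5)

    def test_beta_is_smallest_eigenvalue_of_lumped_chain(self):
        n, M = 10, 0.1
        lumped = np.array([[-(1 + M), M], [M / (n - 1), -M / (n - 1)]])
        eig = np.sort(np.abs(np.linalg.eigvals(lumped)))
        assert beta_asymptote(n, M) == pytest.approx(eig[0], rel=1e-12)
        assert alpha_companion(n, M) == pytest.approx(eig[1], rel=1e-12)

    def test_nei_takahata(self):
        assert nei_takahata_ne(2, 1, 1) == 2.5
        assert nei_takahata_ne(10, 1000, 0.1) == pytest.approx(91_000)
        assert nei_takahata_ne(5, 1, 1e6) == pytest.approx(5.0, rel=1e-5)
        with pytest.raises(ValueError):
            nei_takahata_ne(2, 1, 0)

    def test_small_m_plateau(self):
        assert small_m_plateau(10, 1000, 0.1) == 90_000
        assert small_m_plateau(2, 1, 1) == 1
        # ratio to the exact plateau N/beta approaches 1 as M -> 0
        ratio = small_m_plateau(10, 1000, 1e-4) / (1000 / beta_asymptote(10, 1e-4))
        assert abs(ratio - 1) < 0.01
        with pytest.raises(ValueError):
            small_m_plateau(2, 1, 0)


class TestSplitModels:
    def test_recent_past_identical_to_island_model(self, split_model_fig_two_island,
                                                   same_deme):
        grid = np.geomspace(1e-3, 1.99, 48)
        a = exact_iicr(split_model_fig_two_island, same_deme, grid).values
        b = nisland_iicr_closed_form(2, 1, "same", grid).values
        assert np.all(np.abs(a / b - 1) < 1e-10)

    def test_ancient_plateau_is_ancestral_size(self, split_model_fig_two_island,
                                               same_deme):
        curve = exact_iicr(split_model_fig_two_island, same_deme,
                           np.array([20.0, 50.0]))
        assert np.allclose(curve.values, 2.0, rtol=1e-10)

    def test_degenerate_split_collapses_to_panmixia(self, same_deme):
        model = add_population_split(make_n_island(2, 1), 1e-9, [0, 1],
                                     ancestral_size=1.0)
        grid = np.geomspace(1e-6, 10, 30)
        curve = exact_iicr(model, same_deme, grid)
        assert np.allclose(curve.values, 1.0, atol=1e-8)
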