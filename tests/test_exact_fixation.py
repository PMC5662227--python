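"""Auxiliary-root solver, fixation formulas and closed-form limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemoran import (
    ModelParameters,
    ParameterError,
    closed_form_decoupled,
    closed_form_hierarchical,
    closed_form_negligible_dc,
    fixation_from_counts,
    fixation_summary,
    solve_auxiliary_roots,
    success_by_time,
)
from stemoran.markov_oracle import absorption_probability


class TestAuxiliaryRoots:
    def test_decoupled_limit_recovers_rate_ratios(self):
        p = ModelParameters(n_stem=10, n_diff=10, r2=2.0, rt2=2.0)
        roots = solve_auxiliary_roots(p)
        assert roots.z_s == pytest.approx(0.5, abs=1e-12)
        assert roots.z_d == pytest.approx(0.5, abs=1e-12)
        assert not roots.is_degenerate

    def test_crypt_plasticity_root(self, crypt_plasticity_params):
        # frozen from independent elimination + bisection of the quartic
        roots = solve_auxiliary_roots(crypt_plasticity_params)
        assert roots.z_s == pytest.approx(0.66014653, abs=1e-6)
        assert roots.z_d == pytest.approx(0.94702874, abs=1e-6)
        assert max(abs(r) for r in roots.residuals) <= 1e-10

    def test_transcritical_point_is_degenerate(self):
        # lies exactly on the neutrality boundary r* = 0.75 at u = eta = 0.5
        p = ModelParameters(n_stem=10, n_diff=10, r2=0.75, rt2=0.75,
                            u1=0.5, u2=0.5, eta1=0.0, eta2=0.5)
        roots = solve_auxiliary_roots(p)
        assert roots.is_degenerate
        assert (roots.z_s, roots.z_d) == (1.0, 1.0)

    def test_residuals_within_tolerance(self, crypt_plasticity_params):
        for p in (
            crypt_plasticity_params,
            ModelParameters(n_stem=10, n_diff=10, r2=1.5, rt2=1.5,
                            u1=0.5, u2=0.5, eta2=0.1),
            ModelParameters(n_stem=10, n_diff=10, r2=0.9, rt2=1.8,
                            u1=0.2, u2=0.4, eta1=0.1, eta2=0.3),
        ):
            roots = solve_auxiliary_roots(p)
            assert max(abs(r) for r in roots.residuals) <= 1e-10


class TestFixationFromCounts:
    def test_full_mutant_start_fixes_surely(self, crypt_plasticity_params):
        p = crypt_plasticity_params
        roots = solve_auxiliary_roots(p)
        assert fixation_from_counts(p, roots, 10, 10) == pytest.approx(1.0)
        assert fixation_from_counts(p, roots, 0, 0) == 0.0

    def test_single_stem_mutant_in_crypt(self, crypt_plasticity_params):
        roots = solve_auxiliary_roots(crypt_plasticity_params)
        rho = fixation_from_counts(crypt_plasticity_params, roots, 1, 0)
        assert round(rho, 3) == 0.343

    def test_monotone_in_initial_counts(self, crypt_plasticity_params):
        p = crypt_plasticity_params
        roots = solve_auxiliary_roots(p)
        grid = np.array([
            [fixation_from_counts(p, roots, i, j) for j in range(11)]
            for i in range(11)
        ])
        assert np.all(np.diff(grid, axis=0) >= -1e-12)
        assert np.all(np.diff(grid, axis=1) >= -1e-12)


class TestFixationSummary:
    def test_crypt_summary_values(self, crypt_plasticity_params):
        res = fixation_summary(crypt_plasticity_params)
        assert res.rho_s == pytest.approx(0.34298, abs=1e-4)
        assert res.rho_d == pytest.approx(0.05346, abs=1e-4)
        assert res.rho_avg == pytest.approx(0.19822, abs=1e-4)

    @pytest.mark.parametrize("params", [
        ModelParameters(n_stem=10, n_diff=10, r2=0.96, rt2=0.96,
                        u1=0.5, u2=0.25, eta2=0.12),
        ModelParameters(n_stem=10, n_diff=10, r2=1.5, rt2=1.5,
                        u1=0.5, u2=0.5, eta2=0.1),
        ModelParameters(n_stem=8, n_diff=12, r2=1.2, rt2=0.9,
                        u1=0.3, u2=0.4, eta1=0.05, eta2=0.2),
        ModelParameters(n_stem=10, n_diff=10, r2=2.0, rt2=2.0),
    ])
    def test_average_is_size_weighted_mean(self, params):
        res = fixation_summary(params)
        expected = (params.n_stem * res.rho_s + params.n_diff * res.rho_d) \
            / params.n_tot
        assert res.rho_avg == pytest.approx(expected, abs=1e-13)

    def test_symmetric_genotypes_complement_to_one(self):
        # with identical genotypes, a single mutant and a single wild type
        # are exchangeable: rho_S + h(N_S - 1, N_D) = 1
        p = ModelParameters(n_stem=5, n_diff=5, r2=1.0, rt2=1.0,
                            u1=0.4, u2=0.4, eta1=0.2, eta2=0.2)
        res = fixation_summary(p)
        complement = absorption_probability(p, 4, 5)
        assert res.rho_s + complement == pytest.approx(1.0, abs=1e-9)

    def test_decoupled_advantaged_matches_moran_formula(self):
        p = ModelParameters(n_stem=10, n_diff=10, r2=2.0, rt2=2.0)
        res = fixation_summary(p)
        assert res.rho_s == pytest.approx(512 / 1023, abs=1e-12)

    def test_hierarchy_matches_closed_form_and_oracle(self, hierarchical_params):
        res = fixation_summary(hierarchical_params)
        closed = closed_form_hierarchical(hierarchical_params)
        assert res.rho_s == pytest.approx(closed, abs=1e-10)
        assert res.rho_d == pytest.approx(0.0, abs=1e-10)
        oracle = absorption_probability(hierarchical_params, 1, 0)
        assert res.rho_s == pytest.approx(oracle, abs=1e-9)

    def test_weak_coupling_tracks_oracle(self):
        # with little differentiation and plasticity the martingale closure
        # is near exact; strong coupling is exercised in the acceptance suite
        p = ModelParameters(n_stem=10, n_diff=10, r2=1.5, rt2=1.5,
                            u1=0.1, u2=0.1, eta2=0.01)
        res = fixation_summary(p)
        assert res.rho_s == pytest.approx(
            absorption_probability(p, 1, 0), abs=0.02)

    def test_monotone_in_fitness_on_symmetric_sweep(self):
        rhos = []
        for r in np.linspace(0.5, 4.0, 15):
            p = ModelParameters(n_stem=10, n_diff=10, r2=r, rt2=r,
                                u1=0.5, u2=0.5, eta2=0.1)
            rhos.append(fixation_summary(p).rho_s)
        assert np.all(np.diff(rhos) >= -1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        r=st.floats(0.5, 3.0), u1=st.floats(0.05, 0.8),
        u2=st.floats(0.05, 0.8), eta2=st.floats(0.01, 0.8),
    )
    def test_probabilities_stay_in_unit_interval(self, r, u1, u2, eta2):
        p = ModelParameters(n_stem=10, n_diff=10, r2=r, rt2=r,
                            u1=u1, u2=u2, eta2=eta2)
        res = fixation_summary(p)
        for v in (res.rho_s, res.rho_d, res.rho_avg):
            assert 0.0 <= v <= 1.0


class TestClosedForms:
    def test_decoupled_double_advantage(self):
        p = ModelParameters(n_stem=10, n_diff=10, r2=2.0, rt2=2.0)
        rho1, rho2 = closed_form_decoupled(p)
        assert rho1 == pytest.approx(512 / 1023, abs=1e-14)
        assert rho2 == pytest.approx(512 / 1023, abs=1e-14)

    def test_decoupled_neutral_is_one_over_n(self):
        p = ModelParameters(n_stem=10, n_diff=10)
        assert closed_form_decoupled(p)[0] == pytest.approx(0.1)

    def test_decoupled_strong_selection_limit(self):
        p = ModelParameters(n_stem=10, n_diff=10, r2=1e9, rt2=1e9)
        assert closed_form_decoupled(p)[0] == pytest.approx(1.0, abs=1e-8)

    def test_negligible_dc_division(self):
        p = ModelParameters(n_stem=10, n_diff=10, r2=2.0, rt1=0.0, rt2=0.0,
                            u1=0.3, u2=0.3)
        assert closed_form_negligible_dc(p) == pytest.approx(0.250244, abs=1e-6)

    def test_negligible_dc_neutral(self):
        p = ModelParameters(n_stem=10, n_diff=10, rt1=0.0, rt2=0.0,
                            u1=0.3, u2=0.3)
        assert closed_form_negligible_dc(p) == pytest.approx(0.05)

    def test_negligible_dc_is_stem_weighted_decoupled(self):
        p = ModelParameters(n_stem=8, n_diff=12, r2=1.7, rt1=0.0, rt2=0.0,
                            u1=0.2, u2=0.4)
        expected = 8 / 20 * closed_form_decoupled(
            p.replace(rt1=1.0, rt2=1.7, u1=0.0, u2=0.0))[0]
        assert closed_form_negligible_dc(p) == pytest.approx(expected, abs=1e-14)

    def test_hierarchical_balanced_differentiation(self, hierarchical_params):
        rho = closed_form_hierarchical(hierarchical_params)
        assert rho == pytest.approx(0.1479, abs=1e-4)
        assert round(rho, 2) == 0.15

    def test_hierarchical_neutral(self):
        p = ModelParameters(n_stem=10, n_diff=10, u1=0.5, u2=0.5)
        assert closed_form_hierarchical(p) == pytest.approx(0.1)

    def test_hierarchical_effective_fitness_advantage(self):
        # deleterious raw fitness overcome by reduced differentiation
        p = ModelParameters(n_stem=10, n_diff=10, r2=0.96, rt2=0.96,
                            u1=0.5, u2=0.25)
        # (11/36) / (1 - (25/36)^10), frozen from exact rational evaluation
        assert closed_form_hierarchical(p) == pytest.approx(0.313739, abs=1e-6)

    def test_preconditions_enforced(self, crypt_plasticity_params):
        with pytest.raises(ParameterError):
            closed_form_decoupled(crypt_plasticity_params)
        with pytest.raises(ParameterError):
            closed_form_hierarchical(crypt_plasticity_params)  # eta2 > 0
        with pytest.raises(ParameterError):
            closed_form_negligible_dc(crypt_plasticity_params)


class TestSuccessByTime:
    def test_zero_time(self, crypt_plasticity_params):
        assert success_by_time(crypt_plasticity_params, 1e-4, 0.0) == 0.0

    def test_half_life(self, crypt_plasticity_params):
        rho = fixation_summary(crypt_plasticity_params).rho_avg
        t_half = math.log(2) / (20 * 1e-4 * rho)
        assert success_by_time(crypt_plasticity_params, 1e-4, t_half) \
            == pytest.approx(0.5, abs=1e-12)

    def test_monotone_with_unit_asymptote(self, crypt_plasticity_params):
        ts = np.linspace(0, 1e6, 30)
        vals = [success_by_time(crypt_plasticity_params, 1e-4, t) for t in ts]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] <= 1.0
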