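"""Unit and property tests for the closed-form selection-response algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

from greenbeard.core import (
    GMatrix,
    GroupSpec,
    InteractionMatrix,
    SelectionRegime,
    TraitVector,
    compute_fitness,
    greenbeard_response,
    is_evolvable,
    phenotypic_response,
    resolve_phenotypes,
    response_general,
    response_r0,
    threshold_correlation,
)

ZERO = TraitVector(0.0, 0.0)


def as_arrays(vectors):
    return np.array([v.as_array() for v in vectors])


class TestTypes:
    def test_trait_vector_rejects_non_finite(self):
        with pytest.raises(ValueError):
            TraitVector(math.inf, 0.0)

    def test_greenbeard_matrix_shape(self):
        psi = InteractionMatrix.greenbeard(-0.5)
        assert psi.psi == -0.5
        assert psi.is_greenbeard
        assert_allclose(psi.entries, [[0, 0], [-0.5, 0]])

    def test_gmatrix_rejects_non_psd(self):
        with pytest.raises(ValueError):
            GMatrix(g11=1.0, g22=1.0, g12=1.5)

    def test_gmatrix_rho(self):
        g = GMatrix.from_correlation(4.0, 1.0, -0.3)
        assert g.rho == pytest.approx(-0.3)
        assert math.isnan(GMatrix(0.0, 1.0, 0.0).rho)

    def test_greenbeard_regime_enforces_signs(self):
        with pytest.raises(ValueError):
            SelectionRegime.greenbeard(beta_n=1.0, beta_s=1.0)
        with pytest.raises(ValueError):
            SelectionRegime.greenbeard(beta_n=-1.0, beta_s=-1.0)

    def test_group_spec_validation(self):
        with pytest.raises(ValueError):
            GroupSpec(n=1)
        with pytest.raises(ValueError):
            GroupSpec(n=5, r=1.5)
        with pytest.raises(ValueError):
            GroupSpec(n=5, aggregation="median")


class TestResolvePhenotypes:
    def test_no_interaction_is_identity(self):
        rng = np.random.default_rng(0)
        a = [TraitVector(*row) for row in rng.normal(size=(6, 2))]
        e = [TraitVector(*row) for row in rng.normal(size=(6, 2))]
        z = resolve_phenotypes(a, e, InteractionMatrix.zero())
        assert_allclose(as_arrays(z), as_arrays(a) + as_arrays(e), atol=1e-14)

    def test_pair_beard_elicits_altruism(self):
        # hand-solved 2-member system: partner 2's altruism equals
        # partner 1's signaling phenotype
        z = resolve_phenotypes(
            [TraitVector(1.0, 0.0), TraitVector(0.0, 0.0)],
            [ZERO, ZERO],
            InteractionMatrix.greenbeard(1.0),
        )
        assert_allclose(as_arrays(z), [[1, 0], [0, 1]], atol=1e-14)

    def test_triplet_sums_partner_signals(self):
        z = resolve_phenotypes(
            [TraitVector(0.5, 0.0)] * 3,
            [ZERO] * 3,
            InteractionMatrix.greenbeard(1.0),
        )
        assert_allclose(as_arrays(z)[:, 1], [1.0, 1.0, 1.0], atol=1e-14)

    def test_mean_aggregation_divides_by_partner_count(self):
        z = resolve_phenotypes(
            [TraitVector(0.5, 0.0)] * 3,
            [ZERO] * 3,
            InteractionMatrix.greenbeard(1.0),
            aggregation="mean",
        )
        assert_allclose(as_arrays(z)[:, 1], [0.5, 0.5, 0.5], atol=1e-14)

    def test_general_matrix_matches_greenbeard_fast_path(self):
        rng = np.random.default_rng(1)
        a = [TraitVector(*row) for row in rng.normal(size=(5, 2))]
        e = [TraitVector(*row) for row in rng.normal(size=(5, 2))]
        z_fast = as_arrays(resolve_phenotypes(a, e, InteractionMatrix.greenbeard(0.7)))
        # a full matrix with vanishing extra couplings exercises the generic
        # joint solve and must agree with the feed-forward fast path
        near = InteractionMatrix(np.array([[1e-12, 1e-12], [0.7, 1e-12]]))
        z_general = as_arrays(resolve_phenotypes(a, e, near))
        assert_allclose(z_general, z_fast, atol=1e-9)

    def test_general_solver_satisfies_defining_system(self):
        rng = np.random.default_rng(2)
        n = 4
        a = rng.normal(size=(n, 2))
        e = rng.normal(size=(n, 2))
        psi = InteractionMatrix(np.array([[0.1, -0.2], [0.3, 0.05]]))
        z = as_arrays(
            resolve_phenotypes(
                [TraitVector(*r) for r in a], [TraitVector(*r) for r in e], psi
            )
        )
        for i in range(n):
            partner_sum = z.sum(axis=0) - z[i]
            assert_allclose(z[i], a[i] + e[i] + psi.entries @ partner_sum, atol=1e-12)

    def test_singular_system_raises(self):
        psi = InteractionMatrix(np.eye(2))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            resolve_phenotypes([ZERO, ZERO], [ZERO, ZERO], psi)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            resolve_phenotypes([ZERO], [ZERO], InteractionMatrix.zero())


class TestComputeFitness:
    regime = SelectionRegime(TraitVector(0.0, -1.0), TraitVector(0.0, 1.0), alpha=1.0)

    def test_zero_phenotypes_give_baseline(self):
        assert compute_fitness(ZERO, [ZERO, ZERO], self.regime) == 1.0

    def test_pair_example(self):
        w = compute_fitness(TraitVector(0.0, 1.0), [TraitVector(0.0, 2.0)], self.regime)
        assert w == pytest.approx(2.0)

    def test_no_selection_returns_alpha(self):
        regime = SelectionRegime(ZERO, ZERO, alpha=3.5)
        rng = np.random.default_rng(3)
        own = TraitVector(*rng.normal(size=2))
        partners = [TraitVector(*row) for row in rng.normal(size=(4, 2))]
        assert compute_fitness(own, partners, regime) == pytest.approx(3.5)

    def test_requires_partners(self):
        with pytest.raises(ValueError):
            compute_fitness(ZERO, [], self.regime)


def random_psd_g(rng):
    g11, g22 = rng.uniform(0.05, 3.0, size=2)
    rho = rng.uniform(-1.0, 1.0)
    return GMatrix.from_correlation(g11, g22, rho)


class TestResponses:
    def test_no_interaction_collapses_to_direct_selection(self):
        g = GMatrix(1.0, 2.0, 0.5)
        regime = SelectionRegime(TraitVector(0.3, -1.0), TraitVector(0.2, 0.9))
        spec = GroupSpec(n=8, m=5, r=0.0)
        da = response_general(g, InteractionMatrix.zero(), regime, spec)
        assert_allclose(da.as_array(), g.matrix @ regime.beta_n.as_array(), atol=1e-12)

    def test_full_relatedness_recovers_inclusive_response(self):
        # with psi = 0 and r = 1 the response is G (beta_N + (N-1) beta_S)
        g = GMatrix(1.0, 2.0, -0.7)
        regime = SelectionRegime(TraitVector(0.1, -1.0), TraitVector(0.0, 0.5))
        n = 6
        spec = GroupSpec(n=n, m=5, r=1.0)
        da = response_general(g, InteractionMatrix.zero(), regime, spec)
        expected = g.matrix @ (
            regime.beta_n.as_array() + (n - 1) * regime.beta_s.as_array()
        )
        assert_allclose(da.as_array(), expected, atol=1e-12)

    def test_r0_equals_general_for_arbitrary_interactions(self):
        rng = np.random.default_rng(7)
        regime = SelectionRegime(TraitVector(0.2, -1.0), TraitVector(-0.1, 0.8))
        for _ in range(200):
            g = random_psd_g(rng)
            psi = InteractionMatrix(rng.uniform(-0.15, 0.15, size=(2, 2)))
            n = int(rng.integers(2, 20))
            spec = GroupSpec(n=n, m=3, r=0.0)
            assert_allclose(
                response_r0(g, psi, regime, spec).as_array(),
                response_general(g, psi, regime, spec).as_array(),
                atol=1e-12,
            )

    def test_greenbeard_identity_g_example(self):
        da = greenbeard_response(GMatrix(1.0, 1.0, 0.0), 1.0, -1.0, 1.0, n=2)
        assert_allclose(da.as_array(), [1.0, -1.0], atol=1e-14)

    def test_without_beard_altruism_can_only_decline(self):
        g = GMatrix(1.0, 0.8, 0.4)
        da = greenbeard_response(g, 0.0, -1.0, 1.0, n=10)
        assert da.s == pytest.approx(-0.4)
        assert da.a == pytest.approx(-0.8)
        assert da.a < 0

    def test_altruism_response_vanishes_at_threshold_covariance(self):
        # G12 = -beta_N G22 / ((N-1) beta_S psi) zeroes the altruism response
        n, psi, bn, bs = 15, 1.0, -1.0, 1.0
        g22 = 1.0
        g12 = -bn * g22 / ((n - 1) * bs * psi)
        da = greenbeard_response(GMatrix(1.0, g22, g12), psi, bn, bs, n)
        assert abs(da.a) < 1e-15

    @settings(derandomize=True, max_examples=150)
    @given(
        g11=st.floats(0.05, 4.0),
        g22=st.floats(0.05, 4.0),
        rho=st.floats(-1.0, 1.0),
        psi=st.floats(-2.0, 2.0),
        beta_n=st.floats(-2.0, -0.01),
        beta_s=st.floats(0.01, 2.0),
        n=st.integers(2, 40),
    )
    def test_greenbeard_collapse_property(self, g11, g22, rho, psi, beta_n, beta_s, n):
        """The nilpotent interaction makes Eq.-3/4 forms collapse exactly."""
        g = GMatrix.from_correlation(g11, g22, rho)
        pm = InteractionMatrix.greenbeard(psi)
        regime = SelectionRegime(TraitVector(0.0, beta_n), TraitVector(0.0, beta_s))
        spec = GroupSpec(n=n, m=2, r=0.0)
        gb = greenbeard_response(g, psi, beta_n, beta_s, n).as_array()
        scale = max(1.0, np.abs(gb).max())
        assert np.abs(response_general(g, pm, regime, spec).as_array() - gb).max() < 1e-10 * scale
        assert np.abs(response_r0(g, pm, regime, spec).as_array() - gb).max() < 1e-10 * scale

    def test_linearity_in_gradients_interaction_and_g(self):
        g = GMatrix(0.9, 1.3, 0.5)
        base = greenbeard_response(g, 0.4, -1.0, 0.7, n=12).as_array()
        doubled_bs_part = greenbeard_response(g, 0.4, 0.0, 1.4, n=12).as_array()
        bs_part = greenbeard_response(g, 0.4, 0.0, 0.7, n=12).as_array()
        bn_part = greenbeard_response(g, 0.4, -1.0, 0.0, n=12).as_array()
        assert_allclose(base, bs_part + bn_part, atol=1e-12)
        assert_allclose(doubled_bs_part, 2 * bs_part, atol=1e-12)
        # scaling G scales the response
        g2 = GMatrix(1.8, 2.6, 1.0)
        assert_allclose(
            greenbeard_response(g2, 0.4, -1.0, 0.7, n=12).as_array(),
            2 * base,
            atol=1e-12,
        )

    def test_sign_of_altruism_response_matches_threshold(self):
        n, psi, bn, bs = 15, 1.0, -1.0, 1.0
        rho_t = threshold_correlation(bn, bs, psi, n, 1.0, 1.0)
        for rho in np.linspace(-1, 1, 41):
            g = GMatrix.from_correlation(1.0, 1.0, rho)
            da = greenbeard_response(g, psi, bn, bs, n)
            if abs(rho - rho_t) > 1e-9:
                assert np.sign(da.a) == np.sign(rho - rho_t)


class TestThresholdCorrelation:
    def test_printed_parameter_set(self):
        assert threshold_correlation(-1.0, 1.0, 1.0, 15, 1.0, 1.0) == pytest.approx(
            1 / 14, rel=1e-12
        )

    def test_costless_altruism_needs_no_correlation(self):
        assert threshold_correlation(0.0, 1.0, 1.0, 10, 1.0, 1.0) == 0.0

    def test_unreachable_threshold_flags_not_evolvable(self):
        rho_t = threshold_correlation(-1.0, 1.0, 0.5, 2, 1.0, 1.0)
        assert rho_t == pytest.approx(2.0)
        assert not is_evolvable(rho_t)
        assert is_evolvable(1 / 14)

    def test_negative_interaction_flips_sign(self):
        assert threshold_correlation(-1.0, 1.0, -1.0, 15, 1.0, 1.0) < 0

    def test_variance_ratio_scaling(self):
        assert threshold_correlation(-1.0, 1.0, 1.0, 15, 4.0, 1.0) == pytest.approx(
            2 / 14
        )

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError, match="rescued"):
            threshold_correlation(-1.0, 1.0, 0.0, 15, 1.0, 1.0)


class TestPhenotypicResponse:
    def test_no_interaction_is_identity(self):
        da = TraitVector(0.2, -0.4)
        dz = phenotypic_response(da, InteractionMatrix.zero(), n=9)
        assert_allclose(dz.as_array(), da.as_array(), atol=1e-14)

    def test_pair_example(self):
        dz = phenotypic_response(TraitVector(1.0, -1.0), InteractionMatrix.greenbeard(1.0), n=2)
        assert_allclose(dz.as_array(), [1.0, 0.0], atol=1e-14)

    def test_genotypic_decline_can_be_phenotypic_gain(self):
        dz = phenotypic_response(
            TraitVector(0.1, -0.5), InteractionMatrix.greenbeard(1.0), n=15
        )
        assert_allclose(dz.as_array(), [0.1, 0.9], atol=1e-12)
        assert dz.a > 0 > -0.5

    def test_sign_divergence_requires_positive_psi_times_signal_gain(self):
        psi = InteractionMatrix.greenbeard(0.8)
        up = phenotypic_response(TraitVector(0.3, -0.2), psi, n=10)
        down = phenotypic_response(TraitVector(-0.3, -0.2), psi, n=10)
        assert up.a > -0.2  # amplified upward when psi * da_s > 0
        assert down.a < -0.2

    def test_singular_operator_raises(self):
        psi = InteractionMatrix(np.array([[1.0 / 9.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            phenotypic_response(TraitVector(1.0, 0.0), psi, n=10)
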