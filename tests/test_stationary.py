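"""Spinodals, stationary branches, stability, and transition classification."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import bisect

from qvoter import (
    ModelParams,
    classify_transition,
    drift,
    lower_spinodal,
    stability_derivative,
    stationary_diagram,
    stationary_p_of_c,
    tricritical_qc,
    upper_spinodal,
)


class TestLowerSpinodal:
    def test_reference_values(self):
        assert lower_spinodal(2, 4) == 0.2
        assert lower_spinodal(2, 4, exact=True) == Fraction(1, 5)
        # exact rational: 2^2*7 / (2^2*7 + 2^8*3) = 28/796 = 7/199
        assert lower_spinodal(2, 8, exact=True) == Fraction(7, 199)

    def test_single_group_size_reduction(self):
        # qa = qc = q reduces to (q-1)/2q of the one-parameter model
        for q in range(1, 21):
            assert lower_spinodal(q, q, exact=True) == Fraction(q - 1, 2 * q)
        assert lower_spinodal(3, 3) == pytest.approx(1 / 3)

    def test_degenerate_conformity_size_one(self):
        # qc=1: conformity needs no agreement, no ordered phase for p > 0
        assert lower_spinodal(5, 1) == 0.0

    def test_equal_maximum_at_qc_2_and_3(self):
        # exact rational identity p1*(qa,2) = p1*(qa,3) for every qa
        for qa in range(1, 31):
            assert lower_spinodal(qa, 2, exact=True) == lower_spinodal(
                qa, 3, exact=True
            )

    def test_agrees_with_stationary_limit(self):
        # linear stability and the cst->1/2 limit of p(cst) are two routes
        # to the same bifurcation point
        for qa in range(1, 21):
            for qc in range(1, 21):
                assert abs(
                    lower_spinodal(qa, qc) - stationary_p_of_c(0.5, qa, qc)
                ) < 1e-10

    def test_rejects_bad_sizes(self):
        with pytest.raises((TypeError, ValueError)):
            lower_spinodal(2.5, 4)
        with pytest.raises(ValueError):
            lower_spinodal(0, 4)


class TestStabilityDerivative:
    def test_vanishes_at_lower_spinodal(self):
        p1 = lower_spinodal(2, 4)
        assert stability_derivative(0.5, ModelParams(2, 4, p1)) == pytest.approx(
            0.0, abs=1e-15
        )

    @pytest.mark.parametrize("p,sign", [(0.25, -1), (0.15, +1)])
    def test_sign_flips_across_spinodal(self, p, sign):
        d = stability_derivative(0.5, ModelParams(2, 4, p))
        assert np.sign(d) == sign

    def test_closed_form_at_half(self):
        # 2[(1-p)(qc-1)/2^qc - p(qa+1)/2^qa]
        for qa, qc, p in [(2, 4, 0.15), (3, 9, 0.4), (1, 2, 0.9)]:
            expected = 2 * ((1 - p) * (qc - 1) / 2**qc - p * (qa + 1) / 2**qa)
            got = stability_derivative(0.5, ModelParams(qa, qc, p))
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_matches_finite_difference_of_drift(self, rng):
        h = 1e-6
        for _ in range(30):
            params = ModelParams(
                qa=int(rng.integers(1, 12)), qc=int(rng.integers(1, 12)),
                p=float(rng.random()),
            )
            c = float(rng.uniform(0.05, 0.95))
            fd = (drift(c + h, params) - drift(c - h, params)) / (2 * h)
            assert stability_derivative(c, params) == pytest.approx(
                fd, rel=1e-5, abs=1e-8
            )

    def test_rejects_boundary(self):
        with pytest.raises(ValueError):
            stability_derivative(0.0, ModelParams(2, 4, 0.1))


class TestStationaryRelation:
    def test_limit_inserted_at_half(self):
        assert stationary_p_of_c(0.5, 2, 4) == pytest.approx(0.2, abs=1e-15)
        with pytest.raises(ValueError):
            stationary_p_of_c(0.5, 2, 4, at_half="raise")

    def test_mirror_symmetry(self):
        assert stationary_p_of_c(0.9, 2, 8) == pytest.approx(
            stationary_p_of_c(0.1, 2, 8), rel=1e-14
        )

    def test_inversion_agrees_with_root_finding_oracle(self, rng):
        # fix cst, read off p(cst); the same p must make F(cst)=0, and
        # bisecting F in p (F is monotone in p off the symmetric point)
        # must recover it
        for _ in range(50):
            qa = int(rng.integers(1, 10))
            qc = int(rng.integers(2, 12))
            cst = float(rng.uniform(0.55, 0.97))
            p = stationary_p_of_c(cst, qa, qc)
            if not 1e-6 < p < 1 - 1e-6:
                continue
            assert abs(drift(cst, ModelParams(qa, qc, p))) < 1e-12
            root = bisect(
                lambda pp: drift(cst, ModelParams(qa, qc, pp)), 0.0, 1.0,
                xtol=1e-12,
            )
            assert p == pytest.approx(root, abs=1e-10)


class TestTricritical:
    def test_integer_exact_value(self):
        # discriminant 25-12+36=49: qc*(3) = (5+7)/2 = 6 exactly
        assert tricritical_qc(3) == 6.0

    def test_first_discontinuous_integer_sizes(self):
        assert tricritical_qc(2) == pytest.approx((5 + np.sqrt(33)) / 2)
        assert int(np.floor(tricritical_qc(2))) + 1 == 6
        # qa=4: qc* ~ 6.77, so qc=6 continuous, qc=7 discontinuous
        assert classify_transition(4, 6).transition_type == "continuous"
        assert classify_transition(4, 7).transition_type == "discontinuous"

    def test_integer_offset_rule(self):
        # smallest discontinuous qc is qa+3 for qa >= 4, qa+4 for qa in {2,3}
        for qa in range(4, 31):
            qcs = tricritical_qc(qa)
            smallest = int(np.floor(qcs)) + 1 if qcs != int(qcs) else int(qcs) + 1
            assert smallest == qa + 3
        for qa in (2, 3):
            qcs = tricritical_qc(qa)
            smallest = int(np.floor(qcs)) + 1 if qcs != int(qcs) else int(qcs) + 1
            assert smallest == qa + 4


class TestUpperSpinodal:
    def test_continuous_case_collapses(self):
        spin = upper_spinodal(2, 4)
        assert spin.continuous
        assert (spin.p2_star, spin.c_plus) == (0.2, 0.5)

    def test_metastable_window_contains_known_point(self):
        # the potential at p=0.06 (qa=2, qc=8) still has ordered minima,
        # so the upper spinodal must lie above it
        assert upper_spinodal(2, 8).p2_star > 0.06

    def test_against_brute_force_grid(self):
        spin = upper_spinodal(4, 10)
        assert not spin.continuous
        grid = np.linspace(0.5 + 1e-9, 1 - 1e-9, 1_000_001)
        brute = stationary_p_of_c(grid, 4, 10).max()
        assert spin.p2_star == pytest.approx(brute, abs=1e-6)


class TestClassifyAndDiagram:
    def test_continuous_summary(self):
        s = classify_transition(2, 4)
        assert s.transition_type == "continuous"
        assert s.p1_star == s.p_star == s.p2_star == 0.2
        assert s.c_plus is None and s.width == 0.0

    def test_tricritical_summary(self):
        s = classify_transition(3, 6)
        assert s.transition_type == "tricritical"
        assert s.p_star == s.p1_star

    def test_discontinuous_summary(self):
        s = classify_transition(2, 8)
        assert s.transition_type == "discontinuous"
        assert s.p1_star < s.p_star < s.p2_star
        assert s.c_plus == pytest.approx(1.0 - s.c_minus, abs=1e-12)
        assert s.width > 0

    def test_supercritical_fold_is_single_valued(self):
        # continuous case: each p below the critical point has exactly one
        # stable stationary concentration above 1/2
        branch = stationary_diagram(2, 4, grid_size=2001)
        upper = (branch.cst_values > 0.5) & branch.stability
        p_upper = np.sort(branch.p_values[upper])
        assert p_upper.max() <= 0.2
        # p(cst) restricted to the stable upper branch is injective
        assert np.all(np.diff(p_upper) > 0)

    def test_subcritical_branch_is_s_shaped(self):
        branch = stationary_diagram(2, 8, grid_size=2001)
        p1 = lower_spinodal(2, 8)
        p2 = upper_spinodal(2, 8).p2_star
        for p_probe in np.linspace(p1 + 0.003, p2 - 0.003, 5):
            upper = branch.cst_values > 0.5
            near = upper & (np.abs(branch.p_values - p_probe) < 5e-4)
            # both a stable and an unstable nontrivial state at this p
            assert branch.stability[near].any()
            assert (~branch.stability[near]).any()

    def test_branch_mirror_invariance(self):
        branch = stationary_diagram(3, 7, grid_size=501)
        nontrivial = branch.cst_values != 0.5
        c = branch.cst_values[nontrivial]
        p = branch.p_values[nontrivial]
        order = np.argsort(c)
        assert np.allclose(p[order], p[order][::-1], atol=1e-12)
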