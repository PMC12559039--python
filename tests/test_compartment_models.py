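"""Compartment-model forward solutions, fitting, Vt and model criteria.

The independent oracle for the analytic convolution solutions is brute-force
numerical integration of the model ODEs with a stiff-capable adaptive solver
on the same piecewise-linear input.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from petkinfit.compartment_models import (DEFAULT_INIT, KineticParams1T,
                                          KineticParams2T, VbPolicy,
                                          compute_vt, fit_model,
                                          model_criteria, model_tac,
                                          solve_1tcm, solve_2tcm)
from petkinfit.plasma_input import InputFunction
from petkinfit.synthetic_data import simulate_tissue
from petkinfit.tac_io import TimeActivityCurve


def ode_tissue(params, input_fn, times):
    """Adaptive-step ODE integration of the compartment system (the oracle)."""
    if isinstance(params, KineticParams1T):
        def rhs(t, y):
            return [params.K1 * input_fn(t) - params.k2 * y[0]]
        y0 = [0.0]
    else:
        def rhs(t, y):
            c1, c2 = y
            return [params.K1 * input_fn(t) - (params.k2 + params.k3) * c1
                    + params.k4 * c2,
                    params.k3 * c1 - params.k4 * c2]
        y0 = [0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, float(np.max(times))), y0, t_eval=times,
                    method="LSODA", rtol=1e-9, atol=1e-12, max_step=0.25)
    return sol.y.sum(axis=0)


class TestForwardSolutions:
    def test_zero_input_gives_zero_output(self, schedule):
        cp = InputFunction([0.0, 90.0], [0.0, 0.0])
        p = KineticParams1T(0.2, 0.05, vB=0.03)
        assert np.allclose(solve_1tcm(p, cp, schedule.frame_mid), 0.0)

    def test_zero_k1_leaves_only_blood_term(self, schedule, cp_true, blood_true):
        p = KineticParams1T(0.0, 0.05, vB=0.03)
        out = solve_1tcm(p, cp_true, schedule.frame_mid, blood=blood_true)
        assert np.allclose(out, 0.03 * blood_true(schedule.frame_mid))

    def test_1tcm_matches_ode_oracle(self, schedule, cp_true):
        p = KineticParams1T(0.2, 0.04, vB=0.0)
        ana = solve_1tcm(p, cp_true, schedule.frame_mid)
        ref = ode_tissue(p, cp_true, schedule.frame_mid)
        assert np.max(np.abs(ana - ref)) < 1e-3 * np.max(np.abs(ref))

    @pytest.mark.parametrize("K1,k2,k3,k4", [
        (0.05, 0.01, 0.0, 0.01),
        (0.20, 0.19, 0.21, 0.04),   # deep-white-matter-like means
        (0.54, 2.85, 1.10, 0.04),   # fast-exchange cortical-like means
        (0.60, 3.00, 1.20, 0.12),
        (0.33, 0.50, 0.58, 0.11),
    ])
    def test_2tcm_matches_ode_oracle(self, schedule, cp_true, K1, k2, k3, k4):
        """Analytic convolution vs stiff ODE within 0.1% sup-norm across the
        realistic parameter range."""
        p = KineticParams2T(K1, k2, k3, k4, vB=0.0)
        ana = solve_2tcm(p, cp_true, schedule.frame_mid)
        ref = ode_tissue(p, cp_true, schedule.frame_mid)
        assert np.max(np.abs(ana - ref)) < 1e-3 * np.max(np.abs(ref))

    def test_nested_identity_k3_zero(self, schedule, cp_true, blood_true):
        """2TCM with k3 = 0 collapses exactly to the 1TCM."""
        mids = schedule.frame_mid
        a = solve_1tcm(KineticParams1T(0.2, 0.19, vB=0.03), cp_true, mids,
                       blood=blood_true)
        b = solve_2tcm(KineticParams2T(0.2, 0.19, 0.0, 0.05, vB=0.03),
                       cp_true, mids, blood=blood_true)
        assert np.max(np.abs(a - b)) < 1e-10 * np.max(np.abs(a))

    def test_large_k4_limit_approaches_1tcm(self, schedule, cp_true):
        """k4 -> infinity with k3 fixed: the bound pool empties instantly and
        the 2TCM converges to the 1TCM with the same K1, k2."""
        mids = schedule.frame_mid
        one = solve_1tcm(KineticParams1T(0.2, 0.1), cp_true, mids)
        two = solve_2tcm(KineticParams2T(0.2, 0.1, 0.05, 1000.0), cp_true, mids)
        assert np.max(np.abs(one - two)) < 1e-3 * np.max(np.abs(one))

    def test_repeated_eigenvalue_uses_confluent_form(self, schedule, cp_true):
        """Exact repeated root (k2+k3+k4)^2 = 4 k2 k4 must not fail and must
        agree with the ODE oracle."""
        k2 = k4 = 0.1
        k3 = 0.0  # s = 0.2, disc = 0.04 - 0.04 = 0 -> repeated root
        p = KineticParams2T(0.3, k2, k3, k4, vB=0.0)
        ana = solve_2tcm(p, cp_true, schedule.frame_mid)
        ref = ode_tissue(p, cp_true, schedule.frame_mid)
        assert np.max(np.abs(ana - ref)) < 1e-3 * np.max(np.abs(ref))


class TestComputeVt:
    def test_closed_forms(self):
        assert compute_vt(KineticParams1T(0.1, 0.1)) == pytest.approx(1.0)
        assert compute_vt(KineticParams2T(0.2, 0.1, 0.05, 0.05)) == pytest.approx(4.0)
        # nesting: k3 = 0 reduces to the 1TCM volume
        assert compute_vt(KineticParams2T(0.2, 0.1, 0.0, 0.05)) == \
            compute_vt(KineticParams1T(0.2, 0.1))

    def test_irreversible_limit_rejected(self):
        with pytest.raises(ValueError, match="irreversible"):
            compute_vt(KineticParams2T(0.2, 0.1, 0.05, 0.0))


class TestFitting:
    def test_noiseless_1tcm_recovery(self, schedule, cp_true, blood_true):
        true = KineticParams1T(0.22, 0.04, vB=0.03)
        clean = model_tac(true, cp_true, schedule, blood=blood_true,
                          sampling="average")
        tac = TimeActivityCurve("r", schedule.frame_mid, clean)
        fit = fit_model(tac, cp_true, "1tcm", schedule=schedule,
                        vb_policy=VbPolicy.fixed(0.03), blood=blood_true,
                        sampling="average")
        assert fit.converged
        assert fit.params.K1 == pytest.approx(0.22, rel=1e-3)
        assert fit.params.k2 == pytest.approx(0.04, rel=1e-3)
        assert np.all(fit.pcov_percent < 1e-3)

    def test_noiseless_2tcm_recovery_from_standard_inits(self, schedule,
                                                         cp_true, blood_true):
        """All four rates recovered within 1% from the standard starting
        values (K1=0.5, k2=0.035, k3=0.01, k4=0.01), vB fixed at 3%."""
        true = KineticParams2T(0.20, 0.19, 0.21, 0.04, vB=0.03)
        tac = simulate_tissue(true, cp_true, schedule, 0.0, 0, blood=blood_true)
        fit = fit_model(tac, cp_true, "2tcm", schedule=schedule,
                        vb_policy=VbPolicy.fixed(0.03), blood=blood_true,
                        sampling="average")
        assert fit.converged
        for name in ("K1", "k2", "k3", "k4"):
            assert getattr(fit.params, name) == \
                pytest.approx(getattr(true, name), rel=0.01)
        assert fit.vt == pytest.approx(compute_vt(true), rel=0.01)
        # consistency: reported Vt equals the closed form of the estimates
        assert fit.vt == pytest.approx(compute_vt(fit.params), rel=1e-12)

    def test_default_inits_match_standard_values(self):
        assert DEFAULT_INIT["K1"] == 0.5 and DEFAULT_INIT["k2"] == 0.035
        assert DEFAULT_INIT["k3"] == 0.01 and DEFAULT_INIT["k4"] == 0.01

    def test_fit_of_2tcm_to_1tcm_data_never_beats_nested_optimum(
            self, schedule, sampled_curves):
        """The 1TCM is nested in the 2TCM, so the richer model's weighted
        residual can only be lower or equal."""
        cp, total = sampled_curves
        true = KineticParams1T(0.22, 0.04, vB=0.03)
        clean = model_tac(true, cp, schedule, blood=total)
        rng = np.random.default_rng(5)
        noisy = clean + rng.normal(0, 0.02 * clean.max(), clean.size)
        tac = TimeActivityCurve("r", schedule.frame_mid, np.maximum(noisy, 0))
        f1 = fit_model(tac, cp, "1tcm", schedule=schedule, blood=total)
        f2 = fit_model(tac, cp, "2tcm", schedule=schedule, blood=total)
        assert f2.wrss <= f1.wrss * (1 + 1e-9)

    def test_pcov_of_microparameters_grows_with_noise(self, schedule,
                                                      cp_true, blood_true,
                                                      sampled_curves):
        """Median %COV of the 2TCM rate constants is non-decreasing over
        increasing noise (seeded, 8 replicates per level)."""
        cp, total = sampled_curves
        true = KineticParams2T(0.20, 0.19, 0.21, 0.04, vB=0.03)
        med = []
        for level in (0.1, 0.4, 1.0):
            vals = []
            for rep in range(8):
                tac = simulate_tissue(true, cp_true, schedule, level,
                                      seed=900 + rep, blood=blood_true)
                fit = fit_model(tac, cp, "2tcm", schedule=schedule,
                                blood=total)
                vals.append(np.median(fit.pcov_percent[:4]))
            med.append(np.median(vals))
        assert med[0] <= med[1] <= med[2]

    def test_vb_fixed_at_5_percent_inflates_1tcm_vt(self, schedule, cp_true,
                                                    blood_true, sampled_curves):
        """With data generated at vB = 3%, fixing vB at 5% in the 1TCM fit
        yields slightly larger Vt (direction only)."""
        cp, total = sampled_curves
        true = KineticParams2T(0.48, 2.87, 1.09, 0.06, vB=0.03)
        tac = simulate_tissue(true, cp_true, schedule, 0.3, seed=21,
                              blood=blood_true)
        f3 = fit_model(tac, cp, "1tcm", schedule=schedule,
                       vb_policy=VbPolicy.fixed(0.03), blood=total)
        f5 = fit_model(tac, cp, "1tcm", schedule=schedule,
                       vb_policy=VbPolicy.fixed(0.05), blood=total)
        assert f5.vt > f3.vt


class TestModelCriteria:
    def test_perfect_fit_has_tiny_chi2_and_sentinel_aic(self, schedule,
                                                        cp_true, blood_true):
        true = KineticParams2T(0.20, 0.19, 0.21, 0.04, vB=0.03)
        tac = simulate_tissue(true, cp_true, schedule, 0.0, 0, blood=blood_true)
        fit = fit_model(tac, cp_true, "2tcm", schedule=schedule,
                        blood=blood_true, sampling="average")
        chi2, aic = model_criteria(fit)
        assert fit.wrss < 1e-10
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert aic < -100  # essentially the -inf/degenerate regime

    def test_chi2_and_aic_formulas(self):
        from petkinfit.compartment_models import _criteria
        chi2, aic = _criteria(wrss=2.0, n=29, p=4)
        assert chi2 == pytest.approx(2.0 / 25)
        assert aic == pytest.approx(29 * np.log(2.0 / 29) + 8)
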