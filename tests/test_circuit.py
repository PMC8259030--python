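"""Unit and property tests for the switch-circuit kinetic model."""

import dataclasses

import numpy as np
import pytest

from lactoswitch.circuit import (
    CircuitParams,
    PromoterParams,
    RegulatorState,
    SignalInput,
    STATE_VARS,
    activity_placm,
    activity_patp2,
    activity_pRE,
    cii_degradation_rate,
    circuit_rhs,
    find_stable_states,
    hill_repression,
    simulate_circuit,
    _rhs_array,
)


# ---------------------------------------------------------------------------
# promoter response functions
# ---------------------------------------------------------------------------
class TestPromoters:
    def test_placm_basal_and_midpoint(self, params):
        p = params.placm
        assert activity_placm(0.0, params) == pytest.approx(p.v0)
        assert activity_placm(p.K, params) == pytest.approx(p.v0 + (p.v - p.v0) / 2)

    def test_placm_near_saturation(self, params):
        # Hill n=2 at 10K: response reaches 100/101 of the dynamic range
        p = params.placm
        val = activity_placm(10 * p.K, params)
        assert val > 0.99 * p.v

    def test_placm_monotone(self, params):
        grid = np.linspace(0, 50, 40)
        vals = [activity_placm(x, params) for x in grid]
        assert np.all(np.diff(vals) >= 0)
        assert max(vals) <= params.placm.v

    def test_patp2_half_repression_at_pKh(self, params):
        p = params.patp2
        pH_mid = -np.log10(p.K)
        assert activity_patp2(pH_mid, params) == pytest.approx(p.v0 + (p.v - p.v0) / 2)

    def test_patp2_limits_and_ph_ordering(self, params):
        assert activity_patp2(13.999, params) == pytest.approx(params.patp2.v, rel=1e-3)
        # neutral colon is permissive, acidic colon represses
        assert activity_patp2(7.0, params) > activity_patp2(5.0, params)

    def test_hill_repression_endpoints(self):
        assert hill_repression(0.0, 10.0, 0.5, 1.0, 2.0) == pytest.approx(10.0)
        assert hill_repression(1.0, 10.0, 0.5, 1.0, 2.0) == pytest.approx(5.25)
        assert hill_repression(1e9, 10.0, 0.5, 1.0, 2.0) == pytest.approx(0.5, abs=1e-6)

    def test_pre_activation(self, params):
        p = params.pRE
        assert activity_pRE(0.0, params) == pytest.approx(p.v0)
        assert activity_pRE(p.K, params) == pytest.approx((p.v + p.v0) / 2)
        grid = np.linspace(0, 10 * p.K, 50)
        vals = [activity_pRE(x, params) for x in grid]
        assert np.all(np.diff(vals) > 0)

    def test_ftsh_degradation(self, params):
        lo, hi = params.delta_cII, params.delta_cII + params.delta_ftsh
        assert cii_degradation_rate(0.0, params) == pytest.approx(hi)
        assert cii_degradation_rate(1e9, params) == pytest.approx(lo, abs=1e-6)
        assert cii_degradation_rate(params.K_cIII, params) == pytest.approx(
            lo + params.delta_ftsh / 2)

    @pytest.mark.parametrize("fn,bad", [
        (lambda p: activity_placm(-1.0, p), "lactose"),
        (lambda p: activity_patp2(0.0, p), "pH"),
        (lambda p: activity_patp2(14.5, p), "pH"),
        (lambda p: activity_pRE(-0.1, p), "cII"),
        (lambda p: cii_degradation_rate(-2.0, p), "cIII"),
    ])
    def test_domain_errors(self, params, fn, bad):
        with pytest.raises(ValueError, match=bad):
            fn(params)

    def test_promoter_param_validation(self):
        with pytest.raises(ValueError):
            PromoterParams(v=1.0, v0=2.0, K=1.0, n=2.0)  # leak above max
        with pytest.raises(ValueError):
            PromoterParams(v=1.0, v0=0.0, K=-1.0, n=2.0)


# ---------------------------------------------------------------------------
# right-hand side and integration
# ---------------------------------------------------------------------------
def _leaky(params: CircuitParams, **prom) -> CircuitParams:
    """Replace selected promoters by constant (leak-only) sources."""
    out = params
    for name, rate in prom.items():
        out = out.with_promoter(name, v=rate if rate > 0 else 1e-12,
                                v0=rate if rate > 0 else 0.0)
    return out


class TestRhs:
    def test_zero_state_production_only(self, params):
        d = circuit_rhs(RegulatorState(), SignalInput(0.0, 7.0), params)
        assert d.cI == pytest.approx(activity_patp2(7.0, params))
        assert all(getattr(d, k) >= 0 for k in STATE_VARS)

    def test_derivatives_vanish_at_fixed_point(self, params):
        sig = SignalInput(0.0, 7.0)
        (state,) = find_stable_states(sig, params, n_starts=10, seed=3)
        d = circuit_rhs(state, sig, params)
        assert max(abs(getattr(d, k)) for k in STATE_VARS) < 1e-9

    def test_linear_steady_state_scales_with_degradation(self, params):
        # with all promoters leak-only the system is linear; steady cI is
        # production / degradation, so doubling delta_cI halves it
        lp = _leaky(params, placm=0.0, patp2=2.0, pR=0.0, pRM=0.0, pRE=0.0)
        sig = SignalInput(0.0, 7.0)
        (s1,) = find_stable_states(sig, lp, n_starts=4, seed=0)
        assert s1.cI == pytest.approx(2.0 / lp.delta_cI, rel=1e-6)
        lp2 = dataclasses.replace(lp, delta_cI=2 * lp.delta_cI)
        (s2,) = find_stable_states(sig, lp2, n_starts=4, seed=0)
        assert s2.cI == pytest.approx(s1.cI / 2, rel=1e-6)

    def test_non_finite_state_rejected(self, params):
        state = RegulatorState(cI=1.0)
        object.__setattr__(state, "cI", float("nan"))
        with pytest.raises(ValueError):
            circuit_rhs(state, SignalInput(0.0, 7.0), params)


class TestSimulate:
    def test_pure_decay_closed_form(self, params):
        lp = _leaky(params, placm=0.0, patp2=0.0, pR=0.0, pRM=0.0, pRE=0.0)
        lp = dataclasses.replace(lp, delta_cI=1.0)
        t = np.linspace(0, 5, 26)
        traj = simulate_circuit(RegulatorState(cI=1.0), lambda _: SignalInput(0.0, 7.0),
                                lp, t)
        ci = traj[traj.variable == "cI"].value.to_numpy()
        assert np.allclose(ci, np.exp(-t), atol=1e-6)

    def test_stays_at_stable_fixed_point(self, params):
        sig = SignalInput(0.0, 7.0)
        (state,) = find_stable_states(sig, params, n_starts=10, seed=3)
        traj = simulate_circuit(state, lambda _: sig, params, np.linspace(0, 20, 21))
        piv = traj.pivot(index="time_h", columns="variable", values="value")
        for k in STATE_VARS:
            assert np.max(np.abs(piv[k] - getattr(state, k))) < 1e-6

    def test_lactose_step_drives_cro_past_prm_threshold(self, params):
        sig_fn = lambda t: SignalInput(20.0 if t >= 2.0 else 0.0, 7.0)
        start = find_stable_states(SignalInput(0.0, 7.0), params, 10, 3)[0]
        traj = simulate_circuit(start, sig_fn, params, np.linspace(0, 12, 121))
        cro = traj[traj.variable == "cro"].value.to_numpy()
        assert cro.max() > params.pRM.K

    def test_non_negative_and_bounded(self, params):
        # bound: max production / degradation per variable
        sig_fn = lambda t: SignalInput(30.0 if 1 < t < 6 else 0.0, 6.0)
        init = RegulatorState(cI=5.0, cro=5.0, cII=5.0, cIII=5.0,
                              beta_gal=5.0, l_ldh=5.0)
        traj = simulate_circuit(init, sig_fn, params, np.linspace(0, 20, 81))
        piv = traj.pivot(index="time_h", columns="variable", values="value")
        assert (piv >= 0).all().all()
        prod = {
            "cI": params.patp2.v, "cro": params.placm.v + params.pRE.v,
            "cII": params.placm.v + params.pRE.v, "cIII": params.pR.v,
            "beta_gal": params.pRM.v, "l_ldh": params.pR.v,
        }
        deg = {"cI": params.delta_cI, "cro": params.delta_cro,
               "cII": params.delta_cII, "cIII": params.delta_cIII,
               "beta_gal": params.delta_gal, "l_ldh": params.delta_ldh}
        for k in STATE_VARS:
            bound = max(prod[k] / deg[k], getattr(init, k)) + 1e-9
            assert piv[k].max() <= bound

    def test_bad_grid_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_circuit(RegulatorState(), lambda _: SignalInput(0, 7), params,
                             [0.0, 0.5, 0.4])


# ---------------------------------------------------------------------------
# stable states
# ---------------------------------------------------------------------------
def _cascade_oracle(signals: SignalInput, params: CircuitParams):
    """Independent fixed-point enumeration exploiting the cascade structure.

    cI and cIII steady states are explicit; the only nonlinear closure is
    the scalar cII equation, whose roots are found by dense scanning plus
    bisection.  Everything else follows in closed form.
    """
    from scipy.optimize import brentq

    cI = activity_patp2(signals.pH, params) / params.delta_cI
    a_pr = hill_repression(cI, params.pR.v, params.pR.v0, params.pR.K, params.pR.n)
    cIII = a_pr / params.delta_cIII
    deg = cii_degradation_rate(cIII, params)
    a_lacm = activity_placm(signals.lactose, params)

    def g(c):
        return a_lacm + activity_pRE(c, params) - deg * c

    grid = np.linspace(0.0, (a_lacm + params.pRE.v) / deg * 1.5 + 1.0, 20001)
    vals = np.array([g(c) for c in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    states = []
    for cII in roots:
        if not (g(cII - 1e-7) > 0 > g(cII + 1e-7)):
            continue  # unstable along the cII direction
        cro = (a_lacm + activity_pRE(cII, params)) / params.delta_cro
        beta_gal = hill_repression(cro, params.pRM.v, params.pRM.v0, params.pRM.K,
                                   params.pRM.n) / params.delta_gal
        l_ldh = a_pr / params.delta_ldh
        states.append(RegulatorState(cI=cI, cro=cro, cII=cII, cIII=cIII,
                                     beta_gal=beta_gal, l_ldh=l_ldh))
    return states


class TestStableStates:
    @pytest.mark.parametrize("sig,dominant", [
        (SignalInput(0.0, 7.0), "beta_gal"),
        (SignalInput(20.0, 5.0), "l_ldh"),
    ])
    def test_regimes_unique_and_dominant(self, params, sig, dominant):
        states = find_stable_states(sig, params, n_starts=20, seed=1)
        assert len(states) == 1
        s = states[0]
        other = "l_ldh" if dominant == "beta_gal" else "beta_gal"
        assert getattr(s, dominant) > 10 * getattr(s, other)

    def test_deterministic_given_seed(self, params):
        sig = SignalInput(5.0, 6.0)
        a = find_stable_states(sig, params, n_starts=15, seed=9)
        b = find_stable_states(sig, params, n_starts=15, seed=9)
        assert [s.as_array().tolist() for s in a] == [s.as_array().tolist() for s in b]

    @pytest.mark.parametrize("sig", [
        SignalInput(0.0, 7.0), SignalInput(20.0, 5.0),
        SignalInput(0.0, 5.0), SignalInput(20.0, 7.0), SignalInput(5.0, 6.0),
    ])
    def test_matches_cascade_enumeration_oracle(self, params, sig):
        found = find_stable_states(sig, params, n_starts=25, seed=2)
        oracle = _cascade_oracle(sig, params)
        assert len(found) == len(oracle)
        for f, o in zip(found, sorted(oracle, key=lambda s: tuple(s.as_array()))):
            assert np.allclose(f.as_array(), o.as_array(), rtol=1e-5, atol=1e-6)

    def test_signal_monotonicity_at_steady_state(self, params):
        # steady state reached by relaxation from the origin
        def steady(lactose, pH):
            sig = SignalInput(lactose, pH)
            traj = simulate_circuit(RegulatorState(), lambda _: sig, params,
                                    np.linspace(0, 400, 11))
            return traj.pivot(index="time_h", columns="variable", values="value").iloc[-1]

        lac = np.linspace(0, 25, 5)
        phs = np.linspace(4.5, 7.5, 5)
        grid = {(l, p): steady(l, p) for l in lac for p in phs}
        for p in phs:
            cro_vals = [grid[(l, p)]["cro"] for l in lac]
            assert np.all(np.diff(cro_vals) >= -1e-6)
        for l in lac:
            ci_vals = [grid[(l, p)]["cI"] for p in phs]
            assert np.all(np.diff(ci_vals) >= -1e-6)
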