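import numpy as np
import pytest

from sigbnet.competition import (COMP_SPECIES, N_COMP, competition_rhs,
                                 competition_steady_state,
                                 dose_response_vs_A_T, half_max_K_sigB,
                                 phenom_free_sigma, simulate_competition,
                                 three_sigma_defaults, three_sigma_response,
                                 three_sigma_steady_state)
from sigbnet.inputs import BurstParams, make_constant, sample_gamma_ou
from sigbnet.params import (NEGATIVE_FEEDBACK, POSITIVE_FEEDBACK,
                            CompetitionParams, PhenomSigmaParams)

N_CORE = 9


@pytest.fixture(scope="module")
def comp():
    return CompetitionParams()


@pytest.fixture(scope="module")
def comp_ss(kin, op, comp):
    return competition_steady_state(kin, op, comp.replace(A_T=9.0), 0.5)


class TestCompetitionModel:
    def test_affinities(self, comp):
        assert comp.k_db / comp.k_bb == pytest.approx(1.2)
        assert comp.k_da / comp.k_ba == pytest.approx(0.02)

    def test_conservations_along_trajectory(self, kin, op, comp, comp_ss):
        c = comp.replace(A_T=9.0)
        bp = BurstParams(a=2.0, b=0.25, T=5.0, seed=7)
        inp = sample_gamma_ou(bp)
        t, Y = simulate_competition(kin, op, c, inp, 5.0, comp_ss.y,
                                    t_eval=np.linspace(0, 5, 501))
        RA, RB, RBp = Y[:, N_CORE], Y[:, N_CORE + 1], Y[:, N_CORE + 2]
        # totals bounded by their conservation pools
        assert np.all(RA + RB + RBp <= c.RNApol_tot + 1e-6)
        assert np.all(RA <= c.A_T + 1e-6)
        assert np.all(RBp <= c.p_B_tot + 1e-9)
        assert np.all(Y >= 0)

    def test_total_sigB_ode_holds(self, kin, op, comp):
        # d(B_T)/dt with holoenzyme forms included must equal
        # production - k_deg * B_T
        c = comp.replace(A_T=9.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.uniform(0, 0.5, N_COMP)
            dy = competition_rhs(y, kin, op, c, 0.5)
            B_T = y[0] + y[5] + y[N_CORE + 1] + y[N_CORE + 2]
            dB_T = dy[0] + dy[5] + dy[N_CORE + 1] + dy[N_CORE + 2]
            v_B = op.v0 + op.v0 * op.f / c.p_B_tot * y[N_CORE + 2]
            assert dB_T == pytest.approx(v_B - kin.k_deg * B_T, rel=1e-9,
                                         abs=1e-12)

    def test_no_competitor_limit(self, kin, op, comp):
        st = competition_steady_state(kin, op, comp.replace(A_T=0.0), 0.5)
        assert st.y[N_CORE] == pytest.approx(0.0, abs=1e-12)   # no RNApol-sigA
        assert st.sigA_free == 0.0
        assert st.RNApol_free > 0.5 * comp.RNApol_tot

    def test_steady_state_is_fixed_point(self, kin, op, comp, comp_ss):
        dy = competition_rhs(comp_ss.y, kin, op, comp.replace(A_T=9.0), 0.5)
        assert np.max(np.abs(dy)) < 1e-7


class TestDoseResponse:
    @pytest.fixture(scope="class")
    def curves(self, kin, op, comp):
        grid = np.linspace(5.0, 15.0, 6)
        wt = dose_response_vs_A_T(kin, op, comp, 0.5, grid)
        nf = dose_response_vs_A_T(kin, op.replace(f=0.0, v0=8.64), comp,
                                  0.5, grid)
        return wt, nf

    def test_wildtype_free_sigB_rises_with_competition(self, curves):
        wt, _ = curves
        assert np.all(np.diff(wt["sigB_free"]) > 0)

    def test_no_feedback_free_sigB_flat(self, curves):
        _, nf = curves
        rng = nf["sigB_free"].max() / nf["sigB_free"].min()
        assert rng < 1.05

    def test_no_feedback_activity_collapses_at_high_sigA(self, curves):
        _, nf = curves
        assert np.all(np.diff(nf["target_activity"]) < 0)
        assert nf["target_activity"][-1] < 0.1 * nf["target_activity"][0]

    def test_wildtype_insulated_relative_to_no_feedback(self, curves):
        wt, nf = curves
        # log-sensitivity of target activity to A_T over [9, 12]
        def sens(c):
            A, y = c["A_T"], c["target_activity"]
            lo, hi = np.interp([9.0, 12.0], A, y)
            return abs(np.log(hi / lo) / np.log(12.0 / 9.0))
        assert sens(wt) < 0.5 * sens(nf)


class TestHalfMaxConstant:
    def test_increasing_in_sigA(self, comp):
        Ks = [half_max_K_sigB(comp, A_T=a) for a in (0.0, 5.0, 9.0, 12.0)]
        assert np.all(np.diff(Ks) > 0)

    def test_no_competitor_is_smallest(self, comp):
        K0 = half_max_K_sigB(comp, A_T=0.0)
        assert K0 < half_max_K_sigB(comp, A_T=5.0)

    def test_increasing_in_sigW_at_fixed_sigA(self, comp):
        for A_T in (9.0, 12.0):
            Ks = [half_max_K_sigB(comp, A_T=A_T, sigW_free=w)
                  for w in (0.0, 2.0, 5.0)]
            assert np.all(np.diff(Ks) > 0)


class TestPhenomFreeSigma:
    def test_large_signal_releases_everything(self):
        pp = NEGATIVE_FEEDBACK
        assert phenom_free_sigma(3.0, 1e9, pp) == pytest.approx(3.0, rel=1e-5)

    def test_no_titration_variant_is_increasing(self):
        pp = POSITIVE_FEEDBACK
        S = np.linspace(0.0, 20.0, 50)
        out = phenom_free_sigma(S, 2.0, pp)
        assert np.all(np.diff(out) > 0)
        assert out[-1] == pytest.approx(20.0 / (1.0 + 2.0 ** -3))

    def test_titration_variant_has_interior_maximum(self):
        pp = PhenomSigmaParams(K=5.0, nb=7.0, mb=5.0)
        S = np.linspace(0.01, 20.0, 400)
        out = phenom_free_sigma(S, 2.0, pp)
        i = int(np.argmax(out))
        assert 0 < i < len(S) - 1
        assert out[-1] < out[i]

    def test_zero_signal_limit(self):
        assert phenom_free_sigma(3.0, 0.0, NEGATIVE_FEEDBACK) == 0.0
        with pytest.raises(ValueError):
            phenom_free_sigma(-1.0, 1.0, NEGATIVE_FEEDBACK)


class TestThreeSigma:
    @pytest.fixture(scope="class")
    def responses(self, kin, op):
        comp3 = three_sigma_defaults()
        PB = np.linspace(0.2, 5.0, 6)
        neg = three_sigma_response(kin, op, comp3, NEGATIVE_FEEDBACK,
                                   NEGATIVE_FEEDBACK, PB, P_W=2.0)
        pos = three_sigma_response(kin, op, comp3, POSITIVE_FEEDBACK,
                                   POSITIVE_FEEDBACK, PB, P_W=2.0)
        return neg, pos

    def test_sigB_activated_by_its_signal(self, responses):
        for r in responses:
            assert np.all(np.diff(r["sigB_free"]) > 0)

    def test_negative_feedback_spares_sigW(self, responses):
        neg, _ = responses
        assert np.all(np.diff(neg["sigW_free"]) >= -1e-9)

    def test_positive_feedback_starves_sigW(self, responses):
        _, pos = responses
        assert pos["sigW_free"][-1] < pos["sigW_free"][0]

    def test_polymerase_drawn_from_sigA_under_negative_feedback(self,
                                                                responses):
        neg, pos = responses
        assert abs(neg["delta_Rpol_sigA"][-1]) \
            > abs(neg["delta_Rpol_sigW"][-1])
        assert abs(pos["delta_Rpol_sigW"][-1]) \
            > abs(pos["delta_Rpol_sigA"][-1])

    def test_polymerase_accounting_closes(self, responses):
        for r in responses:
            gain = r["delta_Rpol_sigB"] \
                + (r["activity_B"] - r["activity_B"][0]) \
                * three_sigma_defaults().p_B_tot
            loss = -(r["delta_Rpol_sigA"] + r["delta_Rpol_sigW"]
                     + r["delta_Rpol_free"]
                     + (r["activity_W"] - r["activity_W"][0])
                     * three_sigma_defaults().p_B_tot)
            assert np.allclose(gain, loss, atol=1e-6)

    def test_step_in_P_B_gives_adaptive_sigB_pulse(self, kin, op):
        # the reduced negative-feedback module must still pulse on a
        # step in its signaling protein
        from scipy.integrate import solve_ivp
        from sigbnet.competition import _three_sigma_rhs

        comp3 = three_sigma_defaults()
        st0 = three_sigma_steady_state(kin, op, comp3, NEGATIVE_FEEDBACK,
                                       NEGATIVE_FEEDBACK, 0.1, 2.0)

        def rhs(t, y):
            # step P_B 0.1 -> 0.5 lands on the steep titration branch
            return _three_sigma_rhs(y, kin, op, comp3, NEGATIVE_FEEDBACK,
                                    NEGATIVE_FEEDBACK, 0.5, 2.0)

        sol = solve_ivp(rhs, (0.0, 30.0), st0["y"], method="LSODA",
                        t_eval=np.linspace(0, 30, 601), rtol=1e-9,
                        atol=1e-11)
        sig = np.array([
            phenom_free_sigma(BT, 0.5, NEGATIVE_FEEDBACK)
            for BT in sol.y[0]])
        amp = sig.max() - sig[0]
        assert amp > 0.5
        assert (sig.max() - sig[-1]) > 0.3 * amp   # adapts back down
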