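"""RNA-polymerase competition models.

Two levels of description:

1. Mechanistic sigma-A/sigma-B competition: the core partner-switching
   network extended with reversible sigma-RNApol holoenzyme formation,
   holoenzyme-promoter binding, and operon production fired from the
   promoter-bound holoenzyme (maximal rate v0*f/p_B_tot per unit of
   promoter complex, plus an unconditioned basal flux v0).  sigma-A is
   a fixed total competing for the same core polymerase with ~60-fold
   higher affinity.  Only free sigma-B (not holoenzyme-bound) takes
   part in partner switching.

2. Phenomenological three-sigma model (sigma-A, sigma-B, sigma-W):
   post-translational release of each stress sigma is collapsed into
   sigma_free = S_T / (1 + (S_T/K)^nb / P^mb), and the two stress-sigma
   modules are identical; production of each total is driven by its own
   promoter-bound holoenzyme.

State vector layout (mechanistic model): the 9 core species followed by
RNApol_sigA, RNApol_sigB, RNApol_sigB_pB.  Free RNApol, free sigma-A
and free promoter are eliminated by conservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .inputs import BurstParams, PhosphataseInput, sample_gamma_ou
from .model import N_SPECIES, SPECIES, reaction_rhs
from .params import (CompetitionParams, KineticParams, OperonParams,
                     PhenomSigmaParams)
from .pulses import detect_pulses, ensemble_pulse_stats, target_expression

__all__ = [
    "COMP_SPECIES",
    "CompetitionState",
    "competition_rhs",
    "simulate_competition",
    "competition_steady_state",
    "competition_stochastic_run",
    "dose_response_vs_A_T",
    "half_max_K_sigB",
    "phenom_free_sigma",
    "three_sigma_defaults",
    "three_sigma_partition",
    "three_sigma_response",
    "three_sigma_steady_state",
]

COMP_SPECIES = SPECIES + ("RNApol_sigA", "RNApol_sigB", "RNApol_sigB_pB")
_IRA, _IRB, _IRBP = N_SPECIES, N_SPECIES + 1, N_SPECIES + 2
N_COMP = len(COMP_SPECIES)


@dataclass(frozen=True)
class CompetitionState:
    """Concentrations of the extended network plus derived free pools."""

    y: np.ndarray
    P_T: float
    comp: CompetitionParams

    @property
    def RNApol_free(self) -> float:
        return self.comp.RNApol_tot - self.y[_IRA] - self.y[_IRB] \
            - self.y[_IRBP]

    @property
    def sigA_free(self) -> float:
        return self.comp.A_T - self.y[_IRA]

    @property
    def p_B_free(self) -> float:
        return self.comp.p_B_tot - self.y[_IRBP]

    @property
    def target_activity(self) -> float:
        return self.y[_IRBP] / self.comp.p_B_tot

    @property
    def sigB_free(self) -> float:
        return self.y[0]

    @property
    def B_T(self) -> float:
        # sigma-B in all of its forms: free, anti-sigma-bound, holoenzyme
        i = {s: k for k, s in enumerate(COMP_SPECIES)}
        return float(self.y[i["sigB"]] + self.y[i["W2sigB"]]
                     + self.y[_IRB] + self.y[_IRBP])


def competition_rhs(y: np.ndarray, kin: KineticParams, op: OperonParams,
                    comp: CompetitionParams, P_T: float) -> np.ndarray:
    """Mass-action derivative of the sigma-A/sigma-B competition model."""
    sigB = y[0]
    RA, RB, RBp = y[_IRA], y[_IRB], y[_IRBP]
    R = max(comp.RNApol_tot - RA - RB - RBp, 0.0)
    sigA = max(comp.A_T - RA, 0.0)
    pB = max(comp.p_B_tot - RBp, 0.0)

    v_max = op.v0 * op.f / comp.p_B_tot
    v_B = op.v0 + v_max * RBp          # operon firing flux

    dy = np.empty(N_COMP)
    dy[:N_SPECIES] = reaction_rhs(y[:N_SPECIES], kin, op, P_T, v_B=v_B)

    bindB_f = comp.k_bb * sigB * R
    bindB_b = comp.k_db * RB
    bindA_f = comp.k_ba * sigA * R
    bindA_b = comp.k_da * RA
    prom_f = comp.k_bpb * RB * pB
    prom_b = comp.k_dpb * RBp

    dy[0] += -bindB_f + bindB_b
    dy[_IRA] = bindA_f - bindA_b
    dy[_IRB] = (bindB_f - bindB_b - prom_f + prom_b
                + v_max * RBp - kin.k_deg * RB)
    dy[_IRBP] = prom_f - prom_b - v_max * RBp - kin.k_deg * RBp
    return dy


def simulate_competition(kin: KineticParams, op: OperonParams,
                         comp: CompetitionParams, input: PhosphataseInput,
                         horizon: float, y0: np.ndarray,
                         t_eval: np.ndarray | None = None,
                         rtol: float = 1e-6, atol: float = 1e-9):
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 1001)

    def rhs(t, y):
        return competition_rhs(y, kin, op, comp, float(input(t)))

    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, None)


def competition_steady_state(kin: KineticParams, op: OperonParams,
                             comp: CompetitionParams, P_T: float,
                             tol: float = 1e-7) -> CompetitionState:
    from .inputs import make_constant

    horizon = 200.0 / kin.k_deg
    _, Y = simulate_competition(kin, op, comp, make_constant(P_T), horizon,
                                np.zeros(N_COMP),
                                t_eval=np.array([0.0, horizon]),
                                rtol=1e-9, atol=1e-11)
    y1 = Y[-1]

    def fun(y):
        return competition_rhs(y, kin, op, comp, P_T)

    sol = root(fun, y1, method="hybr", tol=1e-13)
    y = sol.x
    if np.any(y < -1e-9) or np.max(np.abs(fun(y))) > np.max(np.abs(fun(y1))):
        y = y1
    y = np.clip(y, 0.0, None)
    if np.max(np.abs(fun(y))) > tol:
        raise RuntimeError(
            f"competition steady state did not converge at P_T={P_T}, "
            f"A_T={comp.A_T}")
    return CompetitionState(y, P_T, comp)


def competition_stochastic_run(kin: KineticParams, op: OperonParams,
                               comp: CompetitionParams, bp: BurstParams,
                               A_T_values, n_traces: int = 10,
                               seed: int = 0,
                               min_prominence: float = 0.02) -> dict:
    """Pulse statistics of target promoter activity and free sigma-B
    under gamma-OU phosphatase input, per total-sigma-A level.

    min_prominence is absolute, in activity units (the activity signal
    is already normalized to [0, 1]); the same threshold, scaled by the
    ratio of signal ranges, is applied to free sigma-B.
    """
    out = {}
    root_seq = np.random.SeedSequence(seed)
    for A_T, sseq in zip(np.asarray(A_T_values, float),
                         root_seq.spawn(len(list(A_T_values)))):
        c = comp.replace(A_T=float(A_T))
        ss = competition_steady_state(kin, op, c, bp.mean)
        act_sets, sig_sets = [], []
        exprs = []
        for child in sseq.spawn(n_traces):
            rng = np.random.default_rng(child)
            inp = sample_gamma_ou(bp, rng)
            t, Y = simulate_competition(kin, op, c, inp, bp.T, ss.y,
                                        t_eval=np.linspace(0, bp.T, 1001))
            act = Y[:, _IRBP] / c.p_B_tot
            sig = Y[:, 0]
            keep = t >= 2.0
            act_sets.append(detect_pulses(act[keep], t[keep],
                                          min_prominence=min_prominence,
                                          signal_name="target_activity"))
            sig_prom = min_prominence \
                * max(np.ptp(sig[keep]), 1e-12) \
                / max(np.ptp(act[keep]), 1e-12)
            sig_sets.append(detect_pulses(sig[keep], t[keep],
                                          min_prominence=sig_prom,
                                          signal_name="sigB"))
            exprs.append(float(np.mean(act[keep])))
        out[float(A_T)] = {
            "activity": ensemble_pulse_stats(act_sets),
            "sigB": ensemble_pulse_stats(sig_sets),
            "mean_activity": float(np.mean(exprs)),
        }
    return out


def dose_response_vs_A_T(kin: KineticParams, op: OperonParams,
                         comp: CompetitionParams, mean_P_T: float,
                         A_T_grid) -> dict:
    """Steady-state free sigma-B and target activity vs total sigma-A
    at fixed phosphatase."""
    if mean_P_T <= 0:
        raise ValueError("mean_P_T must be positive")
    sig, act = [], []
    for A_T in np.asarray(A_T_grid, float):
        st = competition_steady_state(kin, op, comp.replace(A_T=float(A_T)),
                                      mean_P_T)
        sig.append(st.sigB_free)
        act.append(st.target_activity)
    return {"A_T": np.asarray(A_T_grid, float), "sigB_free": np.array(sig),
            "target_activity": np.array(act)}


def _rnapol_equilibrium(comp: CompetitionParams, sigB_free: float,
                        sigW_free: float = 0.0) -> dict:
    """Equilibrium partition of core RNApol between sigma-A, sigma-B
    (and optionally a second stress sigma with sigma-B's affinity) and
    the sigma-B target promoter, with free sigma levels clamped."""
    KA = comp.k_da / comp.k_ba
    KB = comp.k_db / comp.k_bb
    Kp = comp.k_dpb / comp.k_bpb

    def excess(R):
        RA = comp.A_T * R / (KA + R)
        RB = sigB_free * R / KB
        RW = sigW_free * R / KB
        RBp = RB * comp.p_B_tot / (Kp + RB) if RB > 0 else 0.0
        return comp.RNApol_tot - R - RA - RB - RW - RBp

    R = brentq(excess, 0.0, comp.RNApol_tot, xtol=1e-14)
    RA = comp.A_T * R / (KA + R)
    RB = sigB_free * R / KB
    RW = sigW_free * R / KB
    RBp = RB * comp.p_B_tot / (Kp + RB) if RB > 0 else 0.0
    return {"R": R, "RA": RA, "RB": RB, "RW": RW, "RBp": RBp,
            "activity": RBp / comp.p_B_tot}


def half_max_K_sigB(comp: CompetitionParams, A_T: float | None = None,
                    sigW_free: float = 0.0,
                    sigma_grid: np.ndarray | None = None) -> float:
    """Half-maximal free sigma-B of the sigma-B -> target-expression
    dose-response at a fixed competitor background.

    Computed on the clamped-sigma equilibrium partition; K_sigB is the
    free sigma-B at which target activity reaches half its value at the
    top of the scanned range.
    """
    c = comp if A_T is None else comp.replace(A_T=float(A_T))
    if sigma_grid is None:
        sigma_grid = np.geomspace(1e-3, 50.0, 200)
    act = np.array([_rnapol_equilibrium(c, float(s), sigW_free)["activity"]
                    for s in sigma_grid])
    half = 0.5 * act[-1]
    i = int(np.searchsorted(act, half))
    if i == 0 or i >= len(sigma_grid):
        raise RuntimeError("half-max outside the scanned sigma range")
    # log-linear interpolation
    x0, x1 = np.log(sigma_grid[i - 1]), np.log(sigma_grid[i])
    y0, y1 = act[i - 1], act[i]
    return float(np.exp(x0 + (half - y0) * (x1 - x0) / (y1 - y0)))


# ---------------------------------------------------------------------------
# phenomenological three-sigma model


def phenom_free_sigma(S_T: float, P: float, pp: PhenomSigmaParams):
    """sigma_free = S_T / (1 + (S_T/K)^nb / P^mb).

    For nb > 0 the curve is non-monotonic in S_T (negative-feedback
    regime); for nb = 0 it is strictly increasing (no titration).
    P = 0 with nb > 0 gives the limit sigma_free = 0.
    """
    S_T = np.asarray(S_T, float)
    if np.any(S_T < 0):
        raise ValueError("S_T must be nonnegative")
    if pp.nb > 0 and np.any(np.asarray(P) <= 0):
        if np.any(np.asarray(P) < 0):
            raise ValueError("P must be nonnegative")
        return S_T * 0.0  # titration fully wins without signaling protein
    with np.errstate(divide="ignore"):
        denom = 1.0 + (S_T / pp.K) ** pp.nb / np.asarray(P, float) ** pp.mb
    out = S_T / denom
    return float(out) if out.ndim == 0 else out


# Default constants for the reduced three-sigma model.  The sigma
# totals here run at tens of uM (production saturates near
# v0(1+f)/k_deg per module), so the full model's nM-scale promoter
# affinity would pin every promoter at saturation and extinguish the
# transcriptional feedback, and a 0.02 uM sigma-A-RNApol affinity
# would make the housekeeping holoenzyme an effectively perfect
# polymerase buffer that supplies all demand by itself.  Both
# affinities are therefore rescaled to the model's concentration
# scale: sigma-A keeps a stronger polymerase affinity than the stress
# sigmas (0.8 vs 1.2 uM), and promoter occupancy sits in its sensitive
# 10-40% range.
def three_sigma_defaults() -> "CompetitionParams":
    return CompetitionParams(A_T=12.0, k_da=576.0, k_dpb=2160.0)


# Three-sigma model state: only the two stress-sigma totals evolve
# (production minus dilution, exactly as the mechanistic totals do);
# the post-translational titration (phenomenological formula) and the
# RNApol/promoter binding partition are treated as quasi-static.


def _partition_stress_sigma(comp: CompetitionParams, avail: float,
                            R: float) -> tuple[float, float, float]:
    """Split an available stress-sigma pool into free / holoenzyme /
    promoter-bound forms at free-RNApol level R (binding equilibrium)."""
    KB = comp.k_db / comp.k_bb
    Kp = comp.k_dpb / comp.k_bpb
    if avail <= 0 or R <= 0:
        return max(avail, 0.0), 0.0, 0.0

    def excess(RS):
        RSp = comp.p_B_tot * RS / (Kp + RS)
        return RS * KB / R + RS + RSp - avail

    hi = avail
    RS = brentq(excess, 0.0, hi, xtol=1e-15)
    RSp = comp.p_B_tot * RS / (Kp + RS)
    return avail - RS - RSp, RS, RSp


def three_sigma_partition(comp: CompetitionParams, avail_B: float,
                          avail_W: float) -> dict:
    """Equilibrium partition of core RNApol between sigma-A and the
    available (untitrated) stress-sigma pools."""
    KA = comp.k_da / comp.k_ba

    def excess(R):
        RA = comp.A_T * R / (KA + R)
        _, RB, RBp = _partition_stress_sigma(comp, avail_B, R)
        _, RW, RWp = _partition_stress_sigma(comp, avail_W, R)
        return comp.RNApol_tot - R - RA - RB - RBp - RW - RWp

    R = brentq(excess, 0.0, comp.RNApol_tot, xtol=1e-14)
    RA = comp.A_T * R / (KA + R)
    sigB, RB, RBp = _partition_stress_sigma(comp, avail_B, R)
    sigW, RW, RWp = _partition_stress_sigma(comp, avail_W, R)
    return {"R": R, "RA": RA, "RB": RB, "RBp": RBp, "RW": RW, "RWp": RWp,
            "sigB_free": sigB, "sigW_free": sigW}


def _three_sigma_rhs(y, kin, op, comp, pp_B, pp_W, P_B, P_W):
    B_T, W_T = y
    avail_B = float(phenom_free_sigma(B_T, P_B, pp_B))
    avail_W = float(phenom_free_sigma(W_T, P_W, pp_W))
    part = three_sigma_partition(comp, avail_B, avail_W)
    v_max = op.v0 * op.f / comp.p_B_tot
    dB_T = op.v0 + v_max * part["RBp"] - kin.k_deg * B_T
    dW_T = op.v0 + v_max * part["RWp"] - kin.k_deg * W_T
    return np.array([dB_T, dW_T])


def three_sigma_steady_state(kin: KineticParams, op: OperonParams,
                             comp: CompetitionParams,
                             pp_B: PhenomSigmaParams,
                             pp_W: PhenomSigmaParams,
                             P_B: float, P_W: float,
                             y0: np.ndarray | None = None) -> dict:
    """Steady state of the three-sigma model at one (P_B, P_W)."""
    if y0 is None:
        y0 = np.array([1.0, 1.0])
    horizon = 200.0 / kin.k_deg

    def rhs(t, y):
        return _three_sigma_rhs(y, kin, op, comp, pp_B, pp_W, P_B, P_W)

    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                    t_eval=[horizon], rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"three-sigma integration failed: {sol.message}")
    y = np.clip(sol.y[:, -1], 0.0, None)
    res = np.max(np.abs(rhs(0.0, y)))
    if res > 1e-6:
        raise RuntimeError(f"three-sigma steady state residual {res:.2e}")
    B_T, W_T = y
    part = three_sigma_partition(
        comp, float(phenom_free_sigma(B_T, P_B, pp_B)),
        float(phenom_free_sigma(W_T, P_W, pp_W)))
    return {
        "y": y,
        "B_T": B_T, "W_T": W_T,
        "sigB_free": part["sigB_free"],
        "sigW_free": part["sigW_free"],
        "Rpol_sigA": part["RA"], "Rpol_sigB": part["RB"],
        "Rpol_sigW": part["RW"], "Rpol_free": part["R"],
        "activity_B": part["RBp"] / comp.p_B_tot,
        "activity_W": part["RWp"] / comp.p_B_tot,
    }


def three_sigma_response(kin: KineticParams, op: OperonParams,
                         comp: CompetitionParams,
                         pp_B: PhenomSigmaParams, pp_W: PhenomSigmaParams,
                         P_B_grid, P_W: float = 2.0) -> dict:
    """Steady states over a P_B grid at fixed P_W, with the RNApol
    partition deltas referenced to the smallest P_B."""
    P_B_grid = np.sort(np.asarray(P_B_grid, float))
    rows = []
    y0 = None
    for P_B in P_B_grid:
        st = three_sigma_steady_state(kin, op, comp, pp_B, pp_W,
                                      float(P_B), P_W, y0=y0)
        y0 = st["y"]
        rows.append(st)
    base = rows[0]
    out = {k: np.array([r[k] for r in rows])
           for k in ("sigB_free", "sigW_free", "Rpol_sigA", "Rpol_sigB",
                     "Rpol_sigW", "Rpol_free", "activity_B", "activity_W",
                     "B_T", "W_T")}
    out["P_B"] = P_B_grid
    out["delta_Rpol_sigA"] = out["Rpol_sigA"] - base["Rpol_sigA"]
    out["delta_Rpol_sigW"] = out["Rpol_sigW"] - base["Rpol_sigW"]
    out["delta_Rpol_free"] = out["Rpol_free"] - base["Rpol_free"]
    out["delta_Rpol_sigB"] = out["Rpol_sigB"] - base["Rpol_sigB"]
    return out
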