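"""Mass-action ODE model of the sigma-B partner-switching network.

Explicit species (uM):

    sigB    free sigma-B
    W       RsbW monomer
    W2      RsbW dimer (the active anti-sigma / kinase unit)
    V       unphosphorylated RsbV
    VP      phosphorylated RsbV (RsbV~P)
    W2sigB  RsbW2 . sigma-B complex
    W2V     RsbW2 . RsbV complex
    W2V2    RsbW2 . (RsbV)2 complex
    VPP     RsbV~P . phosphatase complex

Free phosphatase is eliminated through the conservation
[P] = P_T(t) - [VPP]; P_T is an external input.  The right-hand side is
assembled term by term from the elementary reactions (dimerization,
complex association/dissociation, phosphorylation, partner
displacement, dephosphorylation, uniform first-order degradation, and
co-production of sigma-B : RsbW : RsbV at 1 : lambda_W : lambda_V from
the autoregulated operon), so the total-concentration identities

    d[B_T]/dt     = v_B - k_deg [B_T]
    d[RsbW_T]/dt  = lambda_W v_B - k_deg [RsbW_T]
    d[RsbV_T]/dt  = lambda_V v_B - k_deg [RsbV_T]

hold exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .inputs import PhosphataseInput, make_constant
from .params import KineticParams, OperonParams

__all__ = [
    "SPECIES",
    "NetworkState",
    "Trajectory",
    "operon_synthesis_rate",
    "reaction_rhs",
    "simulate",
    "steady_state",
    "conservation_residuals",
]

SPECIES = ("sigB", "W", "W2", "V", "VP", "W2sigB", "W2V", "W2V2", "VPP")
_IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)


@dataclass(frozen=True)
class NetworkState:
    """One point in concentration space, with the totals derived from it."""

    y: np.ndarray          # length-9 vector in SPECIES order, uM
    P_T: float = 0.0       # total phosphatase at this instant, uM

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.shape != (N_SPECIES,):
            raise ValueError(f"state vector must have length {N_SPECIES}")
        object.__setattr__(self, "y", y)

    def __getattr__(self, name):
        try:
            return self.y[_IDX[name]]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def P(self) -> float:
        """Free phosphatase from the conservation [P] = P_T - [VPP]."""
        return max(self.P_T - self.y[_IDX["VPP"]], 0.0)

    @property
    def B_T(self) -> float:
        return self.sigB + self.W2sigB

    @property
    def RsbW_T(self) -> float:
        return self.W + 2 * (self.W2 + self.W2sigB + self.W2V + self.W2V2)

    @property
    def RsbV_T(self) -> float:
        return self.V + self.W2V + 2 * self.W2V2 + self.VP + self.VPP

    @classmethod
    def zeros(cls, P_T: float = 0.0) -> "NetworkState":
        return cls(np.zeros(N_SPECIES), P_T)

    @classmethod
    def from_dict(cls, d: dict, P_T: float = 0.0) -> "NetworkState":
        return cls(np.array([d.get(s, 0.0) for s in SPECIES], float), P_T)


def operon_synthesis_rate(sigB_free: float, op: OperonParams) -> float:
    """Autoregulated operon firing rate v_B = v0 (1 + f sig/(K+sig))."""
    s = np.asarray(sigB_free, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigB_free must be nonnegative")
    out = op.v0 * (1.0 + op.f * s / (op.K + s))
    return float(out) if out.ndim == 0 else out


def reaction_rhs(y: np.ndarray, kin: KineticParams, op: OperonParams,
                 P_T: float, v_B: float | None = None) -> np.ndarray:
    """Time derivative of the explicit species at total phosphatase P_T.

    If v_B is given the operon fires at that constant rate
    (autoregulation disabled); otherwise v_B follows from free sigma-B.
    """
    sigB, W, W2, V, VP, W2sigB, W2V, W2V2, VPP = y
    P = max(P_T - VPP, 0.0)
    if v_B is None:
        v_B = op.v0 * (1.0 + op.f * sigB / (op.K + sigB))

    r_dim_f = kin.k_bw * W * W           # 2W -> W2
    r_dim_b = kin.k_dw * W2
    r1f = kin.k_b1 * W2 * V              # W2 + V -> W2V
    r1b = kin.k_d1 * W2V
    r2f = kin.k_b2 * W2V * V             # W2V + V -> W2V2
    r2b = kin.k_d2 * W2V2
    rk1 = kin.k_k1 * W2V                 # W2V -> W2 + VP
    rk2 = kin.k_k2 * W2V2                # W2V2 -> W2V + VP
    r3f = kin.k_b3 * W2 * sigB           # W2 + sigB -> W2sigB
    r3b = kin.k_d3 * W2sigB
    r4f = kin.k_b4 * W2sigB * V          # W2sigB + V -> W2V + sigB
    r4b = kin.k_d4 * W2V * sigB
    r5f = kin.k_b5 * VP * P              # VP + P -> VPP
    r5b = kin.k_d5 * VPP
    rp = kin.k_p * VPP                   # VPP -> V + P

    kd = kin.k_deg
    dy = np.empty(N_SPECIES)
    dy[_IDX["sigB"]] = v_B - r3f + r3b + r4f - r4b - kd * sigB
    dy[_IDX["W"]] = op.lambda_W * v_B - 2 * r_dim_f + 2 * r_dim_b - kd * W
    dy[_IDX["W2"]] = (r_dim_f - r_dim_b - r1f + r1b + rk1
                      - r3f + r3b - kd * W2)
    dy[_IDX["V"]] = (op.lambda_V * v_B - r1f + r1b - r2f + r2b
                     - r4f + r4b + rp - kd * V)
    dy[_IDX["VP"]] = rk1 + rk2 - r5f + r5b - kd * VP
    dy[_IDX["W2sigB"]] = r3f - r3b - r4f + r4b - kd * W2sigB
    dy[_IDX["W2V"]] = (r1f - r1b - r2f + r2b + rk2 - rk1
                       + r4f - r4b - kd * W2V)
    dy[_IDX["W2V2"]] = r2f - r2b - rk2 - kd * W2V2
    dy[_IDX["VPP"]] = r5f - r5b - rp - kd * VPP
    return dy


@dataclass
class Trajectory:
    """Simulated time course on a user grid."""

    t: np.ndarray                  # hr, strictly increasing
    y: np.ndarray                  # (n_t, 9) concentrations, uM
    input: PhosphataseInput        # the P_T(t) record used
    seed: int | None = None

    def __getitem__(self, species: str) -> np.ndarray:
        return self.y[:, _IDX[species]]

    @property
    def P_T(self) -> np.ndarray:
        return np.asarray(self.input(self.t), dtype=float)

    @property
    def B_T(self) -> np.ndarray:
        return self["sigB"] + self["W2sigB"]

    @property
    def RsbW_T(self) -> np.ndarray:
        return self["W"] + 2 * (self["W2"] + self["W2sigB"]
                                + self["W2V"] + self["W2V2"])

    @property
    def RsbV_T(self) -> np.ndarray:
        return (self["V"] + self["W2V"] + 2 * self["W2V2"]
                + self["VP"] + self["VPP"])

    def state_at(self, i: int) -> NetworkState:
        return NetworkState(self.y[i], float(self.P_T[i]))

    def target_promoter_activity(self, K: float) -> np.ndarray:
        """Occupancy sig/(K+sig) of a sigma-B target promoter."""
        s = self["sigB"]
        return s / (K + s)


def simulate(kin: KineticParams, op: OperonParams, input: PhosphataseInput,
             horizon: float, init: NetworkState | np.ndarray,
             t_eval: np.ndarray | None = None, rtol: float = 1e-8,
             atol: float = 1e-10, v_B: float | None = None,
             seed: int | None = None) -> Trajectory:
    """Integrate the stiff network ODEs under a time-varying P_T(t)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    y0 = init.y if isinstance(init, NetworkState) else np.asarray(init, float)
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 501)

    def rhs(t, y):
        return reaction_rhs(y, kin, op, float(input(t)), v_B=v_B)

    sol = solve_ivp(rhs, (0.0, horizon), y0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else 0.0:.3f}"
            f" hr: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)   # negatives only at tolerance level
    if seed is None:
        seed = getattr(input, "seed", None)
    return Trajectory(t=sol.t, y=y, input=input, seed=seed)


def steady_state(kin: KineticParams, op: OperonParams, P_T: float,
                 v_B: float | None = None, tol: float = 1e-8,
                 init: np.ndarray | None = None) -> NetworkState:
    """Steady state at constant P_T: long integration, then root refinement.

    Raises if the refined residual ||rhs||_inf exceeds tol (uM/hr).
    """
    if P_T < 0:
        raise ValueError("P_T must be nonnegative")
    if init is None:
        init = np.zeros(N_SPECIES)
    horizon = 200.0 / kin.k_deg
    inp = make_constant(P_T)
    traj = simulate(kin, op, inp, horizon, init,
                    t_eval=np.array([0.0, horizon]), v_B=v_B)
    y1 = traj.y[-1]

    def fun(y):
        return reaction_rhs(y, kin, op, P_T, v_B=v_B)

    sol = root(fun, y1, method="hybr", tol=1e-13)
    y = sol.x
    if np.any(y < -1e-9) or np.max(np.abs(fun(y))) > tol:
        # fall back to the integrated endpoint if the refinement wandered
        y = y1
    y = np.clip(y, 0.0, None)
    res = np.max(np.abs(fun(y)))
    if res > tol:
        raise RuntimeError(
            f"steady state did not converge (residual {res:.2e} uM/hr) for "
            f"P_T={P_T}, v_B={v_B}, lambda_W={op.lambda_W}, "
            f"lambda_V={op.lambda_V}")
    return NetworkState(y, P_T)


def conservation_residuals(state: NetworkState, B_T: float | None = None,
                           RsbW_T: float | None = None,
                           RsbV_T: float | None = None,
                           P_T: float | None = None) -> np.ndarray:
    """Relative residuals of the four conservation identities.

    With no reference totals supplied, the totals are recomputed from
    the state itself and the sigma-B/W/V residuals vanish identically;
    pass independently tracked totals to check a trajectory.  Each
    residual is normalized by its total (residual 0 where the total is 0).
    """
    refs = [B_T if B_T is not None else state.B_T,
            RsbW_T if RsbW_T is not None else state.RsbW_T,
            RsbV_T if RsbV_T is not None else state.RsbV_T,
            P_T if P_T is not None else state.P_T]
    vals = [state.sigB + state.W2sigB,
            state.W + 2 * (state.W2 + state.W2sigB + state.W2V + state.W2V2),
            state.V + state.W2V + 2 * state.W2V2 + state.VP + state.VPP,
            state.P + state.VPP]
    out = np.zeros(4)
    for i, (v, r) in enumerate(zip(vals, refs)):
        if r > 0:
            out[i] = (v - r) / r
        else:
            out[i] = v
    return out
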