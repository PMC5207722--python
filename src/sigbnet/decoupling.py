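"""Decoupled post-translational / transcriptional analysis.

The closed feedback loop is cut into two open-loop response functions:

* post-translational  F_P: (B_T, P_T) -> free sigma-B, computed by
  firing the operon at a fixed rate v (autoregulation off) so that the
  steady-state totals are B_T = v/k_deg, RsbW_T = lambda_W v/k_deg,
  RsbV_T = lambda_V v/k_deg, and reading off free sigma-B;
* transcriptional     F_T: free sigma-B -> B_T, the closed form
  v0 (1 + f sig/(K+sig)) / k_deg.

The logarithmic gain LG_P = d log sigB / d log B_T along F_P, evaluated
at the closed-loop steady state, gives the effective feedback sign
(F_T is increasing, so the loop sign is the sign of LG_P) and its
magnitude the degree of ultrasensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .inputs import make_step
from .model import NetworkState, simulate, steady_state
from .params import KineticParams, OperonParams

__all__ = [
    "ResponseCurve",
    "RegionLabel",
    "ThresholdResult",
    "post_translational_response",
    "transcriptional_response",
    "closed_loop_steady_state",
    "logarithmic_gain",
    "classify_region",
    "analytic_region_boundaries",
    "phosphatase_threshold",
    "step_pulse_amplitude",
]

log = logging.getLogger(__name__)

REGION_DEAD_ZONE = 0.05   # |LG_P| below this counts as non-responsive


@dataclass
class ResponseCurve:
    """(abscissa, ordinate) pairs for one decoupled response."""

    x: np.ndarray
    y: np.ndarray
    role: str                       # "post_translational" | "transcriptional"
    context: dict

    def interp_log(self, x0: float) -> float:
        """Log-log interpolation of the ordinate at x0 (for gains)."""
        pos = self.y > 0
        return float(np.exp(np.interp(np.log(x0), np.log(self.x[pos]),
                                      np.log(self.y[pos]))))


@dataclass(frozen=True)
class RegionLabel:
    label: str     # "I" | "II" | "III"
    LG_P: float


@dataclass(frozen=True)
class ThresholdResult:
    numeric: float            # uM, from bisection over step simulations
    analytic: float           # printed strong-binding approximation
    basal_B_T: float          # v0 / k_deg, uM


def _fixed_v_steady(kin: KineticParams, op: OperonParams, v: float,
                    P_T: float, init=None) -> NetworkState:
    return steady_state(kin, op, P_T, v_B=v, init=init)


def post_translational_response(kin: KineticParams, op: OperonParams,
                                P_T: float,
                                v_grid: np.ndarray | None = None
                                ) -> ResponseCurve:
    """F_P at fixed P_T, parameterized by the constant operon rate v.

    B_T on the abscissa is v/k_deg; the curve is scanned in v (monotone
    in B_T) so folds in sigma-B never fold the parameterization.
    """
    if v_grid is None:
        v_grid = np.geomspace(0.02, 40.0, 60)
    v_grid = np.asarray(v_grid, float)
    if np.any(np.diff(v_grid) <= 0) or np.any(v_grid <= 0):
        raise ValueError("v_grid must be positive and increasing")
    B_T, sig = [], []
    init = None
    for v in v_grid:
        try:
            st = _fixed_v_steady(kin, op, float(v), P_T, init=init)
        except RuntimeError as err:
            log.warning("dropping v=%.3g: %s", v, err)
            continue
        init = st.y
        B_T.append(st.B_T)
        sig.append(st.sigB)
    return ResponseCurve(np.array(B_T), np.array(sig), "post_translational",
                         {"P_T": P_T, "lambda_W": op.lambda_W,
                          "lambda_V": op.lambda_V})


def transcriptional_response(op: OperonParams, kin: KineticParams,
                             sigma_grid: np.ndarray) -> ResponseCurve:
    """F_T in closed form: B_T = v0 (1 + f sig/(K+sig)) / k_deg."""
    s = np.asarray(sigma_grid, float)
    if np.any(s < 0):
        raise ValueError("sigma_grid must be nonnegative")
    B_T = op.v0 * (1.0 + op.f * s / (op.K + s)) / kin.k_deg
    return ResponseCurve(s, B_T, "transcriptional",
                         {"v0": op.v0, "f": op.f, "K": op.K})


def closed_loop_steady_state(kin: KineticParams, op: OperonParams,
                             P_T: float) -> tuple[float, float]:
    """Intersection of F_P and F_T: returns (free sigma-B, B_T).

    Solved as a root of g(v) = v_B(F_P(v/k_deg, P_T)) - v on the operon
    rate axis, which is where the two curves cross.
    """
    def g(v):
        st = _fixed_v_steady(kin, op, v, P_T)
        return op.v0 * (1.0 + op.f * st.sigB / (op.K + st.sigB)) - v

    v_lo, v_hi = op.v0 * 0.999 if op.v0 > 0 else 1e-6, op.v0 * (1.0 + op.f) * 1.001
    if op.f == 0:
        st = _fixed_v_steady(kin, op, op.v0, P_T)
        return st.sigB, st.B_T
    g_lo = g(v_lo)
    if g_lo < 0:   # already above the fixed point at basal rate
        raise RuntimeError("no intersection found on the scanned range")
    v_star = brentq(g, v_lo, v_hi, xtol=1e-12, rtol=1e-12)
    st = _fixed_v_steady(kin, op, v_star, P_T)
    return st.sigB, st.B_T


def logarithmic_gain(curve: ResponseCurve, at_B_T: float,
                     rel_step: float = 0.01) -> float:
    """Centered finite difference of log(ordinate) vs log(abscissa).

    Uses log-log interpolation along the curve; exact for power laws.
    """
    if at_B_T <= 0 or at_B_T < curve.x.min() or at_B_T > curve.x.max():
        raise ValueError("at_B_T outside the curve support")
    y0 = curve.interp_log(at_B_T)
    if y0 <= 0:
        raise ValueError("ordinate is zero near the point; gain undefined")
    xl = at_B_T * (1.0 - rel_step)
    xr = at_B_T * (1.0 + rel_step)
    xl = max(xl, curve.x.min())
    xr = min(xr, curve.x.max())
    yl, yr = curve.interp_log(xl), curve.interp_log(xr)
    return float((np.log(yr) - np.log(yl)) / (np.log(xr) - np.log(xl)))


def logarithmic_gain_exact(kin: KineticParams, op: OperonParams, P_T: float,
                           at_B_T: float, rel_step: float = 0.01) -> float:
    """LG_P by solving the two flanking fixed-v steady states directly
    (no curve interpolation); used where precision matters."""
    vals = []
    for fac in (1.0 - rel_step, 1.0 + rel_step):
        v = at_B_T * kin.k_deg * fac
        st = _fixed_v_steady(kin, op, v, P_T)
        vals.append((np.log(st.B_T), np.log(max(st.sigB, 1e-300))))
    (x0, y0), (x1, y1) = vals
    return float((y1 - y0) / (x1 - x0))


RELEASE_FLOOR = 0.15   # min releasable free-sigma-B fraction of B_T for a
                       # responsive network: the strong-binding releasable
                       # fraction is ~(2 + lambda_V - lambda_W)/2, so 0.15
                       # sits inside its drop across one unit of lambda_W


def classify_region(lambda_W: float, lambda_V: float, kin: KineticParams,
                    op: OperonParams, P_T_ref: float = 0.5) -> RegionLabel:
    """Feedback-sign region of a (lambda_W, lambda_V) pair.

    LG_P is evaluated on the post-translational curve at the closed-loop
    steady state under P_T_ref.  I: LG_P > +0.05 (positive feedback),
    II: LG_P < -0.05 (negative feedback), III otherwise.  A network
    where free sigma-B never exceeds RELEASE_FLOOR of B_T anywhere on
    the post-translational curve is non-responsive (III) regardless of
    the local slope: with RsbW in excess of all its binding partners the
    phosphatase cannot release sigma-B, which is the strong-binding
    criterion behind the upper region boundary.
    """
    if P_T_ref <= 0:
        raise ValueError("P_T_ref must be positive")
    o = op.replace(lambda_W=lambda_W, lambda_V=lambda_V)
    _, B_T = closed_loop_steady_state(kin, o, P_T_ref)
    lg = logarithmic_gain_exact(kin, o, P_T_ref, B_T)
    # maximum releasable sigma-B fraction along the curve
    v_grid = np.geomspace(0.25 * op.v0, op.v0 * (1.0 + op.f), 12)
    frac = 0.0
    for v in v_grid:
        try:
            st = _fixed_v_steady(kin, o, float(v), P_T_ref)
        except RuntimeError:
            continue
        if st.B_T > 0:
            frac = max(frac, st.sigB / st.B_T)
    if frac < RELEASE_FLOOR or abs(lg) <= REGION_DEAD_ZONE:
        label = "III"
    elif lg > 0:
        label = "I"
    else:
        label = "II"
    return RegionLabel(label, lg)


def analytic_region_boundaries(kin: KineticParams):
    """The two strong-binding boundary lines lambda_W(lambda_V).

    Lower line lambda_W = 2 (1 + lambda_V k_deg / k_k) separates the
    always-free regime (I) from the phosphatase-controlled regime (II);
    upper line lambda_W = 2 + lambda_V separates II from the
    RsbW-saturated, non-responsive regime (III).
    """
    k_k = kin.k_k1

    def lower(lv):
        return 2.0 * (1.0 + np.asarray(lv, float) * kin.k_deg / k_k)

    def upper(lv):
        return 2.0 + np.asarray(lv, float)

    return lower, upper


def step_pulse_amplitude(kin: KineticParams, op: OperonParams, P_step: float,
                         horizon: float = 10.0, n_t: int = 801) -> float:
    """Amplitude (max free sigma-B minus initial) of the response to a
    step 0 -> P_step applied at the unstressed steady state."""
    ss0 = steady_state(kin, op, 0.0)
    tr = simulate(kin, op, make_step(0.0, P_step, 0.0), horizon, ss0,
                  t_eval=np.linspace(0.0, horizon, n_t))
    s = tr["sigB"]
    return float(s.max() - s[0])


def is_pulsing(kin: KineticParams, op: OperonParams, P_step: float = 0.5,
               min_amplitude: float = 0.03, min_adaptation: float = 0.15,
               horizon: float = 15.0) -> bool:
    """Whether a phosphatase step elicits an adaptive sigma-B pulse.

    A pulse requires a peak excursion of at least min_amplitude (uM)
    that subsequently relaxes by at least min_adaptation of its height
    (distinguishing an adaptive transient from the monotone rise of
    positive-feedback networks and from the negligible excursions of
    RsbW-saturated ones).
    """
    ss0 = steady_state(kin, op, 0.0)
    tr = simulate(kin, op, make_step(0.0, P_step, 0.0), horizon, ss0,
                  t_eval=np.linspace(0.0, horizon, 601))
    s = tr["sigB"]
    amp = float(s.max() - s[0])
    if amp < min_amplitude:
        return False
    return float(s.max() - s[-1]) >= min_adaptation * amp


def region_map(kin: KineticParams, op: OperonParams, lambda_W_grid,
               lambda_V_grid, P_T_ref: float = 0.5):
    """Classify every grid point; returns a pandas DataFrame
    (lambda_W, lambda_V, LG_P, label)."""
    import pandas as pd

    rows = []
    for lv in np.asarray(lambda_V_grid, float):
        for lw in np.asarray(lambda_W_grid, float):
            r = classify_region(lw, lv, kin, op, P_T_ref)
            rows.append({"lambda_W": lw, "lambda_V": lv,
                         "LG_P": r.LG_P, "label": r.label})
    return pd.DataFrame(rows)


def analytic_threshold(kin: KineticParams, op: OperonParams) -> float:
    """Printed strong-binding approximation of the pulsing threshold,
    P_T* = v0 k_k (lambda_W/2 - 1 - lambda_W k_deg/k_k) / (k_p/k_deg),
    evaluated verbatim (tested only for trend directions)."""
    k_k = kin.k_k1
    return (op.v0 * k_k
            * (op.lambda_W / 2.0 - 1.0 - op.lambda_W * kin.k_deg / k_k)
            / (kin.k_p / kin.k_deg))


def phosphatase_threshold(kin: KineticParams, op: OperonParams,
                          amplitude_floor: float | None = None,
                          P_max: float = 1.0, tol: float = 1e-3
                          ) -> ThresholdResult:
    """Smallest step P_T whose pulse amplitude exceeds the floor.

    Default floor = 1% of the pre-step B_T.  Found by bisection on the
    step amplitude; also reports the analytic approximation.
    """
    basal_B_T = op.v0 / kin.k_deg
    if amplitude_floor is None:
        amplitude_floor = 0.01 * steady_state(kin, op, 0.0).B_T
    if amplitude_floor <= 0:
        raise ValueError("amplitude_floor must be positive")

    def excess(P):
        return step_pulse_amplitude(kin, op, P) - amplitude_floor

    lo, hi = 0.0, P_max
    if excess(hi) < 0:
        raise RuntimeError(f"no threshold found below P_T = {P_max} uM")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(numeric=0.5 * (lo + hi),
                           analytic=analytic_threshold(kin, op),
                           basal_B_T=basal_B_T)
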