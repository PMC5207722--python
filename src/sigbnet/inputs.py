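"""Total-phosphatase inputs P_T(t): deterministic steps/ramps and
stochastic burst trajectories.

The stochastic generator is a gamma-distributed Ornstein-Uhlenbeck
(shot-noise) process: phosphatase is produced in bursts arriving as a
Poisson process, burst sizes are exponential with mean ``b`` (uM), and
the level relaxes exponentially at rate ``gamma`` between bursts.  With
burst frequency ``a`` expressed per cell cycle and ``gamma`` equal to
the inverse cell-cycle time, the stationary law is Gamma(shape=a,
scale=b) and the stationary mean is exactly a*b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhosphataseInput",
    "BurstParams",
    "make_step",
    "make_ramp",
    "make_decaying_step",
    "make_constant",
    "sample_gamma_ou",
    "sweep_mean",
]


@dataclass(frozen=True)
class PhosphataseInput:
    """A callable P_T(t) with a declared kind and provenance metadata."""

    kind: str                      # "step" | "ramp" | "decaying_step" | "trajectory"
    params: dict
    t_grid: np.ndarray | None = None   # trajectory kind only (uniform grid, hr)
    values: np.ndarray | None = None   # trajectory kind only (uM)
    seed: int | None = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "step":
            out = np.where(t < p["t_step"], p["P0"], p["P1"])
        elif self.kind == "ramp":
            t0, dur = p["t0"], p["T_ramp"]
            if dur == 0.0:
                out = np.where(t < t0, p["P0"], p["P1"])
            else:
                frac = np.clip((t - t0) / dur, 0.0, 1.0)
                out = p["P0"] + (p["P1"] - p["P0"]) * frac
        elif self.kind == "decaying_step":
            dt = t - p["t_step"]
            out = np.where(
                dt < 0, p["P0"],
                p["P0"] + (p["P1"] - p["P0"]) * np.exp(-p["decay_rate"] * np.clip(dt, 0, None)),
            )
        elif self.kind == "trajectory":
            out = np.interp(t, self.t_grid, self.values)
        else:  # pragma: no cover
            raise ValueError(f"unknown input kind {self.kind!r}")
        return float(out) if out.ndim == 0 else out

    def to_table(self, path: str | Path, t_grid=None) -> None:
        if self.kind == "trajectory":
            t, v = self.t_grid, self.values
        else:
            t = np.asarray(t_grid, dtype=float)
            v = self(t)
        header = "time_hr\tP_T_uM"
        np.savetxt(path, np.column_stack([t, v]), delimiter="\t",
                   header=header, comments="", fmt="%.17g")

    @classmethod
    def from_table(cls, path: str | Path) -> "PhosphataseInput":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(kind="trajectory", params={},
                   t_grid=arr[:, 0], values=arr[:, 1])


def make_constant(P: float) -> PhosphataseInput:
    return make_step(P, P, 0.0)


def make_step(P0: float, P1: float, t_step: float) -> PhosphataseInput:
    if P0 < 0 or P1 < 0:
        raise ValueError("phosphatase concentrations must be nonnegative")
    return PhosphataseInput("step", {"P0": P0, "P1": P1, "t_step": t_step})


def make_ramp(P0: float, P1: float, t0: float, T_ramp: float) -> PhosphataseInput:
    """Piecewise-linear ramp from P0 to P1 over [t0, t0+T_ramp]."""
    if P0 < 0 or P1 < 0:
        raise ValueError("phosphatase concentrations must be nonnegative")
    if T_ramp < 0:
        raise ValueError("T_ramp must be nonnegative")
    return PhosphataseInput("ramp", {"P0": P0, "P1": P1, "t0": t0,
                                     "T_ramp": T_ramp})


def make_decaying_step(P0: float, P1: float, t_step: float,
                       decay_rate: float) -> PhosphataseInput:
    """Step to P1 followed by exponential relaxation back toward P0
    (dilution of the phosphatase after the initial stress jump)."""
    if P0 < 0 or P1 < 0:
        raise ValueError("phosphatase concentrations must be nonnegative")
    return PhosphataseInput("decaying_step",
                            {"P0": P0, "P1": P1, "t_step": t_step,
                             "decay_rate": decay_rate})


@dataclass(frozen=True)
class BurstParams:
    """Parameters of the gamma-OU burst process.

    a: bursts per cell cycle; b: mean burst size (uM); gamma: relaxation
    rate (hr^-1, default = 1/cell_cycle so that the stationary mean is
    exactly a*b); dt: sampling step (hr); T: duration (hr).
    """

    a: float = 2.0
    b: float = 0.25
    cell_cycle: float = 1.0
    gamma: float | None = None       # None -> 1/cell_cycle
    dt: float = 0.005
    T: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.cell_cycle, self.dt, self.T) <= 0:
            raise ValueError("a, b, cell_cycle, dt, T must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def relaxation_rate(self) -> float:
        return self.gamma if self.gamma is not None else 1.0 / self.cell_cycle

    @property
    def jump_rate(self) -> float:
        """Poisson burst arrival rate per hour."""
        return self.a / self.cell_cycle

    @property
    def mean(self) -> float:
        """Stationary mean = jump_rate * b / gamma."""
        return self.jump_rate * self.b / self.relaxation_rate

    @property
    def stationary_shape(self) -> float:
        return self.jump_rate / self.relaxation_rate

    def replace(self, **kw) -> "BurstParams":
        return replace(self, **kw)


def sample_gamma_ou(bp: BurstParams, rng: np.random.Generator | None = None
                    ) -> PhosphataseInput:
    """Sample one phosphatase trajectory from the gamma-OU burst process.

    Exact pathwise construction on a uniform grid: within each step,
    Poisson-many bursts arrive at uniform times and each contribution is
    decayed by the remaining fraction of the step, so the marginal at
    every grid point follows the stationary Gamma law when started from
    it (the initial value is drawn from that law).
    """
    if rng is None:
        rng = np.random.default_rng(bp.seed)
    lam, g = bp.jump_rate, bp.relaxation_rate
    if bp.dt > 1.0 / (10.0 * lam):
        warnings.warn(
            "sampling step dt is coarse relative to the burst rate; "
            "bursts may alias", stacklevel=2)
    n = int(round(bp.T / bp.dt)) + 1
    t = np.arange(n) * bp.dt
    x = np.empty(n)
    x[0] = rng.gamma(shape=bp.stationary_shape, scale=bp.b)
    decay = np.exp(-g * bp.dt)
    counts = rng.poisson(lam * bp.dt, size=n - 1)
    for i in range(1, n):
        xi = x[i - 1] * decay
        k = counts[i - 1]
        if k:
            u = rng.uniform(0.0, bp.dt, size=k)       # arrival offsets
            jumps = rng.exponential(bp.b, size=k)
            xi += np.sum(jumps * np.exp(-g * (bp.dt - u)))
        x[i] = xi
    return PhosphataseInput("trajectory", {"burst": bp.__dict__.copy()},
                            t_grid=t, values=x, seed=bp.seed)


def sweep_mean(bp0: BurstParams, target_means, mode: str) -> list[BurstParams]:
    """Burst-parameter sets hitting the given stationary means.

    mode="size" holds the burst frequency a fixed and scales b;
    mode="frequency" holds b fixed and scales a.
    """
    out = []
    for m in np.atleast_1d(target_means):
        if m <= 0:
            raise ValueError("target means must be positive")
        scale = float(m) / bp0.mean
        if mode == "size":
            out.append(bp0.replace(b=bp0.b * scale))
        elif mode == "frequency":
            out.append(bp0.replace(a=bp0.a * scale))
        else:
            raise ValueError("mode must be 'size' or 'frequency'")
    return out
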