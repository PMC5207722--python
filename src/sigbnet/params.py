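"""Model parameters for the sigma-B partner-switching network.

All concentrations are in uM and all times in hours throughout the
package; rate constants are uM^-1 hr^-1 (association) or hr^-1
(dissociation / catalytic / first-order).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace, asdict
from pathlib import Path

import yaml

__all__ = [
    "KineticParams",
    "OperonParams",
    "CompetitionParams",
    "PhenomSigmaParams",
    "make_default_params",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the post-translational partner-switching module.

    Defaults are the published reference values for the B. subtilis
    sigma-B network: diffusion-limited association (3600 uM^-1 hr^-1)
    with ~5 nM complex affinities, a slow RsbW kinase (k_k ~ 1e-2 s^-1),
    a faster phosphatase turnover, and dilution at a ~1 hr doubling time.
    """

    k_bw: float = 3600.0   # RsbW dimerization on-rate, uM^-1 hr^-1
    k_dw: float = 18.0     # RsbW2 dissociation, hr^-1
    k_b1: float = 3600.0   # W2 + V -> W2V
    k_d1: float = 18.0
    k_b2: float = 3600.0   # W2V + V -> W2V2
    k_d2: float = 18.0
    k_b3: float = 3600.0   # W2 + sigB -> W2sigB
    k_d3: float = 18.0
    k_b5: float = 3600.0   # VP + P -> VPP
    k_d5: float = 18.0
    k_b4: float = 1800.0   # W2sigB + V -> W2V + sigB (partner displacement)
    k_d4: float = 1800.0   # reverse displacement
    k_k1: float = 36.0     # phosphorylation of V in W2V, hr^-1
    k_k2: float = 36.0     # phosphorylation of V in W2V2, hr^-1
    k_p: float = 180.0     # dephosphorylation catalytic rate, hr^-1
    k_deg: float = 0.7     # degradation/dilution of every species, hr^-1

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    def replace(self, **kw) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class OperonParams:
    """Autoregulated operon synthesis: v_B = v0 * (1 + f*sig/(K+sig)).

    lambda_W and lambda_V are the synthesis rates of RsbW and RsbV
    relative to sigma-B; the operon fires as one unit so the three
    proteins are always co-produced at rates v_B, lambda_W*v_B,
    lambda_V*v_B.
    """

    v0: float = 0.4         # basal transcription, uM hr^-1
    f: float = 30.0         # autoregulatory fold change
    K: float = 0.2          # sigB-promoter affinity, uM
    lambda_W: float = 4.0   # RsbW : sigB relative synthesis
    lambda_V: float = 4.5   # RsbV : sigB relative synthesis

    def __post_init__(self) -> None:
        if self.v0 < 0 or self.f < 0:
            raise ValueError("v0 and f must be nonnegative")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.lambda_W < 0 or self.lambda_V < 0:
            raise ValueError("relative synthesis rates must be nonnegative")

    def replace(self, **kw) -> "OperonParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CompetitionParams:
    """RNA-polymerase competition constants (holoenzyme + promoter binding)."""

    k_bb: float = 720.0      # sigB + RNApol association, uM^-1 hr^-1
    k_db: float = 864.0      # (affinity 1.2 uM)
    k_ba: float = 720.0      # sigA + RNApol association
    k_da: float = 14.4       # (affinity 0.02 uM)
    k_bpb: float = 720.0     # holoenzyme + promoter association
    k_dpb: float = 72.0      # (affinity 0.1 uM)
    p_B_tot: float = 0.05    # sigB target promoter sites, uM
    RNApol_tot: float = 10.0  # total core polymerase, uM
    A_T: float = 10.0        # total housekeeping sigma-A, uM

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "A_T":
                if v < 0:
                    raise ValueError("A_T must be nonnegative")
            elif v <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    def replace(self, **kw) -> "CompetitionParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PhenomSigmaParams:
    """Phenomenological post-translational release of a stress sigma factor.

    sigma_free = S_T / (1 + (S_T/K)^nb / P^mb) where S_T is the total
    sigma pool, P the activating signaling protein.  (nb=7, mb=5)
    reproduces the non-monotonic (negative-feedback) release curve;
    (nb=0, mb=3) is the monotonic positive-feedback variant.
    """

    K: float = 5.0
    nb: float = 7.0
    mb: float = 5.0

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.nb < 0:
            raise ValueError("nb must be nonnegative")
        if self.mb <= 0:
            raise ValueError("mb must be positive")


NEGATIVE_FEEDBACK = PhenomSigmaParams(K=5.0, nb=7.0, mb=5.0)
POSITIVE_FEEDBACK = PhenomSigmaParams(K=5.0, nb=0.0, mb=3.0)


def make_default_params() -> tuple[KineticParams, OperonParams]:
    """Return the reference parameter set (kinetic + operon)."""
    return KineticParams(), OperonParams()


# ---------------------------------------------------------------------------
# config file I/O — flat YAML keyed by the symbol names above

_CLASSES = {"kinetic": KineticParams, "operon": OperonParams,
            "competition": CompetitionParams}


def save_params(path: str | Path, kin: KineticParams, op: OperonParams,
                comp: CompetitionParams | None = None) -> None:
    doc = {"kinetic": asdict(kin), "operon": asdict(op)}
    if comp is not None:
        doc["competition"] = asdict(comp)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: str | Path):
    """Load parameters from YAML; unknown keys raise with the key named."""
    doc = yaml.safe_load(Path(path).read_text())
    out = []
    for section, cls in _CLASSES.items():
        if section not in doc:
            if section == "competition":
                continue
            raise KeyError(f"missing config section: {section}")
        known = {f.name for f in fields(cls)}
        unknown = set(doc[section]) - known
        if unknown:
            raise KeyError(
                f"unknown parameter key(s) in [{section}]: {sorted(unknown)}")
        out.append(cls(**doc[section]))
    return tuple(out)
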