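"""Rate laws and ODE right-hand side of the pyrimidine-biosynthesis model.

Nine state variables (mM): carbamoyl phosphate (cap), carbamoyl aspartate
(casp), dihydroorotate (dho), orotate (oro), orotidine monophosphate (omp),
UMP, UDP, UTP and CTP, connected as a linear enzymatic chain

    -> cap -> casp -> dho <-> oro -> omp -> ump -> udp -> utp -> ctp

with first-order outflows draining udp (V15), utp (V10) and ctp (V11, V12)
into nucleic-acid synthesis, and eight negative-feedback loops through which
the downstream nucleotides throttle five of the enzymes:

    loop 1  UMP --| V1 (CPSase, Hill h_UMP1)
    loop 8  UDP --| V1 (Hill h_UDP1)
    loop 3  UTP --| V1 (Hill h_UTP1)
    loop 4  CTP --| V2 (ATCase; partial, delta_CTP2 < 1)
    loop 5  UTP --| V2 (partial, synergistic with CTP via w2)
    loop 2  ORO --| V4 (DHO dehydrogenase product inhibition)
    loop 6  UTP --| V7 (UMP kinase; r mixes competitive/noncompetitive)
    loop 7  CTP --| V9 (CTP synthetase product inhibition)

All rates are in mM/s. ``x`` is a length-9 sequence in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ExternalPools, KineticParameters

__all__ = [
    "METABOLITES",
    "N_STATES",
    "FEEDBACK_LOOPS",
    "REGULATED_REACTIONS",
    "FeedbackLoop",
    "RateVector",
    "rate_v1", "rate_v2", "rate_v3", "rate_v4", "rate_v5",
    "rate_v6", "rate_v7", "rate_v8", "rate_v9",
    "outflows", "rates", "rhs", "feedback_off",
]

METABOLITES = ("cap", "casp", "dho", "oro", "omp", "ump", "udp", "utp", "ctp")
N_STATES = len(METABOLITES)


@dataclass(frozen=True)
class FeedbackLoop:
    """One negative regulatory loop: ``inhibitor --| reaction``."""

    loop_id: int
    inhibitor: str     # metabolite name
    reaction: str      # "v1".."v9"
    enzyme: str


FEEDBACK_LOOPS = (
    FeedbackLoop(1, "ump", "v1", "carbamoyl-phosphate synthetase"),
    FeedbackLoop(2, "oro", "v4", "dihydroorotate dehydrogenase"),
    FeedbackLoop(3, "utp", "v1", "carbamoyl-phosphate synthetase"),
    FeedbackLoop(4, "ctp", "v2", "aspartate transcarbamoylase"),
    FeedbackLoop(5, "utp", "v2", "aspartate transcarbamoylase"),
    FeedbackLoop(6, "utp", "v7", "UMP kinase"),
    FeedbackLoop(7, "ctp", "v9", "CTP synthetase"),
    FeedbackLoop(8, "udp", "v1", "carbamoyl-phosphate synthetase"),
)

REGULATED_REACTIONS = tuple(sorted({l.reaction for l in FEEDBACK_LOOPS}))


@dataclass(frozen=True)
class RateVector:
    """All reaction and outflow rates at one state (mM/s)."""

    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    v6: float
    v7: float
    v8: float
    v9: float
    v10: float
    v11: float
    v12: float
    v15: float


def _check_finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    return x


def rate_v1(x, p: KineticParameters, ext: ExternalPools) -> float:
    """CPSase flux: IMP-activated, inhibited by UMP/UDP/UTP (loops 1, 8, 3).

    All inhibitors enter one shared denominator additively, so each of them
    alone can throttle the enzyme and the inhibitions are mutually
    competitive at the regulatory site.
    """
    ump, udp, utp = x[5], x[6], x[7]
    num = 1.0 + p.d_IMP * ext.imp / p.Ka_IMP1
    den = (1.0
           + (ump / p.K_UMP1) ** p.h_UMP1
           + ext.imp / p.K_IMP1
           + (udp / p.K_UDP1) ** p.h_UDP1
           + (utp / p.K_UTP1) ** p.h_UTP1)
    return p.k1 * num / den


def rate_v2(x, p: KineticParameters, ext: ExternalPools) -> float:
    """ATCase flux: Hill in carbamoyl phosphate, mixed CTP/UTP/ATP regulation.

    The regulatory factor is a ratio of weighted to unweighted occupancies:
    delta < 1 makes the corresponding ligand a partial inhibitor, delta > 1 an
    activator, and w2 adds CTP·UTP synergy in the denominator only.
    """
    cap, utp, ctp = x[0], x[7], x[8]
    s = (cap / p.Km_CAP2) ** p.h_CAP
    sub = s / (1.0 + s)
    c9 = ctp / p.K_CTP2
    a = ext.atp / p.K_ATP2
    u = utp / p.K_UTP2
    reg = (1.0 + p.d_CTP2 * c9 + p.d_ATP2 * a + p.d_UTP2 * u) / (
        1.0 + c9 + a + u + p.w2 * c9 * u)
    return p.k2 * sub * reg


def rate_v3(x, p: KineticParameters) -> float:
    """Dihydroorotase flux: Michaelis–Menten in carbamoyl aspartate."""
    s = x[1] / p.Km_CAASP3
    return p.k3 * s / (1.0 + s)


def rate_v4(x, p: KineticParameters) -> float:
    """DHO dehydrogenase net flux: reversible, product-inhibited by orotate.

    The dimensionless k4 scales the whole denominator; the sign of the flux
    is the sign of k4f·dho/Km_DHO4 − k4r·oro/Km_ORO4.
    """
    dho, oro = x[2], x[3]
    sf = dho / p.Km_DHO4
    sr = oro / p.Km_ORO4
    num = p.k4f * sf - p.k4r * sr
    den = p.k4 * (1.0 + sf) * (1.0 + oro / p.Ki_ORO4 + sr)
    return num / den


def rate_v5(x, p: KineticParameters) -> float:
    """Orotate phosphoribosyltransferase flux (PRPP saturation in k5prpp)."""
    s = x[3] / p.Km_ORO5
    return p.k5 * s / (p.k5prpp + s)


def rate_v6(x, p: KineticParameters) -> float:
    """OMP decarboxylase flux: Michaelis–Menten in OMP."""
    s = x[4] / p.Km_OMP6
    return p.k6 * s / (1.0 + s)


def rate_v7(x, p: KineticParameters) -> float:
    """UMP kinase flux with mixed-mechanism UTP inhibition (loop 6).

    ``r`` interpolates the mechanism: at r=0 UTP only inflates the apparent
    Km (competitive); at r=1 it only scales Vmax (noncompetitive); in between
    the two branches share the inhibitor with weights (1−r) and r.
    """
    ump, utp = x[5], x[7]
    km_app = p.Km_UMP7 * (1.0 + ((1.0 - p.r) * utp / p.K_UTP72) ** p.h_UTP7)
    vmax_fac = 1.0 / (1.0 + (p.r * utp / p.K_UTP71) ** p.h_UTP7)
    return p.k7 * ump / (km_app + ump) * vmax_fac


def rate_v8(x, p: KineticParameters) -> float:
    """Nucleoside diphosphate kinase flux: Michaelis–Menten in UDP."""
    s = x[6] / p.Km_UDP8
    return p.k8 * s / (1.0 + s)


def rate_v9(x, p: KineticParameters) -> float:
    """CTP synthetase flux: sigmoid in UTP, product-inhibited by CTP (loop 7)."""
    utp, ctp = x[7], x[8]
    sh = utp ** p.h_UTP9
    return p.k9 * sh / (p.Km_UTP9 ** p.h_UTP9 * (1.0 + ctp / p.K_CTP9) + sh)


def outflows(x, p: KineticParameters) -> tuple[float, float, float, float]:
    """First-order outflows (V10, V11, V12, V15) of UTP, CTP, CTP, UDP."""
    return (p.k10 * x[7], p.k11 * x[8], p.k23 * x[8], p.k22 * x[6])


def rates(x, p: KineticParameters, ext: ExternalPools) -> RateVector:
    """Evaluate all thirteen rates at a (validated, clipped) state."""
    x = np.clip(_check_finite(x), 0.0, None)
    v10, v11, v12, v15 = outflows(x, p)
    return RateVector(
        v1=rate_v1(x, p, ext), v2=rate_v2(x, p, ext), v3=rate_v3(x, p),
        v4=rate_v4(x, p), v5=rate_v5(x, p), v6=rate_v6(x, p),
        v7=rate_v7(x, p), v8=rate_v8(x, p), v9=rate_v9(x, p),
        v10=v10, v11=v11, v12=v12, v15=v15,
    )


def rhs(t: float, x, p: KineticParameters, ext: ExternalPools) -> np.ndarray:
    """Time derivative of the state (mM/s).

    Negative components (solver undershoot) are clipped to zero before rate
    evaluation. The chain stoichiometry telescopes:
    sum(dx/dt) = V1 − V10 − V11 − V12 − V15.
    """
    v = rates(x, p, ext)
    return np.array([
        v.v1 - v.v2,
        v.v2 - v.v3,
        v.v3 - v.v4,
        v.v4 - v.v5,
        v.v5 - v.v6,
        v.v6 - v.v7,
        v.v7 - v.v8 - v.v15,
        v.v8 - v.v9 - v.v10,
        v.v9 - v.v12 - v.v11,
    ])


def feedback_off(p: KineticParameters, factor: float = 1e9) -> KineticParameters:
    """Open-loop variant: all feedback affinity constants pushed to ~infinity.

    With every inhibition constant scaled by ``factor`` the eight loops carry
    no signal and the chain reduces to a cascade with a unique stable fixed
    point; useful as a negative control in regime scans.
    """
    return p.replace(
        K_UMP1=p.K_UMP1 * factor,
        K_UDP1=p.K_UDP1 * factor,
        K_UTP1=p.K_UTP1 * factor,
        K_CTP2=p.K_CTP2 * factor,
        K_UTP2=p.K_UTP2 * factor,
        Ki_ORO4=p.Ki_ORO4 * factor,
        K_UTP71=p.K_UTP71 * factor,
        K_UTP72=p.K_UTP72 * factor,
        K_CTP9=p.K_CTP9 * factor,
    )
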