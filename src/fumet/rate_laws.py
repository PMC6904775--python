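"""Closed-form enzyme rate-law kernels.

Three families cover every reaction in the 5-FU metabolism network:

* irreversible Michaelis–Menten,          v = V·S / (Km + S)
* reversible Michaelis–Menten,            v = (Vf·S/Kms − Vr·P/Kmp) / (1 + S/Kms + P/Kmp)
* reversible Ping Pong Bi Bi (Cleland),   see :func:`rate_ping_pong`

Units are µM for concentrations and Michaelis/inhibition constants and µM/h
for maximal rates, so every kernel returns a rate in µM/h.  All kernels are
continuous at zero concentration and finite for any non-negative state; the
all-zero state is a fixed point of each of them.

Each kernel has a matching ``d<kernel>`` function returning the analytic
partial derivatives with respect to the concentrations, used by the metabolic
control analysis (and cross-checked against finite differences in the tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

__all__ = [
    "IrrMMParams",
    "RevMMParams",
    "PingPongParams",
    "rate_irr_mm",
    "rate_rev_mm",
    "rate_ping_pong",
    "d_rate_irr_mm",
    "d_rate_rev_mm",
    "d_rate_ping_pong",
]


def _check_nonneg(**concs: float) -> None:
    for name, value in concs.items():
        if value < 0.0:
            raise ValueError(f"negative concentration {name}={value!r}")


@dataclass(frozen=True)
class IrrMMParams:
    """Irreversible Michaelis–Menten parameters: V (µM/h), Km (µM)."""

    V: float
    Km: float

    def __post_init__(self) -> None:
        if self.V < 0.0:
            raise ValueError(f"V must be >= 0, got {self.V}")
        if self.Km <= 0.0:
            raise ValueError(f"Km must be > 0, got {self.Km}")


@dataclass(frozen=True)
class RevMMParams:
    """Reversible Michaelis–Menten parameters.

    Vf/Vr are the forward/reverse maximal rates (µM/h); Kms/Kmp the
    substrate/product Michaelis constants (µM).
    """

    Vf: float
    Vr: float
    Kms: float
    Kmp: float

    def __post_init__(self) -> None:
        if self.Vf < 0.0 or self.Vr < 0.0:
            raise ValueError("Vf and Vr must be >= 0")
        if self.Kms <= 0.0 or self.Kmp <= 0.0:
            raise ValueError("Kms and Kmp must be > 0")


@dataclass(frozen=True)
class PingPongParams:
    """Reversible Ping Pong Bi Bi parameters (Cleland form).

    Keq is the apparent equilibrium constant (dimensionless in the 1:1:1:1
    stoichiometry used here); Kia/Kiq are inhibition constants, Kma..Kmq the
    apparent Michaelis constants (µM); Vf/Vr the maximal rates (µM/h).
    """

    Keq: float
    Kia: float
    Kiq: float
    Kma: float
    Kmb: float
    Kmp: float
    Kmq: float
    Vf: float
    Vr: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("Vf", "Vr"):
                if v < 0.0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
            elif v <= 0.0:
                raise ValueError(f"{f.name} must be > 0, got {v}")


def rate_irr_mm(S: float, p: IrrMMParams) -> float:
    """Irreversible Michaelis–Menten rate V·S/(Km+S), bounded by V."""
    _check_nonneg(S=S)
    return p.V * S / (p.Km + S)


def d_rate_irr_mm(S: float, p: IrrMMParams) -> float:
    """dv/dS = V·Km/(Km+S)²."""
    _check_nonneg(S=S)
    d = p.Km + S
    return p.V * p.Km / (d * d)


def rate_rev_mm(S: float, P: float, p: RevMMParams) -> float:
    """Reversible Michaelis–Menten net rate.

    (Vf·S/Kms − Vr·P/Kmp) / (1 + S/Kms + P/Kmp); positive in the
    substrate→product direction, zero exactly on the balance manifold
    Vf·S/Kms = Vr·P/Kmp.
    """
    _check_nonneg(S=S, P=P)
    s, q = S / p.Kms, P / p.Kmp
    return (p.Vf * s - p.Vr * q) / (1.0 + s + q)


def d_rate_rev_mm(S: float, P: float, p: RevMMParams) -> tuple[float, float]:
    """(dv/dS, dv/dP) for the reversible Michaelis–Menten rate."""
    _check_nonneg(S=S, P=P)
    s, q = S / p.Kms, P / p.Kmp
    num = p.Vf * s - p.Vr * q
    den = 1.0 + s + q
    dS = (p.Vf / p.Kms * den - num / p.Kms) / (den * den)
    dP = (-p.Vr / p.Kmp * den - num / p.Kmp) / (den * den)
    return dS, dP


def _pp_num_den(A: float, B: float, P: float, Q: float, p: PingPongParams):
    num = p.Vf * p.Vr * (A * B - P * Q / p.Keq)
    den = (
        p.Vr * p.Kmb * A
        + p.Vr * p.Kma * B
        + p.Vr * A * B
        + p.Vf * p.Kmq * P / p.Keq
        + p.Vf * p.Kmp * Q / p.Keq
        + p.Vf * P * Q / p.Keq
        + p.Vr * p.Kma * B * Q / p.Kiq
        + p.Vf * p.Kmq * A * P / (p.Kia * p.Keq)
    )
    return num, den


def rate_ping_pong(A: float, B: float, P: float, Q: float, p: PingPongParams) -> float:
    """Cleland's reversible Ping Pong Bi Bi rate.

    v = Vf·Vr·(A·B − P·Q/Keq) / (Vr·Kmb·A + Vr·Kma·B + Vr·A·B
        + Vf·Kmq·P/Keq + Vf·Kmp·Q/Keq + Vf·P·Q/Keq
        + Vr·Kma·B·Q/Kiq + Vf·Kmq·A·P/(Kia·Keq))

    Zero exactly on the thermodynamic equilibrium manifold A·B = P·Q/Keq;
    saturates at +Vf (A,B→∞ with P=Q=0) and −Vr (P,Q→∞ with A=B=0).  The
    all-zero state returns 0 (fixed point), not an error.
    """
    _check_nonneg(A=A, B=B, P=P, Q=Q)
    num, den = _pp_num_den(A, B, P, Q, p)
    if den == 0.0:
        if num != 0.0:  # pragma: no cover - unreachable for valid params
            warnings.warn("ping-pong denominator underflow; returning 0")
        return 0.0
    return num / den


def d_rate_ping_pong(
    A: float, B: float, P: float, Q: float, p: PingPongParams
) -> tuple[float, float, float, float]:
    """(dv/dA, dv/dB, dv/dP, dv/dQ) by the quotient rule on the Cleland form."""
    _check_nonneg(A=A, B=B, P=P, Q=Q)
    num, den = _pp_num_den(A, B, P, Q, p)
    if den == 0.0:
        # all-zero state: v ≡ 0 along each axis except through the num slope
        den = p.Vr * p.Kmb * 1e-300 + 1e-300  # avoid 0/0; derivative limit is 0
        return 0.0, 0.0, 0.0, 0.0
    dnum = (
        p.Vf * p.Vr * B,
        p.Vf * p.Vr * A,
        -p.Vf * p.Vr * Q / p.Keq,
        -p.Vf * p.Vr * P / p.Keq,
    )
    dden = (
        p.Vr * p.Kmb + p.Vr * B + p.Vf * p.Kmq * P / (p.Kia * p.Keq),
        p.Vr * p.Kma + p.Vr * A + p.Vr * p.Kma * Q / p.Kiq,
        p.Vf * p.Kmq / p.Keq + p.Vf * Q / p.Keq + p.Vf * p.Kmq * A / (p.Kia * p.Keq),
        p.Vf * p.Kmp / p.Keq + p.Vf * P / p.Keq + p.Vr * p.Kma * B / p.Kiq,
    )
    return tuple((dn * den - num * dd) / (den * den) for dn, dd in zip(dnum, dden))
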