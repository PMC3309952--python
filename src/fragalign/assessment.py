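"""Final alignment quality statistics: PSI, z-score, cRMSD, RMSD100.

PSI (percentage of structural similarity) is the share of aligned residue
pairs within 4.0 A after superposition, expressed on the scale of the
shorter chain length k = min(L_Q, L_P).  Its statistical significance is a
z-score against a fitted length-dependent null,

    mu_PSI(k)    = 375.64 * k^-0.5295
    sigma_PSI(k) =  99.67 * k^-0.5885

so unrelated chains of any length score near zero.  cRMSD is normalised to
the value expected for 100-residue chains by RMSD100 = cRMSD/(1+ln(Ne/100));
the denominator crosses zero near Ne ~ 37, below which the raw cRMSD is
reported with a ``short_alignment`` flag instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .superposition import RigidTransform, apply_transform

__all__ = [
    "AlignmentReport",
    "psi",
    "mu_psi",
    "sigma_psi",
    "z_score",
    "rmsd100",
    "RMSD100_MIN_PAIRS",
]

MU_COEF, MU_EXP = 375.64, -0.5295
SIGMA_COEF, SIGMA_EXP = 99.67, -0.5885

#: Below this many aligned pairs the RMSD100 denominator 1 + ln(Ne/100)
#: is non-positive or unstable; the raw cRMSD is reported instead.
RMSD100_MIN_PAIRS = 37


@dataclass(frozen=True)
class AlignmentReport:
    """All statistics of one pairwise comparison."""

    target_id: str
    db_id: str
    L_Q: int
    L_P: int
    Ne: int
    cRMSD: float
    RMSD100: float
    S_a: float
    PSI: float
    z: float
    k: int
    pairs: tuple = ()
    T: RigidTransform | None = None
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.Ne != len(self.pairs):
            raise ValueError("Ne must equal the number of final pairs")
        if not (0.0 <= self.PSI <= 100.0 + 1e-9):
            raise ValueError("PSI must lie in [0, 100]")
        if self.cRMSD < 0:
            raise ValueError("cRMSD must be non-negative")


def psi(pairs, traceQ, traceP, T: RigidTransform | None, cutoff: float = 4.0) -> float:
    """Percentage of pairs within ``cutoff`` after superposition, over k.

    k = min(L_Q, L_P); an empty pair list scores 0.
    """
    k = min(len(traceQ), len(traceP))
    pairs = list(pairs)
    if not pairs or T is None:
        return 0.0
    qi = [q for q, _ in pairs]
    pi = [p for _, p in pairs]
    d = np.linalg.norm(
        apply_transform(T, traceQ.coords[qi]) - traceP.coords[pi], axis=1
    )
    return 100.0 * int(np.count_nonzero(d < cutoff)) / k


def mu_psi(k: int) -> float:
    """Mean PSI of the length-dependent null for minimum chain length k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return MU_COEF * k ** MU_EXP


def sigma_psi(k: int) -> float:
    """Standard deviation of the PSI null for minimum chain length k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return SIGMA_COEF * k ** SIGMA_EXP


def z_score(psi_value: float, k: int) -> float:
    """z = (PSI - mu_PSI(k)) / sigma_PSI(k)."""
    return (psi_value - mu_psi(k)) / sigma_psi(k)


def rmsd100(cRMSD: float, Ne: int) -> float:
    """Length-normalised RMSD expected for 100-residue chains.

    Defined for Ne >= RMSD100_MIN_PAIRS; shorter alignments carry raw
    cRMSD with a flag (handled by the caller).
    """
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    if cRMSD < 0:
        raise ValueError("cRMSD must be non-negative")
    denom = 1.0 + math.log(Ne / 100.0)
    if Ne < RMSD100_MIN_PAIRS or denom <= 0:
        raise ValueError("alignment too short for RMSD100 normalisation")
    return cRMSD / denom
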