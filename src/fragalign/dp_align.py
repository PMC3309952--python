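"""Dynamic-programming alignment with traceback, at fragment and residue level.

One generic aligner serves both stages: fragment-level alignment runs it on
the inverse-cosine similarity submatrix of a seed with a negative gap
penalty, residue-level alignment runs it on the TM-align-style residue
score matrix with gap penalty 0.  End gaps are free: the boundary row and
column are initialised to zero and the optimal score is taken over the last
row and column, so structures of different length align without terminal
penalties.  Tie-breaking during traceback is diagonal > up > left, which
makes paths deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .superposition import apply_transform, qcp_rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentPath",
    "ScoringParams",
    "dp_align",
    "assemble_initial_alignment",
    "d0",
    "residue_similarity_matrix",
    "residue_level_align",
]

from .fragment_model import FRAGMENT_LENGTH


@dataclass(frozen=True)
class ScoringParams:
    """Gap penalties and distance scales shared by the alignment stages.

    G_f: fragment-level gap penalty (<= 0).  G_r: residue-level gap penalty,
    fixed at 0.  d0_min: floor of the TM-score distance scale.  cutoff: the
    4.0 A distance below which a superimposed residue pair counts as
    aligned.
    """

    G_f: float = -0.6
    G_r: float = 0.0
    d0_min: float = 0.5
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.G_f > 0:
            raise ValueError("G_f must be <= 0")
        if self.G_r != 0.0:
            raise ValueError("G_r is fixed at 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class AlignmentPath:
    """An order-preserving list of (row, col) index pairs plus its score."""

    pairs: tuple
    score: float

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            if i2 <= i1 or j2 <= j1:
                raise ValueError("path must be strictly increasing in both indices")
        object.__setattr__(self, "pairs", pairs)


def _fill_gap0(S: np.ndarray) -> np.ndarray:
    """Vectorised fill for gap penalty 0: each row is a running maximum."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        cand = np.maximum(H[i - 1, :m] + S[i - 1], H[i - 1, 1:])
        H[i, 1:] = np.maximum.accumulate(cand)
        # running max already absorbs the left move (gap = 0)
    return H


def _fill_generic(S: np.ndarray, gap: float) -> np.ndarray:
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        Hi = H[i]
        Hp = H[i - 1]
        Si = S[i - 1]
        for j in range(1, m + 1):
            Hi[j] = max(Hp[j - 1] + Si[j - 1], Hi[j - 1] + gap, Hp[j] + gap)
    return H


def dp_align(S: np.ndarray, gap: float = 0.0) -> AlignmentPath:
    """Best order-preserving path through score matrix S with free end gaps.

    Maximises the sum of matched scores plus ``gap`` per skipped interior
    row/column; leading and trailing overhangs are free.  May return an
    empty path (score 0) when every extension scores worse than aligning
    nothing.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("score matrix must be non-empty and 2-D")
    if not np.all(np.isfinite(S)):
        raise ValueError("score matrix must be finite")
    n, m = S.shape

    H = _fill_gap0(S) if gap == 0.0 else _fill_generic(S, gap)

    # Free trailing gaps: best cell on the last row or column.  Ties prefer
    # the cell closest to the corner (largest i+j), then the largest i.
    best = (-np.inf, -1, -1)
    for j in range(m + 1):
        v = H[n, j]
        if (v, n + j, n) > best:
            best = (v, n + j, n)
    for i in range(n + 1):
        v = H[i, m]
        if (v, i + m, i) > best:
            best = (v, i + m, i)
    score, ipj, i = best[0], best[1], best[2]
    j = ipj - i

    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return AlignmentPath(tuple(pairs), float(score))


def assemble_initial_alignment(path: AlignmentPath, L_f: int = FRAGMENT_LENGTH):
    """Expand a fragment-level path into residue index pairs.

    Fragment pair (i, j) becomes residue pairs (i*L_f + t, j*L_f + t) for
    t = 0..L_f-1; concatenation keeps strict monotonicity because fragment
    indices are strictly increasing.
    """
    pairs: list[tuple[int, int]] = []
    for fi, fj in path.pairs:
        base_q = fi * L_f
        base_p = fj * L_f
        pairs.extend((base_q + t, base_p + t) for t in range(L_f))
    return pairs


def d0(L: int, d0_min: float = 0.5) -> float:
    """TM-score distance scale for a chain of L residues (Angstrom).

    d0 = 1.24 (L - 15)^(1/3) - 1.8, floored at ``d0_min`` (the floor covers
    every L <= 15).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 15:
        return d0_min
    return max(1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8, d0_min)


def residue_similarity_matrix(
    movedQ: np.ndarray, coordsP: np.ndarray, d0_val: float
) -> np.ndarray:
    """S_r(i, j) = 1 / (1 + (d_ij / d0)^2) for superimposed Q vs P."""
    d = cdist(movedQ, coordsP)
    return 1.0 / (1.0 + (d / d0_val) ** 2)


def residue_level_align(pairs, traceQ, traceP, params: ScoringParams = ScoringParams()):
    """Refine a residue alignment by superposition plus full-matrix DP.

    Fits the optimal rigid transform over the current pairs, superimposes
    all of Q over P, scores every residue pair with the TM-align function
    (d0 from the shorter chain), and runs the gap-0 DP.  Returns the
    refined pair list and the transform used.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("seed too small: at least 3 residue pairs required")
    qi = [q for q, _ in pairs]
    pi = [p for _, p in pairs]
    _, T = qcp_rmsd(traceQ.coords[qi], traceP.coords[pi], want_rotation=True)
    movedQ = apply_transform(T, traceQ.coords)
    d0_val = d0(min(len(traceQ), len(traceP)), params.d0_min)
    S = residue_similarity_matrix(movedQ, traceP.coords, d0_val)
    path = dp_align(S, params.G_r)
    return list(path.pairs), T
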