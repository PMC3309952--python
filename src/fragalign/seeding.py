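"""Matched fragment set (MFS) generation, scoring, filtering, and ranking.

An MFS pairs an ordered subset of target fragments with an ordered subset
of database fragments and seeds one independent alignment.  Candidate
fragment pairs come from thresholding the all-against-all similarity
matrix; pairs are grouped into sets by a spatial-consistency test on
fragment centroids: two matched pairs are compatible when they keep
backbone order on both chains and their centroid separations agree within
``eps_d`` on the two structures.  Every compatible anchor pair spawns the
MFS of all candidate pairs compatible with both anchors.

Sets are ranked by

    S_MFS = w1 * N_Q / Nf_Q + w2 * N_P / Nf_P + w3 * min(N_Q,N_P)/max(N_Q,N_P)

(coverage of either chain plus a balance term favouring comparable subset
sizes), de-duplicated by a greedy Jaccard filter, and truncated to the top
``N_seed``.  When no candidate set exists at all, the fallback seed pairs
every fragment of both chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedFragmentSet",
    "find_matched_pairs",
    "build_mfs",
    "score_mfs",
    "filter_redundant_mfs",
    "select_seeds",
]

#: Spatial-consistency anchors are drawn from at most this many
#: best-scoring matched fragment pairs, bounding worst-case seeding cost.
MAX_ANCHOR_PAIRS = 200

DEFAULT_TAU_F = 0.8
DEFAULT_EPS_D = 2.0
DEFAULT_JACCARD = 0.7
DEFAULT_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)

_ONE_MINUS_PI = 1.0 - np.pi


@dataclass(frozen=True)
class MatchedFragmentSet:
    """Two ordered, non-empty fragment index subsets plus their score."""

    F_Q: tuple
    F_P: tuple
    score: float = 0.0
    pairs: tuple = ()  # member matched pairs (qi, pj) that built the set

    def __post_init__(self) -> None:
        fq = tuple(int(i) for i in self.F_Q)
        fp = tuple(int(j) for j in self.F_P)
        if not fq or not fp:
            raise ValueError("MFS subsets must be non-empty")
        if any(b <= a for a, b in zip(fq, fq[1:])) or any(
            b <= a for a, b in zip(fp, fp[1:])
        ):
            raise ValueError("MFS subsets must be strictly increasing")
        object.__setattr__(self, "F_Q", fq)
        object.__setattr__(self, "F_P", fp)
        object.__setattr__(self, "pairs", tuple(self.pairs))

    @property
    def N_Q(self) -> int:
        return len(self.F_Q)

    @property
    def N_P(self) -> int:
        return len(self.F_P)

    def member_set(self) -> frozenset:
        """Tagged fragment members used by the redundancy filter."""
        return frozenset(2 * q for q in self.F_Q) | frozenset(
            2 * p + 1 for p in self.F_P
        )


def find_matched_pairs(score_matrix: np.ndarray, tau_f: float) -> list[tuple[int, int]]:
    """All fragment index pairs (i, j) with s_f(i, j) >= tau_f, row-major."""
    if not (_ONE_MINUS_PI < tau_f <= 1.0):
        raise ValueError(f"tau_f must lie in (1 - pi, 1], got {tau_f}")
    S = np.asarray(score_matrix, dtype=float)
    ii, jj = np.nonzero(S >= tau_f)
    return list(zip(ii.tolist(), jj.tolist()))


def build_mfs(
    matched_pairs,
    fragsQ,
    fragsP,
    eps_d: float = DEFAULT_EPS_D,
    score_matrix: np.ndarray | None = None,
) -> list[MatchedFragmentSet]:
    """Group matched fragment pairs into spatially consistent sets.

    Each ordered anchor pair ((i,j),(k,l)) with i<k, j<l whose fragment
    centroid separations agree within eps_d spawns one MFS containing every
    matched pair compatible with both anchors under the same test.  Scores
    are left at 0; rank with :func:`score_mfs`.  When ``score_matrix`` is
    given, anchors are restricted to the best-scoring matched pairs
    (``MAX_ANCHOR_PAIRS``) to bound cost.
    """
    if eps_d <= 0:
        raise ValueError("eps_d must be positive")
    if not matched_pairs:
        return []

    pairs = list(matched_pairs)
    if len(pairs) > MAX_ANCHOR_PAIRS:
        if score_matrix is not None:
            S = np.asarray(score_matrix, dtype=float)
            pairs.sort(key=lambda ij: (-S[ij[0], ij[1]], ij[0], ij[1]))
        pairs = pairs[:MAX_ANCHOR_PAIRS]

    qi = np.array([p[0] for p in pairs])
    pj = np.array([p[1] for p in pairs])
    cQ = np.stack([f.centroid for f in fragsQ])
    cP = np.stack([f.centroid for f in fragsP])
    dQ = cdist(cQ[qi], cQ[qi])
    dP = cdist(cP[pj], cP[pj])

    di = qi[None, :] - qi[:, None]
    dj = pj[None, :] - pj[:, None]
    order_ok = ((di > 0) & (dj > 0)) | ((di < 0) & (dj < 0))
    compat = order_ok & (np.abs(dQ - dP) <= eps_d)
    np.fill_diagonal(compat, True)

    n = len(pairs)
    seen: set[bytes] = set()
    out: list[MatchedFragmentSet] = []
    forward = np.triu(compat, k=1)
    anchors = np.argwhere(forward & (di > 0))
    for a, b in anchors:
        members = compat[a] & compat[b]
        members[a] = True
        members[b] = True
        key = members.tobytes()
        if key in seen:
            continue
        seen.add(key)
        idx = np.nonzero(members)[0]
        member_pairs = tuple(pairs[m] for m in idx)
        fq = tuple(sorted({p[0] for p in member_pairs}))
        fp = tuple(sorted({p[1] for p in member_pairs}))
        out.append(MatchedFragmentSet(fq, fp, 0.0, member_pairs))
    return out


def score_mfs(
    mfs: MatchedFragmentSet,
    N_f_Q: int,
    N_f_P: int,
    w: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Three-term coverage/balance score; lies in (0, w1 + w2 + w3]."""
    if N_f_Q < 1 or N_f_P < 1:
        raise ValueError("fragment counts must be >= 1")
    w1, w2, w3 = w
    if min(w1, w2, w3) < 0:
        raise ValueError("weights must be non-negative")
    nq, np_ = mfs.N_Q, mfs.N_P
    return (
        w1 * nq / N_f_Q
        + w2 * np_ / N_f_P
        + w3 * min(nq, np_) / max(nq, np_)
    )


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def filter_redundant_mfs(
    mfs_list, jaccard_threshold: float = DEFAULT_JACCARD
) -> list[MatchedFragmentSet]:
    """Greedy keep-best filter dropping sets too similar to a kept one."""
    if not (0.0 < jaccard_threshold <= 1.0):
        raise ValueError("jaccard_threshold must lie in (0, 1]")
    ranked = sorted(
        mfs_list, key=lambda m: (-m.score, m.F_Q[0], m.F_P[0], m.F_Q, m.F_P)
    )
    kept: list[MatchedFragmentSet] = []
    kept_sets: list[frozenset] = []
    for cand in ranked:
        cs = cand.member_set()
        if any(_jaccard(cs, ks) >= jaccard_threshold for ks in kept_sets):
            continue
        kept.append(cand)
        kept_sets.append(cs)
    return kept


def select_seeds(mfs_list, N_seed: int, fragsQ, fragsP) -> list[MatchedFragmentSet]:
    """Top N_seed sets by score; all-fragments fallback when none exist.

    Ties in score break by smaller first F_Q index, then first F_P index.
    """
    if N_seed < 1:
        raise ValueError("N_seed must be >= 1")
    if not mfs_list:
        logger.info("no MFS found; falling back to the all-fragments seed")
        fq = tuple(range(len(fragsQ)))
        fp = tuple(range(len(fragsP)))
        return [MatchedFragmentSet(fq, fp, 0.0)]
    ranked = sorted(
        mfs_list, key=lambda m: (-m.score, m.F_Q[0], m.F_P[0], m.F_Q, m.F_P)
    )
    return ranked[:N_seed]
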