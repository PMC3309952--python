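"""Maximal alignment search: window seeding, 4 A extension, TM-score choice.

Given a residue alignment R, every contiguous window of ``L_W`` pairs seeds
a superposition.  A window is refined for ``N_MS`` rounds: fit the optimal
transform to the current members, superimpose the target side of every
pair in R, and re-admit exactly those pairs closer than the 4.0 A cutoff
(the seeding window itself always stays).  The refined window with the
largest TM-score becomes the maximal subset M; its transform is then used
to superimpose the whole target chain and a fresh residue alignment is
built through the gap-0 DP, keeping path pairs under the cutoff — routing
through the DP preserves the order invariant that raw proximity selection
would break.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dp_align import ScoringParams, d0, dp_align, residue_similarity_matrix
from .superposition import RigidTransform, apply_transform, qcp_rmsd

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueAlignment",
    "generate_windows",
    "refine_window",
    "tm_score",
    "max_subset",
    "DEFAULT_WINDOW",
    "DEFAULT_N_MS",
]

#: Seed window length L_W (pairs) and extension rounds N_MS.
DEFAULT_WINDOW = 4
DEFAULT_N_MS = 4


@dataclass(frozen=True)
class ResidueAlignment:
    """An ordered set of (target, database) residue index pairs."""

    pairs: tuple
    transform: RigidTransform | None = None
    S_a: float | None = None

    def __post_init__(self) -> None:
        pairs = tuple((int(q), int(p)) for q, p in self.pairs)
        for (q1, p1), (q2, p2) in zip(pairs, pairs[1:]):
            if q2 <= q1 or p2 <= p1:
                raise ValueError("residue pairs must be strictly increasing")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def generate_windows(pairs, L_W: int = DEFAULT_WINDOW) -> list[tuple[int, int]]:
    """(start, stop) spans of the L_R - L_W + 1 contiguous seed windows.

    An alignment shorter than L_W degenerates to one whole-R window.
    """
    L_R = len(pairs)
    if L_W < 3:
        raise ValueError("L_W must be >= 3")
    if L_R < L_W:
        logger.warning("alignment length %d < window %d; using whole R", L_R, L_W)
        return [(0, L_R)]
    return [(s, s + L_W) for s in range(L_R - L_W + 1)]


def refine_window(
    window: tuple[int, int],
    pairs,
    coordsQ: np.ndarray,
    coordsP: np.ndarray,
    cutoff: float = 4.0,
    N_MS: int = DEFAULT_N_MS,
):
    """Iteratively grow one seed window; returns (member indices, transform).

    Member indices are positions into ``pairs``.  Raises ValueError when
    the window geometry is degenerate (caller discards that window).
    """
    qi = np.array([q for q, _ in pairs])
    pi = np.array([p for _, p in pairs])
    XQ = coordsQ[qi]
    XP = coordsP[pi]
    start, stop = window
    seed = np.zeros(len(pairs), dtype=bool)
    seed[start:stop] = True
    members = seed.copy()
    T = None
    for _ in range(N_MS):
        _, T = qcp_rmsd(XQ[members], XP[members], want_rotation=True)
        d = np.linalg.norm(apply_transform(T, XQ) - XP, axis=1)
        new_members = seed | (d < cutoff)
        if np.array_equal(new_members, members):
            break
        members = new_members
    return np.nonzero(members)[0], T


def tm_score(distances, L_norm: int, d0_val: float) -> float:
    """TM-score: mean of 1/(1 + (d_i/d0)^2) over pairs, normalised by L_norm."""
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return 0.0
    return float(np.sum(1.0 / (1.0 + (d / d0_val) ** 2)) / L_norm)


def max_subset(
    alignment: ResidueAlignment,
    traceQ,
    traceP,
    params: ScoringParams = ScoringParams(),
    L_W: int = DEFAULT_WINDOW,
    N_MS: int = DEFAULT_N_MS,
):
    """Best refined window over R and the next-round alignment it induces.

    Returns (M, T, S_a, R_next) where M is the winning member pair tuple,
    T its transform, S_a its TM-score (normalised by the shorter chain),
    and R_next the new alignment built from T through the gap-0 DP with
    the 4.0 A cutoff.  Ties on S_a break by larger member count, then
    smaller window start.  If every window is degenerate the input
    alignment is returned unchanged with a warning flag.
    """
    pairs = alignment.pairs
    if len(pairs) < 3:
        raise ValueError("alignment too short for maximal subset search")
    L_norm = min(len(traceQ), len(traceP))
    d0_val = d0(L_norm, params.d0_min)
    qi = np.array([q for q, _ in pairs])
    pi = np.array([p for _, p in pairs])
    XQ = traceQ.coords[qi]
    XP = traceP.coords[pi]

    best = None  # (S_a, |M|, -start) maximised
    for start, stop in generate_windows(pairs, L_W):
        try:
            member_idx, T = refine_window(
                (start, stop), pairs, traceQ.coords, traceP.coords,
                cutoff=params.cutoff, N_MS=N_MS,
            )
        except (ValueError, np.linalg.LinAlgError):
            logger.warning("degenerate window at %d; discarded", start)
            continue
        d = np.linalg.norm(
            apply_transform(T, XQ[member_idx]) - XP[member_idx], axis=1
        )
        s_a = tm_score(d, L_norm, d0_val)
        key = (s_a, len(member_idx), -start)
        if best is None or key > best[0]:
            best = (key, member_idx, T)

    if best is None:
        logger.warning("all windows degenerate; alignment kept unchanged")
        return (
            pairs,
            alignment.transform,
            alignment.S_a if alignment.S_a is not None else 0.0,
            ResidueAlignment(pairs, alignment.transform, alignment.S_a),
        )

    (s_a, _, _), member_idx, T = best
    M = tuple(pairs[i] for i in member_idx)

    # New-R construction: superimpose the whole target with T and take the
    # gap-0 DP path pairs under the cutoff (keeps pairs strictly ordered).
    movedQ = apply_transform(T, traceQ.coords)
    S = residue_similarity_matrix(movedQ, traceP.coords, d0_val)
    path = dp_align(S, params.G_r)
    dists = np.linalg.norm(
        movedQ[[q for q, _ in path.pairs]] - traceP.coords[[p for _, p in path.pairs]],
        axis=1,
    ) if path.pairs else np.empty(0)
    next_pairs = tuple(
        pr for pr, dd in zip(path.pairs, dists) if dd < params.cutoff
    )
    R_next = ResidueAlignment(next_pairs, T, s_a)
    return M, T, s_a, R_next
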