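"""Independent oracles shared by the unit and acceptance tests.

Everything here is deliberately naive: exhaustive enumeration for the
dynamic-programming aligner, a scripted step-by-step re-implementation of
the window refinement loop built on the Kabsch (SVD) superposition, and a
brute-force window sweep for the maximal subset search.  None of it shares
code with the production path it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from fragalign.superposition import kabsch_rmsd, apply_transform


def brute_force_dp_score(S: np.ndarray, gap: float) -> float:
    """Best score over every monotone pair sequence (free end gaps).

    Gap accounting mirrors the aligner's contract: interior skipped rows
    and columns each cost ``gap``; an overhang before the first pair or
    after the last costs ``gap`` per step on the cheaper side only.
    """
    n, m = S.shape
    best = 0.0  # the empty alignment
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in combinations(range(m), k):
                pairs = list(zip(rows, cols))
                s = sum(S[i, j] for i, j in pairs)
                lead = min(pairs[0][0], pairs[0][1])
                trail = min(n - 1 - pairs[-1][0], m - 1 - pairs[-1][1])
                internal = sum(
                    (i2 - i1 - 1) + (j2 - j1 - 1)
                    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:])
                )
                s += gap * (lead + trail + internal)
                if s > best:
                    best = s
    return best


def path_score(S: np.ndarray, pairs, gap: float) -> float:
    """Score an explicit path under the same accounting (validity check)."""
    if not pairs:
        return 0.0
    n, m = S.shape
    s = sum(S[i, j] for i, j in pairs)
    lead = min(pairs[0][0], pairs[0][1])
    trail = min(n - 1 - pairs[-1][0], m - 1 - pairs[-1][1])
    internal = sum(
        (i2 - i1 - 1) + (j2 - j1 - 1)
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:])
    )
    return s + gap * (lead + trail + internal)


def scripted_refine(window, pairs, coordsQ, coordsP, cutoff=4.0, n_ms=4):
    """Step-by-step re-implementation of one window's extension loop.

    Uses the Kabsch superposition (not QCP) so the trajectory is computed
    through an independent route.  Returns (member index tuple, transform).
    """
    qi = np.array([q for q, _ in pairs])
    pi = np.array([p for _, p in pairs])
    start, stop = window
    seed = set(range(start, stop))
    members = set(seed)
    T = None
    for _ in range(n_ms):
        idx = sorted(members)
        _, T = kabsch_rmsd(coordsQ[qi[idx]], coordsP[pi[idx]])
        moved = apply_transform(T, coordsQ[qi])
        d = np.linalg.norm(moved - coordsP[pi], axis=1)
        new_members = seed | {i for i in range(len(pairs)) if d[i] < cutoff}
        if new_members == members:
            break
        members = new_members
    return tuple(sorted(members)), T


def brute_force_max_subset(pairs, traceQ, traceP, L_W=4, n_ms=4, cutoff=4.0):
    """Evaluate every window's refined subset; return the best (M, S_a).

    Normalisation and d0 follow the production definitions (shorter chain);
    the per-window trajectories come from :func:`scripted_refine`.
    """
    from fragalign.dp_align import d0
    from fragalign.maxsub import tm_score

    L_R = len(pairs)
    L_norm = min(len(traceQ), len(traceP))
    d0_val = d0(L_norm)
    qi = np.array([q for q, _ in pairs])
    pi = np.array([p for _, p in pairs])
    windows = (
        [(s, s + L_W) for s in range(L_R - L_W + 1)] if L_R >= L_W else [(0, L_R)]
    )
    best = None
    for start, stop in windows:
        idx, T = scripted_refine(
            (start, stop), pairs, traceQ.coords, traceP.coords, cutoff, n_ms
        )
        moved = apply_transform(T, traceQ.coords[qi[list(idx)]])
        d = np.linalg.norm(moved - traceP.coords[pi[list(idx)]], axis=1)
        s_a = tm_score(d, L_norm, d0_val)
        key = (s_a, len(idx), -start)
        if best is None or key > best[0]:
            best = (key, tuple(pairs[i] for i in idx))
    (s_a, _, _), M = best
    return M, s_a
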