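"""Orchestration of the five-stage alignment per pair and across a database.

For one target/database pair: (1) seed matched fragment sets, (2) assemble
each seed into an initial residue alignment by fragment-level DP, (3)
refine at residue level (superposition + gap-0 DP), (4) run the maximal
alignment search, carrying each seed's new alignment into the next of
``N_iter`` rounds while keeping the best TM-score seen and dropping
near-duplicate alignments between rounds, then (5) report PSI, z-score,
cRMSD and RMSD100 for the best alignment.  The whole pipeline is
deterministic for fixed inputs and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import seeding
from .assessment import (
    AlignmentReport,
    RMSD100_MIN_PAIRS,
    psi as psi_fn,
    rmsd100,
    z_score,
)
from .dp_align import (
    AlignmentPath,
    ScoringParams,
    assemble_initial_alignment,
    dp_align,
    residue_level_align,
)
from .fragment_model import FRAGMENT_LENGTH, decompose, fragment_score_matrix
from .maxsub import DEFAULT_N_MS, DEFAULT_WINDOW, ResidueAlignment, max_subset
from .superposition import qcp_rmsd

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "align_pair", "one_against_all", "count_comparisons"]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable of the pipeline, with its default.

    N_iter: refinement rounds; N_seed: maximum seed alignments carried;
    tau_f: fragment-similarity threshold for matched pairs; eps_d: centroid
    distance consistency (A); jaccard_threshold: redundancy filter level;
    w1..w3: seed-score weights; G_f/G_r: gap penalties; L_W/N_MS: maximal
    search window length and extension rounds; cutoff: aligned-pair
    distance (A); d0_min: TM-score distance-scale floor (A).
    """

    N_iter: int = 3
    N_seed: int = 20
    tau_f: float = seeding.DEFAULT_TAU_F
    eps_d: float = seeding.DEFAULT_EPS_D
    jaccard_threshold: float = seeding.DEFAULT_JACCARD
    w1: float = 1.0 / 3.0
    w2: float = 1.0 / 3.0
    w3: float = 1.0 / 3.0
    G_f: float = -0.6
    G_r: float = 0.0
    L_W: int = DEFAULT_WINDOW
    N_MS: int = DEFAULT_N_MS
    cutoff: float = 4.0
    d0_min: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.N_iter < 1 or self.N_seed < 1:
            raise ValueError("N_iter and N_seed must be >= 1")

    def scoring(self) -> ScoringParams:
        return ScoringParams(
            G_f=self.G_f, G_r=self.G_r, d0_min=self.d0_min, cutoff=self.cutoff
        )


def count_comparisons(n_targets: int, db_sizes) -> int:
    """Planned pairwise comparisons for a batch: |targets| x |database|."""
    if n_targets < 0:
        raise ValueError("n_targets must be non-negative")
    return n_targets * sum(int(s) for s in db_sizes)


def _seed_alignments(traceQ, traceP, params: PipelineParams, flags: list):
    """Stages (1)-(2): seed MFS generation plus fragment-level assembly."""
    L_f = FRAGMENT_LENGTH
    if min(len(traceQ), len(traceP)) < L_f:
        # Residue-only fallback: neither chain can be fragmented usefully.
        flags.append("short_trace")
        n = min(len(traceQ), len(traceP))
        return [tuple((i, i) for i in range(n))]

    fragsQ = decompose(traceQ)
    fragsP = decompose(traceP)
    S = fragment_score_matrix(fragsQ, fragsP)
    matched = seeding.find_matched_pairs(S, params.tau_f)
    candidates = seeding.build_mfs(
        matched, fragsQ, fragsP, eps_d=params.eps_d, score_matrix=S
    )
    weights = (params.w1, params.w2, params.w3)
    scored = [
        replace(m, score=seeding.score_mfs(m, len(fragsQ), len(fragsP), weights))
        for m in candidates
    ]
    kept = seeding.filter_redundant_mfs(scored, params.jaccard_threshold)
    seeds = seeding.select_seeds(kept, params.N_seed, fragsQ, fragsP)

    alignments = []
    for seed in seeds:
        sub = S[np.ix_(seed.F_Q, seed.F_P)]
        path = dp_align(sub, params.G_f)
        frag_pairs = tuple((seed.F_Q[i], seed.F_P[j]) for i, j in path.pairs)
        if not frag_pairs:
            continue
        res_pairs = assemble_initial_alignment(
            AlignmentPath(frag_pairs, path.score), L_f
        )
        if len(res_pairs) < 3:
            logger.debug("seed produced %d residue pairs; dropped", len(res_pairs))
            continue
        alignments.append(tuple(res_pairs))
    return alignments


def _jaccard_pairs(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if (a or b) else 1.0


def _filter_alignments(cands, threshold: float):
    """Greedy keep-best (by S_a) drop of near-duplicate alignments."""
    ranked = sorted(cands, key=lambda c: (-c[0], c[1]))
    kept, kept_sets = [], []
    for c in ranked:
        cs = frozenset(c[1])
        if any(_jaccard_pairs(cs, ks) >= threshold for ks in kept_sets):
            continue
        kept.append(c)
        kept_sets.append(cs)
    return kept


def _empty_report(traceQ, traceP, flags) -> AlignmentReport:
    return AlignmentReport(
        target_id=traceQ.id,
        db_id=traceP.id,
        L_Q=len(traceQ),
        L_P=len(traceP),
        Ne=0,
        cRMSD=0.0,
        RMSD100=0.0,
        S_a=0.0,
        PSI=0.0,
        z=z_score(0.0, min(len(traceQ), len(traceP))),
        k=min(len(traceQ), len(traceP)),
        pairs=(),
        T=None,
        flags=tuple(flags) + ("no_alignment",),
    )


def align_pair(traceQ, traceP, params: PipelineParams = PipelineParams()) -> AlignmentReport:
    """Full pairwise alignment of a target trace against a database trace."""
    flags: list = []
    scoring = params.scoring()
    k = min(len(traceQ), len(traceP))

    alignments = _seed_alignments(traceQ, traceP, params, flags)
    alignments = [a for a in alignments if len(a) >= 3]
    if not alignments:
        return _empty_report(traceQ, traceP, flags)

    best = None  # (S_a, pairs, T)
    current = [(0.0, a, None) for a in alignments]
    for round_no in range(params.N_iter):
        prev_best_pairs = best[1] if best else None
        nxt = []
        for _, pairs, _ in current:
            if len(pairs) < 3:
                continue
            try:
                refined, _ = residue_level_align(pairs, traceQ, traceP, scoring)
                if len(refined) < 3:
                    continue
                M, T, s_a, R_next = max_subset(
                    ResidueAlignment(tuple(refined)),
                    traceQ,
                    traceP,
                    scoring,
                    L_W=params.L_W,
                    N_MS=params.N_MS,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.debug("seed refinement failed in round %d: %s", round_no, exc)
                continue
            cand = (s_a, tuple(R_next.pairs), T)
            nxt.append(cand)
            if best is None or cand[0] > best[0]:
                best = cand
        if not nxt:
            break
        current = _filter_alignments(nxt, params.jaccard_threshold)
        if best is not None and prev_best_pairs == best[1]:
            break  # converged: keep-best cannot change any more

    if best is None or len(best[1]) == 0:
        return _empty_report(traceQ, traceP, flags)

    s_a, pairs, _ = best
    qi = [q for q, _ in pairs]
    pi = [p for _, p in pairs]
    if len(pairs) >= 3:
        cRMSD, T_fin = qcp_rmsd(
            traceQ.coords[qi], traceP.coords[pi], want_rotation=True
        )
    else:
        return _empty_report(traceQ, traceP, flags)

    Ne = len(pairs)
    psi_value = psi_fn(pairs, traceQ, traceP, T_fin, scoring.cutoff)
    z = z_score(psi_value, k)
    if Ne >= RMSD100_MIN_PAIRS:
        r100 = rmsd100(cRMSD, Ne)
    else:
        flags.append("short_alignment")
        r100 = cRMSD
    return AlignmentReport(
        target_id=traceQ.id,
        db_id=traceP.id,
        L_Q=len(traceQ),
        L_P=len(traceP),
        Ne=Ne,
        cRMSD=cRMSD,
        RMSD100=r100,
        S_a=s_a,
        PSI=psi_value,
        z=z,
        k=k,
        pairs=tuple(pairs),
        T=T_fin,
        flags=tuple(flags),
    )


def one_against_all(traceQ, db, params: PipelineParams = PipelineParams()):
    """Align one target against every database trace, ranked by z-score.

    Individual pair failures become flagged zero rows, never abort the
    batch.
    """
    db = list(db)
    if not db:
        raise ValueError("database must be non-empty")
    logger.info(
        "planned comparisons: %d", count_comparisons(1, [len(db)])
    )
    reports = []
    for traceP in db:
        try:
            reports.append(align_pair(traceQ, traceP, params))
        except Exception as exc:  # noqa: BLE001 - batch must survive any pair
            logger.error("alignment %s vs %s failed: %s", traceQ.id, traceP.id, exc)
            reports.append(_empty_report(traceQ, traceP, ["error"]))
    reports.sort(key=lambda r: -r.z)
    return reports
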