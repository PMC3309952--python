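"""Fixed-length backbone fragments and their distance-pattern similarity.

A trace is tiled into non-overlapping 8-residue fragments.  Each fragment
is summarised by the 28 pairwise Ca-Ca Euclidean distances of its residues
(a rigid-motion-invariant signature), and two fragments are compared by the
inverse-cosine similarity of those feature vectors:

    s_f = 1 - arccos( <D_A, D_B> / (||D_A|| ||D_B||) )

so identical distance patterns score 1 and the score decreases with the
angle between the feature vectors (worst case 1 - pi).  Distances cannot
see chirality; mirror-image fragments score 1 and are only rejected later
by the proper-rotation superposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

__all__ = [
    "FRAGMENT_LENGTH",
    "Fragment",
    "decompose",
    "feature_vector",
    "fragment_similarity",
    "fragment_score_matrix",
]

#: Residues per fragment (L_f); fragments tile the chain without overlap.
FRAGMENT_LENGTH = 8

_N_FEATURES = FRAGMENT_LENGTH * (FRAGMENT_LENGTH - 1) // 2  # 28


@dataclass(frozen=True)
class Fragment:
    """An 8-residue backbone window with its pairwise-distance feature."""

    source_id: str
    index: int
    start: int
    coords: np.ndarray
    feature: np.ndarray

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def feature_vector(coords: np.ndarray) -> np.ndarray:
    """The 28 pairwise distances of an 8-point fragment, pairs (i,j), i<j,
    in lexicographic order (0,1),(0,2),...,(6,7)."""
    X = np.asarray(coords, dtype=float)
    if X.shape != (FRAGMENT_LENGTH, 3):
        raise ValueError(f"fragment must be {FRAGMENT_LENGTH} x 3")
    if not np.all(np.isfinite(X)):
        raise ValueError("fragment coordinates must be finite")
    D = pdist(X)  # scipy's condensed order is exactly lexicographic (i<j)
    if np.any(D <= 0.0):
        raise ValueError("degenerate fragment: coincident CA coordinates")
    return D


def decompose(trace) -> list[Fragment]:
    """Tile a CaTrace into floor(L / 8) non-overlapping fragments.

    Trailing residues shorter than a fragment stay unfragmented (they are
    still alignable at residue level).
    """
    L = len(trace)
    if L < FRAGMENT_LENGTH:
        raise ValueError(
            f"trace too short for fragments: L={L} < {FRAGMENT_LENGTH}"
        )
    n_frag = L // FRAGMENT_LENGTH
    frags = []
    for k in range(n_frag):
        start = k * FRAGMENT_LENGTH
        window = trace.coords[start : start + FRAGMENT_LENGTH]
        frags.append(
            Fragment(
                source_id=trace.id,
                index=k,
                start=start,
                coords=np.array(window),
                feature=feature_vector(window),
            )
        )
    return frags


def fragment_similarity(D_A: np.ndarray, D_B: np.ndarray) -> float:
    """Inverse-cosine similarity of two feature vectors, in [1 - pi, 1]."""
    a = np.asarray(D_A, dtype=float).ravel()
    b = np.asarray(D_B, dtype=float).ravel()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("degenerate feature: zero-norm vector")
    cosine = np.clip(float(a @ b) / (na * nb), -1.0, 1.0)
    return 1.0 - float(np.arccos(cosine))


def fragment_score_matrix(fragsQ, fragsP) -> np.ndarray:
    """All-against-all s_f matrix, entry (i, j) for fragment i of Q vs j of P."""
    if not fragsQ or not fragsP:
        raise ValueError("fragment lists must be non-empty")
    FQ = np.stack([f.feature for f in fragsQ])
    FP = np.stack([f.feature for f in fragsP])
    nq = np.linalg.norm(FQ, axis=1)
    np_ = np.linalg.norm(FP, axis=1)
    cosine = np.clip((FQ @ FP.T) / np.outer(nq, np_), -1.0, 1.0)
    return 1.0 - np.arccos(cosine)
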