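"""Synthetic C-alpha traces: ideal helices, noised/rigidly moved copies,
and self-avoiding random-walk decoys.

These generators stand in for downloaded structures in tests and demos:
a canonical alpha-helix (rise 1.5 A, twist 100 degrees, radius 2.3 A gives
the familiar ~3.8 A Ca-Ca spacing), Gaussian coordinate perturbation,
seeded proper rigid motion, and fixed-step self-avoiding random walks as
length-matched decoys.  Everything is reproducible from (kind, n, sigma,
seed).  Real chains differ in having secondary-structure mixtures,
loops and packing; the generators emulate geometry only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structure_io import CaTrace

logger = logging.getLogger(__name__)

__all__ = [
    "generate_helix",
    "perturb",
    "random_walk_decoy",
    "rigid_copy",
    "make_fixture",
    "write_pdb",
]

HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
HELIX_RADIUS = 2.3

WALK_STEP = 3.8
WALK_MIN_SEP = 3.0


def generate_helix(
    n: int,
    rise: float = HELIX_RISE,
    twist: float = HELIX_TWIST_DEG,
    radius: float = HELIX_RADIUS,
    trace_id: str = "helix",
) -> CaTrace:
    """Ideal alpha-helical Ca spiral of n residues along the z axis."""
    if n < 1:
        raise ValueError("n must be >= 1")
    t = np.arange(n)
    ang = np.deg2rad(twist) * t
    coords = np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), rise * t]
    )
    return CaTrace(id=trace_id, chain_id="A", coords=coords)


def perturb(trace: CaTrace, sigma: float, seed: int = 0) -> CaTrace:
    """Add isotropic Gaussian noise (per-coordinate std sigma, Angstrom)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=trace.coords.shape) if sigma > 0 else 0.0
    return CaTrace(
        id=f"{trace.id}_perturbed",
        chain_id=trace.chain_id,
        coords=trace.coords + noise,
        residue_ids=trace.residue_ids,
    )


def random_walk_decoy(
    n: int,
    step: float = WALK_STEP,
    min_sep: float = WALK_MIN_SEP,
    seed: int = 0,
    trace_id: str = "decoy",
    _max_attempts: int = 200,
) -> CaTrace:
    """Fixed-step self-avoiding random chain of n points.

    New points closer than ``min_sep`` to any non-neighbouring previous
    point are rejected; if a chain stalls, the whole walk restarts
    deterministically with seed + 1 (logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    current_seed = seed
    while True:
        rng = np.random.default_rng(current_seed)
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n:
            placed = False
            for _ in range(_max_attempts):
                v = rng.normal(size=3)
                v *= step / np.linalg.norm(v)
                cand = pts[-1] + v
                if len(pts) > 1:
                    d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                    if np.min(d) < min_sep:
                        continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return CaTrace(id=trace_id, chain_id="A", coords=np.asarray(pts))
        logger.warning(
            "random walk stalled with seed %d; retrying with seed %d",
            current_seed,
            current_seed + 1,
        )
        current_seed += 1


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    q0, q1, q2, q3 = q
    return np.array(
        [
            [
                q0 * q0 + q1 * q1 - q2 * q2 - q3 * q3,
                2 * (q1 * q2 - q0 * q3),
                2 * (q1 * q3 + q0 * q2),
            ],
            [
                2 * (q1 * q2 + q0 * q3),
                q0 * q0 - q1 * q1 + q2 * q2 - q3 * q3,
                2 * (q2 * q3 - q0 * q1),
            ],
            [
                2 * (q1 * q3 - q0 * q2),
                2 * (q2 * q3 + q0 * q1),
                q0 * q0 - q1 * q1 - q2 * q2 + q3 * q3,
            ],
        ]
    )


def rigid_copy(trace: CaTrace, seed: int = 0) -> CaTrace:
    """Apply a seeded uniform random proper rotation and U(-50, 50) A
    translation."""
    rng = np.random.default_rng(seed)
    R = _random_rotation(rng)
    t = rng.uniform(-50.0, 50.0, size=3)
    return CaTrace(
        id=f"{trace.id}_moved",
        chain_id=trace.chain_id,
        coords=trace.coords @ R.T + t,
        residue_ids=trace.residue_ids,
    )


def make_fixture(kind: str, n: int, sigma: float = 0.0, seed: int = 0) -> CaTrace:
    """Build a trace from a (kind, n, sigma, seed) specification."""
    if kind == "helix":
        return generate_helix(n)
    if kind == "perturbed_copy":
        return perturb(generate_helix(n), sigma, seed)
    if kind == "random_walk":
        return random_walk_decoy(n, seed=seed)
    if kind == "rigid_copy":
        return rigid_copy(generate_helix(n), seed)
    raise ValueError(f"unknown fixture kind: {kind!r}")


def write_pdb(trace: CaTrace, path) -> None:
    """Write a trace as a minimal single-chain PDB (CA-only ALA residues)."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = trace.id
    model = gemmi.Model("1")
    chain = gemmi.Chain(trace.chain_id or "A")
    for rid, (x, y, z) in zip(trace.residue_ids, trace.coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(str(rid))
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    doc_ok = structure.make_pdb_string()
    with open(path, "w", encoding="ascii") as fh:
        fh.write(doc_ok)
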