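"""Read protein structures into C-alpha traces and write alignment results.

Input handling is deliberately minimal: a comparison operates on a single
chain reduced to its ordered C-alpha coordinates (the only atoms the
alignment ever touches).  PDB parsing is delegated to gemmi; only the first
model is read, alternate locations keep the blank/'A' conformer, and any
residue carrying a C-alpha (including HETATM variants such as MSE) enters
the trace.  Chain breaks (consecutive Ca-Ca distance above 4.5 A) are
logged but the trace is kept whole.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["CaTrace", "read_ca_trace", "write_report_table", "write_pair_alignment"]

#: Consecutive Ca-Ca distance above which a chain break is logged (Angstrom).
CHAIN_BREAK_DISTANCE = 4.5

#: Column order of the TSV report table (kept stable for downstream parsing).
REPORT_COLUMNS = (
    "target_id",
    "db_id",
    "L_Q",
    "L_P",
    "Ne",
    "cRMSD",
    "RMSD100",
    "TM_score",
    "PSI",
    "z_score",
    "flags",
)


@dataclass(frozen=True)
class CaTrace:
    """A protein chain reduced to an ordered C-alpha coordinate list.

    ``residue_ids`` carries author numbering (with insertion codes mangled
    into the string form where present); internal indexing everywhere else
    is 0-based positional.
    """

    id: str
    chain_id: str
    coords: np.ndarray
    residue_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.coords, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 1:
            raise ValueError("coords must be an L x 3 array with L >= 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("coordinates must be finite")
        rid = tuple(self.residue_ids) if self.residue_ids else tuple(range(1, X.shape[0] + 1))
        if len(rid) != X.shape[0]:
            raise ValueError("residue_ids length must match coords")
        object.__setattr__(self, "coords", X)
        object.__setattr__(self, "residue_ids", rid)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def L(self) -> int:
        return self.coords.shape[0]


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    for atom in residue:
        if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
            return atom
    return None


def read_ca_trace(path: str, chain: str | None = None) -> CaTrace:
    """Read one chain of a PDB file as a CaTrace (first model only).

    If ``chain`` is omitted the first chain containing C-alpha atoms is
    used.  Residues lacking a C-alpha are skipped with a warning.
    """
    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path!r}: {exc}") from exc
    if len(structure) == 0:
        raise ValueError(f"empty trace: no models in {path!r}")
    model = structure[0]

    candidates = [ch for ch in model if chain is None or ch.name == chain]
    if chain is not None and not candidates:
        raise KeyError(f"chain not found: {chain!r} in {path!r}")

    for ch in candidates:
        coords: list[tuple[float, float, float]] = []
        rids: list = []
        for residue in ch:
            atom = _pick_ca(residue)
            if atom is None:
                logger.warning(
                    "residue %s %s%s in %s lacks a CA atom; skipped",
                    residue.name,
                    residue.seqid.num,
                    (residue.seqid.icode or "").strip(),
                    path,
                )
                continue
            coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            icode = (residue.seqid.icode or "").strip()
            rids.append(f"{residue.seqid.num}{icode}" if icode else residue.seqid.num)
        if coords:
            trace = CaTrace(
                id=structure.name or str(path),
                chain_id=ch.name,
                coords=np.asarray(coords),
                residue_ids=tuple(rids),
            )
            _warn_chain_breaks(trace, path)
            return trace
    raise ValueError(f"empty trace: no CA atoms found in {path!r}")


def _warn_chain_breaks(trace: CaTrace, path: str) -> None:
    d = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
    for i in np.nonzero(d > CHAIN_BREAK_DISTANCE)[0]:
        logger.warning(
            "chain break in %s between residues %s and %s (%.2f A)",
            path,
            trace.residue_ids[i],
            trace.residue_ids[i + 1],
            d[i],
        )


def _fmt(value, ndigits=4) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.{ndigits}f}"
    return str(value)


def write_report_table(reports, path) -> None:
    """Write alignment reports as a TSV sorted by descending z-score.

    A report with no aligned pairs keeps its row with empty alignment
    fields and the ``no_alignment`` flag.
    """
    rows = sorted(
        reports,
        key=lambda r: -(r.z if r.z is not None and not math.isnan(r.z) else -math.inf),
    )
    try:
        with open(path, "w", encoding="ascii") as fh:
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for r in rows:
                empty = r.Ne == 0
                fields = [
                    r.target_id,
                    r.db_id,
                    str(r.L_Q),
                    str(r.L_P),
                    str(r.Ne),
                    "" if empty else _fmt(r.cRMSD),
                    "" if empty else _fmt(r.RMSD100),
                    "" if empty else _fmt(r.S_a),
                    "" if empty else _fmt(r.PSI, 2),
                    "" if empty else _fmt(r.z, 3),
                    ",".join(r.flags),
                ]
                fh.write("\t".join(fields) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write report table to {path!r}: {exc}") from exc


def write_pair_alignment(report, traceQ: CaTrace, traceP: CaTrace, path) -> None:
    """Write one comparison's residue pair list and transform as plain text.

    Each pair line shows the author residue ids of the target and database
    structures and the post-superposition distance in Angstrom.
    """
    from .superposition import apply_transform  # local import avoids a cycle

    try:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(f"# target {report.target_id} chain {traceQ.chain_id}\n")
            fh.write(f"# database {report.db_id} chain {traceP.chain_id}\n")
            fh.write(f"# Ne {report.Ne}\n")
            if report.T is not None:
                fh.write("# rotation\n")
                for row in report.T.rotation:
                    fh.write("# " + " ".join(f"{v:12.8f}" for v in row) + "\n")
                fh.write(
                    "# translation "
                    + " ".join(f"{v:12.6f}" for v in report.T.translation)
                    + "\n"
                )
            if report.Ne and report.T is not None:
                qi = [q for q, _ in report.pairs]
                pi = [p for _, p in report.pairs]
                moved = apply_transform(report.T, traceQ.coords[qi])
                dists = np.linalg.norm(moved - traceP.coords[pi], axis=1)
                for (q, p), d in zip(report.pairs, dists):
                    fh.write(
                        f"{traceQ.residue_ids[q]}\t{traceP.residue_ids[p]}\t{d:.3f}\n"
                    )
    except OSError as exc:
        raise IOError(f"cannot write pair alignment to {path!r}: {exc}") from exc
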