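"""PDB reading into Ca traces and result writing."""

import numpy as np
import pytest

from fragalign.assessment import AlignmentReport
from fragalign.fixtures import generate_helix, write_pdb
from fragalign.structure_io import (
    CaTrace,
    read_ca_trace,
    write_pair_alignment,
    write_report_table,
)
from fragalign.superposition import RigidTransform

MINI_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1      99.000  99.000  99.000  1.00  0.00           C
ATOM      2  CA  ALA A   2      95.000  99.000  99.000  1.00  0.00           C
ATOM      3  CA  ALA A   3      91.000  99.000  99.000  1.00  0.00           C
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
ATOM      5  CA  MSE A   4      11.400   0.000   0.000  1.00  0.00           C
END
"""


def _report(pairs, z=1.0, Ne=None, T=None, flags=()):
    Ne = len(pairs) if Ne is None else Ne
    return AlignmentReport(
        target_id="q",
        db_id="p",
        L_Q=5,
        L_P=5,
        Ne=Ne,
        cRMSD=0.5 if Ne else 0.0,
        RMSD100=0.5 if Ne else 0.0,
        S_a=0.9 if Ne else 0.0,
        PSI=80.0 if Ne else 0.0,
        z=z,
        k=5,
        pairs=tuple(pairs),
        T=T,
        flags=tuple(flags) if flags else (("no_alignment",) if Ne == 0 else ()),
    )


class TestReadCaTrace:
    def test_three_residue_echo(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINI_PDB)
        trace = read_ca_trace(path)
        assert trace.L == 3
        assert np.allclose(
            trace.coords, [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], atol=1e-3
        )
        assert trace.residue_ids == (1, 2, 3)

    def test_missing_chain_raises(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(MINI_PDB)
        with pytest.raises(KeyError, match="chain not found"):
            read_ca_trace(path, chain="Z")

    def test_first_model_only(self, tmp_path):
        path = tmp_path / "models.pdb"
        path.write_text(TWO_MODEL_PDB)
        trace = read_ca_trace(path)
        assert trace.L == 3
        assert np.allclose(trace.coords[0], [0, 0, 0], atol=1e-3)

    def test_altloc_keeps_A_and_het_ca_included(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(ALTLOC_PDB)
        trace = read_ca_trace(path)
        assert trace.L == 4  # one Ca per residue, MSE included
        assert np.allclose(trace.coords[0], [0, 0, 0], atol=1e-3)

    def test_unreadable_file(self, tmp_path):
        with pytest.raises((IOError, ValueError)):
            read_ca_trace(tmp_path / "absent.pdb")

    def test_round_trip_preserves_coordinates(self, tmp_path):
        h = generate_helix(50)
        path = tmp_path / "helix.pdb"
        write_pdb(h, path)
        back = read_ca_trace(path)
        assert back.L == 50
        assert np.abs(back.coords - h.coords).max() < 1e-3

    def test_reading_preserves_residue_order(self, tmp_path):
        h = generate_helix(20)
        path = tmp_path / "helix.pdb"
        write_pdb(h, path)
        back = read_ca_trace(path)
        assert list(back.residue_ids) == sorted(back.residue_ids)


class TestCaTraceInvariants:
    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            CaTrace(id="x", chain_id="A", coords=np.array([[np.nan, 0, 0]]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            CaTrace(
                id="x", chain_id="A", coords=np.zeros((2, 3)), residue_ids=(1,)
            )


class TestWriteReportTable:
    def test_empty_reports_header_only(self, tmp_path):
        out = tmp_path / "t.tsv"
        write_report_table([], out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("target_id\tdb_id")

    def test_sorted_by_descending_z(self, tmp_path):
        out = tmp_path / "t.tsv"
        a = _report([(0, 0), (1, 1), (2, 2)], z=1.0)
        b = _report([(0, 0), (1, 1), (2, 2)], z=5.0)
        write_report_table([a, b], out)
        rows = out.read_text().splitlines()[1:]
        assert rows[0].split("\t")[9] == "5.000"
        assert rows[1].split("\t")[9] == "1.000"

    def test_no_alignment_row_flagged_with_empty_fields(self, tmp_path):
        out = tmp_path / "t.tsv"
        write_report_table([_report([], Ne=0)], out)
        row = out.read_text().splitlines()[1].split("\t")
        assert row[4] == "0"
        assert row[5] == ""  # cRMSD blank
        assert "no_alignment" in row[10]


class TestWritePairAlignment:
    def test_self_alignment_distances_zero(self, tmp_path):
        h = generate_helix(5)
        r = _report(
            [(i, i) for i in range(5)], T=RigidTransform.identity()
        )
        out = tmp_path / "pairs.txt"
        write_pair_alignment(r, h, h, out)
        data_lines = [
            ln for ln in out.read_text().splitlines() if not ln.startswith("#")
        ]
        assert len(data_lines) == 5
        assert all(ln.split("\t")[2] == "0.000" for ln in data_lines)

    def test_empty_pairs_header_only(self, tmp_path):
        h = generate_helix(5)
        r = _report([], Ne=0, T=RigidTransform.identity(), flags=("no_alignment",))
        out = tmp_path / "pairs.txt"
        write_pair_alignment(r, h, h, out)
        lines = out.read_text().splitlines()
        assert all(ln.startswith("#") for ln in lines)
        assert any("rotation" in ln for ln in lines)
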