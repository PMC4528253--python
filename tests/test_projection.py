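"""Alignment->structure mapping, disorder rescue, color code, projection artifacts."""

import numpy as np
import pytest

from ptmhotspots.catalog import PTMRecord
from ptmhotspots.errors import PairingError, ValidationError
from ptmhotspots.fixtures import generate_structure
from ptmhotspots.hotspots import build_hotspots
from ptmhotspots.msa import FamilyAlignment
from ptmhotspots.projection import (
    assign_unresolved_sasa,
    color_for_count,
    map_alignment_to_structure,
    read_disorder_annotation,
    write_projection,
)
from ptmhotspots.structure import MAX_SASA, read_structure, shrake_rupley_sasa

SEQ = "MKVLNDEAKRSTGHWQFYIC"


@pytest.fixture
def full_structure():
    pdb, _ = generate_structure(SEQ, disordered_prefix_len=0)
    return read_structure(pdb)


@pytest.fixture
def tailless_structure():
    """First 7 residues unresolved (disordered N-tail)."""
    pdb, disorder = generate_structure(SEQ, disordered_prefix_len=7)
    return read_structure(pdb), disorder


@pytest.fixture
def single_member_alignment():
    return FamilyAlignment.from_members([("m1", SEQ)], family_id="fam")


class TestColorForCount:
    @pytest.mark.parametrize(
        "count, color",
        [
            (0, "default"),
            (1, "green"),
            (2, "yellow"),
            (3, "orange"),
            (4, "magenta"),
            (5, "red"),
            (17, "red"),
        ],
    )
    def test_printed_color_code(self, count, color):
        assert color_for_count(count) == color

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            color_for_count(-1)


class TestMapAlignmentToStructure:
    def test_identity_map_full_chain(self, single_member_alignment, full_structure):
        tm = map_alignment_to_structure(
            single_member_alignment, "m1", full_structure.chains[0]
        )
        assert tm.column_to_author == {i: i for i in range(1, len(SEQ) + 1)}
        assert tm.unresolved_columns == set()
        assert tm.offset == 0

    def test_unresolved_tail_flagged(self, single_member_alignment, tailless_structure):
        structure, _ = tailless_structure
        tm = map_alignment_to_structure(
            single_member_alignment, "m1", structure.chains[0]
        )
        assert tm.unresolved_columns == set(range(1, 8))
        assert tm.residue_to_author[8] == 8  # author numbering preserved

    def test_gapped_member_maps_through_columns(self, full_structure):
        aln = FamilyAlignment.from_members(
            [("m1", SEQ[:5] + "--" + SEQ[5:]), ("m2", SEQ[:5] + "AA" + SEQ[5:])],
            family_id="fam",
        )
        tm = map_alignment_to_structure(aln, "m1", full_structure.chains[0])
        # residue 6 (D) sits at column 8 because of the two-column gap
        assert tm.column_to_author[8] == 6

    def test_wrong_protein_raises_pairing_error(self, full_structure):
        aln = FamilyAlignment.from_members([("other", "WWWWWWWWWWWWWWWWWWWW")])
        with pytest.raises(PairingError, match="identity|could not be aligned"):
            map_alignment_to_structure(aln, "other", full_structure.chains[0])


class TestAssignUnresolvedSasa:
    def test_disordered_tail_gets_full_accessibility(
        self, single_member_alignment, tailless_structure
    ):
        structure, disorder_rows = tailless_structure
        chain = structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        sasa = shrake_rupley_sasa(chain)
        disorder = set(range(1, disorder_rows[0]["end"] + 1))
        info = assign_unresolved_sasa(SEQ, tm, sasa, disorder=disorder)
        for r in range(1, 8):
            assert info[r].disordered_unresolved
            assert info[r].relative_sasa == 1.0
            assert info[r].sasa == pytest.approx(MAX_SASA[SEQ[r - 1]])
        for r in range(8, len(SEQ) + 1):
            assert not info[r].disordered_unresolved
            assert info[r].author_seq_id == r

    def test_unresolved_without_disorder_excluded(
        self, single_member_alignment, tailless_structure, caplog
    ):
        structure, _ = tailless_structure
        chain = structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        sasa = shrake_rupley_sasa(chain)
        with caplog.at_level("WARNING"):
            info = assign_unresolved_sasa(SEQ, tm, sasa, disorder=None)
        assert set(info) == set(range(8, len(SEQ) + 1))
        assert any("excluded" in msg for msg in caplog.messages)

    def test_terminal_disorder_heuristic(
        self, single_member_alignment, tailless_structure
    ):
        structure, _ = tailless_structure
        chain = structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        sasa = shrake_rupley_sasa(chain)
        info = assign_unresolved_sasa(
            SEQ, tm, sasa, disorder=None, assume_terminal_disorder=True
        )
        assert all(info[r].disordered_unresolved for r in range(1, 8))

    def test_resolved_residue_ignores_disorder_annotation(
        self, single_member_alignment, full_structure
    ):
        chain = full_structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        sasa = shrake_rupley_sasa(chain)
        info = assign_unresolved_sasa(SEQ, tm, sasa, disorder={3})
        assert not info[3].disordered_unresolved
        assert info[3].sasa == pytest.approx(sasa[3])

    def test_disorder_tsv_roundtrip(self):
        text = "member_id\tstart\tend\nm1\t1\t7\nm1\t20\t21\nm2\t5\t5\n"
        parsed = read_disorder_annotation(text)
        assert parsed == {"m1": set(range(1, 8)) | {20, 21}, "m2": {5}}


class TestWriteProjection:
    def test_artifacts_roundtrip(self, single_member_alignment, full_structure, tmp_path):
        chain = full_structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        records = [
            PTMRecord("m1", 2, "K", "ubiquitination"),
            PTMRecord("m1", 9, "K", "ubiquitination"),
            PTMRecord("m1", 9, "K", "acetylation"),
        ]
        hotspots = build_hotspots(single_member_alignment, records)
        paths = write_projection(full_structure, tm, hotspots, tmp_path)

        reread = read_structure(str(paths["pdb"]))
        # B-factor column carries the PTM count
        b_by_res = {}
        import gemmi

        st = gemmi.read_structure(str(paths["pdb"]))
        for res in st[0]["A"]:
            b_by_res[res.seqid.num] = res[0].b_iso
        assert b_by_res[2] == pytest.approx(1.0)
        assert b_by_res[9] == pytest.approx(2.0)
        assert b_by_res[3] == pytest.approx(0.0)

        script = paths["script"].read_text()
        assert "color green, chain A and resi 2" in script
        assert "color yellow, chain A and resi 9" in script
        assert "sphere_scale, 1.0" in script
        assert paths["unmapped"].read_text().strip().splitlines()[1:] == []

    def test_unmapped_hotspot_goes_to_sidecar(self, tailless_structure, tmp_path):
        structure, _ = tailless_structure
        aln = FamilyAlignment.from_members([("m1", SEQ)], family_id="fam")
        tm = map_alignment_to_structure(aln, "m1", structure.chains[0])
        records = [PTMRecord("m1", 2, "K", "ubiquitination")]  # in the unresolved tail
        hotspots = build_hotspots(aln, records)
        paths = write_projection(structure, tm, hotspots, tmp_path)
        lines = paths["unmapped"].read_text().strip().splitlines()
        assert lines[1].split("\t") == ["2", "1", "unresolved_in_structure"]
        assert "color" not in paths["script"].read_text()

    def test_no_hotspots_empty_script_body(self, full_structure, tmp_path):
        aln = FamilyAlignment.from_members([("m1", SEQ)], family_id="fam")
        tm = map_alignment_to_structure(aln, "m1", full_structure.chains[0])
        paths = write_projection(full_structure, tm, [], tmp_path)
        body = [
            line
            for line in paths["script"].read_text().splitlines()
            if line and not line.startswith("#") and "sphere_scale" not in line
        ]
        assert body == []

    def test_projection_is_deterministic(self, full_structure, single_member_alignment, tmp_path):
        chain = full_structure.chains[0]
        tm = map_alignment_to_structure(single_member_alignment, "m1", chain)
        records = [PTMRecord("m1", 9, "K", "ubiquitination")]
        hotspots = build_hotspots(single_member_alignment, records)
        p1 = write_projection(full_structure, tm, hotspots, tmp_path / "a")
        p2 = write_projection(full_structure, tm, hotspots, tmp_path / "b")
        assert p1["pdb"].read_bytes() == p2["pdb"].read_bytes()
        assert p1["script"].read_bytes() == p2["script"].read_bytes()
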