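"""Family multiple sequence alignments and residue/column coordinate maps.

Everything downstream works in alignment-column coordinates, so the central
object here is a :class:`FamilyAlignment` carrying explicit bidirectional
maps between each member's 1-based ungapped residue index and the 1-based
alignment column.  Maps are built once and never recomputed ad hoc.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from .errors import AlignerNotFoundError, ValidationError

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class FamilyAlignment:
    """A protein-family MSA with residue <-> column coordinate maps."""

    family_id: str
    members: list[tuple[str, str]]  # (member_id, aligned sequence, gap '-')
    residue_to_column: dict[str, dict[int, int]] = field(repr=False, default_factory=dict)
    column_to_residue: dict[str, dict[int, int]] = field(repr=False, default_factory=dict)

    @classmethod
    def from_members(cls, members: Sequence[tuple[str, str]], family_id: str = "family"):
        members = [(mid, seq.upper().replace(".", GAP)) for mid, seq in members]
        if not members:
            raise ValidationError("alignment has no members")
        length = len(members[0][1])
        if length < 1:
            raise ValidationError("alignment has zero columns")
        for mid, seq in members:
            if len(seq) != length:
                raise ValidationError(
                    f"ragged alignment: member {mid!r} has length {len(seq)}, expected {length}"
                )
        aln = cls(family_id=family_id, members=list(members))
        for mid, seq in members:
            r2c: dict[int, int] = {}
            c2r: dict[int, int] = {}
            res = 0
            for col, aa in enumerate(seq, start=1):
                if aa != GAP:
                    res += 1
                    r2c[res] = col
                    c2r[col] = res
            aln.residue_to_column[mid] = r2c
            aln.column_to_residue[mid] = c2r
        return aln

    @property
    def length(self) -> int:
        return len(self.members[0][1])

    @property
    def member_ids(self) -> list[str]:
        return [mid for mid, _ in self.members]

    def aligned(self, member_id: str) -> str:
        for mid, seq in self.members:
            if mid == member_id:
                return seq
        raise KeyError(member_id)

    def ungapped(self, member_id: str) -> str:
        return self.aligned(member_id).replace(GAP, "")

    def column_letters(self, column: int) -> list[str]:
        """Residue letters (or gaps) of every member at a 1-based column."""
        if not 1 <= column <= self.length:
            raise ValidationError(f"column {column} out of range 1..{self.length}")
        return [seq[column - 1] for _, seq in self.members]


def read_alignment(source, family_id: str = "family") -> FamilyAlignment:
    """Read an aligned FASTA file ('.' is treated as the gap character '-')."""
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and ("\n" in source or source == ""):
        handle = io.StringIO(source)
    else:
        handle = open(Path(source), "r", encoding="utf-8")
    members = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]
    if not members:
        raise ValidationError("no sequences found in alignment input")
    return FamilyAlignment.from_members(members, family_id=family_id)


DEFAULT_ALIGNER = ("mafft", "--auto", "--quiet")


def align_family(
    source,
    family_id: str = "family",
    aligner_cmd: Sequence[str] = DEFAULT_ALIGNER,
) -> FamilyAlignment:
    """Align an unaligned FASTA by shelling out to an external aligner.

    The aligner must read a FASTA path as its last argument and write aligned
    FASTA to stdout (mafft-style).  When no aligner is installed the pipeline
    remains fully usable with pre-aligned input via :func:`read_alignment`.
    """
    aligner_cmd = list(aligner_cmd)
    if hasattr(source, "read") or (isinstance(source, str) and "\n" in source):
        text = source.read() if hasattr(source, "read") else source
        tmp = tempfile.NamedTemporaryFile(
            "w", suffix=".fasta", delete=False, encoding="utf-8"
        )
        tmp.write(text)
        tmp.close()
        path = tmp.name
    else:
        path = str(source)
    n_seqs = sum(1 for line in open(path, encoding="utf-8") if line.startswith(">"))
    if n_seqs == 1:
        # single member: the trivial alignment is the input itself
        return read_alignment(path, family_id=family_id)
    if shutil.which(aligner_cmd[0]) is None:
        raise AlignerNotFoundError(
            f"aligner {aligner_cmd[0]!r} not found on PATH; supply a pre-aligned "
            "FASTA and use read_alignment() instead"
        )
    proc = subprocess.run(
        aligner_cmd + [path], capture_output=True, text=True, check=False
    )
    if proc.returncode != 0:
        raise AlignerNotFoundError(
            f"aligner {' '.join(aligner_cmd)} failed (exit {proc.returncode}): "
            f"{proc.stderr.strip()[:500]}"
        )
    logger.info("aligned %d sequences with %s", n_seqs, " ".join(aligner_cmd))
    return read_alignment(proc.stdout, family_id=family_id)
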