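"""Project alignment-column hotspots onto a representative structure.

The projection target is one family member for which a structure chain is
available.  Mapping proceeds residue-by-residue (structure chain sequence
located within the member sequence, author numbering offset resolved), and
per-residue structural context is then completed: relative SASA against the
theoretical per-residue maximum, burial, interface residence, and — for
residues the crystallographer never resolved — full accessibility whenever
the region is annotated as intrinsically disordered.  Disordered tails are
exactly the case where "unresolved" must not mean "buried": an unmodeled
flexible tail is maximally solvent-exposed in solution.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align

from .errors import PairingError, ValidationError
from .hotspots import Hotspot
from .msa import FamilyAlignment
from .structure import MAX_SASA, ONE_TO_THREE, Chain, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_BURIAL_THRESHOLD = 0.05  # relative SASA below which a residue is buried
MAX_TERMINAL_DISORDER_RUN = 30  # heuristic fallback, residues

#: PTM-count color code for structure rendering.
COLOR_SCALE = {0: "default", 1: "green", 2: "yellow", 3: "orange", 4: "magenta"}
COLOR_MAX = "red"  # five or more


def color_for_count(total_ptms: int) -> str:
    """Color label for a residue by its total observed PTMs.

    0 keeps the default model color; 1 green, 2 yellow, 3 orange,
    4 magenta, five or more red.
    """
    if total_ptms < 0:
        raise ValidationError(f"negative PTM count: {total_ptms}")
    return COLOR_SCALE.get(total_ptms, COLOR_MAX)


@dataclass
class ResidueStructureInfo:
    """Structural context for one member residue on the projection target."""

    chain_id: str
    author_seq_id: int | None
    sasa: float  # Å²
    relative_sasa: float  # in [0, 1]
    buried: bool
    interface: bool
    disordered_unresolved: bool


@dataclass
class TargetMap:
    """Alignment-column -> structure-residue map for one projection target."""

    family_id: str
    member_id: str
    chain_id: str
    column_to_author: dict[int, int]  # alignment column -> author residue number
    residue_to_author: dict[int, int]  # member residue index -> author number
    unresolved_columns: set[int]
    offset: int  # author numbering minus member numbering over the mapped span


def _locate_chain_in_member(member_seq: str, chain_seq: str) -> list[tuple[int, int]]:
    """Pair chain positions with member positions (both 0-based).

    Exact substring match first; otherwise a global pairwise alignment
    handles internal unresolved stretches.  Returns [(member_pos, chain_pos)].
    """
    start = member_seq.find(chain_seq)
    if start >= 0:
        return [(start + i, i) for i in range(len(chain_seq))]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    alignment = aligner.align(member_seq, chain_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        pairs.extend((t0 + k, q0 + k) for k in range(t1 - t0))
    return pairs


def map_alignment_to_structure(
    alignment: FamilyAlignment,
    member_id: str,
    chain: Chain,
    min_identity: float = 0.9,
) -> TargetMap:
    """Build the column -> author-residue map for a member/chain pairing.

    The chain's one-letter sequence is located inside the member's ungapped
    sequence (exact substring, with a pairwise-alignment fallback for
    internal breaks).  Pairings under ``min_identity`` over the mapped span
    raise :class:`PairingError` — that means the wrong chain or member.
    Columns of member residues absent from the structure are flagged
    unresolved.
    """
    member_seq = alignment.ungapped(member_id)
    chain_seq = chain.sequence
    if not chain_seq:
        raise PairingError(f"chain {chain.chain_id} has no standard residues")
    pairs = _locate_chain_in_member(member_seq, chain_seq)
    if not pairs:
        raise PairingError(
            f"chain {chain.chain_id} could not be aligned to member {member_id}"
        )
    matches = sum(1 for m, c in pairs if member_seq[m] == chain_seq[c])
    identity = matches / len(pairs)
    if identity < min_identity:
        raise PairingError(
            f"chain {chain.chain_id} vs member {member_id}: identity "
            f"{identity:.1%} over {len(pairs)} mapped residues (< {min_identity:.0%}); "
            "wrong chain/member pairing?"
        )
    author_ids = chain.author_seq_ids
    r2c = alignment.residue_to_column[member_id]
    residue_to_author = {
        m + 1: author_ids[c] for m, c in pairs if member_seq[m] == chain_seq[c]
    }
    column_to_author = {r2c[r]: a for r, a in residue_to_author.items()}
    unresolved = {
        r2c[r] for r in range(1, len(member_seq) + 1) if r not in residue_to_author
    }
    first_m, first_c = pairs[0]
    offset = author_ids[first_c] - (first_m + 1)
    logger.info(
        "mapped chain %s to member %s: %d/%d residues resolved, identity %.1f%%, "
        "author-numbering offset %+d",
        chain.chain_id, member_id, len(residue_to_author), len(member_seq),
        100 * identity, offset,
    )
    return TargetMap(
        family_id=alignment.family_id,
        member_id=member_id,
        chain_id=chain.chain_id,
        column_to_author=column_to_author,
        residue_to_author=residue_to_author,
        unresolved_columns=unresolved,
        offset=offset,
    )


def read_disorder_annotation(source) -> dict[str, set[int]]:
    """Read per-residue disorder ranges: TSV with member_id, start, end (1-based, closed)."""
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and "\n" in source:
        handle = io.StringIO(source)
    else:
        handle = open(Path(source), "r", encoding="utf-8", newline="")
    reader = csv.DictReader(handle, delimiter="\t")
    out: dict[str, set[int]] = {}
    for row in reader:
        member = row["member_id"].strip()
        start, end = int(row["start"]), int(row["end"])
        out.setdefault(member, set()).update(range(start, end + 1))
    return out


def assign_unresolved_sasa(
    member_seq: str,
    target_map: TargetMap,
    sasa_map: Mapping[int, float],
    disorder: Iterable[int] | None = None,
    interface_residues: Iterable[tuple[str, int]] | None = None,
    burial_threshold: float = DEFAULT_BURIAL_THRESHOLD,
    assume_terminal_disorder: bool = False,
    max_terminal_run: int = MAX_TERMINAL_DISORDER_RUN,
) -> dict[int, ResidueStructureInfo]:
    """Complete per-residue structural info, rescuing disordered tails.

    Resolved residues get their computed SASA normalized by the residue-type
    theoretical maximum.  Residues absent from the structure that are
    annotated disordered (``disorder`` = 1-based member residue indices) are
    assigned the maximum SASA of their residue type (relative SASA 1.0) —
    an unmodeled flexible segment is fully exposed in solution.  Unresolved
    residues with no disorder evidence are excluded from scoring with a
    warning.  With ``assume_terminal_disorder``, unresolved terminal runs of
    at most ``max_terminal_run`` residues count as disordered even without
    an annotation.
    """
    disorder = set(disorder or ())
    interface_set = set(interface_residues or ())
    n = len(member_seq)
    resolved = set(target_map.residue_to_author)

    if assume_terminal_disorder:
        run: list[int] = []
        for r in range(1, n + 1):
            if r in resolved:
                break
            run.append(r)
        if 0 < len(run) <= max_terminal_run:
            disorder.update(run)
        run = []
        for r in range(n, 0, -1):
            if r in resolved:
                break
            run.append(r)
        if 0 < len(run) <= max_terminal_run:
            disorder.update(run)

    info: dict[int, ResidueStructureInfo] = {}
    n_excluded = 0
    for r in range(1, n + 1):
        aa = member_seq[r - 1]
        max_sasa = MAX_SASA[aa]
        author = target_map.residue_to_author.get(r)
        if author is not None and author in sasa_map:
            sasa = float(sasa_map[author])
            rel = min(1.0, sasa / max_sasa)
            info[r] = ResidueStructureInfo(
                chain_id=target_map.chain_id,
                author_seq_id=author,
                sasa=sasa,
                relative_sasa=rel,
                buried=rel < burial_threshold,
                interface=(target_map.chain_id, author) in interface_set,
                disordered_unresolved=False,
            )
        elif r in disorder:
            info[r] = ResidueStructureInfo(
                chain_id=target_map.chain_id,
                author_seq_id=None,
                sasa=max_sasa,
                relative_sasa=1.0,
                buried=False,
                interface=False,
                disordered_unresolved=True,
            )
        else:
            n_excluded += 1
    if n_excluded:
        logger.warning(
            "%d unresolved residues without disorder evidence excluded from scoring",
            n_excluded,
        )
    return info


def _structure_to_gemmi(
    structure: StructureModel, b_factors: Mapping[tuple[str, int], float]
) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for ch in structure.chains:
        gchain = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            b = float(b_factors.get((ch.chain_id, res.seq_id), 0.0))
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.xyz)
                gatom.occ = 1.0
                gatom.b_iso = b
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_projection(
    structure: StructureModel,
    target_map: TargetMap,
    hotspots: Sequence[Hotspot],
    out_dir,
    basename: str = "projection",
) -> dict[str, Path]:
    """Write the structural projection artifacts for a hotspot set.

    Produces (i) a PDB copy whose B-factor column carries each residue's
    total PTM count (0 elsewhere), (ii) a PyMOL command script that shows
    side-chain van der Waals spheres for every mapped hotspot residue and
    applies the PTM-count color code, and (iii) a sidecar TSV listing
    hotspot columns that could not be mapped onto the structure (these are
    reported, never fatal).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b_factors: dict[tuple[str, int], float] = {}
    script_lines: list[str] = [
        "# structural projection of PTM hotspots",
        "set sphere_scale, 1.0",
    ]
    unmapped: list[Hotspot] = []
    for h in sorted(hotspots, key=lambda h: h.column):
        author = target_map.column_to_author.get(h.column)
        if author is None:
            unmapped.append(h)
            continue
        b_factors[(target_map.chain_id, author)] = float(h.total_ptms)
        color = color_for_count(h.total_ptms)
        sel = f"chain {target_map.chain_id} and resi {author}"
        script_lines.append(
            f"# column {h.column}: {h.total_ptms} PTM(s) -> {color}"
        )
        script_lines.append(f"show spheres, ({sel}) and sidechain")
        if color != "default":
            script_lines.append(f"color {color}, {sel}")

    pdb_path = out_dir / f"{basename}.pdb"
    pml_path = out_dir / f"{basename}.pml"
    report_path = out_dir / f"{basename}_unmapped.tsv"

    st = _structure_to_gemmi(structure, b_factors)
    pdb_path.write_text(st.make_pdb_string(), encoding="utf-8")
    pml_path.write_text("\n".join(script_lines) + "\n", encoding="utf-8")
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("column\ttotal_ptms\treason\n")
        for h in unmapped:
            reason = (
                "unresolved_in_structure"
                if h.column in target_map.unresolved_columns
                else "not_in_target_member"
            )
            fh.write(f"{h.column}\t{h.total_ptms}\t{reason}\n")
    if unmapped:
        logger.info("%d hotspot columns not mappable onto the structure", len(unmapped))
    return {"pdb": pdb_path, "script": pml_path, "unmapped": report_path}
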