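"""Hotspot analysis: layer PTM records onto alignment columns.

A hotspot is one alignment column that received at least one experimentally
observed PTM from any family member.  Its intensity is the total PTM count,
and two conservation features are attached: CS, the conservation of the
column itself, and PRC, the fraction of members carrying a residue that is
chemically modifiable by the hotspot's modification types (S/T/Y for
phosphorylation, K for ubiquitination, and so on).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalog import PTMRecord
from .errors import ValidationError
from .msa import GAP, FamilyAlignment

logger = logging.getLogger(__name__)

#: Residues chemically capable of carrying each modification type.
MODIFIABLE_RESIDUES: Mapping[str, frozenset[str]] = {
    "phosphorylation": frozenset("STY"),
    "ubiquitination": frozenset("K"),
    "acetylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "palmitoylation": frozenset("C"),
    "s-nitrosylation": frozenset("C"),
    "prenylation": frozenset("C"),
    "myristoylation": frozenset("G"),
}


@dataclass
class Hotspot:
    """One alignment column's aggregated PTM evidence."""

    family_id: str
    column: int  # 1-based alignment column
    total_ptms: int
    per_type_counts: dict[str, int]
    contributing: list[tuple[str, int, str]]  # (member_id, residue_index, mod_type)
    known_function: bool
    cs: float  # column conservation, [0, 1]
    prc: float  # modifiable-residue conservation, [0, 1]

    @property
    def n_types(self) -> int:
        return sum(1 for c in self.per_type_counts.values() if c > 0)

    @property
    def mod_types(self) -> set[str]:
        return {t for t, c in self.per_type_counts.items() if c > 0}


def column_conservation(
    alignment: FamilyAlignment,
    column: int,
    residue_classes: Sequence[str] | None = None,
) -> float:
    """Conservation of an alignment column in [0, 1].

    Default: frequency of the modal residue among non-gap rows; gaps are
    excluded from numerator and denominator, and an all-gap column scores 0.
    ``residue_classes`` optionally groups residues (e.g. ``["ST", "KR"]``)
    so that substitutions within a class count as conserved.
    """
    letters = [aa for aa in alignment.column_letters(column) if aa != GAP]
    if not letters:
        return 0.0
    if residue_classes:
        cls = {}
        for group in residue_classes:
            for aa in group:
                cls[aa] = group
        letters = [cls.get(aa, aa) for aa in letters]
    counts = Counter(letters)
    return counts.most_common(1)[0][1] / len(letters)


def modifiable_residue_conservation(
    alignment: FamilyAlignment,
    column: int,
    mod_types: Iterable[str],
    observed_residues: Iterable[str] = (),
) -> float:
    """Fraction of non-gap rows carrying a residue modifiable by ``mod_types``.

    For ``other:<label>`` types outside the built-in table, the modifiable
    set falls back to the residues actually observed modified at the column
    (``observed_residues``).
    """
    mod_types = set(mod_types)
    if not mod_types:
        raise ValidationError("mod_types must be nonempty")
    allowed: set[str] = set()
    for mod in mod_types:
        residues = MODIFIABLE_RESIDUES.get(mod)
        if residues is None:
            residues = frozenset(observed_residues)
        allowed |= residues
    letters = [aa for aa in alignment.column_letters(column) if aa != GAP]
    if not letters:
        return 0.0
    return sum(1 for aa in letters if aa in allowed) / len(letters)


def build_hotspots(
    alignment: FamilyAlignment,
    records: Sequence[PTMRecord],
    id_map: Mapping[str, str] | None = None,
    cs_residue_classes: Sequence[str] | None = None,
) -> list[Hotspot]:
    """Group deduplicated PTM records by the alignment column they map to.

    ``id_map`` translates record protein accessions to alignment member ids
    (identity by default).  Records on members absent from the map are
    reported unmapped; records whose residue letter disagrees with the
    member's sequence at that position are reported and excluded — a
    mismatch means an isoform or numbering error and neither source can be
    trusted.  The sum of hotspot intensities equals the number of mapped,
    letter-matching records.
    """
    if id_map is None:
        id_map = {mid: mid for mid in alignment.member_ids}
    known_members = set(alignment.member_ids)
    per_column: dict[int, list[PTMRecord]] = {}
    n_unmapped = n_mismatch = n_out_of_range = 0
    for rec in records:
        member = id_map.get(rec.protein_id)
        if member is None or member not in known_members:
            n_unmapped += 1
            logger.warning("record %s: protein not in id_map/alignment", rec.key)
            continue
        seq = alignment.ungapped(member)
        if rec.residue_index > len(seq):
            n_out_of_range += 1
            logger.warning(
                "record %s: residue %d beyond member length %d",
                rec.key, rec.residue_index, len(seq),
            )
            continue
        if seq[rec.residue_index - 1] != rec.residue:
            n_mismatch += 1
            logger.warning(
                "record %s: residue letter %r does not match alignment %r",
                rec.key, rec.residue, seq[rec.residue_index - 1],
            )
            continue
        column = alignment.residue_to_column[member][rec.residue_index]
        per_column.setdefault(column, []).append(rec)
    if n_unmapped or n_mismatch or n_out_of_range:
        logger.info(
            "build_hotspots excluded %d unmapped, %d letter-mismatch, %d out-of-range records",
            n_unmapped, n_mismatch, n_out_of_range,
        )

    hotspots: list[Hotspot] = []
    for column in sorted(per_column):
        recs = per_column[column]
        per_type = Counter(rec.mod_type for rec in recs)
        contributing = sorted(
            (id_map[rec.protein_id], rec.residue_index, rec.mod_type) for rec in recs
        )
        observed = {rec.residue for rec in recs}
        hotspots.append(
            Hotspot(
                family_id=alignment.family_id,
                column=column,
                total_ptms=len(recs),
                per_type_counts=dict(sorted(per_type.items())),
                contributing=contributing,
                known_function=any(rec.known_function for rec in recs),
                cs=column_conservation(alignment, column, cs_residue_classes),
                prc=modifiable_residue_conservation(
                    alignment, column, set(per_type), observed
                ),
            )
        )
    return hotspots


HOTSPOT_TABLE_COLUMNS = (
    "family_id", "column", "total_ptms", "n_types", "per_type_counts",
    "cs", "prc", "known_function",
)


def write_hotspot_table(hotspots: Sequence[Hotspot], path) -> None:
    """Write hotspots as TSV; per-type counts are a JSON cell."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(HOTSPOT_TABLE_COLUMNS) + "\n")
        for h in hotspots:
            fh.write(
                "\t".join(
                    [
                        h.family_id,
                        str(h.column),
                        str(h.total_ptms),
                        str(h.n_types),
                        json.dumps(h.per_type_counts, sort_keys=True),
                        f"{h.cs:.6f}",
                        f"{h.prc:.6f}",
                        str(h.known_function).lower(),
                    ]
                )
                + "\n"
            )
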