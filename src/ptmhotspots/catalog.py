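"""Catalog of experimentally observed post-translational modifications.

One PTM record is a single experimental observation of a modification
(phosphorylation, ubiquitination, acetylation, ...) on one residue of one
protein.  Public PTM databases disagree on labels and overlap heavily, so the
reader normalizes modification-type vocabulary, deduplication collapses
observations of the same site reported by several sources, and a separate
function table attaches literature-backed "known function" flags to the
subset of sites whose biological role has actually been demonstrated.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Controlled vocabulary for modification types.
CANONICAL_MOD_TYPES = frozenset(
    {
        "phosphorylation",
        "ubiquitination",
        "acetylation",
        "methylation",
        "palmitoylation",
        "myristoylation",
        "prenylation",
        "s-nitrosylation",
    }
)

#: Source databases disagree on naming; map common variants onto the
#: controlled vocabulary (matched case-insensitively after stripping).
MOD_SYNONYMS: Mapping[str, str] = {
    "phospho": "phosphorylation",
    "phosphorylated": "phosphorylation",
    "phosphoserine": "phosphorylation",
    "phosphothreonine": "phosphorylation",
    "phosphotyrosine": "phosphorylation",
    "ubiquitin": "ubiquitination",
    "ubiquitinylation": "ubiquitination",
    "ubiquitylation": "ubiquitination",
    "acetyl": "acetylation",
    "acetylated": "acetylation",
    "methyl": "methylation",
    "methylated": "methylation",
    "mono-methylation": "methylation",
    "dimethylation": "methylation",
    "trimethylation": "methylation",
    "palmitoyl": "palmitoylation",
    "s-palmitoylation": "palmitoylation",
    "myristoyl": "myristoylation",
    "n-myristoylation": "myristoylation",
    "prenyl": "prenylation",
    "geranylgeranylation": "prenylation",
    "farnesylation": "prenylation",
    "nitrosylation": "s-nitrosylation",
    "s-nitrosation": "s-nitrosylation",
}

_TRUE_STRINGS = {"true", "t", "1", "yes", "y"}
_FALSE_STRINGS = {"false", "f", "0", "no", "n", ""}


def normalize_mod_type(label: str) -> str:
    """Map a free-text modification label onto the controlled vocabulary.

    Unknown labels pass through as ``other:<label>`` rather than being
    rejected, so rare modification types survive the import.
    """
    raw = label.strip()
    if not raw:
        raise ValidationError("empty modification type")
    low = raw.lower()
    if low.startswith("other:"):
        return low
    if low in CANONICAL_MOD_TYPES:
        return low
    if low in MOD_SYNONYMS:
        return MOD_SYNONYMS[low]
    return f"other:{low}"


@dataclass
class PTMRecord:
    """One experimentally observed modification on one residue of one protein."""

    protein_id: str
    residue_index: int  # 1-based position in the full-length protein
    residue: str  # one-letter amino-acid code
    mod_type: str
    organism: str = ""
    evidence: str = ""
    experimental: bool = True
    known_function: bool = False
    citation: str | None = None

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValidationError(
                f"{self.protein_id}: residue_index must be >= 1, got {self.residue_index}"
            )
        self.residue = self.residue.upper()
        if self.residue not in AMINO_ACIDS:
            raise ValidationError(
                f"{self.protein_id}:{self.residue_index}: invalid residue letter "
                f"{self.residue!r}"
            )
        self.mod_type = normalize_mod_type(self.mod_type)

    @property
    def key(self) -> tuple[str, int, str]:
        """Deduplication key: one site, one modification type."""
        return (self.protein_id, self.residue_index, self.mod_type)


REQUIRED_COLUMNS = ("protein_id", "residue_index", "residue", "mod_type")
OPTIONAL_COLUMNS = ("organism", "evidence", "experimental", "known_function", "citation")


def _parse_bool(value: str, default: bool) -> bool:
    low = value.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return default if low == "" else False
    raise ValueError(f"not a boolean: {value!r}")


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    if isinstance(source, str) and ("\n" in source or source == ""):
        return io.StringIO(source)
    return open(Path(source), "r", encoding="utf-8", newline="")


def read_ptm_table(
    source,
    dialect: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[PTMRecord]:
    """Read PTM records from a delimited text table.

    Parameters
    ----------
    source
        Path, open text handle, or the table contents as a string.
    dialect
        Optional map from canonical column names (``protein_id``,
        ``residue_index``, ...) to the column names actually used by the
        source database, so each of the upstream databases can be imported
        without a bespoke parser.

    Rows whose residue index or residue letter cannot be parsed are rejected
    and reported (with their line number) via the module logger; missing
    optional columns default to ``experimental=True``, ``known_function=False``.
    An empty table yields an empty list.
    """
    dialect = dict(dialect or {})
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter=delimiter)
    if reader.fieldnames is None:
        return []
    fields = set(reader.fieldnames)

    colname = {canon: dialect.get(canon, canon) for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    for canon in REQUIRED_COLUMNS:
        if colname[canon] not in fields:
            raise ConfigurationError(
                f"required column {canon!r} (mapped to {colname[canon]!r}) "
                f"not found in header {sorted(fields)}"
            )

    records: list[PTMRecord] = []
    for lineno, row in enumerate(reader, start=2):  # line 1 is the header
        def cell(canon: str, default: str = "") -> str:
            value = row.get(colname[canon])
            return default if value is None else value

        try:
            residue_index = int(cell("residue_index").strip())
            record = PTMRecord(
                protein_id=cell("protein_id").strip(),
                residue_index=residue_index,
                residue=cell("residue").strip(),
                mod_type=cell("mod_type"),
                organism=cell("organism").strip(),
                evidence=cell("evidence").strip(),
                experimental=_parse_bool(cell("experimental"), default=True),
                known_function=_parse_bool(cell("known_function"), default=False),
                citation=cell("citation").strip() or None,
            )
        except (ValueError, ValidationError) as exc:
            logger.warning("line %d rejected: %s", lineno, exc)
            continue
        records.append(record)
    return records


def _merge_citations(*citations: str | None) -> str | None:
    seen: list[str] = []
    for cit in citations:
        if not cit:
            continue
        for part in cit.split("; "):
            if part and part not in seen:
                seen.append(part)
    return "; ".join(seen) or None


def deduplicate(records: Sequence[PTMRecord]) -> list[PTMRecord]:
    """Collapse records sharing (protein_id, residue_index, mod_type).

    The same site is typically reported by several source databases; after
    deduplication each site/modification pair appears exactly once.
    ``known_function`` is OR-merged, citations and evidence labels are
    concatenated, and the output is sorted by key so the result is
    deterministic.  Duplicates that disagree on the residue letter indicate
    an isoform or off-by-one problem and raise :class:`ValidationError`.
    """
    by_key: dict[tuple[str, int, str], PTMRecord] = {}
    for rec in records:
        prev = by_key.get(rec.key)
        if prev is None:
            by_key[rec.key] = replace(rec)
            continue
        if prev.residue != rec.residue:
            raise ValidationError(
                f"conflicting residue letters for {rec.protein_id} position "
                f"{rec.residue_index}: {prev.residue!r} vs {rec.residue!r}"
            )
        prev.known_function = prev.known_function or rec.known_function
        prev.experimental = prev.experimental or rec.experimental
        prev.citation = _merge_citations(prev.citation, rec.citation)
        prev.evidence = ";".join(
            lab for lab in dict.fromkeys(prev.evidence.split(";") + rec.evidence.split(";")) if lab
        )
    return [by_key[k] for k in sorted(by_key)]


def filter_records(
    records: Sequence[PTMRecord],
    keep_experimental_only: bool = True,
    organism_filter: Callable[[str], bool] | None = None,
) -> list[PTMRecord]:
    """Drop predicted (non-experimental) sites and, optionally, organisms.

    Only experimentally observed sites in the organisms of interest (the
    caller supplies the predicate, e.g. eukaryotes only) enter the analysis.
    Order is preserved; removal counts are logged by reason.
    """
    kept: list[PTMRecord] = []
    removed = {"predicted": 0, "organism": 0}
    for rec in records:
        if keep_experimental_only and not rec.experimental:
            removed["predicted"] += 1
            continue
        if organism_filter is not None and not organism_filter(rec.organism):
            removed["organism"] += 1
            continue
        kept.append(rec)
    if any(removed.values()):
        logger.info(
            "filter_records removed %d predicted and %d by organism; %d kept",
            removed["predicted"], removed["organism"], len(kept),
        )
    if not kept and records:
        logger.warning("filter_records removed every record")
    return kept


def read_function_table(
    source, dialect: Mapping[str, str] | None = None, delimiter: str = "\t"
) -> list[dict]:
    """Read a known-function table: protein_id, residue_index, mod_type, citation."""
    dialect = dict(dialect or {})
    handle = _open_text(source)
    reader = csv.DictReader(handle, delimiter=delimiter)
    if reader.fieldnames is None:
        return []
    rows: list[dict] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            rows.append(
                {
                    "protein_id": row[dialect.get("protein_id", "protein_id")].strip(),
                    "residue_index": int(row[dialect.get("residue_index", "residue_index")]),
                    "mod_type": normalize_mod_type(row[dialect.get("mod_type", "mod_type")]),
                    "citation": (row.get(dialect.get("citation", "citation")) or "").strip(),
                }
            )
        except (KeyError, ValueError, ValidationError) as exc:
            logger.warning("function table line %d rejected: %s", lineno, exc)
    return rows


def annotate_known_function(
    records: Sequence[PTMRecord], function_rows: Iterable[Mapping]
) -> list[PTMRecord]:
    """Flag records whose site appears in the literature-mined function table.

    Matching records get ``known_function=True`` with the citation attached
    (several table rows on the same site join their citations).  Table rows
    matching no record are reported as orphans — a warning, not an error,
    since the function table is mined independently of the PTM compilation.
    """
    out = [replace(rec) for rec in records]
    index: dict[tuple[str, int, str], PTMRecord] = {rec.key: rec for rec in out}
    n_orphans = 0
    for row in function_rows:
        key = (row["protein_id"], int(row["residue_index"]), normalize_mod_type(row["mod_type"]))
        rec = index.get(key)
        if rec is None:
            n_orphans += 1
            logger.warning("function table orphan: no PTM record for %s", key)
            continue
        rec.known_function = True
        rec.citation = _merge_citations(rec.citation, row.get("citation"))
    if n_orphans:
        logger.info("%d function-table rows matched no record", n_orphans)
    return out
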