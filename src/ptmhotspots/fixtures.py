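"""Synthetic protein-family fixtures with planted PTM hotspots.

The generator emulates the statistical structure the method is built to
exploit: a family of homologous sequences in which some alignment columns
are PTM hotspots, and hotspots whose function is "known" carry a stronger
signal on every axis — they are observed more often (higher intensity),
their column is more conserved, the modifiable residue is retained in more
members, and a configurable fraction of them sit in an intrinsically
disordered N-terminal tail that the accompanying structure leaves
unresolved (hence fully solvent-exposed after disorder rescue).  Because
the signal is planted parametrically, recovering the separation is a
parameter-recovery test rather than a tautology, and a null mode with
identical class distributions must show no separation.

Everything is driven by one integer seed; a fixed seed reproduces every
emitted byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .hotspots import MODIFIABLE_RESIDUES
from .msa import GAP, FamilyAlignment

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic family.

    Defaults describe a family of 30 members, 150 columns, with 10
    known-function and 40 unknown hotspots; known hotspots average 5
    observations at 95% column conservation versus 1.5 observations at 60%
    for unknown ones, and 30% of known hotspots live in a 12-residue
    disordered N-terminal tail.  ``null_mode`` gives the known class the
    unknown class's distributions (labels kept), for negative controls.
    """

    n_members: int = 30
    seq_length: int = 150
    substitution_rate: float = 0.4  # background per-site substitution
    indel_rate: float = 0.02  # per-member, per-site gap probability
    n_hotspots_known: int = 10
    n_hotspots_unknown: int = 40
    known_count_mean: float = 5.0  # planted PTMs per known hotspot
    unknown_count_mean: float = 1.5
    known_conservation: float = 0.95  # ancestor-residue retention at the column
    unknown_conservation: float = 0.6
    mod_types: tuple[str, ...] = (
        "phosphorylation", "ubiquitination", "acetylation", "methylation",
    )
    disordered_tail_len: int = 12
    known_tail_fraction: float = 0.3  # fraction of known hotspots in the tail
    null_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "known_conservation",
                     "unknown_conservation", "known_tail_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        n_hot = self.n_hotspots_known + self.n_hotspots_unknown
        if n_hot > self.seq_length:
            raise ValidationError("more hotspots than columns")


@dataclass
class HotspotTruth:
    column: int
    mod_type: str
    known: bool
    conservation: float


@dataclass
class FamilyFixture:
    """A generated family: true alignment plus planted-hotspot truth."""

    spec: FixtureSpec
    alignment: FamilyAlignment
    hotspot_truth: list[HotspotTruth]
    ancestor: str

    @property
    def member_ids(self) -> list[str]:
        return self.alignment.member_ids


def _member_id(i: int) -> str:
    return f"SYN{i + 1:04d}"


def generate_family(spec: FixtureSpec, rng: np.random.Generator | None = None) -> FamilyFixture:
    """Evolve a family from a random ancestor with planted hotspot columns.

    Hotspot columns substitute at ``1 - conservation`` instead of the
    background rate and their ancestor residue is modifiable by the
    assigned modification type.  Member 1 is an anchor: it always retains
    the ancestor residue (and never gaps) at hotspot columns, so every
    planted hotspot has at least one plantable site and the family's
    structure target covers all hotspots.  Gaps are drawn i.i.d. per
    member and site at ``indel_rate`` (never at hotspot columns of the
    anchor).
    """
    rng = rng or np.random.default_rng(spec.seed)
    L = spec.seq_length
    known_cons = spec.unknown_conservation if spec.null_mode else spec.known_conservation

    tail = min(spec.disordered_tail_len, L)
    # null mode: identical class distributions, so no preferential tail placement
    tail_fraction = 0.0 if spec.null_mode else spec.known_tail_fraction
    n_tail_known = int(round(tail_fraction * spec.n_hotspots_known))
    n_tail_known = min(n_tail_known, tail)
    tail_cols = rng.choice(np.arange(1, tail + 1), size=n_tail_known, replace=False)
    body_pool = np.arange(tail + 1, L + 1)
    n_body = spec.n_hotspots_known - n_tail_known + spec.n_hotspots_unknown
    body_cols = rng.choice(body_pool, size=n_body, replace=False)
    known_cols = sorted(
        int(c) for c in np.concatenate(
            [tail_cols, body_cols[: spec.n_hotspots_known - n_tail_known]]
        )
    )
    unknown_cols = sorted(int(c) for c in body_cols[spec.n_hotspots_known - n_tail_known:])

    truth: list[HotspotTruth] = []
    cons_at: dict[int, float] = {}
    for col in known_cols:
        truth.append(HotspotTruth(col, str(rng.choice(spec.mod_types)), True, known_cons))
        cons_at[col] = known_cons
    for col in unknown_cols:
        truth.append(
            HotspotTruth(col, str(rng.choice(spec.mod_types)), False, spec.unknown_conservation)
        )
        cons_at[col] = spec.unknown_conservation
    truth.sort(key=lambda t: t.column)
    mod_at = {t.column: t.mod_type for t in truth}

    ancestor = [AMINO_ACIDS[k] for k in rng.integers(0, 20, size=L)]
    for t in truth:
        choices = sorted(MODIFIABLE_RESIDUES[t.mod_type])
        ancestor[t.column - 1] = str(rng.choice(choices))
    ancestor_str = "".join(ancestor)

    members: list[tuple[str, str]] = []
    for i in range(spec.n_members):
        row = []
        for col in range(1, L + 1):
            anchor_hotspot = i == 0 and col in mod_at
            if not anchor_hotspot and rng.random() < spec.indel_rate:
                row.append(GAP)
                continue
            keep_p = 1.0 - spec.substitution_rate
            if col in cons_at:
                keep_p = cons_at[col]
            if anchor_hotspot or rng.random() < keep_p:
                row.append(ancestor[col - 1])
            else:
                row.append(AMINO_ACIDS[int(rng.integers(0, 20))])
        members.append((_member_id(i), "".join(row)))

    alignment = FamilyAlignment.from_members(members, family_id=f"synfam{spec.seed}")
    return FamilyFixture(
        spec=spec, alignment=alignment, hotspot_truth=truth, ancestor=ancestor_str
    )


def plant_ptms(
    fixture: FamilyFixture, rng: np.random.Generator | None = None
) -> tuple[list[dict], list[dict], dict[int, list[dict]]]:
    """Emit PTM table rows (and known-function rows) for the planted hotspots.

    Per hotspot the observation count is 1 + Poisson(mean - 1) (so every
    hotspot has at least one observation — the method must cope with
    single-observation known sites).  Records go to distinct members
    carrying a modifiable, non-gap residue at the column; known hotspots
    additionally emit function-table rows.  Returns (ptm_rows,
    function_rows, truth_map column -> rows).
    """
    spec = fixture.spec
    rng = rng or np.random.default_rng(spec.seed + 1)
    aln = fixture.alignment
    known_mean = spec.unknown_count_mean if spec.null_mode else spec.known_count_mean

    ptm_rows: list[dict] = []
    function_rows: list[dict] = []
    truth_map: dict[int, list[dict]] = {}
    for t in fixture.hotspot_truth:
        mean = known_mean if t.known else spec.unknown_count_mean
        count = 1 + int(rng.poisson(max(mean - 1.0, 0.0)))
        modifiable = MODIFIABLE_RESIDUES[t.mod_type]
        eligible = [
            mid
            for mid, seq in aln.members
            if seq[t.column - 1] != GAP and seq[t.column - 1] in modifiable
        ]
        chosen = [
            str(m)
            for m in rng.choice(eligible, size=min(count, len(eligible)), replace=False)
        ]
        rows_here: list[dict] = []
        for mid in sorted(chosen):
            residue_index = aln.column_to_residue[mid][t.column]
            row = {
                "protein_id": mid,
                "organism": "synthetic",
                "residue_index": residue_index,
                "residue": aln.aligned(mid)[t.column - 1],
                "mod_type": t.mod_type,
                "evidence": "synthetic",
                "experimental": "true",
                "known_function": "false",
                "citation": "",
            }
            rows_here.append(row)
            if t.known:
                function_rows.append(
                    {
                        "protein_id": mid,
                        "residue_index": residue_index,
                        "mod_type": t.mod_type,
                        "citation": f"synthetic-truth:col{t.column}",
                    }
                )
        ptm_rows.extend(rows_here)
        truth_map[t.column] = rows_here
    return ptm_rows, function_rows, truth_map


# ideal alpha-helix parameters: 100 degrees and 1.5 A rise per residue; each
# backbone atom type sits on its own coaxial helix (radius, phase, z offset)
_HELIX_ATOMS = (
    # name, element, radius (A), phase offset (deg), z offset (A)
    ("N", "N", 1.60, -28.0, -0.90),
    ("CA", "C", 2.30, 0.0, 0.00),
    ("C", "C", 2.00, 27.0, 1.05),
    ("O", "O", 2.00, 24.0, 2.25),
    ("CB", "C", 3.30, 8.0, -0.35),
)
_TWIST_DEG = 100.0
_RISE = 1.5

from .structure import ONE_TO_THREE  # noqa: E402  (cycle-free, placed after data)


def generate_structure(
    sequence: str,
    disordered_prefix_len: int = 0,
    chain_id: str = "A",
    member_id: str = "SYN0001",
) -> tuple[str, list[dict]]:
    """Ideal α-helix PDB text for a sequence with an unresolved disordered tail.

    Residues 1..prefix are omitted from the coordinates (emulating a
    flexible N-terminal tail invisible to crystallography) and returned as
    disorder-annotation rows instead; author numbering of the modeled part
    matches the member numbering (prefix + 1 onward).  Backbone N/CA/C/O
    plus Cβ (except glycine) are placed on coaxial ideal-helix tracks with
    a 3.8 Å consecutive Cα–Cα distance.
    """
    if disordered_prefix_len >= len(sequence):
        raise ValidationError("disordered prefix must be shorter than the sequence")
    lines: list[str] = []
    serial = 0
    for i in range(disordered_prefix_len, len(sequence)):
        aa = sequence[i]
        resname = ONE_TO_THREE[aa]
        theta0 = np.deg2rad(_TWIST_DEG * i)
        z0 = _RISE * i
        for name, element, radius, phase, dz in _HELIX_ATOMS:
            if name == "CB" and aa == "G":
                continue
            serial += 1
            theta = theta0 + np.deg2rad(phase)
            x = radius * np.cos(theta)
            y = radius * np.sin(theta)
            z = z0 + dz
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {resname:3s} {chain_id}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
            )
    lines.append("END")
    disorder_rows = (
        [{"member_id": member_id, "start": 1, "end": disordered_prefix_len}]
        if disordered_prefix_len > 0
        else []
    )
    return "\n".join(lines) + "\n", disorder_rows


PTM_TABLE_COLUMNS = (
    "protein_id", "organism", "residue_index", "residue", "mod_type",
    "evidence", "experimental", "known_function", "citation",
)


def _write_tsv(path: Path, columns: tuple[str, ...], rows: list[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def write_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Generate a complete fixture on disk in the formats the pipeline reads.

    Writes unaligned FASTA, the true aligned FASTA, the target-member
    structure (PDB, disordered tail unresolved), the disorder TSV, the PTM
    table, the known-function table, and a JSON truth file.  Returns a
    manifest of paths plus the truth needed by recovery tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    fixture = generate_family(spec, rng)
    ptm_rows, function_rows, truth_map = plant_ptms(fixture, rng)
    target_member = fixture.member_ids[0]
    target_seq = fixture.alignment.ungapped(target_member)
    pdb_text, disorder_rows = generate_structure(
        target_seq,
        disordered_prefix_len=min(spec.disordered_tail_len, len(target_seq) - 1),
        member_id=target_member,
    )

    paths = {
        "unaligned_fasta": out_dir / "family.fasta",
        "alignment": out_dir / "family.aln.fasta",
        "structure": out_dir / "target.pdb",
        "disorder": out_dir / "disorder.tsv",
        "ptm_table": out_dir / "ptms.tsv",
        "function_table": out_dir / "functions.tsv",
        "truth": out_dir / "truth.json",
    }
    with open(paths["unaligned_fasta"], "w", encoding="utf-8") as fh:
        for mid in fixture.member_ids:
            fh.write(f">{mid}\n{fixture.alignment.ungapped(mid)}\n")
    with open(paths["alignment"], "w", encoding="utf-8") as fh:
        for mid, seq in fixture.alignment.members:
            fh.write(f">{mid}\n{seq}\n")
    paths["structure"].write_text(pdb_text, encoding="utf-8")
    _write_tsv(paths["disorder"], ("member_id", "start", "end"), disorder_rows)
    _write_tsv(paths["ptm_table"], PTM_TABLE_COLUMNS, ptm_rows)
    _write_tsv(
        paths["function_table"],
        ("protein_id", "residue_index", "mod_type", "citation"),
        function_rows,
    )
    truth = {
        "spec": asdict(spec),
        "family_id": fixture.alignment.family_id,
        "target_member": target_member,
        "target_chain": "A",
        "hotspots": [asdict(t) for t in truth_sorted(fixture)],
        "n_ptm_records": len(ptm_rows),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2) + "\n", encoding="utf-8")
    manifest = {name: str(p) for name, p in paths.items()}
    manifest.update(
        family_id=fixture.alignment.family_id,
        target_member=target_member,
        target_chain="A",
    )
    return manifest


def truth_sorted(fixture: FamilyFixture) -> list[HotspotTruth]:
    return sorted(fixture.hotspot_truth, key=lambda t: t.column)
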