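"""Run the full method on an in-memory synthetic family.

Glue for evaluation runs: generate a family, plant PTMs, build the target
structure, and push everything through hotspot building, projection, and
function-potential ranking without touching disk.  Used by the planted-
signal recovery checks and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import PTMRecord, annotate_known_function, deduplicate
from .fixtures import FamilyFixture, FixtureSpec, generate_family, generate_structure, plant_ptms
from .hotspots import Hotspot, build_hotspots
from .projection import assign_unresolved_sasa, map_alignment_to_structure
from .scoring import FPResult, FPWeights, compute_fp, rank_hotspots
from .structure import read_structure, shrake_rupley_sasa


@dataclass
class FixtureEvaluation:
    fixture: FamilyFixture
    hotspots: list[Hotspot]
    results: list[FPResult]  # ranked

    @property
    def known_above_median(self) -> tuple[int, int]:
        """(number of known-function hotspots above the family median FP, total known)."""
        known = [r for r in self.results if r.known_function]
        above = sum(1 for r in known if r.fp > r.family_median_fp)
        return above, len(known)


def evaluate_fixture(
    spec: FixtureSpec, weights: FPWeights | None = None
) -> FixtureEvaluation:
    """Generate a synthetic family and score it end to end.

    The projection target is the family's anchor member; its N-terminal
    disordered tail is left out of the structure and rescued through the
    disorder annotation, exactly as in a file-based run.
    """
    rng = np.random.default_rng(spec.seed)
    fixture = generate_family(spec, rng)
    ptm_rows, function_rows, _ = plant_ptms(fixture, rng)
    records = deduplicate(
        [
            PTMRecord(
                r["protein_id"], int(r["residue_index"]), r["residue"], r["mod_type"]
            )
            for r in ptm_rows
        ]
    )
    records = annotate_known_function(records, function_rows)

    target = fixture.member_ids[0]
    target_seq = fixture.alignment.ungapped(target)
    prefix = min(spec.disordered_tail_len, len(target_seq) - 1)
    pdb_text, disorder_rows = generate_structure(target_seq, prefix, member_id=target)
    structure = read_structure(pdb_text)
    chain = structure.chains[0]

    hotspots = build_hotspots(fixture.alignment, records)
    target_map = map_alignment_to_structure(fixture.alignment, target, chain)
    sasa = shrake_rupley_sasa(chain)
    disorder = set(range(1, prefix + 1)) if disorder_rows else set()
    weights = weights or FPWeights()
    info = assign_unresolved_sasa(
        target_seq,
        target_map,
        sasa,
        disorder=disorder,
        burial_threshold=weights.burial_threshold,
    )
    c2r = fixture.alignment.column_to_residue[target]
    scored = []
    for h in hotspots:
        res = compute_fp(h, info.get(c2r.get(h.column, -1)), weights=weights)
        if res is not None:
            scored.append(res)
    results = rank_hotspots(scored, group_by="family")
    return FixtureEvaluation(fixture=fixture, hotspots=hotspots, results=results)
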