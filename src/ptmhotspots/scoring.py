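"""Function Potential (FP) scoring and ranking of PTM hotspots.

FP combines four signals, each of which is expected to raise the chance
that a modification matters biologically: how often the modification has
been observed (PS, the hotspot intensity), how solvent-accessible the
residue is on the folded structure, whether it sits at a protein–protein
interface, and how conserved both the column (CS) and a modifiable residue
at the column (PRC) are.  The default combination is multiplicative:

    IS  = PS x (1 + w_if)          if interface else PS
    FP  = IS x relSASA x (cs_scale x CS) x (prc_scale x PRC)   (exposed)
    FP_b= IS x theta_b x (cs_scale x CS) x (prc_scale x PRC)   (buried)

with relSASA the SASA normalized by the residue-type theoretical maximum
and theta_b the burial threshold on relative SASA, so the two branches
agree exactly at the threshold.  Buried residues (relSASA < theta_b) score
on the FP_b branch: a deeply buried site is unlikely to be modified on the
folded protein, but is not assigned zero outright.  Absolute FP magnitudes
are arbitrary under rescaling of the weights; rank order is the contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .hotspots import Hotspot
from .projection import ResidueStructureInfo

logger = logging.getLogger(__name__)


@dataclass
class FPWeights:
    """Tunable weights of the FP combination (all positive)."""

    interface_boost: float = 1.0  # w_if: interface doubles PS by default
    burial_threshold: float = 0.05  # theta_b on relative SASA
    buried_penalty: float | None = None  # defaults to theta_b (continuity)
    prc_scale: float = 100.0  # express PRC as a percentage
    cs_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.buried_penalty is None:
            self.buried_penalty = self.burial_threshold
        if not 0.0 < self.burial_threshold < 1.0:
            raise ValidationError("burial_threshold must lie in (0, 1)")
        for name in ("interface_boost", "buried_penalty", "prc_scale", "cs_scale"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class FPResult:
    """A scored hotspot with its audit trail and (after ranking) its rank."""

    hotspot: Hotspot
    ps: float
    interface_score: float
    relative_sasa: float
    interface: bool
    cs: float
    prc: float
    fp: float
    branch: str  # "exposed" | "buried"
    rank: int | None = None
    family_median_fp: float | None = None
    fold_over_median: float | None = None

    @property
    def column(self) -> int:
        return self.hotspot.column

    @property
    def family_id(self) -> str:
        return self.hotspot.family_id

    @property
    def known_function(self) -> bool:
        return self.hotspot.known_function


def ptm_score(hotspot: Hotspot, mode: str = "linear") -> float:
    """PS, the intensity term: the total observed PTMs at the hotspot.

    ``mode="log"`` selects a log-damped alternative (1 + ln(count)) for
    corpora where a few heavily re-observed sites would otherwise dominate.
    """
    if hotspot.total_ptms < 1:
        raise ValidationError("hotspot must contain at least one PTM")
    if mode == "linear":
        return float(hotspot.total_ptms)
    if mode == "log":
        return 1.0 + math.log(hotspot.total_ptms)
    raise ValidationError(f"unknown ptm_score mode {mode!r}")


def interface_score(ps: float, interface: bool, interface_boost: float = 1.0) -> float:
    """IS: the PTM score, boosted when the residue sits at an interface."""
    if ps <= 0:
        raise ValidationError("PS must be positive")
    return ps * (1.0 + interface_boost) if interface else ps


def compute_fp(
    hotspot: Hotspot,
    residue_info: ResidueStructureInfo | None,
    weights: FPWeights | None = None,
    ptm_score_mode: str = "linear",
) -> FPResult | None:
    """Score one hotspot; returns None (with a warning) when it cannot be.

    A hotspot can only be scored with structural context — either a
    resolved residue on the projection target or a disordered-unresolved
    residue assigned full accessibility.
    """
    weights = weights or FPWeights()
    if residue_info is None:
        logger.warning(
            "hotspot at column %d has no mapped residue info; skipped", hotspot.column
        )
        return None
    ps = ptm_score(hotspot, ptm_score_mode)
    is_score = interface_score(ps, residue_info.interface, weights.interface_boost)
    conservation = (weights.cs_scale * hotspot.cs) * (weights.prc_scale * hotspot.prc)
    exposed = (
        residue_info.relative_sasa >= weights.burial_threshold
        or residue_info.disordered_unresolved
    )
    if exposed:
        fp = is_score * residue_info.relative_sasa * conservation
        branch = "exposed"
    else:
        fp = is_score * weights.buried_penalty * conservation
        branch = "buried"
    return FPResult(
        hotspot=hotspot,
        ps=ps,
        interface_score=is_score,
        relative_sasa=residue_info.relative_sasa,
        interface=residue_info.interface,
        cs=hotspot.cs,
        prc=hotspot.prc,
        fp=fp,
        branch=branch,
    )


def rank_hotspots(
    results: Sequence[FPResult], group_by: str = "family"
) -> list[FPResult]:
    """Rank scored hotspots (descending FP) and attach fold-over-median.

    ``group_by="family"`` ranks and takes the median within each family;
    ``group_by="pooled"`` treats all results as one group (the mode used to
    compare subunit families of one complex side by side).  Ties break
    deterministically by (total PTMs descending, column ascending).
    """
    if not results:
        raise ValidationError("no results to rank")
    if group_by not in ("family", "pooled"):
        raise ValidationError(f"group_by must be 'family' or 'pooled', got {group_by!r}")
    groups: dict[str, list[FPResult]] = {}
    for res in results:
        key = res.family_id if group_by == "family" else "__pooled__"
        groups.setdefault(key, []).append(res)
    ranked: list[FPResult] = []
    for key in sorted(groups):
        members = sorted(
            groups[key],
            key=lambda r: (-r.fp, -r.hotspot.total_ptms, r.column),
        )
        median = float(np.median([r.fp for r in members]))
        for rank, res in enumerate(members, start=1):
            res.rank = rank
            res.family_median_fp = median
            res.fold_over_median = res.fp / median if median > 0 else None
        ranked.extend(members)
    return ranked


SCORE_TABLE_COLUMNS = (
    "family_id", "column", "total_ptms", "known_function", "ps", "interface_score",
    "relative_sasa", "interface", "cs", "prc", "branch", "fp", "rank",
    "family_median_fp", "fold_over_median",
)


def write_score_table(results: Sequence[FPResult], path) -> None:
    """Write scored/ranked hotspots as TSV with the full audit trail."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SCORE_TABLE_COLUMNS) + "\n")
        for r in results:
            fold = "" if r.fold_over_median is None else f"{r.fold_over_median:.4f}"
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        str(r.column),
                        str(r.hotspot.total_ptms),
                        str(r.known_function).lower(),
                        f"{r.ps:.4f}",
                        f"{r.interface_score:.4f}",
                        f"{r.relative_sasa:.6f}",
                        str(r.interface).lower(),
                        f"{r.cs:.6f}",
                        f"{r.prc:.6f}",
                        r.branch,
                        f"{r.fp:.6f}",
                        str(r.rank if r.rank is not None else ""),
                        f"{r.family_median_fp:.6f}" if r.family_median_fp is not None else "",
                        fold,
                    ]
                )
                + "\n"
            )
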