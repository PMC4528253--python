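"""Known-vs-unknown separation statistics and corpus summaries.

The evaluation logic: if a ranking factor is informative, hotspots whose
biological function has been demonstrated ("known") should concentrate at
the top of the ranking.  Separation is summarized by the ratio of class
means (normalized so the unknown class sits at 1) and tested with a
two-sided Mann–Whitney U — exact by enumeration for small samples,
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .catalog import PTMRecord
from .errors import ValidationError
from .hotspots import Hotspot
from .scoring import FPResult

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8  # exact Mann-Whitney enumeration up to this size per class


def mann_whitney_u(
    known: Sequence[float], unknown: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U of ``known`` vs ``unknown``.

    Returns (U, p) with U the statistic of the known sample (pairs where
    known > unknown, ties counting 1/2).  ``method``: "exact" enumerates
    every label split (feasible and default for n <= 8 per class, ties
    handled naturally), "asymptotic" uses the tie-corrected normal
    approximation, "auto" picks between them.
    """
    x = np.asarray(known, float)
    y = np.asarray(unknown, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both classes must be nonempty")
    n, m = len(x), len(y)
    if method == "auto":
        method = "exact" if (n <= EXACT_MAX_N and m <= EXACT_MAX_N) else "asymptotic"

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)

    if method == "asymptotic":
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return u_obs, float(res.pvalue)
    if method != "exact":
        raise ValidationError(f"unknown method {method!r}")

    # Exact: enumerate every way of labelling n of the pooled values as
    # "known"; p is the fraction of splits at least as extreme (in |U - nm/2|)
    # as observed.  Ranks are shared across splits so ties need no special case.
    center = n * m / 2.0
    dev_obs = abs(u_obs - center)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(n + m), n):
        u = float(ranks[list(idx)].sum() - n * (n + 1) / 2)
        total += 1
        if abs(u - center) >= dev_obs - 1e-9:
            extreme += 1
    return u_obs, extreme / total


@dataclass
class SeparationReport:
    """Known-vs-unknown separation for one ranking factor."""

    factor: str
    mean_known: float
    mean_unknown: float
    normalized_mean_known: float  # unknown class normalized to 1
    fold_difference: float
    u_statistic: float
    p_value: float
    n_known: int
    n_unknown: int

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "mean_known": self.mean_known,
            "mean_unknown": self.mean_unknown,
            "normalized_mean_known": self.normalized_mean_known,
            "fold_difference": self.fold_difference,
            "u_statistic": self.u_statistic,
            "p_value": self.p_value,
            "n_known": self.n_known,
            "n_unknown": self.n_unknown,
        }


def separation_report(
    values: Sequence[float],
    known_labels: Sequence[bool],
    factor: str = "custom",
    rank_mode: bool = False,
) -> SeparationReport:
    """Compare a ranking factor between known- and unknown-function hotspots.

    ``rank_mode=True`` replaces raw values with their ordinal ranks before
    averaging (sensitivity analysis; the default compares raw values, since
    normalizing to the unknown-class mean is meaningful for values).
    """
    values = np.asarray(values, float)
    labels = np.asarray(known_labels, bool)
    if len(values) != len(labels):
        raise ValidationError("values and labels differ in length")
    if labels.all() or not labels.any():
        raise ValidationError("need at least one known and one unknown hotspot")
    if rank_mode:
        values = sps.rankdata(values)
    known = values[labels]
    unknown = values[~labels]
    mean_known = float(known.mean())
    mean_unknown = float(unknown.mean())
    u, p = mann_whitney_u(known, unknown)
    fold = mean_known / mean_unknown if mean_unknown != 0 else math.inf
    return SeparationReport(
        factor=factor,
        mean_known=mean_known,
        mean_unknown=mean_unknown,
        normalized_mean_known=fold,
        fold_difference=fold,
        u_statistic=u,
        p_value=p,
        n_known=int(labels.sum()),
        n_unknown=int((~labels).sum()),
    )


@dataclass
class ThresholdPoint:
    threshold: float  # multiple of the family median FP
    n_known: int
    n_unknown: int
    pct_known: float | None  # known / (known + unknown); None when empty

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_known": self.n_known,
            "n_unknown": self.n_unknown,
            "pct_known": self.pct_known,
        }


def known_fraction_vs_threshold(
    results: Sequence[FPResult], thresholds: Sequence[float]
) -> list[ThresholdPoint]:
    """Known-hotspot fraction among hotspots above t x (family median FP).

    Each hotspot is compared against its own family's median, so the curve
    is meaningful across families of different FP magnitude.
    """
    points: list[ThresholdPoint] = []
    for t in thresholds:
        n_known = n_unknown = 0
        for res in results:
            if res.family_median_fp is None:
                raise ValidationError("results must be ranked first (median missing)")
            if res.fp >= t * res.family_median_fp:
                if res.known_function:
                    n_known += 1
                else:
                    n_unknown += 1
        total = n_known + n_unknown
        points.append(
            ThresholdPoint(
                threshold=float(t),
                n_known=n_known,
                n_unknown=n_unknown,
                pct_known=(n_known / total) if total else None,
            )
        )
    return points


def ptm_load(
    records: Sequence[PTMRecord], protein_lengths: Mapping[str, int]
) -> dict[str, float]:
    """PTMs per residue for each protein: count / full-length protein length.

    Proteins with a missing or non-positive length are skipped with a warning.
    """
    counts = Counter(rec.protein_id for rec in records)
    loads: dict[str, float] = {}
    for protein, count in sorted(counts.items()):
        length = protein_lengths.get(protein)
        if length is None or length <= 0:
            logger.warning("protein %s: missing/invalid length, skipped", protein)
            continue
        loads[protein] = count / length
    return loads


@dataclass
class RegionEnrichment:
    n_region: int
    n_total: int
    fraction: float
    per_type: dict[str, tuple[int, int, float]]  # type -> (in region, total, fraction)


def region_enrichment(
    records: Sequence[PTMRecord], regions: Mapping[str, tuple[int, int]]
) -> RegionEnrichment:
    """Fraction of a family's PTMs inside per-member residue intervals.

    ``regions`` maps protein ids to closed 1-based intervals (e.g. each
    member's N-terminal tail).  The per-type breakdown divides by each
    modification type's own family total.
    """
    for protein, (start, end) in regions.items():
        if start < 1 or end < start:
            raise ValidationError(f"malformed region for {protein}: {(start, end)}")
    n_total = len(records)
    n_region = 0
    type_total: Counter[str] = Counter()
    type_region: Counter[str] = Counter()
    for rec in records:
        type_total[rec.mod_type] += 1
        interval = regions.get(rec.protein_id)
        if interval and interval[0] <= rec.residue_index <= interval[1]:
            n_region += 1
            type_region[rec.mod_type] += 1
    per_type = {
        mod: (type_region[mod], tot, type_region[mod] / tot)
        for mod, tot in sorted(type_total.items())
    }
    return RegionEnrichment(
        n_region=n_region,
        n_total=n_total,
        fraction=(n_region / n_total) if n_total else 0.0,
        per_type=per_type,
    )


@dataclass
class MultiTypeDistribution:
    fractions: dict[str, float]  # keys "1", "2", "3+"
    pair_counts: dict[tuple[str, str], int]  # unordered PTM-type pairs

    def to_dict(self) -> dict:
        return {
            "fractions": self.fractions,
            "pair_counts": {" + ".join(k): v for k, v in sorted(self.pair_counts.items())},
        }


def multi_type_distribution(hotspots: Sequence[Hotspot]) -> MultiTypeDistribution:
    """How many hotspots carry one, two, or three-plus modification types.

    The pair table counts hotspots containing each unordered pair of PTM
    types (a 3-type hotspot contributes all three of its pairs).
    """
    if not hotspots:
        raise ValidationError("need at least one hotspot")
    n = len(hotspots)
    buckets = Counter()
    pairs: Counter[tuple[str, str]] = Counter()
    for h in hotspots:
        k = h.n_types
        buckets["1" if k == 1 else "2" if k == 2 else "3+"] += 1
        for a, b in itertools.combinations(sorted(h.mod_types), 2):
            pairs[(a, b)] += 1
    fractions = {key: buckets.get(key, 0) / n for key in ("1", "2", "3+")}
    return MultiTypeDistribution(fractions=fractions, pair_counts=dict(pairs))
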