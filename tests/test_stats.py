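"""Separation statistics: Mann-Whitney oracles, threshold curves, summaries."""

import itertools

import numpy as np
import pytest

from ptmhotspots.catalog import PTMRecord
from ptmhotspots.errors import ValidationError
from ptmhotspots.scoring import FPResult
from ptmhotspots.stats import (
    known_fraction_vs_threshold,
    mann_whitney_u,
    multi_type_distribution,
    ptm_load,
    region_enrichment,
    separation_report,
)
from test_scoring import make_hotspot, make_info
from ptmhotspots.scoring import compute_fp, rank_hotspots


def brute_force_mw_p(x, y):
    """Independent oracle: naive pair-counting U over every label split."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(sample_x, sample_y):
        u = 0.0
        for a in sample_x:
            for b in sample_y:
                u += 1.0 if a > b else 0.5 if a == b else 0.0
        return u

    center = n * (len(pooled) - n) / 2.0
    dev_obs = abs(u_of(x, y) - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        sx = [pooled[i] for i in idx]
        sy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(sx, sy) - center) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_hand_enumerable_example(self):
        # known {3,4} vs unknown {1,2}: U=4; of the 6 splits only U in {0,4}
        # is as extreme -> p = 2/6
        u, p = mann_whitney_u([3, 4], [1, 2], method="exact")
        assert u == 4.0
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize(
        "nx, ny, with_ties",
        [(3, 5, False), (4, 4, True), (5, 3, True), (6, 6, False), (8, 8, True)],
    )
    def test_exact_matches_brute_force_enumeration(self, nx, ny, with_ties):
        rng = np.random.default_rng(nx * 100 + ny + with_ties)
        pool = np.arange(4) if with_ties else None
        for _ in range(3):
            x = (rng.choice(pool, nx) if with_ties else rng.normal(0, 1, nx)).tolist()
            y = (rng.choice(pool, ny) if with_ties else rng.normal(1, 1, ny)).tolist()
            _, p = mann_whitney_u(x, y, method="exact")
            assert p == pytest.approx(brute_force_mw_p(x, y))

    def test_exact_close_to_tie_corrected_normal_balanced_n8(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.7, 1, 8)
            _, pe = mann_whitney_u(x, y, method="exact")
            _, pa = mann_whitney_u(x, y, method="asymptotic")
            assert abs(pe - pa) < 0.02

    def test_identical_distributions_p_near_one(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3], method="exact")
        assert p == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestSeparationReport:
    def test_hand_arithmetic_fold(self):
        rep = separation_report([4, 4, 1, 1, 2], [True, True, False, False, False])
        assert rep.mean_known == 4.0
        assert rep.mean_unknown == pytest.approx(4 / 3)
        assert rep.fold_difference == pytest.approx(3.0)
        assert rep.normalized_mean_known == pytest.approx(3.0)
        assert (rep.n_known, rep.n_unknown) == (2, 3)

    def test_identical_distributions(self):
        rep = separation_report([5, 5, 5, 5], [True, False, True, False])
        assert rep.fold_difference == pytest.approx(1.0)
        assert rep.p_value == pytest.approx(1.0)

    def test_rank_mode_uses_ordinal_ranks(self):
        # raw fold is huge; rank fold is modest
        raw = separation_report([1000.0, 1.0, 2.0], [True, False, False])
        ranks = separation_report([1000.0, 1.0, 2.0], [True, False, False], rank_mode=True)
        assert raw.fold_difference > ranks.fold_difference
        assert ranks.mean_known == 3.0  # top rank of 3

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            separation_report([1, 2], [True, True])


def _ranked_results(fps, known_flags):
    results = []
    for i, (fp, known) in enumerate(zip(fps, known_flags)):
        res = compute_fp(make_hotspot(column=i + 1, known=known), make_info(0.5))
        res.fp = float(fp)
        results.append(res)
    return rank_hotspots(results)


class TestThresholdCurve:
    def test_zero_threshold_counts_everything(self):
        results = _ranked_results([10, 8, 4, 2, 1], [True, True, False, False, False])
        (point,) = known_fraction_vs_threshold(results, [0.0])
        assert (point.n_known, point.n_unknown) == (2, 3)
        assert point.pct_known == pytest.approx(0.4)

    def test_counts_match_separation_report_at_zero(self):
        fps = [10, 8, 4, 2, 1, 0.5]
        labels = [True, False, True, False, False, False]
        results = _ranked_results(fps, labels)
        rep = separation_report(fps, labels)
        (point,) = known_fraction_vs_threshold(results, [0.0])
        assert (point.n_known, point.n_unknown) == (rep.n_known, rep.n_unknown)

    def test_beyond_max_reports_null(self):
        results = _ranked_results([10, 5], [True, False])
        (point,) = known_fraction_vs_threshold(results, [100.0])
        assert (point.n_known, point.n_unknown) == (0, 0)
        assert point.pct_known is None

    def test_top_concentrated_known_gives_nondecreasing_curve(self):
        # plant known at the top of the ranking
        fps = [100, 90, 80, 10, 9, 8, 7, 6]
        labels = [True, True, True, False, False, False, False, False]
        results = _ranked_results(fps, labels)
        curve = known_fraction_vs_threshold(results, [0.0, 1.0, 2.0, 5.0])
        pcts = [p.pct_known for p in curve if p.pct_known is not None]
        assert pcts == sorted(pcts)


class TestPtmLoad:
    def test_count_over_length(self):
        records = [PTMRecord("P1", i, "S", "phosphorylation") for i in range(1, 11)]
        assert ptm_load(records, {"P1": 100}) == {"P1": pytest.approx(0.10)}

    def test_no_records_means_no_entry(self):
        assert ptm_load([], {"P1": 100}) == {}

    def test_zero_or_missing_length_skipped(self, caplog):
        records = [PTMRecord("P1", 1, "S", "phosphorylation"),
                   PTMRecord("P2", 1, "S", "phosphorylation")]
        with caplog.at_level("WARNING"):
            loads = ptm_load(records, {"P1": 0})
        assert loads == {}
        assert len(caplog.messages) == 2


class TestRegionEnrichment:
    RECORDS = [
        PTMRecord("g1", 2, "S", "phosphorylation"),
        PTMRecord("g1", 3, "S", "phosphorylation"),
        PTMRecord("g1", 40, "S", "phosphorylation"),
        PTMRecord("g1", 50, "K", "ubiquitination"),
        PTMRecord("g2", 5, "S", "phosphorylation"),
        PTMRecord("g2", 60, "S", "phosphorylation"),
        PTMRecord("g2", 61, "S", "phosphorylation"),
        PTMRecord("g2", 62, "S", "phosphorylation"),
    ]

    def test_fraction_and_per_type_breakdown(self):
        enrich = region_enrichment(self.RECORDS, {"g1": (1, 10), "g2": (1, 10)})
        assert enrich.n_total == 8 and enrich.n_region == 3
        assert enrich.fraction == pytest.approx(3 / 8)
        n_in, n_tot, frac = enrich.per_type["phosphorylation"]
        assert (n_in, n_tot) == (3, 7) and frac == pytest.approx(3 / 7)
        assert enrich.per_type["ubiquitination"][2] == 0.0

    def test_all_inside(self):
        enrich = region_enrichment(self.RECORDS[:2], {"g1": (1, 10)})
        assert enrich.fraction == 1.0

    def test_malformed_region_rejected(self):
        with pytest.raises(ValidationError):
            region_enrichment(self.RECORDS, {"g1": (5, 2)})


class TestMultiTypeDistribution:
    def test_hand_count_fractions(self):
        hotspots = [
            _typed_hotspot(["phosphorylation"], 1),
            _typed_hotspot(["phosphorylation"], 2),
            _typed_hotspot(["ubiquitination"], 3),
            _typed_hotspot(["phosphorylation", "ubiquitination"], 4),
        ]
        dist = multi_type_distribution(hotspots)
        assert dist.fractions == {"1": 0.75, "2": 0.25, "3+": 0.0}
        assert dist.pair_counts == {("phosphorylation", "ubiquitination"): 1}

    def test_three_type_hotspot(self):
        dist = multi_type_distribution(
            [_typed_hotspot(["acetylation", "methylation", "ubiquitination"], 1)]
        )
        assert dist.fractions == {"1": 0.0, "2": 0.0, "3+": 1.0}
        assert len(dist.pair_counts) == 3  # all unordered pairs of the 3 types

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        hotspots = [
            _typed_hotspot(
                list(rng.choice(
                    ["phosphorylation", "ubiquitination", "acetylation"],
                    size=rng.integers(1, 4), replace=False,
                )),
                col,
            )
            for col in range(1, 40)
        ]
        dist = multi_type_distribution(hotspots)
        assert sum(dist.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            multi_type_distribution([])


def _typed_hotspot(types, column):
    h = make_hotspot(column=column)
    h.per_type_counts = {t: 1 for t in types}
    h.total_ptms = len(types)
    return h
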