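import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edmap.ed_scan import (
    CandidateRegion,
    EDPoint,
    ScanConfig,
    allele_frequency,
    call_regions,
    call_threshold,
    ed_statistic,
    manhattan_plot,
    power_transform,
    region_summary,
)
from edmap.reference import candidate_regions_from_table, load_candidate_region_table

from conftest import quantile_oracle

SQRT2 = math.sqrt(2)


class TestPointStatistics:
    @pytest.mark.parametrize(
        "ad, expected",
        [((10, 10), 0.5), ((0, 40), 1.0), ((30, 10), 0.25)],
    )
    def test_allele_frequency(self, ad, expected):
        assert allele_frequency(ad) == expected

    def test_zero_depth_frequency_is_an_error(self):
        with pytest.raises(ValueError, match="zero total depth"):
            allele_frequency((0, 0))

    @pytest.mark.parametrize(
        "f_mut, f_wt, expected",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.0, SQRT2),
            (2 / 3, 0.0, 0.942809),  # expectation at a dominant causal SNP
        ],
    )
    def test_ed_closed_forms(self, f_mut, f_wt, expected):
        assert ed_statistic(f_mut, f_wt) == pytest.approx(expected, abs=1e-6)

    def test_ed_domain_error(self):
        with pytest.raises(ValueError):
            ed_statistic(1.2, 0.5)

    @pytest.mark.parametrize(
        "ed, k, expected",
        [(1.0, 5, 1.0), (0.0, 5, 0.0), (0.942809, 5, 0.7449354)],
    )
    def test_power_transform(self, ed, k, expected):
        assert power_transform(ed, k) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_ed_symmetry_and_biallelic_identity(self, a, b):
        assert ed_statistic(a, b) == ed_statistic(b, a)
        assert abs(ed_statistic(a, b) - SQRT2 * abs(a - b)) < 1e-12


class TestThreshold:
    def test_constant_distribution(self):
        assert call_threshold([3.5] * 20, 0.995) == 3.5

    def test_single_value(self):
        assert call_threshold([1.25], 0.5) == 1.25

    def test_interpolated_quantile_of_1_to_1000(self):
        values = list(range(1, 1001))
        assert call_threshold(values, 0.995) == pytest.approx(
            quantile_oracle(values, 0.995), abs=1e-12
        )
        assert call_threshold(values, 0.995) == pytest.approx(995.005)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            call_threshold([], 0.995)

    def test_matches_independent_oracle_on_random_values(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            values = rng.gamma(0.5, size=rng.integers(2, 400)).tolist()
            q = rng.uniform(0.01, 0.99)
            assert call_threshold(values, q) == pytest.approx(
                quantile_oracle(values, q), rel=1e-12
            )

    def test_raising_q_never_increases_sites_above(self):
        rng = np.random.default_rng(11)
        values = rng.gamma(0.5, size=500)
        counts = [
            int((values > call_threshold(values, q)).sum())
            for q in (0.5, 0.8, 0.9, 0.99, 0.995)
        ]
        assert counts == sorted(counts, reverse=True)


def _points(pos_ed, chrom="chr1"):
    return [
        EDPoint(chrom=chrom, pos=p, f_mut=0, f_wt=0, ed=e, ed_k=e)
        for p, e in pos_ed
    ]


def brute_force_regions(points, threshold, cfg):
    """Independent clustering oracle: connected components of consecutive
    above-threshold sites (edge when gap <= merge_gap) via scipy."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    above = [p for p in points if p.ed_k > threshold]
    out = []
    for chrom in dict.fromkeys(p.chrom for p in above):
        sub = [p for p in above if p.chrom == chrom]
        n = len(sub)
        rows, cols = [], []
        for i in range(n - 1):
            if sub[i + 1].pos - sub[i].pos <= cfg.merge_gap_bp:
                rows.append(i)
                cols.append(i + 1)
        graph = coo_matrix(([1] * len(rows), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        for comp in range(n_comp):
            members = [sub[i] for i in range(n) if labels[i] == comp]
            if len(members) < cfg.min_sites:
                continue
            start, end = members[0].pos, members[-1].pos
            span = [p for p in points if p.chrom == chrom and start <= p.pos <= end]
            out.append(
                (chrom, start, end, len(members), len(span), max(p.ed_k for p in span))
            )
    return sorted(out)


class TestCallRegions:
    def test_twelve_consecutive_sites_form_one_region(self):
        points = _points([(10_000 * (i + 1), 2.0) for i in range(12)])
        regions = call_regions(points, 1.0, ScanConfig())
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp, r.n_above, r.n_total) == (10_000, 120_000, 12, 12)

    def test_too_few_sites_give_no_region(self):
        points = _points([(10_000 * (i + 1), 2.0) for i in range(5)])
        assert call_regions(points, 1.0, ScanConfig()) == []

    def test_clusters_past_merge_gap_stay_separate(self):
        cluster1 = [(10_000 * (i + 1), 2.0) for i in range(10)]
        cluster2 = [(5_100_000 + 10_000 * (i + 1), 2.0) for i in range(10)]
        regions = call_regions(_points(cluster1 + cluster2), 1.0, ScanConfig())
        assert len(regions) == 2
        assert regions[0].end_bp < regions[1].start_bp

    def test_unsorted_input_is_an_error(self):
        points = _points([(200, 2.0), (100, 2.0)])
        with pytest.raises(ValueError, match="not sorted"):
            call_regions(points, 1.0, ScanConfig())

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        cfg = ScanConfig(min_sites=3, merge_gap_bp=50_000)
        for _ in range(100):
            n = int(rng.integers(1, 200))
            pos = np.sort(rng.choice(np.arange(1, 2_000_000, 1000), size=n, replace=False))
            ed = rng.gamma(0.5, size=n)
            chrom = rng.choice(["chr1", "chr2"], size=n)
            order = np.lexsort((pos, chrom))
            points = [
                EDPoint(chrom=str(chrom[i]), pos=int(pos[i]), f_mut=0, f_wt=0, ed=0, ed_k=float(ed[i]))
                for i in order
            ]
            threshold = float(np.quantile(ed, 0.5))
            got = sorted(
                (r.chrom, r.start_bp, r.end_bp, r.n_above, r.n_total, r.peak_ed)
                for r in call_regions(points, threshold, cfg)
            )
            assert got == brute_force_regions(points, threshold, cfg)

    def test_region_conservation(self):
        rng = np.random.default_rng(3)
        cfg = ScanConfig(min_sites=3, merge_gap_bp=80_000)
        pos = np.sort(rng.choice(np.arange(1, 3_000_000, 997), size=150, replace=False))
        points = _points(list(zip(pos.tolist(), rng.gamma(0.4, size=150).tolist())))
        threshold = float(np.quantile([p.ed_k for p in points], 0.7))
        regions = call_regions(points, threshold, cfg)
        above = {p.pos for p in points if p.ed_k > threshold}
        assert sum(r.n_above for r in regions) <= len(above)
        for r in regions:
            assert r.start_bp in above and r.end_bp in above


class TestRegionSummary:
    def test_published_interval_table_totals(self):
        totals = region_summary(candidate_regions_from_table())
        assert totals.n_regions == 22
        assert totals.total_size_mb == pytest.approx(8.996802, abs=1e-6)
        assert totals.total_genes == 960
        assert totals.total_transcripts == 1328

    def test_each_published_row_size_is_end_minus_start(self):
        table = load_candidate_region_table()
        for region, row in zip(candidate_regions_from_table(table), table.itertuples()):
            assert region.size_mb == pytest.approx(row.size_mb, abs=1e-6)

    def test_empty_and_toy_sums(self):
        empty = region_summary([])
        assert (empty.n_regions, empty.total_size_mb, empty.total_genes, empty.total_transcripts) == (0, 0, 0, 0)
        toy = [
            CandidateRegion("chr1", 1, 1_000_001, 10, 10, 1.0, n_genes=3, n_transcripts=4),
            CandidateRegion("chr2", 1, 2_000_001, 10, 10, 1.0, n_genes=5, n_transcripts=6),
        ]
        totals = region_summary(toy)
        assert totals.total_size_mb == pytest.approx(3.0)
        assert (totals.total_genes, totals.total_transcripts) == (8, 10)


class TestManhattanPlot:
    def test_writes_nonempty_png(self, tmp_path):
        points = _points([(10_000 * (i + 1), float(i % 5)) for i in range(50)])
        regions = call_regions(points, 3.5, ScanConfig(min_sites=2))
        out = tmp_path / "scan.png"
        manhattan_plot(points, regions, 3.5, out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_regions_still_plot(self, tmp_path):
        points = _points([(10_000, 1.0), (20_000, 2.0)])
        out = tmp_path / "flat.png"
        manhattan_plot(points, [], 5.0, out)
        assert out.exists() and out.stat().st_size > 0
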