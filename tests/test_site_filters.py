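"""Site-inclusion rules: coverage, MAC, high-coverage cut, placement/strand, masks."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import hypergeom

from poolpig.pool_io import BiallelicSite, SiteMetadata
from poolpig.site_filters import (
    FilterConfig,
    FilterConfigError,
    MetadataRequiredError,
    apply_filters,
    coverage_and_mac_filter,
    high_coverage_filter,
    mask_intervals,
    placement_strand_filter,
    read_bed,
    strand_ratio,
)


def make_site(counts, pos=1000, chrom="2L", other=None):
    counts = np.asarray(counts)
    if other is None:
        other = np.zeros(len(counts), dtype=int)
    return BiallelicSite(chrom, pos, "A", "A", "T", counts, other)


class TestCoverageAndMac:
    def test_low_coverage_sample_fails(self):
        site = make_site([(10, 4), (30, 10)])  # sample 0 coverage 14
        ok, rule = coverage_and_mac_filter(site, ["p1", "p1"], FilterConfig())
        assert not ok and rule == "min_coverage"

    def test_mac_boundary_inclusive(self):
        # population minor counts {p1: 8, p2: 9} at floor 8 -> pass
        site = make_site([(20, 3), (20, 5), (20, 4), (20, 5)])
        ok, rule = coverage_and_mac_filter(site, ["p1", "p1", "p2", "p2"], FilterConfig())
        assert ok and rule is None

    def test_mac_failure_in_one_population(self):
        site = make_site([(20, 7), (20, 20)])
        ok, rule = coverage_and_mac_filter(site, ["p1", "p2"], FilterConfig())
        assert not ok and rule == "min_mac"

    def test_unmapped_sample_is_config_error(self):
        site = make_site([(20, 10), (20, 10)])
        with pytest.raises(FilterConfigError):
            coverage_and_mac_filter(site, {0: "p1"}, FilterConfig())


class TestHighCoverage:
    def test_top_two_percent_removed(self):
        # one sample with coverages 1..100: cutoff is the empirical 98%
        # quantile; the brute-force sort-and-threshold oracle says the top
        # 2 sites go
        sites = [make_site([(c, 0)], pos=i + 1) for i, c in enumerate(range(1, 101))]
        surviving, keep = high_coverage_filter(sites, FilterConfig())
        cov = np.arange(1, 101)
        cutoff = np.sort(cov)[int(math.ceil(0.98 * 100)) - 1 :][0:2]
        assert keep.sum() == 98
        assert [s.coverage()[0] for s in surviving] == list(range(1, 99))

    def test_equal_coverage_keeps_everything(self):
        sites = [make_site([(30, 30)], pos=i + 1) for i in range(60)]
        _, keep = high_coverage_filter(sites, FilterConfig())
        assert keep.all()

    def test_quantile_one_keeps_everything(self):
        sites = [make_site([(i + 1, 0)], pos=i + 1) for i in range(60)]
        _, keep = high_coverage_filter(sites, FilterConfig(high_coverage_quantile=1.0))
        assert keep.all()

    def test_few_sites_pass_through_with_warning(self):
        sites = [make_site([(i + 1, 0)], pos=i + 1) for i in range(10)]
        with pytest.warns(UserWarning):
            _, keep = high_coverage_filter(sites, FilterConfig())
        assert keep.all()


def make_meta(fwd, rev, end=25.0):
    fwd, rev = np.asarray(fwd), np.asarray(rev)
    end_arr = np.full(fwd.shape, float(end))
    return SiteMetadata(forward=fwd, reverse=rev, mean_end_distance=end_arr)


class TestPlacementStrand:
    def test_end_distance_boundary_is_strict(self):
        site = make_site([(50, 50)])
        meta = make_meta([(25, 25)], [(25, 25)], end=8.0)
        ok, rule = placement_strand_filter(site, meta, FilterConfig())
        assert not ok and rule == "end_distance"

    def test_balanced_minor_strands_pass(self):
        site = make_site([(50, 10)])
        meta = make_meta([(25, 5)], [(25, 5)])
        ok, _ = placement_strand_filter(site, meta, FilterConfig())
        assert ok

    def test_one_sided_minor_fails_via_fisher(self):
        # minor 0 fwd / 30 rev against major 50/50: ratio 0 and the exact
        # test on [[50,50],[0,30]] is far below 0.01
        site = make_site([(100, 30)])
        meta = make_meta([(50, 0)], [(50, 30)])
        ok, rule = placement_strand_filter(site, meta, FilterConfig())
        assert not ok and rule == "strand_bias"
        p_oracle = fisher_two_sided_oracle(np.array([[50, 50], [0, 30]]))
        assert p_oracle <= 0.01

    def test_missing_metadata_raises(self):
        with pytest.raises(MetadataRequiredError):
            placement_strand_filter(make_site([(50, 10)]), None, FilterConfig())

    def test_literal_max_aggregator_is_vacuous(self):
        assert strand_ratio(0, 30, "max") == math.inf
        assert strand_ratio(0, 30, "min") == 0.0
        assert strand_ratio(5, 5, "min") == 1.0


def fisher_two_sided_oracle(table):
    """Brute-force two-sided Fisher p: sum hypergeometric point masses
    no larger than the observed one."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


@given(
    st.tuples(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    )
)
def test_fisher_matches_enumeration_oracle(cells):
    """scipy's exact test equals hypergeometric enumeration on all small tables."""
    table = np.array(cells).reshape(2, 2)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return
    _, p = stats.fisher_exact(table, alternative="two-sided")
    assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-9)


class TestMaskIntervals:
    def test_indel_radius_arithmetic(self):
        cfg = FilterConfig()
        sites = [make_site([(20, 10)], pos=p) for p in range(990, 1012)]
        surviving, keep = mask_intervals(sites, [("2L", 1000, 1)], [], cfg)
        kept_pos = {s.pos for s in surviving}
        assert set(range(995, 1007)).isdisjoint(kept_pos)
        assert 994 in kept_pos and 1007 in kept_pos

    def test_empty_interval_set_is_identity(self):
        sites = [make_site([(20, 10)], pos=p) for p in (1, 2, 3)]
        surviving, keep = mask_intervals(sites, [], [], FilterConfig())
        assert keep.all() and len(surviving) == 3

    def test_repeat_interval_removes_site(self):
        sites = [make_site([(20, 10)], pos=500)]
        _, keep = mask_intervals(sites, [], [("2L", 400, 600)], FilterConfig())
        assert not keep.any()

    def test_bed_conversion(self, tmp_path):
        bed = tmp_path / "rep.bed"
        bed.write_text("2L\t399\t600\n")
        intervals = read_bed(bed)
        assert intervals == [("2L", 400, 600)]


def _random_dataset(rng, n=120):
    sites, meta = [], []
    for i in range(n):
        depth = rng.integers(10, 80, size=4)
        minor = rng.binomial(depth, 0.3)
        counts = np.column_stack([depth - minor, minor])
        sites.append(make_site(counts, pos=10 + 7 * i))
        fwd = rng.binomial(counts, 0.5)
        end = np.full((4, 2), float(rng.uniform(5, 30)))
        meta.append(SiteMetadata(fwd, counts - fwd, end))
    return sites, meta


def test_monotonicity_under_threshold_sweeps(rng):
    """Raising any threshold never enlarges the surviving set."""
    sites, meta = _random_dataset(rng)
    pops = ["p1", "p1", "p2", "p2"]
    prev = None
    for cov_min in (5, 15, 25, 40):
        cfg = FilterConfig(min_coverage_per_sample=cov_min)
        rep = apply_filters(sites, pops, cfg, metadata=meta)
        cur = set(np.nonzero(rep.passed)[0])
        if prev is not None:
            assert cur <= prev
        prev = cur
    prev = None
    for mac in (0, 4, 8, 16):
        cfg = FilterConfig(min_minor_count_per_population=mac)
        rep = apply_filters(sites, pops, cfg, metadata=meta)
        cur = set(np.nonzero(rep.passed)[0])
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_rules_intersect_as_sets(rng):
    """The surviving set equals the intersection of per-rule pass sets."""
    sites, meta = _random_dataset(rng)
    pops = ["p1", "p1", "p2", "p2"]
    cfg = FilterConfig()
    rep = apply_filters(sites, pops, cfg, metadata=meta)

    _, keep_hc = high_coverage_filter(sites, cfg)
    manual = []
    for i, site in enumerate(sites):
        ok1, _ = coverage_and_mac_filter(site, pops, cfg)
        ok2, _ = placement_strand_filter(site, meta[i], cfg)
        manual.append(ok1 and ok2 and bool(keep_hc[i]))
    assert rep.passed.tolist() == manual
    assert sum(rep.tallies.values()) == (~rep.passed).sum()
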