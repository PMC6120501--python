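"""CMH testing, MH odds ratios, downsampling and the empirical-null FDR."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from poolpig.association import (
    AUTOSOMES_DEFAULT,
    DesignError,
    FdrResult,
    ReplicateDesign,
    StratifiedCounts,
    UntestableSiteError,
    assemble_strata,
    cmh_scan,
    cmh_test,
    downsample_counts,
    empirical_fdr,
    mantel_haenszel_or,
    null_strata_within_pool_split,
)
from poolpig.pool_io import BiallelicSite


def sc(*tables):
    return StratifiedCounts(np.array(tables))


class TestCmh:
    def test_perfect_independence(self):
        res = cmh_test(sc([[10, 10], [10, 10]], [[10, 10], [10, 10]]),
                       continuity_correction=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.or_mh == pytest.approx(1.0)

    def test_column_swap_symmetry(self):
        tables = [[[12, 3], [5, 10]], [[7, 8], [9, 6]]]
        res = cmh_test(sc(*tables))
        swapped = [[[3, 12], [10, 5]], [[8, 7], [6, 9]]]
        res2 = cmh_test(sc(*swapped))
        assert res2.p_value == pytest.approx(res.p_value, rel=1e-12)
        assert res2.or_mh == pytest.approx(1 / res.or_mh, rel=1e-12)
        assert res2.log_or == pytest.approx(-res.log_or, rel=1e-12)

    def test_frozen_two_stratum_values(self):
        # frozen from an independent evaluation of the textbook formulas
        res = cmh_test(sc([[12, 3], [5, 10]], [[7, 8], [9, 6]]))
        assert res.statistic == pytest.approx(1.0426966292134832, abs=1e-10)
        assert res.p_value == pytest.approx(0.30719513563348166, abs=1e-10)
        assert res.or_mh == pytest.approx(1.8620689655172415, abs=1e-10)
        assert res.ci95[0] == pytest.approx(0.6937251191858085, abs=1e-10)
        assert res.ci95[1] == pytest.approx(4.998090362378479, abs=1e-10)

    def test_single_stratum_or_equals_sample_odds_ratio(self):
        res = cmh_test(sc([[12, 3], [5, 10]]))
        assert res.or_mh == pytest.approx((12 * 10) / (3 * 5), rel=1e-12)

    def test_chi2_p_close_to_exact_conditional_p(self):
        # sanity band, not equality: the 1-df chi-square approximation
        # should sit near the exact two-sided hypergeometric p for small
        # single-stratum tables
        table = np.array([[9, 4], [3, 11]])
        res = cmh_test(sc(table.tolist()), continuity_correction=True)
        _, p_exact = stats.fisher_exact(table, alternative="two-sided")
        assert abs(res.p_value - p_exact) < 0.1

    def test_all_degenerate_raises(self):
        with pytest.raises(UntestableSiteError):
            cmh_test(sc([[0, 0], [0, 0]]))

    def test_infinite_or_flagged(self):
        res = cmh_test(sc([[10, 0], [0, 10]], [[8, 0], [0, 12]]))
        assert math.isinf(res.or_mh) and math.isinf(res.log_or)
        assert res.ci_unbounded

    @given(
        st.lists(
            st.tuples(st.integers(1, 40), st.integers(1, 40),
                      st.integers(1, 40), st.integers(1, 40)),
            min_size=2, max_size=5,
        ),
        st.permutations(range(5)),
    )
    def test_stratum_permutation_invariance(self, cells, perm):
        tables = [np.array(c).reshape(2, 2) for c in cells]
        res1 = cmh_test(sc(*[t.tolist() for t in tables]))
        order = [i for i in perm if i < len(tables)]
        res2 = cmh_test(sc(*[tables[i].tolist() for i in order]))
        assert res2.statistic == pytest.approx(res1.statistic, rel=1e-12)
        assert res2.or_mh == pytest.approx(res1.or_mh, rel=1e-12)

    def test_scan_agrees_with_scalar_path(self, rng):
        tables = rng.integers(1, 60, size=(50, 3, 2, 2))
        stat, p = cmh_scan(tables)
        for i in range(50):
            res = cmh_test(StratifiedCounts(tables[i]))
            assert stat[i] == pytest.approx(res.statistic, rel=1e-12)
            assert p[i] == pytest.approx(res.p_value, rel=1e-12)


class TestDownsampling:
    def test_conservation(self, rng):
        out = downsample_counts((10, 10), 0.5, rng)
        assert out.sum() == 10 and (out >= 0).all() and (out <= 10).all()

    def test_fraction_one_identity(self, rng):
        assert downsample_counts((7, 3), 1.0, rng).tolist() == [7, 3]

    def test_zero_total(self, rng):
        assert downsample_counts((0, 0), 0.5, rng).tolist() == [0, 0]

    def test_hypergeometric_expectation(self, rng):
        # counts (40, 10) at fraction 0.5: draws 25 of 50, E[first] = 20,
        # Var = 25 * 0.8 * 0.2 * 25 / 49
        draws = np.array(
            [downsample_counts((40, 10), 0.5, rng)[0] for _ in range(10_000)]
        )
        se = math.sqrt(25 * 0.8 * 0.2 * (25 / 49) / 10_000)
        assert abs(draws.mean() - 20.0) < 3 * se

    def test_reproducible_under_seed(self):
        a = downsample_counts((40, 17), 0.5, np.random.default_rng(7))
        b = downsample_counts((40, 17), 0.5, np.random.default_rng(7))
        assert a.tolist() == b.tolist()


def make_site(counts, chrom="2L"):
    counts = np.asarray(counts)
    return BiallelicSite(chrom, 100, "A", "A", "T", counts,
                         np.zeros(len(counts), dtype=int))


class TestAssembleStrata:
    design = ReplicateDesign([([0], [1]), ([2], [3])])

    def test_two_replicates_two_strata(self):
        site = make_site([(10, 5), (8, 7), (20, 2), (18, 4)])
        strata = assemble_strata(site, self.design)
        assert strata.k == 2
        assert strata.tables[0].tolist() == [[10, 5], [8, 7]]
        assert strata.tables[1].tolist() == [[20, 2], [18, 4]]

    def test_x_linked_site_never_downsampled(self, rng):
        site = make_site([(10, 5), (8, 7), (20, 2), (18, 4)], chrom="X")
        strata = assemble_strata(site, self.design, downsample_fraction=0.5, rng=rng)
        assert strata.tables.sum() == site.counts.sum()

    def test_autosomal_site_downsampled_on_p_pathway(self, rng):
        site = make_site([(10, 6), (8, 8), (20, 2), (18, 4)])
        strata = assemble_strata(site, self.design, downsample_fraction=0.5, rng=rng)
        for k, (light, dark) in enumerate(self.design.replicates):
            assert strata.tables[k, 0].sum() == site.counts[light].sum() // 2
            assert strata.tables[k, 1].sum() == site.counts[dark].sum() // 2

    def test_zero_pool_retained_until_cmh(self):
        site = make_site([(0, 0), (8, 7), (20, 2), (18, 4)])
        strata = assemble_strata(site, self.design)
        assert strata.tables[0, 0].sum() == 0
        cmh_test(strata)  # still testable: second stratum informative

    def test_missing_pool_is_design_error(self):
        with pytest.raises(DesignError):
            ReplicateDesign([([0], [])])


class TestEmpiricalFdr:
    def test_null_identical_to_observed(self):
        p = np.linspace(0.01, 1, 100)
        res = empirical_fdr(p, p, q=0.05)
        assert res.n_significant == 0

    def test_null_all_ones(self):
        obs = np.array([0.2, 0.4, 1.0])
        res = empirical_fdr(obs, np.ones(50), q=0.05)
        assert res.n_significant == 2
        assert res.p_threshold == pytest.approx(0.4)
        assert res.estimated_fdr_at_threshold == 0.0

    def test_frozen_exhaustive_scan_example(self):
        res = empirical_fdr([0.001, 0.002, 0.5], [0.01, 0.2, 0.9], q=0.05)
        assert res.p_threshold == pytest.approx(0.002)
        assert res.n_significant == 2

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
    )
    def test_matches_brute_force_scan(self, obs, null):
        obs_a, null_a = np.array(obs), np.array(null)
        res = empirical_fdr(obs_a, null_a, q=0.05)
        # oracle: scan every observed p as a candidate threshold
        best_t, best_n = None, 0
        for t in sorted(obs):
            n_obs = (obs_a <= t).sum()
            n_null = (null_a <= t).sum()
            fdr = (n_null * len(obs) / len(null)) / max(1, n_obs)
            if fdr <= 0.05 and (best_t is None or t >= best_t):
                best_t, best_n = t, n_obs
        if best_t is None:
            assert res.n_significant == 0
        else:
            assert res.p_threshold == pytest.approx(best_t)
            assert res.n_significant == best_n

    def test_q_monotonicity(self, rng):
        obs = rng.uniform(0, 1, 200) ** 2
        null = rng.uniform(0, 1, 200)
        n_prev = math.inf
        for q in (0.2, 0.1, 0.05, 0.01):
            n = empirical_fdr(obs, null, q=q).n_significant
            assert n <= n_prev
            n_prev = n

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            empirical_fdr([], [0.5])


def test_within_pool_split_null_conserves_reads(rng):
    site = make_site([(30, 10), (25, 15), (40, 5), (35, 8)])
    design = ReplicateDesign([([0], [1]), ([2], [3])])
    strata = null_strata_within_pool_split(site, design, rng)
    for k, (light, dark) in enumerate(design.replicates):
        combined = site.counts[list(light) + list(dark)].sum(axis=0)
        assert (strata.tables[k].sum(axis=0) == combined).all()


def test_null_rejection_rate_at_depth_60(rng):
    """Uncorrected CMH at 5 strata / depth 60 rejects ~5% of true nulls."""
    n_sites, k, depth = 20_000, 5, 60
    freqs = rng.uniform(0.2, 0.8, size=n_sites)
    a = rng.binomial(depth, freqs[:, None], size=(n_sites, k))
    c = rng.binomial(depth, freqs[:, None], size=(n_sites, k))
    tables = np.empty((n_sites, k, 2, 2), dtype=np.int64)
    tables[..., 0, 0] = a
    tables[..., 0, 1] = depth - a
    tables[..., 1, 0] = c
    tables[..., 1, 1] = depth - c
    _, p = cmh_scan(tables, continuity_correction=False)
    frac = np.mean(p <= 0.05)
    assert 0.04 <= frac <= 0.06
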