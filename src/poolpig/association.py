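"""Replicated light/dark association testing.

For each SNP a 2×2 table of (light pool, dark pool) × (allele 1, allele
2) read counts is built per replicate, and the replicates are combined
with the Cochran–Mantel–Haenszel (CMH) chi-square test (1 df).  Writing
stratum k as::

        allele1  allele2
  row1    a_k      b_k
  row2    c_k      d_k        n_k = a_k + b_k + c_k + d_k

the statistic is ``(|Σ(a_k − E a_k)| − c)² / Σ Var(a_k)`` with the
conditional hypergeometric moments given the stratum margins and
``c = 0.5`` when the continuity correction is on (the default, matching
R's ``mantelhaen.test``).  The common effect size is the Mantel–Haenszel
odds ratio ``Σ a_k d_k / n_k ÷ Σ b_k c_k / n_k``; its 95% CI comes from
the Robins–Breslow–Greenland variance of the log odds ratio, and the
natural log of the odds ratio serves as the effect-size proxy.

Because males carry one X, autosomal pools are sequenced about twice as
deep as the X; to make p-values comparable across chromosomes, autosomal
counts are downsampled to 50% (multivariate hypergeometric, i.e. random
sampling without replacement) on the p-value pathway only — odds ratios
and allele frequencies always use full depth.

Multiple testing is controlled with an FDR estimated from an empirical
null distribution: p-values from contrasts expected to carry no signal
(same-phenotype pools across replicates, or random within-pool read
splits) calibrate the expected false-positive count at each candidate
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pool_io import BiallelicSite

Z975 = stats.norm.ppf(0.975)


class UntestableSiteError(ValueError):
    """All strata degenerate: no informative margin anywhere."""


class DesignError(ValueError):
    """Replicate design does not partition the samples as required."""


@dataclass
class StratifiedCounts:
    """K stratified 2×2 tables; rows = pools, columns = alleles."""

    tables: np.ndarray  # shape (K, 2, 2), non-negative ints
    pool_labels: tuple[str, str] = ("light", "dark")
    allele_labels: tuple[str, str] = ("allele1", "allele2")

    def __post_init__(self) -> None:
        self.tables = np.asarray(self.tables, dtype=np.int64)
        if self.tables.ndim != 3 or self.tables.shape[1:] != (2, 2):
            raise ValueError(f"tables must be (K, 2, 2), got {self.tables.shape}")
        if self.tables.shape[0] < 1:
            raise ValueError("at least one stratum required")
        if (self.tables < 0).any():
            raise ValueError("negative cell count")

    @property
    def k(self) -> int:
        return self.tables.shape[0]


@dataclass
class AssociationResult:
    statistic: float
    p_value: float
    or_mh: float  # may be inf
    ci95: tuple[float, float]
    log_or: float

    @property
    def ci_unbounded(self) -> bool:
        return not (math.isfinite(self.ci95[0]) and math.isfinite(self.ci95[1]))


def _cmh_components(tables: np.ndarray):
    """Vectorized CMH pieces for an (..., K, 2, 2) array of tables."""
    t = np.asarray(tables, dtype=float)
    a, b = t[..., 0, 0], t[..., 0, 1]
    c, d = t[..., 1, 0], t[..., 1, 1]
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(n > 0, r1 * c1 / n, 0.0)
        v = np.where(n > 1, r1 * r2 * c1 * c2 / (n * n * (n - 1)), 0.0)
        ad = np.where(n > 0, a * d / n, 0.0)
        bc = np.where(n > 0, b * c / n, 0.0)
    return a, b, c, d, n, e, v, ad, bc


def cmh_scan(tables: np.ndarray, continuity_correction: bool = True):
    """CMH statistic and p-value for many sites at once.

    ``tables`` has shape (S, K, 2, 2).  Returns ``(statistic, p)`` arrays
    of shape (S,); sites whose strata are all degenerate get NaN.
    """
    a, *_, e, v, ad, bc = _cmh_components(tables)
    num = np.abs((a - e).sum(axis=-1))
    if continuity_correction:
        num = num - 0.5
    var = v.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, num**2 / var, np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    return stat, p


def mantel_haenszel_or(tables: np.ndarray):
    """MH common odds ratio and RBG 95% CI for one (K, 2, 2) stack.

    Returns ``(or_mh, (lo, hi))``; the OR is ``inf`` when the denominator
    vanishes with a positive numerator, and the CI is then unbounded.
    """
    a, b, c, d, n, e, v, ad, bc = _cmh_components(tables)
    r, s = ad.sum(), bc.sum()
    if s == 0:
        or_mh = math.inf if r > 0 else math.nan
        return or_mh, (math.nan, math.inf)
    or_mh = r / s
    if r == 0:
        return 0.0, (0.0, math.nan)
    # Robins–Breslow–Greenland variance of log(OR_MH)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_k = np.where(n > 0, (a + d) / n, 0.0)
        q_k = np.where(n > 0, (b + c) / n, 0.0)
    var = (
        (p_k * ad).sum() / (2 * r**2)
        + ((p_k * bc) + (q_k * ad)).sum() / (2 * r * s)
        + (q_k * bc).sum() / (2 * s**2)
    )
    se = math.sqrt(var)
    log_or = math.log(or_mh)
    return or_mh, (math.exp(log_or - Z975 * se), math.exp(log_or + Z975 * se))


def cmh_test(
    counts: StratifiedCounts, continuity_correction: bool = True
) -> AssociationResult:
    """CMH test, MH odds ratio and RBG CI for one site.

    Strata with a zero margin contribute nothing to the statistic; if
    every stratum is degenerate an :class:`UntestableSiteError` is
    raised.  The odds ratio is oriented so values > 1 mean allele 1 is
    enriched in the first (row-1) pool.
    """
    tables = counts.tables[np.newaxis]
    _, _, _, _, n, e, v, ad, bc = _cmh_components(counts.tables[np.newaxis, ...])
    if float(v.sum()) == 0.0:
        raise UntestableSiteError("all strata degenerate (zero margins)")
    stat, p = cmh_scan(tables, continuity_correction=continuity_correction)
    or_mh, ci = mantel_haenszel_or(counts.tables)
    if or_mh == 0.0:
        log_or = -math.inf
    elif math.isinf(or_mh):
        log_or = math.inf
    elif math.isnan(or_mh):
        log_or = math.nan
    else:
        log_or = math.log(or_mh)
    return AssociationResult(
        statistic=float(stat[0]),
        p_value=float(p[0]),
        or_mh=or_mh,
        ci95=ci,
        log_or=log_or,
    )


def downsample_counts(
    counts: Sequence[int] | np.ndarray,
    fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Downsample per-allele read counts without replacement.

    Draws ``floor(total × fraction)`` reads from the multiset of reads
    labelled by allele (multivariate hypergeometric), so the output sums
    exactly to that target.  ``fraction=1`` is the identity; a zero total
    returns zeros.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    if fraction == 1.0 or total == 0:
        return counts.copy()
    n_draw = int(math.floor(total * fraction))
    if rng is None:
        rng = np.random.default_rng()
    return rng.multivariate_hypergeometric(counts, n_draw).astype(np.int64)


@dataclass
class ReplicateDesign:
    """Per-replicate (light samples, dark samples) column indices.

    Each replicate must own exactly one light and one dark pool; a pool
    may consist of several sync columns (summed).
    """

    replicates: Sequence[tuple[Sequence[int], Sequence[int]]]

    def __post_init__(self) -> None:
        for k, (light, dark) in enumerate(self.replicates):
            if len(light) == 0 or len(dark) == 0:
                raise DesignError(f"replicate {k} is missing a light or dark pool")

    @property
    def k(self) -> int:
        return len(self.replicates)


AUTOSOMES_DEFAULT = frozenset({"2L", "2R", "3L", "3R", "4"})


def assemble_strata(
    site: BiallelicSite,
    design: ReplicateDesign,
    downsample_fraction: float | None = None,
    autosomes: frozenset[str] | set[str] = AUTOSOMES_DEFAULT,
    rng: np.random.Generator | None = None,
) -> StratifiedCounts:
    """Build the K×2×2 stack for one site from the replicate design.

    Rows are (light, dark), columns (major, minor).  When
    ``downsample_fraction`` is given and the site is autosomal, each
    pool's counts are hypergeometrically downsampled — callers use this
    for the p-value pathway only.  X-linked (non-autosomal) sites are
    never downsampled.
    """
    tables = np.zeros((design.k, 2, 2), dtype=np.int64)
    do_downsample = downsample_fraction is not None and site.chrom in autosomes
    for k, (light, dark) in enumerate(design.replicates):
        for row, samples in enumerate((light, dark)):
            pool = site.counts[list(samples)].sum(axis=0)
            if do_downsample:
                pool = downsample_counts(pool, downsample_fraction, rng)
            tables[k, row] = pool
    return StratifiedCounts(
        tables=tables,
        pool_labels=("light", "dark"),
        allele_labels=(site.major_allele, site.minor_allele),
    )


def test_sites(
    sites: Sequence[BiallelicSite],
    design: ReplicateDesign,
    downsample_fraction: float | None = 0.5,
    autosomes: frozenset[str] | set[str] = AUTOSOMES_DEFAULT,
    continuity_correction: bool = True,
    rng: np.random.Generator | None = None,
):
    """Run the full per-site pathway over many sites.

    p-values come from (possibly downsampled) counts, odds ratios from
    full counts.  Returns a list of dict records suitable for a
    DataFrame.  A site whose downsampled strata are all degenerate gets
    NaN statistics.
    """
    records = []
    for site in sites:
        full = assemble_strata(site, design)
        if downsample_fraction is not None and downsample_fraction < 1:
            for_p = assemble_strata(
                site, design, downsample_fraction, autosomes=autosomes, rng=rng
            )
        else:
            for_p = full
        stat, p = cmh_scan(for_p.tables[np.newaxis], continuity_correction)
        or_mh, ci = mantel_haenszel_or(full.tables)
        log_or = (
            math.log(or_mh)
            if (or_mh not in (0.0,) and math.isfinite(or_mh))
            else (-math.inf if or_mh == 0.0 else math.inf)
        )
        records.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "major": site.major_allele,
                "minor": site.minor_allele,
                "statistic": float(stat[0]),
                "p": float(p[0]),
                "or_mh": or_mh,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "log_or": log_or,
            }
        )
    return records


# --------------------------------------------------------------------------
# Empirical-null FDR


@dataclass
class FdrResult:
    q: float
    p_threshold: float
    n_significant: int
    estimated_fdr_at_threshold: float


def empirical_fdr(
    observed_p: Sequence[float] | np.ndarray,
    null_p: Sequence[float] | np.ndarray,
    q: float = 0.05,
) -> FdrResult:
    """Largest p cutoff whose estimated FDR stays at or below ``q``.

    For each candidate threshold t among the sorted observed p-values,
    ``FDR(t) = (#{null ≤ t} × N_obs / N_null) / max(1, #{obs ≤ t})``; the
    scaling makes the expected null exceedance comparable when the null
    set has a different size.  If no candidate qualifies, zero sites are
    significant and the threshold is reported as 0.
    """
    obs = np.sort(np.asarray(observed_p, dtype=float))
    null = np.sort(np.asarray(null_p, dtype=float))
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null p-value sets must be non-empty")
    if ((obs < 0) | (obs > 1)).any() or ((null < 0) | (null > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n_obs_le = np.arange(1, obs.size + 1)  # #{obs <= t} at t = sorted obs
    n_null_le = np.searchsorted(null, obs, side="right")
    est_fdr = (n_null_le * obs.size / null.size) / np.maximum(1, n_obs_le)
    ok = est_fdr <= q
    if not ok.any():
        return FdrResult(q=q, p_threshold=0.0, n_significant=0,
                         estimated_fdr_at_threshold=math.nan)
    i = int(np.max(np.nonzero(ok)[0]))
    return FdrResult(
        q=q,
        p_threshold=float(obs[i]),
        n_significant=int(n_obs_le[i]),
        estimated_fdr_at_threshold=float(est_fdr[i]),
    )


def null_strata_light_vs_light(
    site: BiallelicSite, design: ReplicateDesign, pool: str = "light"
) -> StratifiedCounts:
    """Same-phenotype contrast: pair up same-pool replicates as pseudo
    light/dark strata.  Needs at least two replicates; replicate 2k is
    contrasted with replicate 2k+1 (an odd trailing replicate is
    dropped)."""
    if design.k < 2:
        raise DesignError("same-phenotype null needs >= 2 replicates")
    idx = 0 if pool == "light" else 1
    pools = [site.counts[list(rep[idx])].sum(axis=0) for rep in design.replicates]
    tables = []
    for i in range(0, design.k - 1, 2):
        tables.append([pools[i], pools[i + 1]])
    return StratifiedCounts(
        tables=np.array(tables, dtype=np.int64),
        pool_labels=(f"{pool}_even", f"{pool}_odd"),
        allele_labels=(site.major_allele, site.minor_allele),
    )


def null_strata_within_pool_split(
    site: BiallelicSite, design: ReplicateDesign, rng: np.random.Generator
) -> StratifiedCounts:
    """Within-pool read-split null: randomly halve each replicate's
    combined reads into two pseudo-pools (hypergeometric split), giving a
    contrast that carries no phenotype signal by construction."""
    tables = np.zeros((design.k, 2, 2), dtype=np.int64)
    for k, (light, dark) in enumerate(design.replicates):
        combined = site.counts[list(light) + list(dark)].sum(axis=0)
        half = downsample_counts(combined, 0.5, rng)
        tables[k, 0] = half
        tables[k, 1] = combined - half
    return StratifiedCounts(
        tables=tables,
        pool_labels=("split_a", "split_b"),
        allele_labels=(site.major_allele, site.minor_allele),
    )
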