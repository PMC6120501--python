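"""Site-inclusion filters for pooled extreme-phenotype association scans.

A SNP enters the replicated association test only if it survives, in this
fixed order:

1. per-sample minimum coverage (default 15×) and per-population minimum
   minor allele count (default 8);
2. the dataset-wide high-coverage cut: any sample whose coverage at the
   site strictly exceeds that sample's empirical 98% quantile (taken over
   all sites) removes the site — repetitive or copy-number-variable
   regions attract excess depth;
3. read-placement and strand checks: the mean distance of allele-
   supporting base calls from the nearer read end must exceed 8 bases for
   both alleles, and the variant must not show extreme strand imbalance;
4. interval masks: ±5 bp around short indels, plus repeat annotations.

The strand-imbalance clause is stated in the source pipelines as
``max(fwd/rev, rev/fwd) > 0.1`` which is vacuously true for any table
with a nonzero count (the larger of a ratio and its reciprocal is always
≥ 1).  The default here uses ``min`` — neither strand may fall below a
1:10 deficit — which is the reading that yields a functioning filter; the
literal behaviour is available via ``strand_ratio_aggregator="max"``.
A site failing the ratio check can still be rescued by a two-sided Fisher
exact test on the pooled {major, minor} × {forward, reverse} table with
p > 0.01 (balanced enough once depth is accounted for).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .pool_io import BiallelicSite, SiteMetadata


class FilterConfigError(ValueError):
    """Bad filter configuration (unmapped sample, bad threshold...)."""


class MetadataRequiredError(ValueError):
    """Placement/strand filter invoked without per-allele metadata."""


#: Fixed evaluation order; also the attribution order in reports.
RULES = ("min_coverage", "min_mac", "high_coverage", "end_distance", "strand_bias", "mask")


@dataclass
class FilterConfig:
    """Thresholds of the site-inclusion rules.

    Units: coverages and counts in reads, end distance in bases, the
    high-coverage cut as an empirical quantile of per-sample coverage.
    """

    min_coverage_per_sample: int = 15
    min_minor_count_per_population: int = 8
    high_coverage_quantile: float = 0.98
    min_mean_end_distance: float = 8.0
    strand_ratio_threshold: float = 0.1
    strand_fisher_p_threshold: float = 0.01
    indel_mask_radius: int = 5
    strand_ratio_aggregator: str = "min"  # "min" (functional) or "max" (literal)
    coverage_includes_n_del: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.high_coverage_quantile <= 1):
            raise FilterConfigError("high_coverage_quantile must be in (0, 1]")
        for name in (
            "min_coverage_per_sample", "min_minor_count_per_population",
            "min_mean_end_distance", "strand_ratio_threshold",
            "strand_fisher_p_threshold", "indel_mask_radius",
        ):
            if getattr(self, name) < 0:
                raise FilterConfigError(f"{name} must be non-negative")
        if self.strand_ratio_aggregator not in ("min", "max"):
            raise FilterConfigError("strand_ratio_aggregator must be 'min' or 'max'")


@dataclass
class FilterReport:
    """Pass/fail per site plus the first failing rule, and rule tallies."""

    passed: np.ndarray  # bool per site
    first_failure: list  # rule name or None per site
    tallies: dict

    @property
    def n_passed(self) -> int:
        return int(self.passed.sum())


def coverage_and_mac_filter(
    site: BiallelicSite,
    populations: Mapping[int, str] | Sequence[str],
    cfg: FilterConfig,
) -> tuple[bool, str | None]:
    """Minimum per-sample coverage and per-population minor allele count.

    ``populations`` maps sample index -> population label; every sample
    must be assigned.  The minor allele count is summed over all pools of
    a population.  Returns ``(passed, failing_rule)``.
    """
    n = site.n_samples
    if isinstance(populations, Mapping):
        labels = [populations.get(i) for i in range(n)]
    else:
        labels = list(populations)
    if len(labels) != n or any(l is None for l in labels):
        raise FilterConfigError("every sample must be assigned to a population")

    cov = site.coverage(include_other=cfg.coverage_includes_n_del)
    if (cov < cfg.min_coverage_per_sample).any():
        return False, "min_coverage"
    for pop in set(labels):
        idx = [i for i, l in enumerate(labels) if l == pop]
        if site.counts[idx, 1].sum() < cfg.min_minor_count_per_population:
            return False, "min_mac"
    return True, None


def high_coverage_cutoffs(sites: Sequence[BiallelicSite], cfg: FilterConfig) -> np.ndarray:
    """Per-sample empirical coverage quantile over the whole dataset."""
    cov = np.array(
        [s.coverage(include_other=cfg.coverage_includes_n_del) for s in sites]
    )
    return np.quantile(cov, cfg.high_coverage_quantile, axis=0)


def high_coverage_filter(
    sites: Sequence[BiallelicSite], cfg: FilterConfig
) -> tuple[list[BiallelicSite], np.ndarray]:
    """Drop sites where any sample's coverage strictly exceeds its cutoff.

    The cutoff is each sample's empirical ``high_coverage_quantile`` of
    coverage across the dataset.  With fewer than 50 sites the quantile is
    ill-defined; everything passes with a warning.  Returns the surviving
    sites and the boolean keep-mask.
    """
    if len(sites) < 50:
        warnings.warn("fewer than 50 sites: high-coverage filter is a no-op")
        return list(sites), np.ones(len(sites), dtype=bool)
    cutoffs = high_coverage_cutoffs(sites, cfg)
    cov = np.array(
        [s.coverage(include_other=cfg.coverage_includes_n_del) for s in sites]
    )
    keep = ~(cov > cutoffs).any(axis=1)
    return [s for s, k in zip(sites, keep) if k], keep


def _safe_ratio(num: float, den: float) -> float:
    if den > 0:
        return num / den
    return math.inf if num > 0 else 0.0


def strand_ratio(fwd: int, rev: int, aggregator: str = "min") -> float:
    """min (or literal max) of fwd/rev and rev/fwd, with 0/x = 0, x/0 = inf."""
    r1, r2 = _safe_ratio(fwd, rev), _safe_ratio(rev, fwd)
    return min(r1, r2) if aggregator == "min" else max(r1, r2)


def placement_strand_filter(
    site: BiallelicSite, meta: SiteMetadata | None, cfg: FilterConfig
) -> tuple[bool, str | None]:
    """Mean end-distance and strand-balance checks.

    Passes iff the mean end distance strictly exceeds the threshold for
    both alleles (pooled over samples, weighted by supporting reads) AND
    the strand condition holds: the minor allele's strand ratio passes, or
    the two-sided Fisher exact p on the pooled major/minor × fwd/rev
    table exceeds the threshold.
    """
    if meta is None:
        raise MetadataRequiredError(
            f"{site.chrom}:{site.pos}: placement/strand filter needs metadata"
        )
    support = meta.forward + meta.reverse  # reads per (sample, allele)
    for a in (0, 1):
        w = support[:, a].astype(float)
        if w.sum() == 0:
            continue  # allele absent here; nothing to judge
        d = meta.mean_end_distance[:, a]
        ok = np.isfinite(d) & (w > 0)
        mean_dist = float(np.average(d[ok], weights=w[ok])) if ok.any() else math.nan
        if not (mean_dist > cfg.min_mean_end_distance):
            return False, "end_distance"

    table = meta.pooled_strand_table()
    ratio = strand_ratio(int(table[1, 0]), int(table[1, 1]), cfg.strand_ratio_aggregator)
    if ratio > cfg.strand_ratio_threshold:
        return True, None
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    if fisher_p > cfg.strand_fisher_p_threshold:
        return True, None
    return False, "strand_bias"


def read_bed(source) -> list[tuple[str, int, int]]:
    """Read BED intervals, converting to 1-based closed coordinates."""
    own = not hasattr(source, "read")
    handle = open(str(source)) if own else source
    out = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
            out.append((fields[0], start + 1, end))  # 0-based half-open -> 1-based closed
    finally:
        if own:
            handle.close()
    return out


def masked_positions_test(
    indel_positions: Iterable[tuple[str, int, int]],
    repeat_intervals: Iterable[tuple[str, int, int]],
    cfg: FilterConfig,
):
    """Build a predicate (chrom, pos) -> masked?

    ``indel_positions`` are (chrom, 1-based anchor, length); the masked
    range covers the indel's reference footprint plus ``indel_mask_radius``
    on both sides.  ``repeat_intervals`` are 1-based closed (chrom, start,
    end), e.g. from :func:`read_bed`.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    # Indel footprint spans the anchor base through anchor + length (the
    # flanking base after an insertion / the last deleted base plus one),
    # then the radius extends both ways.
    for chrom, pos, length in indel_positions:
        lo = pos - cfg.indel_mask_radius
        hi = pos + max(int(length), 1) + cfg.indel_mask_radius
        intervals.setdefault(chrom, []).append((lo, hi))
    for chrom, start, end in repeat_intervals:
        intervals.setdefault(chrom, []).append((start, end))

    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for lo, hi in ivs:
            if out and lo <= out[-1][1] + 1:
                out[-1] = (out[-1][0], max(out[-1][1], hi))
            else:
                out.append((lo, hi))
        starts = np.array([i[0] for i in out])
        ends = np.array([i[1] for i in out])
        merged[chrom] = (starts, ends)

    def is_masked(chrom: str, pos: int) -> bool:
        if chrom not in merged:
            return False
        starts, ends = merged[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        return j >= 0 and pos <= ends[j]

    return is_masked


def mask_intervals(
    sites: Sequence[BiallelicSite],
    indel_positions: Iterable[tuple[str, int, int]],
    repeat_intervals: Iterable[tuple[str, int, int]],
    cfg: FilterConfig,
) -> tuple[list[BiallelicSite], np.ndarray]:
    """Remove sites near indels or inside repeat intervals."""
    is_masked = masked_positions_test(indel_positions, repeat_intervals, cfg)
    keep = np.array([not is_masked(s.chrom, s.pos) for s in sites], dtype=bool)
    return [s for s, k in zip(sites, keep) if k], keep


def apply_filters(
    sites: Sequence[BiallelicSite],
    populations: Mapping[int, str] | Sequence[str],
    cfg: FilterConfig,
    metadata: Sequence[SiteMetadata | None] | None = None,
    indel_positions: Iterable[tuple[str, int, int]] = (),
    repeat_intervals: Iterable[tuple[str, int, int]] = (),
) -> FilterReport:
    """Evaluate all rules in fixed order and report per-site outcomes.

    Rule order: coverage → MAC → high-coverage → end-distance →
    strand-bias → mask.  The report attributes each failed site to the
    first rule it violates; the surviving set is order-independent since
    the rules intersect as sets.
    """
    n = len(sites)
    if n >= 50:
        cutoffs = high_coverage_cutoffs(sites, cfg)
        cov = np.array(
            [s.coverage(include_other=cfg.coverage_includes_n_del) for s in sites]
        )
        high_cov_fail = (cov > cutoffs).any(axis=1)
    else:
        high_cov_fail = np.zeros(n, dtype=bool)
    is_masked = masked_positions_test(indel_positions, repeat_intervals, cfg)

    passed = np.ones(n, dtype=bool)
    first_failure: list[str | None] = [None] * n
    tallies = {rule: 0 for rule in RULES}

    for i, site in enumerate(sites):
        ok, rule = coverage_and_mac_filter(site, populations, cfg)
        if ok and high_cov_fail[i]:
            ok, rule = False, "high_coverage"
        if ok and metadata is not None:
            ok, rule = placement_strand_filter(site, metadata[i], cfg)
        if ok and is_masked(site.chrom, site.pos):
            ok, rule = False, "mask"
        if not ok:
            passed[i] = False
            first_failure[i] = rule
            tallies[rule] += 1

    return FilterReport(passed=passed, first_failure=first_failure, tallies=tallies)
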