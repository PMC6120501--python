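"""Ground-truth-bearing generators for every input the pipeline consumes.

Three generators cover the three data channels:

* :func:`generate_pool_experiment` — a replicated extreme-pool Pool-seq
  dataset in sync form.  The default scenario mirrors a two-population
  design (Vienna: 2 replicates, 120 light / 120 dark flies; Bolzano: 3
  replicates, 100 light / 50 dark), with per-sample coverage drawn
  uniformly from 54–112× and binomial read sampling at each site.
  Neutral sites share one allele frequency between pools (drawn from a
  U-shaped Beta(0.2, 0.2) site-frequency spectrum); causal sites derive
  their pool frequencies from the extreme-pool phenotype simulator or
  from directly planted light/dark frequencies.  A configurable fraction
  of sites violates the read-placement and strand filters, and indel or
  repeat masks can be planted; everything planted is recorded in the
  returned :class:`GroundTruth`.

* :func:`generate_fragments` — read-pair fragment observations over the
  focal SNPs of a haplotype model, for the LD estimator.

* :func:`generate_transgenic` — balanced 8-genotype × n-fly factorial
  phenotype data with cell means constructed from zero-sum contrasts so
  that each ANOVA term's population-level variance share matches a given
  plan.

Sequencing noise is plain binomial per site (no overdispersion) by
default; an optional beta-binomial overdispersion parameter is exposed
because real Pool-seq data are overdispersed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import ReplicateDesign
from .extreme_pool_sim import (
    HaplotypeModel,
    noise_sd,
    select_extremes,
    simulate_replicate,
)
from .factorial_anova import FACTORS, TERMS
from .marker_freq import MarkerSet
from .pool_io import BASE_INDEX, BiallelicSite, SiteMetadata, SyncSite
from .site_filters import FilterConfig


class ScenarioError(ValueError):
    pass


@dataclass
class PopulationSpec:
    name: str
    n_replicates: int
    n_light: int
    n_dark: int
    n_phenotyped: int = 1500

    def __post_init__(self) -> None:
        if min(self.n_replicates, self.n_light, self.n_dark) < 1:
            raise ScenarioError("population sizes must be positive")
        if self.n_light + self.n_dark > self.n_phenotyped:
            raise ScenarioError("pool sizes exceed phenotyped individuals")


def default_populations() -> list[PopulationSpec]:
    return [
        PopulationSpec("Vienna", n_replicates=2, n_light=120, n_dark=120),
        PopulationSpec("Bolzano", n_replicates=3, n_light=100, n_dark=50),
    ]


@dataclass
class PlantedFrequencyCausal:
    """Causal site with directly planted light/dark pool frequencies."""

    index: int
    light_freq: float
    dark_freq: float


@dataclass
class HaplotypeCausal:
    """Causal site whose pool frequencies come from phenotype simulation.

    ``snp`` picks which focal SNP of the model the site reports.
    """

    index: int
    model: HaplotypeModel
    snp: int = 0
    h2: float = 0.2


@dataclass
class ScenarioSpec:
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    n_sites: int = 1000
    chrom: str = "2L"
    start_pos: int = 10_001
    pos_step: int = 100
    causal: list = field(default_factory=list)
    coverage_range: tuple[int, int] = (54, 112)
    sfs_beta: tuple[float, float] = (0.2, 0.2)
    overdispersion: float = 0.0  # beta-binomial rho; 0 = binomial
    frac_bad_end_distance: float = 0.0
    frac_bad_strand: float = 0.0
    mean_end_distance: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.coverage_range
        if not (0 < lo <= hi):
            raise ScenarioError("coverage bounds must be ordered and positive")
        for c in self.causal:
            if not (0 <= c.index < self.n_sites):
                raise ScenarioError(f"causal index {c.index} out of range")
        if self.overdispersion < 0 or self.overdispersion >= 1:
            raise ScenarioError("overdispersion must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to score downstream results without re-simulation."""

    pool_freqs: np.ndarray  # (n_sites, n_samples) true minor/D frequency
    causal_mask: np.ndarray  # bool per site
    effect_direction: np.ndarray  # +1 D/minor enriched in dark, -1 light, 0 none
    bad_end_distance: np.ndarray  # bool per site (planted violations)
    bad_strand: np.ndarray
    sample_table: pd.DataFrame  # population, replicate, pool, sample_index
    models: dict  # site index -> HaplotypeModel for haplotype causal sites


def _sample_table(populations: Sequence[PopulationSpec]) -> pd.DataFrame:
    rows = []
    idx = 0
    for pop in populations:
        for rep in range(pop.n_replicates):
            for pool in ("light", "dark"):
                rows.append(
                    {
                        "population": pop.name,
                        "replicate": f"{pop.name}_{rep + 1}",
                        "pool": pool,
                        "sample_index": idx,
                    }
                )
                idx += 1
    return pd.DataFrame(rows)


def design_from_table(table: pd.DataFrame) -> ReplicateDesign:
    reps = []
    for _, grp in table.groupby("replicate", sort=False):
        light = grp.loc[grp["pool"] == "light", "sample_index"].tolist()
        dark = grp.loc[grp["pool"] == "dark", "sample_index"].tolist()
        reps.append((light, dark))
    return ReplicateDesign(reps)


def _draw_counts(
    rng: np.random.Generator, depth: np.ndarray, freq: np.ndarray, rho: float
) -> np.ndarray:
    """Minor-allele read counts: binomial or beta-binomial (rho > 0)."""
    if rho == 0.0:
        return rng.binomial(depth, freq)
    # beta-binomial with mean freq and intra-class correlation rho
    nu = (1 - rho) / rho
    a = np.maximum(freq * nu, 1e-9)
    b = np.maximum((1 - freq) * nu, 1e-9)
    return rng.binomial(depth, rng.beta(a, b))


def _causal_pool_freqs(
    causal, populations: Sequence[PopulationSpec], rng: np.random.Generator
) -> np.ndarray:
    """Per-sample true frequency of the focal (dark-associated) allele."""
    out = []
    if isinstance(causal, PlantedFrequencyCausal):
        for pop in populations:
            for _ in range(pop.n_replicates):
                out.extend([causal.light_freq, causal.dark_freq])
        return np.array(out)
    model, snp = causal.model, causal.snp
    alleles = model.allele_matrix()[:, snp]
    sigma = noise_sd(model, causal.h2)
    for pop in populations:
        for _ in range(pop.n_replicates):
            hap_idx, phen = simulate_replicate(
                model, pop.n_phenotyped, rng, sigma_e=sigma
            )
            light, dark = select_extremes(phen, pop.n_light, pop.n_dark, rng)
            out.append(alleles[hap_idx[light]].mean())
            out.append(alleles[hap_idx[dark]].mean())
    return np.array(out)


def generate_pool_experiment(spec: ScenarioSpec, rng: np.random.Generator | None = None):
    """Simulate a full pooled experiment.

    Returns ``(sites, metadata, design, truth)``: sync sites, per-site
    :class:`SiteMetadata` (ordered as (major?, minor) by construction the
    reference allele 'A' is major at moderate frequencies — metadata is
    keyed to (ref-allele, alt-allele) = (A, T) columns), the replicate
    design, and the ground truth.  All sites are biallelic A/T with 'A'
    the reference; the 'T' (alternative / dark-associated) allele
    carries the planted frequency.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    table = _sample_table(spec.populations)
    n_samples = len(table)
    n_sites = spec.n_sites

    freqs = np.empty((n_sites, n_samples))
    shared = rng.beta(*spec.sfs_beta, size=n_sites)
    freqs[:] = shared[:, None]
    causal_mask = np.zeros(n_sites, dtype=bool)
    direction = np.zeros(n_sites, dtype=np.int8)
    models: dict[int, HaplotypeModel] = {}
    for causal in spec.causal:
        fs = _causal_pool_freqs(causal, spec.populations, rng)
        freqs[causal.index] = fs
        causal_mask[causal.index] = True
        is_dark = table["pool"].to_numpy() == "dark"
        diff = fs[is_dark].mean() - fs[~is_dark].mean()
        direction[causal.index] = 1 if diff > 0 else (-1 if diff < 0 else 0)
        if isinstance(causal, HaplotypeCausal):
            models[causal.index] = causal.model

    lo, hi = spec.coverage_range
    depth = rng.integers(lo, hi + 1, size=(n_sites, n_samples))
    alt = _draw_counts(rng, depth, freqs, spec.overdispersion)
    ref = depth - alt

    n_bad_end = int(round(spec.frac_bad_end_distance * n_sites))
    n_bad_strand = int(round(spec.frac_bad_strand * n_sites))
    bad = rng.choice(n_sites, size=min(n_sites, n_bad_end + n_bad_strand),
                     replace=False)
    bad_end = np.zeros(n_sites, dtype=bool)
    bad_strand = np.zeros(n_sites, dtype=bool)
    bad_end[bad[:n_bad_end]] = True
    bad_strand[bad[n_bad_end:]] = True

    sites: list[SyncSite] = []
    metadata: list[SiteMetadata] = []
    for i in range(n_sites):
        depths = np.zeros((n_samples, 6), dtype=np.int64)
        depths[:, BASE_INDEX["A"]] = ref[i]
        depths[:, BASE_INDEX["T"]] = alt[i]
        sites.append(
            SyncSite(
                chrom=spec.chrom,
                pos=spec.start_pos + i * spec.pos_step,
                ref="A",
                depths=depths,
            )
        )
        counts = np.column_stack([ref[i], alt[i]])
        if bad_strand[i]:
            fwd = np.column_stack(
                [rng.binomial(ref[i], 0.5), counts[:, 1]]  # minor all forward
            )
        else:
            fwd = rng.binomial(counts, 0.5)
        rev = counts - fwd
        if bad_end[i]:
            med = rng.uniform(2.0, 8.0)
        else:
            med = rng.normal(spec.mean_end_distance, 3.0)
            med = max(med, 9.0)
        mean_end = np.full((n_samples, 2), med)
        mean_end[counts == 0] = np.nan
        metadata.append(
            SiteMetadata(forward=fwd, reverse=rev, mean_end_distance=mean_end)
        )

    truth = GroundTruth(
        pool_freqs=freqs,
        causal_mask=causal_mask,
        effect_direction=direction,
        bad_end_distance=bad_end,
        bad_strand=bad_strand,
        sample_table=table,
        models=models,
    )
    return sites, metadata, design_from_table(table), truth


# --------------------------------------------------------------------------
# Inversion-marker pools


def generate_marker_experiment(
    planted: Mapping[str, float],
    populations: Sequence[PopulationSpec] | None = None,
    n_markers: int = 62,
    chrom: str = "3R",
    depth: int = 80,
    rng: np.random.Generator | None = None,
):
    """Synthetic inversion-marker data: pools with planted inversion
    frequencies.

    ``planted`` maps pool class ('light'/'dark') to the true inversion
    frequency in that class.  Per marker and pool the diagnostic-allele
    count is binomial at the planted frequency.  Returns ``(sites,
    marker_set, pool_table)`` where ``pool_table`` carries one row per
    pool with its estimated median frequency left to the caller.
    """
    if rng is None:
        rng = np.random.default_rng()
    if populations is None:
        populations = default_populations()
    table = _sample_table(populations)
    n_samples = len(table)
    truth = table["pool"].map(planted).to_numpy(dtype=float)

    positions = 1_000_001 + 500 * np.arange(n_markers)
    marker_set = MarkerSet(
        name="In(synthetic)",
        markers=[(chrom, int(p), "T") for p in positions],
    )
    sites = []
    for pos in positions:
        inv = rng.binomial(depth, truth)
        depths = np.zeros((n_samples, 6), dtype=np.int64)
        depths[:, BASE_INDEX["A"]] = depth - inv
        depths[:, BASE_INDEX["T"]] = inv
        sites.append(SyncSite(chrom=chrom, pos=int(pos), ref="A", depths=depths))
    return sites, marker_set, table


# --------------------------------------------------------------------------
# Read-pair fragments


def generate_fragments(
    model: HaplotypeModel,
    n_fragments: int,
    loci: Sequence[int] | None = None,
    coverage_pattern: Sequence[tuple[Sequence[int], float]] | None = None,
    rng: np.random.Generator | None = None,
    d_base: str = "T",
    l_base: str = "A",
) -> pd.DataFrame:
    """Long-format fragment observations sampled from a haplotype model.

    Each fragment draws a haplotype by frequency and covers a subset of
    the focal loci: all of them by default, or a subset drawn from
    ``coverage_pattern`` (list of (locus subset, probability)).  D/L
    alleles are emitted as concrete bases (default T/A).  Returns a
    DataFrame with columns fragment_id, locus, base.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n_snps = len(model.snp_names)
    if loci is None:
        loci = [9_121_129 - 100 * i for i in range(n_snps)]
        loci = sorted(loci)
    loci = list(loci)
    if coverage_pattern is None:
        coverage_pattern = [(tuple(range(n_snps)), 1.0)]
    subsets = [tuple(s) for s, _ in coverage_pattern]
    probs = np.array([p for _, p in coverage_pattern], dtype=float)
    probs = probs / probs.sum()

    hap_idx = rng.choice(len(model.haplotypes), size=n_fragments,
                         p=model.frequencies)
    which = rng.choice(len(subsets), size=n_fragments, p=probs)
    rows = []
    strings = model.strings
    for f in range(n_fragments):
        hap = strings[hap_idx[f]]
        for j in subsets[which[f]]:
            rows.append(
                {
                    "fragment_id": f"frag{f}",
                    "locus": loci[j],
                    "base": d_base if hap[j] == "D" else l_base,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Transgenic factorial phenotypes


def generate_transgenic(
    effect_plan: Mapping[str, float],
    n_per_cell: int = 10,
    rng: np.random.Generator | None = None,
    location: float = 150.0,
    scale: float = 30.0,
) -> pd.DataFrame:
    """Balanced 2×2×2 factorial intensities with planned variance shares.

    ``effect_plan`` maps ANOVA terms ('snp1', 'snp2:snp3', ...) to target
    η² shares (non-negative, summing to ≤ 1); the remainder becomes
    Gaussian residual variance.  Cell means are built from zero-sum ±1
    contrasts with coefficient sqrt(share) × scale, so each term's
    population-level variance share matches the plan exactly.  Intensity
    is centred at ``location`` on the 0–255 trident scale.
    """
    unknown = set(effect_plan) - set(TERMS)
    if unknown:
        raise ValueError(f"unknown terms in plan: {sorted(unknown)}")
    shares = {t: float(effect_plan.get(t, 0.0)) for t in TERMS}
    if any(v < 0 for v in shares.values()):
        raise ValueError("effect shares must be non-negative")
    total = sum(shares.values())
    if total > 1 + 1e-12:
        raise ValueError("effect shares must sum to <= 1")
    if rng is None:
        rng = np.random.default_rng()
    resid_sd = scale * math.sqrt(max(0.0, 1.0 - total))

    rows = []
    for combo in itertools.product("DL", repeat=3):
        contrasts = {f: (1.0 if a == "D" else -1.0) for f, a in zip(FACTORS, combo)}
        mean = location
        for term, share in shares.items():
            coef = math.sqrt(share) * scale
            prod = 1.0
            for part in term.split(":"):
                prod *= contrasts[part]
            mean += coef * prod
        y = mean + rng.normal(0.0, resid_sd, size=n_per_cell)
        for val in y:
            rows.append(
                {
                    "snp1": combo[0],
                    "snp2": combo[1],
                    "snp3": combo[2],
                    "intensity": float(val),
                }
            )
    return pd.DataFrame(rows)


#: Trident-column η² profile of the transgenic assay (main effects and
#: the significant SNP2×SNP3 interaction).
TRIDENT_EFFECT_PLAN = {
    "snp1": 0.082,
    "snp2": 0.328,
    "snp3": 0.289,
    "snp2:snp3": 0.052,
}


# --------------------------------------------------------------------------
# Filter fixture with planted violations of every rule


def generate_filter_fixture(seed: int = 0):
    """200-site toy dataset violating each site filter in a planted block.

    Four samples (two replicates × light/dark, one population).  Blocks:
    sites 0–9 coverage 14 in sample 0; 10–19 population minor allele
    count 7; 20–29 mean end distance exactly 8.0; 30–39 minor allele
    fully strand-imbalanced; 40–49 adjacent to a planted indel; four
    sites with extreme coverage that land above the 98% coverage
    quantile.  Everything else passes every rule.  Returns ``(sites,
    metadata, populations, indels, truth)`` with ``truth`` mapping rule
    name -> set of failing site indices.
    """
    rng = np.random.default_rng(seed)
    n_sites, n_samples = 200, 4
    populations = ["pop"] * n_samples

    blocks = {
        "min_coverage": set(range(0, 10)),
        "min_mac": set(range(10, 20)),
        "end_distance": set(range(20, 30)),
        "strand_bias": set(range(30, 40)),
        "mask": set(range(40, 50)),
        "high_coverage": {50, 51, 52, 53},
    }

    sites: list[BiallelicSite] = []
    metadata: list[SiteMetadata] = []
    indels: list[tuple[str, int, int]] = []
    for i in range(n_sites):
        pos = 1000 + i * 20
        # Coverage tops out at exactly 100 for a visible fraction of sites,
        # so each clean sample's 98% quantile is 100 and only the planted
        # extreme-coverage sites strictly exceed their cutoff.
        if i % 8 == 7:
            depth = np.full(n_samples, 100, dtype=np.int64)
        else:
            depth = rng.integers(54, 97, size=n_samples)
        freq = rng.uniform(0.25, 0.5)
        minor = rng.binomial(depth, freq)
        minor = np.clip(minor, 3, depth)  # keep MAC comfortably high
        if i in blocks["min_coverage"]:
            depth = depth.copy()
            depth[0] = 14
            minor[0] = min(minor[0], 7)
        if i in blocks["min_mac"]:
            minor = np.array([2, 2, 2, 1])
        if i in blocks["high_coverage"]:
            depth = depth.copy()
            depth[1] = 500
            minor[1] = 200
        minor = np.minimum(minor, depth)
        major = depth - minor
        counts = np.column_stack([major, minor])
        site = BiallelicSite(
            chrom="2L", pos=pos, ref="A", major_allele="A", minor_allele="T",
            counts=counts, other=np.zeros(n_samples, dtype=np.int64),
        )
        sites.append(site)
        if i in blocks["mask"]:
            indels.append(("2L", pos - rng.integers(0, 6), 1))

        if i in blocks["strand_bias"]:
            fwd = np.column_stack([rng.binomial(major, 0.5), minor])
        else:
            fwd = rng.binomial(counts, 0.5)
        rev = counts - fwd
        med_val = 8.0 if i in blocks["end_distance"] else float(rng.uniform(20, 35))
        mean_end = np.full((n_samples, 2), med_val)
        mean_end[counts == 0] = np.nan
        metadata.append(
            SiteMetadata(forward=fwd, reverse=rev, mean_end_distance=mean_end)
        )

    return sites, metadata, populations, indels, blocks
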