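# Methods

This note documents the statistical models behind `poolpig`, the
assumptions they make, the defaults they ship with, and what the
synthetic-data generators do and do not emulate.

## Data model

Pooled sequencing of phenotypically extreme pools ("Pool-GWAS")
replaces individual genotypes with per-pool allele depths.  The on-disk
representation is the popoolation2 sync format: per site and pool, six
counts in the fixed order A:T:C:G:N:deletion.  Coordinates are 1-based
and fully closed; BED input (0-based, half-open) is converted when read.
Each site is reduced to its two highest-depth bases (ties broken in the
fixed order A < C < G < T); N and deletion depth never participate in
allele calling but do count toward site coverage by default, because
"coverage" in the source thresholds is unqualified — a flag
(`coverage_includes_n_del`) restricts coverage to the four bases.
Third-allele depth is kept in `other` rather than dropped, so filters
can reject suspicious multiallelic sites without biasing the retained
2×2 counts.

## Site filters

Defaults (all configurable via `FilterConfig`):

| rule | default | unit |
|---|---|---|
| minimum coverage, every sample | 15 | reads |
| minimum minor allele count per population | 8 | reads, summed over the population's pools |
| high-coverage exclusion | 0.98 | empirical quantile of per-sample coverage |
| minimum mean end distance | 8 (strict >) | bases from the nearer read end |
| strand ratio floor | 0.1 | min(fwd/rev, rev/fwd) of minor-allele reads |
| strand Fisher rescue | 0.01 | two-sided exact p on {major,minor}×{fwd,rev} |
| indel mask radius | 5 | bases each side of the indel footprint |

Two readings deserve comment.  First, the strand clause is printed in
the source pipelines as `max(fwd/rev, rev/fwd) > 0.1`, which any table
with one nonzero count satisfies (the larger of a ratio and its
reciprocal is ≥ 1); the default here is the `min` aggregator, the
reading under which the clause actually filters, with the literal `max`
behaviour available as a flag.  Second, the minor allele count floor is
applied to the sum over all pools of a population, the closest reading
of "overall ... in each population".  The strand test is applied to the
minor allele (the variant-supporting reads), with 0/x = 0 and
x/0 = +∞.  The high-coverage cutoff is computed per sample over the
whole dataset; a flag switches to per-chromosome-arm cutoffs.  Rules are
evaluated in a fixed order (coverage → MAC → high-coverage →
end-distance → strand → mask) purely for reproducible failure
attribution; the surviving set is the intersection of the per-rule pass
sets and therefore order-independent, which the tests assert.

The indel footprint is taken as `[pos, pos + length]` (anchor base
through the first base after the event) before adding the radius, so a
length-1 indel at 1000 with radius 5 masks 995–1006.

## Replicated association testing

For each biallelic site a 2×2 table of (light, dark) × (major, minor)
read counts is built per replicate and combined with the
Cochran–Mantel–Haenszel test.  With stratum k written as
((a_k, b_k), (c_k, d_k)), n_k the stratum total:

* statistic: (|Σ(a_k − E a_k)| − c)² / Σ Var(a_k), hypergeometric
  moments given the margins, c = 0.5 with the continuity correction
  (default on, matching R's `mantelhaen.test`, the implementation the
  original pipelines relied on); p from χ²(1);
* effect size: the Mantel–Haenszel odds ratio
  Σ a_k d_k / n_k ÷ Σ b_k c_k / n_k, its natural log serving as the
  effect proxy; 95% CI from the Robins–Breslow–Greenland variance of
  log OR (the standard asymptotic CI for stratified 2×2 tables; no
  method is named in the source, and RBG is the default choice here);
* degenerate strata (a zero margin) contribute nothing; if all strata
  are degenerate the site is reported untestable.  Zero cells receive
  no continuity increment in the OR — the MH estimator tolerates them —
  and an exhausted denominator yields an explicit infinite OR with an
  unbounded CI.

Autosomal counts are downsampled to 50% on the p-value pathway only
(males carry one X, so X-linked depth is about half the autosomal
depth and p-values would otherwise not be comparable across
chromosomes).  Downsampling is a single multivariate hypergeometric
draw of floor(total × fraction) reads — sampling without replacement —
with one draw per site under the run's seed (a flag allows multiple
draws with the median p).  Odds ratios and allele frequencies always
use full depth.

### Empirical-null FDR

`empirical_fdr` scans the sorted observed p-values as candidate
thresholds t and estimates
FDR(t) = (#{null ≤ t} × N_obs/N_null) / max(1, #{obs ≤ t}),
reporting the largest t with FDR(t) ≤ q (default q = 0.05).  The null
p-value set is an input; two generators ship: same-phenotype contrasts
(light vs light across replicates — note these have fewer strata than
the observed contrast) and within-pool random read splits (same strata
count and sites, but halved depths coarsen the count lattice, which is
detectable as mild non-uniformity in very large scans).  Which null to
use is a configuration choice, not hard-coded.  A property of the
estimator worth knowing: an observed p smaller than every null p gives
an estimated FDR of exactly 0 at that threshold, so a finite
independent null can declare a lone null site significant; with the
observed 0-causal distribution used as its own null the estimate is 1
everywhere and nothing is called.

Calibration note: the continuity correction is deliberately
conservative, so null uniformity of p-values is a property of the
uncorrected statistic; the calibration tests run with the correction
off and at X-linked sites so the no-downsampling path is exercised at
the nominal depth.

## Inversion frequencies and association

A pool's inversion frequency is the median diagnostic-allele frequency
over the covered markers of an inversion-specific SNP panel (uncovered
markers are skipped, never imputed; an even marker count averages the
central pair).  The same estimator summarises species-diagnostic
markers as a contamination fraction.  Association with the phenotype is
ordinary least squares on arcsine-square-root transformed pool
frequencies with population and pool (light/dark) as categorical
predictors — treatment coding with light as reference; for a binary
factor the pool coefficient's p-value is coding-invariant.  Each
replicate pool enters as one row.  The pool p-value is Bonferroni
corrected over the inversion family screened (default family size 7,
the usual cosmopolitan panel; configurable since the original family
size is not stated).

## Read-pair haplotypes and LD

Fragments (read pairs) covering all requested focal loci are tallied
into haplotype counts directly; a fragment whose two reads disagree at
a shared locus is discarded.  No EM over partially covering fragments
is attempted — direct counting is auditable and matches how the
haplotypic configurations were inferred; an EM extension is explicitly
out of scope.  Base-quality thresholding is a configuration option
defaulting to accept-all, since no threshold is stated for this step.
Two-locus LD uses D = p_AB − p_A p_B and r² = D²/(p_A(1−p_A)p_B(1−p_B));
a locus monomorphic among counted fragments yields a flagged undefined
result rather than r² = 0.

## Extreme-pool simulation

Each simulated individual carries one haplotype over the focal SNPs —
the hemizygous-male convention, since the focal region is X-linked and
only males were phenotyped; a diploid additive mode exists but is off
by default.  Phenotype = base score + N(0, σ_E) with
σ_E² = V_G(1−h²)/h², V_G the frequency-weighted base-score variance.
Defaults: 5 replicates × 1500 individuals, the 100 lightest and 75
darkest selected per replicate (lower value = lighter, matching the
0–255 intensity scale), h² = 0.2, exact boundary ties broken by a
seeded shuffle.  Per-SNP allele counts of the pools are stacked over
replicates and CMH-tested; log OR is oriented dark-allele-in-dark-pool,
so a positive value means the D-labelled allele behaves dark in the
pooled contrast.

The shipped `example_coupled_model` is synthetic, not an empirical
estimate (the measured haplotype frequencies and transgene medians live
in supporting material not reproduced here): four haplotypes with SNP1
and SNP2 fully coupled (LL/DD only), additive half-effects +6/−4/+9
intensity units around 150, frequencies 0.25/0.05/0.15/0.55 for
DDD/DDL/LLD/LLL.  It satisfies every documented structural constraint:
SNP2's isolated effect is lightening (−8 over the full D/L contrast),
the coupled DD block nets darkening (+4), and the block's magnitude is
smaller than SNP2's own (|+4| < |−8|) — so the pooled contrast assigns
SNP2 the reversed (dark) direction, and SNP3 segregates freely with
the largest effect (±18).  Users
replicating the original experiment must supply their own frequencies
and base scores.

## Factorial ANOVA

Trident intensity is 255 minus the mean pixel value of the delimited
trident polygon (0 white, 255 black).  The 2×2×2 transgene assay (all
eight D/L combinations, nominally 10 males per cell) is fitted with
zero-sum ±1 contrasts; type-III SS are computed by comparing the full
model to the model dropping each term's column, and on balanced data
verified against the direct orthogonal projection (the two coincide;
the identity is asserted on every balanced fit, and Σ SS + residual
equals the total SS about the grand mean).  η² = SS_term/SS_total with
the residual row included, so rows sum to 1.  Unbalanced data are
accepted — the model-comparison path is then authoritative and the
orthogonality identities are skipped.  One fly per cell leaves zero
residual df: SS are still computed, F and p are refused unless the
caller opts out of tests.

## Synthetic data: what it does and does not emulate

`generate_pool_experiment` reproduces the study geometry — two
populations (Vienna 2 replicates, 120/120; Bolzano 3 replicates,
100/50 — the dark pools actually held 48–55 flies; 50 is the shipped
default and configurable), per-sample coverage uniform on 54–112×, and
binomial read sampling per site.  Neutral sites share one frequency
between pools, drawn from a U-shaped Beta(0.2, 0.2) spectrum; causal
sites take pool frequencies from the phenotype simulator (or directly
planted values).  Read-placement and strand metadata are drawn so a
configurable fraction of sites violates the filters, with the planted
sets recorded in the ground truth.

Deliberately not emulated: mapping artefacts, reference bias, indel
realignment, overdispersion beyond binomial (a beta-binomial option
exists but defaults off), linkage between genome-scan sites, and the
two-stage sampling of individuals into pools at neutral sites (pools
share the exact population frequency, which makes the no-signal case an
exact null — the property the calibration tests need).  Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated sampling model, not robustness to real-data artefacts.

`generate_transgenic` builds cell means from zero-sum contrasts with
coefficient sqrt(share) × scale per term (scale 30 intensity units,
centre 150), plus Gaussian residual making the shares sum to one, so
population-level η² matches the plan exactly; finite-sample recovered
η² is upward-biased by roughly σ²/SS_total per term (≈ 0.008 at
10 flies/cell), well inside the ±0.05 recovery band used in testing.

## Numerical choices and problem sizes

Quantile computation uses numpy's default linear interpolation; medians
of even counts average the central pair; the CMH scan is vectorised
over sites; random draws all flow from `numpy.random.Generator` seeded
explicitly, and fixed seeds reproduce outputs bit-for-bit.  The test
suite and the acceptance script size their simulations to keep the full
run in the tens of seconds on one CPU: 500 transgenic assays, 1000
random CMH tables, a 22,000-site null scan (≈ 12,000 sites surviving
filters), 200 in-silico experiments, 1000 marker experiments, 10,000
downsampling draws.

## Known limitations

* The empirical-null FDR estimator can report an estimated FDR of zero
  at the smallest observed p (finite-null artefact); consumers wanting
  a conservative floor should enlarge the null set.
* The direct haplotype counter ignores fragments that cover only a
  subset of the loci; with short inserts and distant loci this discards
  most of the data — acceptable for the three tightly clustered focal
  SNPs it was built for.
* The inversion model treats pool frequencies as independent
  observations; replicate pools from one population share ancestry, so
  p-values are optimistic for strongly structured designs.
* Hemizygous (one-haplotype) simulation is only appropriate for
  X-linked loci scored in males; use the diploid mode otherwise.
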