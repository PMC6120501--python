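"""Marker-based frequency estimation and the inversion association model.

Cosmopolitan inversions such as In(3R)Payne suppress recombination over
megabases, so a panel of inversion-specific marker SNPs tags the inverted
arrangement; the pool frequency of the inversion is estimated as the
median of the diagnostic-allele frequencies over the covered markers.
The same machinery summarises species-diagnostic markers (e.g. fixed
D. simulans differences) as a contamination estimate.

Association of an inversion with the extreme-pool phenotype is tested by
ordinary least squares on the arcsine-square-root transformed pool
frequencies, with population and pool (light/dark) as categorical
predictors, followed by a Bonferroni correction of the pool coefficient's
p-value over the family of inversions screened (default family size 7,
the usual cosmopolitan panel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pool_io import BASE_INDEX, SyncSite


class MarkerEstimationError(ValueError):
    """No marker of the set is covered in the pool."""


class ModelError(ValueError):
    """Inversion model cannot be fitted (rank deficiency, tiny design)."""


@dataclass
class MarkerSet:
    """Named marker panel: (chrom, pos, diagnostic allele) triples."""

    name: str
    markers: Sequence[tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError("marker set must be non-empty")
        positions = [(c, p) for c, p, _ in self.markers]
        if len(set(positions)) != len(positions):
            raise ValueError("marker positions must be unique")
        for _, _, allele in self.markers:
            if allele not in BASE_INDEX or allele == "N":
                raise ValueError(f"bad diagnostic allele {allele!r}")


@dataclass
class MarkerFrequencyResult:
    pool: int | str
    median_frequency: float
    n_markers_used: int
    per_marker: dict  # (chrom, pos) -> frequency


def marker_median_frequency(
    sites: Iterable[SyncSite], pool_sample: int, marker_set: MarkerSet
) -> MarkerFrequencyResult:
    """Median diagnostic-allele frequency over covered markers in a pool.

    Per marker: diagnostic-allele depth / total base depth (A+T+C+G) in
    the pool's sync column.  Markers with zero coverage are skipped, not
    imputed.  An even number of covered markers yields the mean of the
    two central values (numpy median convention).
    """
    lookup = {(c, p): allele for c, p, allele in marker_set.markers}
    per_marker: dict[tuple[str, int], float] = {}
    for site in sites:
        key = (site.chrom, site.pos)
        if key not in lookup:
            continue
        row = site.depths[pool_sample]
        total = int(row[:4].sum())
        if total == 0:
            continue
        per_marker[key] = float(row[BASE_INDEX[lookup[key]]] / total)
    if not per_marker:
        raise MarkerEstimationError(
            f"{marker_set.name}: no covered marker in pool {pool_sample}"
        )
    freqs = np.array(list(per_marker.values()))
    return MarkerFrequencyResult(
        pool=pool_sample,
        median_frequency=float(np.median(freqs)),
        n_markers_used=len(per_marker),
        per_marker=per_marker,
    )


def arcsine_sqrt(f: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilising transform asin(sqrt(f)), mapping [0,1] to [0, π/2]."""
    arr = np.asarray(f, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("frequency outside [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out


@dataclass
class InversionModelFit:
    coefficients: dict  # name -> estimate (on the transformed scale)
    pool_p_value: float
    bonferroni_adjusted_p: float
    family_size: int
    pool_coefficient: float


def inversion_association(
    frequencies: pd.DataFrame, family_size: int = 7
) -> InversionModelFit:
    """OLS on arcsine-sqrt frequencies with population and pool predictors.

    ``frequencies`` needs columns ``frequency`` (in [0,1]), ``population``
    and ``pool`` (values 'light'/'dark').  Treatment coding with light as
    the reference level: the ``pool`` coefficient is the transformed-scale
    shift of dark pools, and its two-sided t-test p-value is Bonferroni
    corrected over ``family_size`` inversions.
    """
    df = frequencies
    for col in ("frequency", "population", "pool"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    pools = set(df["pool"])
    if not pools <= {"light", "dark"}:
        raise ValueError(f"pool labels must be 'light'/'dark', got {pools}")
    if (df["pool"] == "light").sum() < 2 or (df["pool"] == "dark").sum() < 2:
        raise ModelError("need >= 2 pools in each pool class")

    y = arcsine_sqrt(df["frequency"].to_numpy())
    x_parts = [np.ones(len(df))]
    names = ["intercept"]
    pop_levels = sorted(set(df["population"]))
    for level in pop_levels[1:]:  # first population is the reference
        x_parts.append((df["population"] == level).to_numpy(float))
        names.append(f"population[{level}]")
    x_parts.append((df["pool"] == "dark").to_numpy(float))
    names.append("pool[dark]")
    x = np.column_stack(x_parts)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ModelError("design matrix is rank deficient")

    fit = sm.OLS(y, x).fit()
    coef = dict(zip(names, fit.params))
    pool_p = float(fit.pvalues[-1])
    return InversionModelFit(
        coefficients=coef,
        pool_p_value=pool_p,
        bonferroni_adjusted_p=min(1.0, pool_p * family_size),
        family_size=family_size,
        pool_coefficient=float(fit.params[-1]),
    )


def read_marker_table(source) -> dict[str, MarkerSet]:
    """Read a marker TSV (inversion, chrom, pos, inverted_allele)."""
    df = pd.read_csv(source, sep="\t")
    required = {"inversion", "chrom", "pos", "inverted_allele"}
    if not required <= set(df.columns):
        raise ValueError(f"marker table needs columns {sorted(required)}")
    out = {}
    for name, grp in df.groupby("inversion"):
        out[str(name)] = MarkerSet(
            name=str(name),
            markers=[
                (str(r.chrom), int(r.pos), str(r.inverted_allele))
                for r in grp.itertuples()
            ],
        )
    return out
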