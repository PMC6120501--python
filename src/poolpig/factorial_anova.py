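"""Trident intensity quantification and 2×2×2 factorial variance partition.

Transgenic lines carrying every combination of the three focal enhancer
SNPs (dark D or light L allele each) are phenotyped by imaging: the mean
pixel value inside the delimited trident polygon is subtracted from 255
so that 0 is white and 255 black.  A full-factorial three-way ANOVA with
zero-sum contrasts and type-III sums of squares then partitions the
phenotypic variance among the three main effects, the three two-way
interactions, the three-way interaction and the residual; effect sizes
are reported as η² = SS_term / SS_total.

Type III is computed the standard way — comparing the full model against
the model dropping each term under zero-sum coding — and, for balanced
data, cross-checked against the direct orthogonal projection (the two
coincide because the sum-coded design columns are orthogonal).
Unbalanced data (lost flies) are accepted; then the model-comparison
path is authoritative and the orthogonality identities no longer hold.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

FACTORS = ("snp1", "snp2", "snp3")
#: ANOVA terms in canonical order (main effects, two-way, three-way).
TERMS = ("snp1", "snp2", "snp3", "snp1:snp2", "snp1:snp3", "snp2:snp3",
         "snp1:snp2:snp3")


class DesignError(ValueError):
    """Missing genotype cell or no residual information."""


class DegenerateDataError(ValueError):
    """Zero total sum of squares: η² undefined."""


class MeasurementError(ValueError):
    pass


def trident_intensity(pixel_values: Sequence[float] | np.ndarray) -> float:
    """Trident pigmentation intensity: 255 − mean pixel value.

    Pixel values come from the delimited trident polygon, on the usual
    0 (black) – 255 (white) camera scale; the flip makes 0 white and 255
    black so darker flies score higher.
    """
    px = np.asarray(pixel_values, dtype=float)
    if px.size == 0:
        raise MeasurementError("empty pixel region")
    if (px < 0).any() or (px > 255).any():
        raise MeasurementError("pixel values outside [0, 255]")
    return float(255.0 - px.mean())


def parse_genotype(genotype: str) -> dict[str, str]:
    """Split a genotype string like 'DLD' into per-SNP alleles."""
    g = genotype.strip().upper()
    if len(g) != 3 or set(g) - {"D", "L"}:
        raise ValueError(f"bad genotype string {genotype!r}")
    return dict(zip(FACTORS, g))


def as_factorial_frame(data: pd.DataFrame) -> pd.DataFrame:
    """Normalise input to columns snp1, snp2, snp3, intensity.

    Accepts either explicit per-SNP columns or a ``genotype`` column of
    three-letter D/L strings.
    """
    df = data.copy()
    if "genotype" in df.columns and not set(FACTORS) <= set(df.columns):
        parsed = df["genotype"].map(parse_genotype)
        for f in FACTORS:
            df[f] = parsed.map(lambda d: d[f])
    missing = (set(FACTORS) | {"intensity"}) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for f in FACTORS:
        levels = set(df[f])
        if not levels <= {"D", "L"}:
            raise ValueError(f"{f}: levels must be D/L, got {levels}")
    return df[[*FACTORS, "intensity"]]


def _design_matrix(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Zero-sum (±1) coded design: intercept plus one column per term."""
    contrasts = {f: np.where(df[f].to_numpy() == "D", 1.0, -1.0) for f in FACTORS}
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in TERMS:
        parts = term.split(":")
        col = np.ones(len(df))
        for p in parts:
            col = col * contrasts[p]
        cols.append(col)
        names.append(term)
    return np.column_stack(cols), names


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(resid @ resid)


def fit_factorial(data: pd.DataFrame, require_f: bool = True) -> pd.DataFrame:
    """Type-III ANOVA table for the full 2×2×2 model.

    Returns a DataFrame indexed by term (plus ``Residuals``) with columns
    ``SS``, ``df``, ``F``, ``p`` and ``eta2``.  Every genotype cell must
    be populated; with one fly per cell the residual df is zero, SS are
    still computed but F and p are NaN (and raised if ``require_f``).
    On balanced data the type-III SS are verified against the direct
    projection decomposition.
    """
    df = as_factorial_frame(data)
    cells = df.groupby(list(FACTORS), observed=False).size()
    if len(cells) < 8 or (cells == 0).any():
        raise DesignError("all 8 genotype cells must be non-empty")
    y = df["intensity"].to_numpy(dtype=float)
    n = len(y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise DegenerateDataError("constant response: zero total SS")

    x, names = _design_matrix(df)
    sse_full = _sse(x, y)
    df_res = n - x.shape[1]
    if df_res <= 0 and require_f:
        raise DesignError("no residual degrees of freedom for F tests")

    ss = {}
    for j, term in enumerate(TERMS, start=1):
        reduced = np.delete(x, j, axis=1)
        ss[term] = _sse(reduced, y) - sse_full

    balanced = cells.nunique() == 1
    if balanced:
        # orthogonal projection path: SS_term = (x_t'y)^2 / (x_t'x_t)
        for j, term in enumerate(TERMS, start=1):
            proj = float(x[:, j] @ y) ** 2 / float(x[:, j] @ x[:, j])
            if not math.isclose(proj, ss[term], rel_tol=1e-8, abs_tol=1e-8):
                raise AssertionError(
                    f"balanced-design decomposition mismatch for {term}"
                )

    rows = []
    ms_res = sse_full / df_res if df_res > 0 else math.nan
    for term in TERMS:
        f_stat = (ss[term] / 1) / ms_res if df_res > 0 else math.nan
        p = float(stats.f.sf(f_stat, 1, df_res)) if df_res > 0 else math.nan
        rows.append((term, ss[term], 1, f_stat, p, ss[term] / ss_total))
    rows.append(("Residuals", sse_full, max(df_res, 0), math.nan, math.nan,
                 sse_full / ss_total))
    table = pd.DataFrame(
        rows, columns=["term", "SS", "df", "F", "p", "eta2"]
    ).set_index("term")
    return table


def eta_squared(table: pd.DataFrame) -> dict[str, float]:
    """η² per term (including residuals) from an ANOVA table.

    Computed as SS/SS_total.  The denominator is the sum of the table's
    SS rows, which equals the total SS about the grand mean exactly for
    balanced designs (how the transgenic assay is laid out).
    """
    ss_total = float(table["SS"].sum())
    if ss_total <= 0:
        raise DegenerateDataError("zero total SS")
    return {term: float(row_ss / ss_total) for term, row_ss in table["SS"].items()}
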