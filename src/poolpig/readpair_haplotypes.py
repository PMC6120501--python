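"""Haplotype counting and pairwise LD from fragments spanning focal SNPs.

Paired-end sequencing fragments (read pairs) that physically span two or
more nearby SNPs reveal the phase of those sites directly, without
genotyped individuals — the idea behind read-pair LD estimation in
pooled data.  Only fragments covering *every* requested locus contribute
to a haplotype count, so the tallies are direct observations rather than
EM reconstructions; a fragment whose two reads disagree at a shared
locus is discarded as a likely sequencing error.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

_BASES = frozenset("ACGT")


@dataclass
class FragmentObservation:
    """Alleles observed on one fragment at the loci it covers."""

    fragment_id: str
    alleles: Mapping[int, str]  # locus (1-based position) -> base
    conflicted: bool = False  # read1 vs read2 disagreed somewhere

    def __post_init__(self) -> None:
        if len(self.alleles) == 0:
            raise ValueError(f"fragment {self.fragment_id}: covers no locus")
        bad = {b for b in self.alleles.values() if b not in _BASES}
        if bad:
            raise ValueError(f"fragment {self.fragment_id}: bad bases {bad}")


@dataclass
class HaplotypeCounts:
    """Allele-string tallies over fragments covering all ``loci``."""

    loci: tuple[int, ...]
    counts: Mapping[str, int]
    total: int

    @property
    def empty(self) -> bool:
        return self.total == 0


def fragments_from_table(table: pd.DataFrame) -> list[FragmentObservation]:
    """Build fragments from long-format rows (fragment_id, locus, base).

    Duplicate calls at a locus (read 1 and read 2 both covering it) are
    merged when they agree and mark the fragment conflicted when they do
    not.
    """
    required = {"fragment_id", "locus", "base"}
    if not required <= set(table.columns):
        raise ValueError(f"fragment table needs columns {sorted(required)}")
    out = []
    for frag_id, grp in table.groupby("fragment_id", sort=False):
        alleles: dict[int, str] = {}
        conflicted = False
        for row in grp.itertuples():
            locus, base = int(row.locus), str(row.base)
            if locus in alleles and alleles[locus] != base:
                conflicted = True
            alleles[locus] = base
        out.append(
            FragmentObservation(
                fragment_id=str(frag_id), alleles=alleles, conflicted=conflicted
            )
        )
    return out


def count_haplotypes(
    fragments: Iterable[FragmentObservation], loci: Sequence[int]
) -> HaplotypeCounts:
    """Tally allele strings over fragments covering every locus in ``loci``.

    Conflicted fragments are discarded.  An empty result (no qualifying
    fragment) is returned with ``total=0`` rather than raised, so callers
    can flag the locus set as uncovered.
    """
    loci = tuple(loci)
    if len(loci) == 0:
        raise ValueError("loci must be non-empty")
    if list(loci) != sorted(loci):
        raise ValueError("loci must be sorted")
    tally: Counter[str] = Counter()
    for frag in fragments:
        if frag.conflicted:
            continue
        if all(l in frag.alleles for l in loci):
            tally["".join(frag.alleles[l] for l in loci)] += 1
    return HaplotypeCounts(loci=loci, counts=dict(tally), total=sum(tally.values()))


def haplotype_frequencies(counts: HaplotypeCounts) -> dict[str, float]:
    """Relative haplotype frequencies; requires at least one fragment."""
    if counts.total == 0:
        raise ValueError("no qualifying fragments: frequencies undefined")
    return {h: c / counts.total for h, c in counts.counts.items()}


def marginalize(counts: HaplotypeCounts, keep: Sequence[int]) -> HaplotypeCounts:
    """Collapse counts onto a subset of the loci (same fragment set)."""
    idx = [counts.loci.index(l) for l in keep]
    tally: Counter[str] = Counter()
    for hap, c in counts.counts.items():
        tally["".join(hap[i] for i in idx)] += c
    return HaplotypeCounts(loci=tuple(keep), counts=dict(tally), total=counts.total)


@dataclass
class PairLD:
    """Two-locus LD summary; ``defined`` is False at monomorphic loci."""

    d: float
    r2: float
    defined: bool
    allele_a: str | None = None  # reference allele at locus 1
    allele_b: str | None = None  # reference allele at locus 2


def pair_ld(counts: HaplotypeCounts) -> PairLD:
    """D and r² over two biallelic loci from directly counted haplotypes.

    With haplotype frequency p_AB and marginals p_A, p_B:
    ``D = p_AB − p_A p_B`` and ``r² = D² / (p_A(1−p_A) p_B(1−p_B))``.
    A locus monomorphic among the counted fragments yields an undefined
    (flagged) result, not r² = 0.
    """
    if len(counts.loci) != 2:
        raise ValueError("pair_ld needs counts over exactly 2 loci")
    if counts.total == 0:
        return PairLD(d=math.nan, r2=math.nan, defined=False)
    alleles_1 = sorted({h[0] for h in counts.counts})
    alleles_2 = sorted({h[1] for h in counts.counts})
    if len(alleles_1) != 2 or len(alleles_2) != 2:
        return PairLD(d=math.nan, r2=math.nan, defined=False)
    a, b = alleles_1[0], alleles_2[0]
    freqs = haplotype_frequencies(counts)
    p_ab = sum(f for h, f in freqs.items() if h[0] == a and h[1] == b)
    p_a = sum(f for h, f in freqs.items() if h[0] == a)
    p_b = sum(f for h, f in freqs.items() if h[1] == b)
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return PairLD(d=d, r2=r2, defined=True, allele_a=a, allele_b=b)
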