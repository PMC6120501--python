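"""Reading and writing pooled allele counts in the popoolation2 "sync" format.

A sync file is tab-separated text with one line per genomic site::

    2L      5002    A       10:0:0:0:0:0    8:2:0:0:0:0

i.e. chromosome arm, 1-based position, reference base, then one
colon-separated count field per sequenced pool.  The six counts are, in
fixed order, the depths supporting A, T, C, G, N and a deletion.  All
coordinates in this package are 1-based and fully closed; BED input
(0-based, half-open) is converted at the boundary by the consumers.

Downstream association testing works on a biallelic reduction of each
site: the two bases with the largest summed depth across pools become the
major and minor allele, everything else (including N and deletion depth)
is retained as ``other`` so that filters can reject suspicious
multiallelic sites instead of silently dropping reads.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

#: Fixed order of the six count categories in a sync column.
SYNC_CATEGORIES = ("A", "T", "C", "G", "N", "del")

#: Index of each base within a sync count vector.
BASE_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}

#: Tie-break order for biallelic calling (fixed base order A < C < G < T).
_CALL_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}


class SyncParseError(ValueError):
    """Malformed sync input (bad count field, wrong column count...)."""


class SyncStructureError(ValueError):
    """Structurally inconsistent sync input (sample count varies)."""


class MonomorphicSiteError(ValueError):
    """Fewer than two segregating bases at a site; not testable."""


class UndefinedFrequencyError(ZeroDivisionError):
    """Allele frequency requested over samples with zero biallelic depth."""


@dataclass
class SyncSite:
    """One sync line: per-pool six-category allele depths at one site."""

    chrom: str
    pos: int
    ref: str
    depths: np.ndarray  # shape (n_samples, 6), non-negative ints

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 2 or self.depths.shape[1] != 6:
            raise SyncParseError(
                f"depths must be (n_samples, 6), got {self.depths.shape}"
            )
        if self.pos < 1:
            raise SyncParseError(f"position must be >= 1, got {self.pos}")
        if (self.depths < 0).any():
            raise SyncParseError("negative allele depth")

    @property
    def n_samples(self) -> int:
        return self.depths.shape[0]

    def coverage(self, include_n_del: bool = True) -> np.ndarray:
        """Per-sample coverage.

        By default all six categories count toward coverage; pass
        ``include_n_del=False`` to restrict to the four bases.
        """
        if include_n_del:
            return self.depths.sum(axis=1)
        return self.depths[:, :4].sum(axis=1)


@dataclass
class BiallelicSite:
    """Major/minor reduction of a :class:`SyncSite`.

    ``counts[s] = (major_count, minor_count)`` for sample ``s``; ``other``
    holds each sample's depth outside the two called alleles (third
    alleles, N, deletions).
    """

    chrom: str
    pos: int
    ref: str
    major_allele: str
    minor_allele: str
    counts: np.ndarray  # shape (n_samples, 2)
    other: np.ndarray  # shape (n_samples,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.other = np.asarray(self.other, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def other_count(self) -> int:
        """Total depth in the non-chosen categories across samples."""
        return int(self.other.sum())

    def coverage(self, include_other: bool = True) -> np.ndarray:
        cov = self.counts.sum(axis=1)
        if include_other:
            cov = cov + self.other
        return cov

    def swapped(self) -> "BiallelicSite":
        """Return a copy with major and minor alleles exchanged."""
        return BiallelicSite(
            self.chrom, self.pos, self.ref,
            self.minor_allele, self.major_allele,
            self.counts[:, ::-1].copy(), self.other.copy(),
        )


@dataclass
class SiteMetadata:
    """Read-placement and strand metadata for the two called alleles.

    For each sample and allele: counts of forward/reverse supporting reads
    and the mean distance of the supporting base calls from the nearer
    read end (in bases).
    """

    forward: np.ndarray  # shape (n_samples, 2): fwd reads per (major, minor)
    reverse: np.ndarray  # shape (n_samples, 2)
    mean_end_distance: np.ndarray  # shape (n_samples, 2), NaN where no reads

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=np.int64)
        self.reverse = np.asarray(self.reverse, dtype=np.int64)
        self.mean_end_distance = np.asarray(self.mean_end_distance, dtype=float)

    def pooled_strand_table(self) -> np.ndarray:
        """2x2 table {major, minor} x {forward, reverse} summed over samples."""
        return np.array(
            [
                [self.forward[:, 0].sum(), self.reverse[:, 0].sum()],
                [self.forward[:, 1].sum(), self.reverse[:, 1].sum()],
            ],
            dtype=np.int64,
        )


def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        return source
    path = str(source)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def iter_sync(source) -> Iterator[SyncSite]:
    """Stream :class:`SyncSite` records from a sync file, path or handle.

    Lines starting with ``#`` are skipped.  Raises
    :class:`SyncParseError` naming the offending line on malformed count
    fields and :class:`SyncStructureError` if the number of sample columns
    changes between lines.
    """
    handle = _open_text(source)
    n_samples = None
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise SyncParseError(f"line {lineno}: expected >= 4 columns, got {len(fields)}")
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise SyncParseError(f"line {lineno}: bad position {pos_s!r}") from exc
        depths = np.empty((len(fields) - 3, 6), dtype=np.int64)
        for j, fld in enumerate(fields[3:]):
            parts = fld.split(":")
            if len(parts) != 6:
                raise SyncParseError(
                    f"line {lineno}: count field {fld!r} has {len(parts)} entries, expected 6"
                )
            try:
                depths[j] = [int(p) for p in parts]
            except ValueError as exc:
                raise SyncParseError(f"line {lineno}: non-integer count in {fld!r}") from exc
        if n_samples is None:
            n_samples = depths.shape[0]
        elif depths.shape[0] != n_samples:
            raise SyncStructureError(
                f"line {lineno}: {depths.shape[0]} samples, expected {n_samples}"
            )
        yield SyncSite(chrom=chrom, pos=pos, ref=ref, depths=depths)


def read_sync(source) -> list[SyncSite]:
    """Read a whole sync file into a list of :class:`SyncSite`."""
    return list(iter_sync(source))


def format_sync_site(site: SyncSite) -> str:
    cols = [site.chrom, str(site.pos), site.ref]
    cols.extend(":".join(str(int(c)) for c in row) for row in site.depths)
    return "\t".join(cols)


def write_sync(sites: Iterable[SyncSite], dest) -> None:
    """Write sites in canonical sync text form (inverse of read_sync)."""
    own = not hasattr(dest, "write")
    handle = open(str(dest), "wt") if own else dest
    try:
        for site in sites:
            handle.write(format_sync_site(site) + "\n")
    finally:
        if own:
            handle.close()


def call_biallelic(site: SyncSite) -> BiallelicSite:
    """Reduce a site to its two most frequent bases across samples.

    N and deletion depth never participate in allele calling.  Ties in
    summed depth are broken by the fixed base order A < C < G < T.
    Raises :class:`MonomorphicSiteError` when fewer than two bases
    segregate.
    """
    totals = site.depths[:, :4].sum(axis=0)  # A, T, C, G
    bases = ["A", "T", "C", "G"]
    segregating = [(int(totals[i]), b) for i, b in enumerate(bases) if totals[i] > 0]
    if len(segregating) < 2:
        raise MonomorphicSiteError(
            f"{site.chrom}:{site.pos}: fewer than two segregating bases"
        )
    # sort by descending count, then fixed base order
    segregating.sort(key=lambda t: (-t[0], _CALL_ORDER[t[1]]))
    major, minor = segregating[0][1], segregating[1][1]
    mi, ni = BASE_INDEX[major], BASE_INDEX[minor]
    counts = site.depths[:, [mi, ni]].copy()
    other = site.depths.sum(axis=1) - counts.sum(axis=1)
    return BiallelicSite(
        chrom=site.chrom, pos=site.pos, ref=site.ref,
        major_allele=major, minor_allele=minor,
        counts=counts, other=other,
    )


def allele_frequency(
    site: BiallelicSite, sample_subset: Sequence[int] | None = None
) -> float:
    """Minor-allele frequency over a sample subset using full depths.

    ``minor / (major + minor)`` summed over the subset (all samples when
    ``None``).  Depths are never downsampled here: downsampling exists
    only on the p-value pathway of the association test.
    """
    counts = site.counts if sample_subset is None else site.counts[list(sample_subset)]
    total = counts.sum()
    if total == 0:
        raise UndefinedFrequencyError(
            f"{site.chrom}:{site.pos}: zero biallelic depth in subset"
        )
    return float(counts[:, 1].sum() / total)
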