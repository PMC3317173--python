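"""Per-nucleotide nucleosomal mapping numbers over genomic windows.

Counts how many mapped nucleosomal DNA fragments contribute at every
nucleotide of an interval, then orients the vector so index 0 is the
gene-5′-most position. Two counting conventions are supported:

* ``coverage`` (default): a fragment counts at every position it overlaps.
* ``dyad``: a fragment counts only at its midpoint (the nucleosome dyad
  proxy); even-length fragments tie-break to the lower central position.

Counts are raw integers — no depth normalisation is applied, because the
downstream comparison is rank-based and invariant to positive scaling.
Intervals are half-open: a fragment ending exactly at a position does not
cover it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np

from .genome_model import GenomicInterval

__all__ = [
    "FragmentSet",
    "OccupancyProfile",
    "BedParseError",
    "read_fragments_bed",
    "compute_occupancy",
    "write_profile_bedgraph",
    "filter_by_length",
]

COVERAGE = "coverage"
DYAD = "dyad"


class BedParseError(ValueError):
    """Malformed BED input; message names the offending line."""


@dataclass
class FragmentSet:
    """Mapped fragment intervals (chrom, start, end), 0-based half-open."""

    fragments: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.fragments:
            if end <= start:
                raise ValueError(f"fragment {chrom}:{start}-{end} has length <= 0")

    def __len__(self) -> int:
        return len(self.fragments)

    def by_chrom(self, chrom: str) -> np.ndarray:
        """(n, 2) array of [start, end) pairs on ``chrom`` (possibly empty)."""
        pairs = [(s, e) for c, s, e in self.fragments if c == chrom]
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    @property
    def chroms(self) -> set[str]:
        return {c for c, _, _ in self.fragments}


@dataclass
class OccupancyProfile:
    """Oriented per-nucleotide fragment counts for one gene region.

    ``counts[0]`` is the most 5′ position in gene orientation; for − strand
    genes the genomic vector is reversed on construction.
    """

    gene_id: str
    region_label: str
    counts: np.ndarray
    genomic_interval: GenomicInterval
    mode: str = COVERAGE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if len(self.counts) != len(self.genomic_interval):
            raise ValueError(
                f"counts length {len(self.counts)} != interval length "
                f"{len(self.genomic_interval)}"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genomic_counts(self) -> np.ndarray:
        """Counts in genomic (unoriented, left-to-right) coordinates."""
        if self.genomic_interval.strand == "-":
            return self.counts[::-1]
        return self.counts


def read_fragments_bed(stream: Union[str, IO[str]]) -> FragmentSet:
    """Read BED3+ fragment intervals; extra columns are ignored."""
    close = isinstance(stream, str)
    fh = open(stream, "rt") if close else stream
    frags: list[tuple[str, int, int]] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"line {lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from None
            if start >= end:
                raise BedParseError(
                    f"line {lineno}: start >= end ({start} >= {end})"
                )
            frags.append((chrom, start, end))
    finally:
        if close:
            fh.close()
    return FragmentSet(frags)


def filter_by_length(
    frags: FragmentSet, min_len: int = 120, max_len: int = 180
) -> FragmentSet:
    """Keep fragments with min_len <= length <= max_len (MNase-style filter)."""
    return FragmentSet(
        [(c, s, e) for c, s, e in frags.fragments if min_len <= e - s <= max_len]
    )


def compute_occupancy(
    frags: FragmentSet,
    interval: GenomicInterval,
    mode: str = COVERAGE,
    gene_id: str = "",
) -> OccupancyProfile:
    """Count fragments per nucleotide of ``interval``, oriented 5′→3′.

    An interval on a chromosome absent from the fragment set yields an
    all-zero profile with a warning, not an error.
    """
    if mode not in (COVERAGE, DYAD):
        raise ValueError(f"mode must be 'coverage' or 'dyad', got {mode!r}")
    n = len(interval)
    pairs = frags.by_chrom(interval.chrom)
    if len(frags) > 0 and pairs.shape[0] == 0:
        warnings.warn(
            f"no fragments on chromosome {interval.chrom!r}; profile is all zeros",
            stacklevel=2,
        )
    if mode == COVERAGE:
        counts = _coverage_counts(pairs, interval.start, n)
    else:
        counts = _dyad_counts(pairs, interval.start, n)
    if interval.strand == "-":
        counts = counts[::-1]
    return OccupancyProfile(gene_id, interval.label, counts, interval, mode)


def _coverage_counts(pairs: np.ndarray, origin: int, n: int) -> np.ndarray:
    diff = np.zeros(n + 1, dtype=np.int64)
    if pairs.shape[0]:
        lo = np.clip(pairs[:, 0] - origin, 0, n)
        hi = np.clip(pairs[:, 1] - origin, 0, n)
        keep = lo < hi
        np.add.at(diff, lo[keep], 1)
        np.add.at(diff, hi[keep], -1)
    return np.cumsum(diff[:-1])


def _dyad_counts(pairs: np.ndarray, origin: int, n: int) -> np.ndarray:
    counts = np.zeros(n, dtype=np.int64)
    if pairs.shape[0]:
        lengths = pairs[:, 1] - pairs[:, 0]
        mids = pairs[:, 0] + (lengths - 1) // 2 - origin
        keep = (mids >= 0) & (mids < n)
        np.add.at(counts, mids[keep], 1)
    return counts


def write_profile_bedgraph(profile: OccupancyProfile, stream: IO[str]) -> None:
    """Write the profile as bedGraph in genomic (unoriented) coordinates.

    Runs of equal counts are merged into single lines.
    """
    counts = profile.genomic_counts
    iv = profile.genomic_interval
    run_start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i] != counts[run_start]:
            stream.write(
                f"{iv.chrom}\t{iv.start + run_start}\t{iv.start + i}\t{counts[run_start]}\n"
            )
            run_start = i
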