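"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nucdup.genome_model import GeneModel, GenomicInterval
from nucdup.occupancy import FragmentSet


def brute_force_coverage(frags: FragmentSet, interval: GenomicInterval) -> np.ndarray:
    """Position-by-position, fragment-by-fragment overlap count (genomic order)."""
    counts = np.zeros(len(interval), dtype=np.int64)
    for i in range(len(interval)):
        pos = interval.start + i
        for chrom, s, e in frags.fragments:
            if chrom == interval.chrom and s <= pos < e:
                counts[i] += 1
    return counts


def brute_force_dyad(frags: FragmentSet, interval: GenomicInterval) -> np.ndarray:
    """Midpoint-per-fragment count (lower-central tie-break), genomic order."""
    counts = np.zeros(len(interval), dtype=np.int64)
    for chrom, s, e in frags.fragments:
        if chrom != interval.chrom:
            continue
        mid = s + (e - s - 1) // 2
        if interval.start <= mid < interval.end:
            counts[mid - interval.start] += 1
    return counts


def mirror_gene(gene: GeneModel, pivot: int) -> GeneModel:
    """Reflect a gene about ``pivot`` and flip its strand."""
    return GeneModel(
        gene.gene_id,
        gene.chrom,
        "-" if gene.strand == "+" else "+",
        pivot - gene.end,
        pivot - gene.start,
        gene.species,
    )


def mirror_fragments(frags: FragmentSet, pivot: int) -> FragmentSet:
    return FragmentSet([(c, pivot - e, pivot - s) for c, s, e in frags.fragments])


@pytest.fixture
def toy_fragments() -> FragmentSet:
    """The two-fragment landscape used by the worked occupancy example."""
    return FragmentSet([("c", 0, 5), ("c", 3, 8)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260917)
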