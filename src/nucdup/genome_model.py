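"""Gene coordinate model and strand-aware promoter / coding window extraction.

A gene is stored with 0-based half-open genomic coordinates (``start`` is the
lower genomic coordinate regardless of strand). The *translational start* is
``start`` on the + strand and ``end - 1`` on the − strand; the promoter is the
``upstream_len`` bases immediately 5′ of it in gene orientation, and the
coding window is the full genomic span between translational start and end.
Introns, if any, are not excised from the coding window (a warning is emitted
when a caller asks for splice-aware behaviour this module does not provide).

Annotation input is 1-based inclusive (GFF3 or a 5/6-column TSV) and converted
on read, matching the BED convention of the fragment data used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Union

__all__ = [
    "GeneModel",
    "GenomicInterval",
    "EmptyRegionError",
    "GeneTableParseError",
    "read_gene_table",
    "promoter_interval",
    "coding_interval",
]

PROMOTER = "promoter"
CODING = "coding"


class GeneTableParseError(ValueError):
    """Malformed annotation input; message names the offending line."""


class EmptyRegionError(ValueError):
    """A requested region is empty after boundary truncation."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: identifiers, locus and strand.

    ``start``/``end`` are 0-based half-open with ``start < end``; on the
    − strand the translational start corresponds to ``end - 1``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    species: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def translational_start(self) -> int:
        """Genomic coordinate (0-based) of the first coding base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic window with a gene-region label."""

    chrom: str
    start: int
    end: int
    strand: str
    label: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def _coerce_stream(stream: Union[str, IO[str]]) -> IO[str]:
    if isinstance(stream, str):
        return open(stream, "rt")
    return stream


def _parse_tsv(lines: Iterable[str]) -> list[GeneModel]:
    genes = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise GeneTableParseError(
                f"line {lineno}: expected >= 5 tab-separated columns, got {len(fields)}"
            )
        gene_id, chrom, strand, start_s, end_s = (f.strip() for f in fields[:5])
        species = fields[5].strip() if len(fields) > 5 else ""
        # optional header row: skip if coordinates are not integers on line 1
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            if lineno == 1:
                continue
            raise GeneTableParseError(
                f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
            ) from None
        start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if end0 <= start0:
            raise GeneTableParseError(
                f"line {lineno}: gene {gene_id!r} has end <= start after normalization"
            )
        try:
            genes.append(GeneModel(gene_id, chrom, strand, start0, end0, species))
        except ValueError as exc:
            raise GeneTableParseError(f"line {lineno}: {exc}") from exc
    return genes


def _parse_gff3(text: str, id_attr: str) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GeneTableParseError(f"GFF3 parse failed: {exc}") from exc

    features = list(db.features_of_type("gene"))
    if not features:
        features = list(db.features_of_type("CDS"))
    genes = []
    for feat in features:
        if id_attr not in feat.attributes:
            raise GeneTableParseError(
                f"GFF3 feature at {feat.seqid}:{feat.start} lacks attribute {id_attr!r}"
            )
        gene_id = feat.attributes[id_attr][0]
        start0, end0 = feat.start - 1, feat.end
        if end0 <= start0:
            raise GeneTableParseError(
                f"gene {gene_id!r}: end <= start after normalization"
            )
        if feat.featuretype == "gene":
            cds_parts = list(db.children(feat, featuretype="CDS"))
            if len(cds_parts) > 1:
                warnings.warn(
                    f"gene {gene_id!r} has {len(cds_parts)} CDS segments; the coding "
                    "window is the full genomic span and includes introns",
                    stacklevel=3,
                )
        genes.append(GeneModel(gene_id, feat.seqid, feat.strand, start0, end0))
    return genes


def read_gene_table(
    stream: Union[str, IO[str]],
    format: str = "tsv",
    id_attr: str = "ID",
) -> list[GeneModel]:
    """Read gene models from a TSV or GFF3 source (path or open text stream).

    TSV columns: gene_id, chrom, strand, start, end[, species], 1-based
    inclusive coordinates, optional header. GFF3 uses ``gene`` features
    (falling back to ``CDS``) with the gene identifier in ``id_attr``.
    """
    fh = _coerce_stream(stream)
    try:
        if format == "tsv":
            return _parse_tsv(fh)
        if format == "gff3":
            return _parse_gff3(fh.read(), id_attr)
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'gff3'")
    finally:
        if isinstance(stream, str):
            fh.close()


def promoter_interval(
    gene: GeneModel,
    upstream_len: int = 1000,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """The ``upstream_len`` bases 5′ of the translational start, gene-oriented.

    Windows running past coordinate 0 (or ``chrom_length``, when known) are
    kept as partial windows with ``truncated=True``; a window that vanishes
    entirely raises :class:`EmptyRegionError`.
    """
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    if gene.strand == "+":
        lo, hi = gene.start - upstream_len, gene.start
    else:
        lo, hi = gene.end, gene.end + upstream_len
    truncated = False
    if lo < 0:
        lo, truncated = 0, True
    if chrom_length is not None and hi > chrom_length:
        hi, truncated = chrom_length, True
    if hi <= lo:
        raise EmptyRegionError(
            f"promoter of {gene.gene_id!r} is empty after truncation at the sequence boundary"
        )
    return GenomicInterval(gene.chrom, lo, hi, gene.strand, PROMOTER, truncated)


def coding_interval(gene: GeneModel) -> GenomicInterval:
    """Full genomic span from translational start to end (introns included)."""
    return GenomicInterval(gene.chrom, gene.start, gene.end, gene.strand, CODING)
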