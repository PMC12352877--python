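"""Gene-annotation parsing and TSS-window geometry.

Every gene is represented by a single transcription start site (TSS) and
analysed through a fixed window of ``half_width`` bases on each side of it
(default ±2.5 kb), divided into ``n_bins`` bins of ``bin_width`` bases
(default 50 bins of 100 bp).

Coordinate conventions are 0-based half-open throughout, matching BAM/BED
semantics.  For a "+" strand gene the TSS is the annotated feature start;
for a "−" strand gene it is ``end − 1``, the last covered base.  Window bins
are gene-oriented by default: on the "−" strand the bin order is reversed so
that bin indices always run 5'→3' of the gene and the TSS-proximal bin is
bin ``n_bins // 2`` on both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

#: Canonical epigenetic feature order used for tensors and design matrices.
CANONICAL_FEATURES: tuple[str, ...] = ("H3K27Ac", "RNAPII", "ATAC", "CTCF")


class AnnotationParseError(ValueError):
    """Raised for a malformed annotation line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its TSS anchor.

    Parameters
    ----------
    gene_id : str
        Unique identifier within one annotation parse.
    chrom : str
        Chromosome name.
    tss : int
        0-based genomic coordinate of the transcription start site.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"TSS must be >= 0, got {self.tss} for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class BinSpec:
    """Window geometry: ``half_width`` bases either side of the TSS, cut into
    bins of ``bin_width`` bases.  The division must be exact."""

    half_width: int = 2500
    bin_width: int = 100

    def __post_init__(self) -> None:
        for name in ("half_width", "bin_width"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if (2 * self.half_width) % self.bin_width != 0:
            raise ValueError(
                f"window of {2 * self.half_width} bases is not an exact multiple "
                f"of bin_width={self.bin_width}"
            )

    @property
    def n_bins(self) -> int:
        return (2 * self.half_width) // self.bin_width

    @property
    def window_length(self) -> int:
        return 2 * self.half_width


@dataclass(frozen=True)
class Window:
    """A TSS-centred genomic interval, 0-based half-open.

    ``oriented=True`` means bin vectors extracted over this window are ordered
    5'→3' of the owning gene (reversed for "−" strand genes).
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    oriented: bool = True

    @property
    def clipped(self) -> bool:
        """True when the window extends past the chromosome start; the
        out-of-range bases contribute zero counts rather than dropping the gene."""
        return self.start < 0


def make_window(gene: GeneRecord, spec: BinSpec | None = None, oriented: bool = True) -> Window:
    """Build the ±``half_width`` window around a gene's TSS.

    The window spans ``[tss − half_width, tss + half_width)``.  Windows
    extending past the chromosome start are kept (``Window.clipped``);
    out-of-range bases contribute zero counts downstream.
    """
    spec = spec or BinSpec()
    return Window(
        chrom=gene.chrom,
        start=gene.tss - spec.half_width,
        end=gene.tss + spec.half_width,
        strand=gene.strand,
        oriented=oriented,
    )


def _iter_lines(stream: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, str):
        yield from stream.splitlines()
    else:
        for line in stream:
            yield line.rstrip("\n")


def _parse_bed_line(fields: list[str], lineno: int) -> GeneRecord:
    if len(fields) < 4:
        raise AnnotationParseError(f"BED line has only {len(fields)} fields", lineno)
    chrom, start_s, end_s, name = fields[:4]
    strand = fields[5] if len(fields) >= 6 else "."
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise AnnotationParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
    if end <= start:
        raise AnnotationParseError(f"end ({end}) must exceed start ({start})", lineno)
    tss = start if strand == "+" else end - 1
    return GeneRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand)


def _parse_gtf_line(line: str, lineno: int) -> GeneRecord | None:
    """Parse one GTF line via gffutils; returns None for non-gene features."""
    from gffutils.feature import feature_from_line

    try:
        feat = feature_from_line(line)
    except Exception as exc:  # gffutils raises assorted exceptions on bad lines
        raise AnnotationParseError(f"malformed GTF line ({exc})", lineno)
    if feat.featuretype != "gene":
        return None
    if feat.strand not in ("+", "-"):
        logger.warning("line %d: gene without strand rejected", lineno)
        return None
    gene_ids = feat.attributes.get("gene_id")
    if not gene_ids:
        raise AnnotationParseError("gene feature lacks a gene_id attribute", lineno)
    # GTF is 1-based inclusive: 0-based start = start − 1, last base = end − 1.
    tss = feat.start - 1 if feat.strand == "+" else feat.end - 1
    return GeneRecord(gene_id=gene_ids[0], chrom=feat.seqid, tss=tss, strand=feat.strand)


def parse_gene_annotation(
    stream: str | IO[str] | Iterable[str], dialect: str = "bed"
) -> list[GeneRecord]:
    """Parse a gene annotation into one :class:`GeneRecord` per distinct gene.

    Parameters
    ----------
    stream : str, file object or iterable of lines
        Annotation text.
    dialect : {"bed", "gtf"}
        BED6/BED12 (strand in column 6) or GTF (features of type ``gene`` with
        a ``gene_id`` attribute).

    Duplicate gene_ids keep the first record seen and log a warning; records
    without a usable strand are rejected with a warning.
    """
    dialect = dialect.lower()
    if dialect not in ("bed", "gtf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    records: dict[str, GeneRecord] = {}
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if dialect == "bed":
            fields = line.split()
            if len(fields) < 6 or fields[5] not in ("+", "-"):
                logger.warning("line %d: record without strand rejected", lineno)
                if len(fields) < 4:
                    _parse_bed_line(fields, lineno)  # raises AnnotationParseError
                continue
            rec = _parse_bed_line(fields, lineno)
        else:
            rec = _parse_gtf_line(raw, lineno)
            if rec is None:
                continue
        if rec.gene_id in records:
            logger.warning(
                "duplicate gene_id %s at line %d; keeping first record", rec.gene_id, lineno
            )
            continue
        records[rec.gene_id] = rec
    return list(records.values())
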