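"""Gene annotation handling: isoform parsing, union-of-isoform gene models,
and genomic <-> transcript coordinate mapping.

All internal coordinates are 0-based, half-open and strand-aware.  GTF input
(1-based, closed) is converted on read; BED12 is already in this convention.
To avoid multiple counting across isoforms, each gene is reduced to a single
union model whose exons (and CDS) are the interval union of all of its
isoforms, and transcript coordinates run 5'->3' along the spliced exon union.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for malformed annotation input; names the offending line."""


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Sort and merge possibly-overlapping half-open intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if b <= a:
            raise ValueError(f"empty or inverted interval [{a},{b})")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class IsoformModel:
    """One transcript isoform: exon intervals plus an optional CDS span."""

    gene_id: str
    transcript_id: str
    reference: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Optional[Interval] = None

    def __post_init__(self):
        object.__setattr__(self, "exons", merge_intervals(self.exons))
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if any(a < 0 for a, _ in self.exons):
            raise ValueError("negative exon coordinate")

    def cds_intervals(self) -> tuple[Interval, ...]:
        """CDS span intersected with the exons (empty if no CDS)."""
        if self.cds is None:
            return ()
        lo, hi = self.cds
        out = []
        for a, b in self.exons:
            s, e = max(a, lo), min(b, hi)
            if s < e:
                out.append((s, e))
        return tuple(out)


@dataclass(frozen=True)
class UnionGeneModel:
    """Union-of-isoforms annotation for one gene.

    ``exon_union`` / ``cds_union`` are sorted disjoint genomic intervals;
    transcript coordinates index the spliced exon union in 5'->3' gene
    orientation (reversed along the genome for '-' strand genes).
    """

    gene_id: str
    reference: str
    strand: str
    exon_union: tuple[Interval, ...]
    cds_union: tuple[Interval, ...]

    @property
    def transcript_length(self) -> int:
        return sum(b - a for a, b in self.exon_union)

    @property
    def cds_start_tx(self) -> int:
        """Transcript coordinate of the first CDS nucleotide."""
        if not self.cds_union:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        if self.strand == "+":
            g = self.cds_union[0][0]
        else:
            g = self.cds_union[-1][1] - 1
        t = genomic_to_transcript(g, self)
        assert t is not None
        return t

    @property
    def cds_end_tx(self) -> int:
        """Transcript coordinate one past the last CDS nucleotide."""
        if not self.cds_union:
            raise ValueError(f"gene {self.gene_id} has no CDS")
        if self.strand == "+":
            g = self.cds_union[-1][1] - 1
        else:
            g = self.cds_union[0][0]
        t = genomic_to_transcript(g, self)
        assert t is not None
        return t + 1

    @property
    def utr5_length(self) -> int:
        return self.cds_start_tx

    @property
    def utr3_length(self) -> int:
        return self.transcript_length - self.cds_end_tx

    # cached exon offsets for coordinate mapping
    def _offsets(self) -> tuple[list[int], list[int]]:
        starts = [a for a, _ in self.exon_union]
        cum = [0]
        for a, b in self.exon_union:
            cum.append(cum[-1] + (b - a))
        return starts, cum


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _read_gtf(lines: Iterable[str]) -> Iterator[IsoformModel]:
    exons: dict[str, dict] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: expected 9 fields, got {len(fields)}"
            )
        ref, _source, feature, start, end, _score, strand, _frame, attr_field = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start_i = int(start) - 1  # GTF is 1-based closed
            end_i = int(end)
        except ValueError:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: non-integer coordinates"
            ) from None
        if strand not in ("+", "-"):
            raise AnnotationError(f"GTF parse error at line {lineno}: bad strand {strand!r}")
        attrs = _parse_gtf_attributes(attr_field)
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise AnnotationError(
                f"GTF parse error at line {lineno}: missing gene_id/transcript_id"
            )
        tid = attrs["transcript_id"]
        rec = exons.setdefault(
            tid,
            {"gene_id": attrs["gene_id"], "reference": ref, "strand": strand,
             "exons": [], "cds": None},
        )
        if feature == "exon":
            rec["exons"].append((start_i, end_i))
        else:
            lo, hi = rec["cds"] if rec["cds"] else (start_i, end_i)
            rec["cds"] = (min(lo, start_i), max(hi, end_i))
    for tid, rec in exons.items():
        yield IsoformModel(
            gene_id=rec["gene_id"], transcript_id=tid, reference=rec["reference"],
            strand=rec["strand"], exons=tuple(rec["exons"]), cds=rec["cds"],
        )


def _read_bed12(lines: Iterable[str]) -> Iterator[IsoformModel]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise AnnotationError(
                f"BED12 parse error at line {lineno}: expected 12 fields, got {len(fields)}"
            )
        try:
            chrom = fields[0]
            chrom_start = int(fields[1])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError:
            raise AnnotationError(
                f"BED12 parse error at line {lineno}: non-integer field"
            ) from None
        if len(sizes) != block_count or len(starts) != block_count:
            raise AnnotationError(
                f"BED12 parse error at line {lineno}: block count mismatch"
            )
        exons = tuple(
            (chrom_start + s, chrom_start + s + size) for s, size in zip(starts, sizes)
        )
        # BED name is treated as both gene and transcript id unless suffixed
        gene_id = name.split("|")[0]
        cds = (thick_start, thick_end) if thick_end > thick_start else None
        yield IsoformModel(
            gene_id=gene_id, transcript_id=name, reference=chrom,
            strand=strand, exons=exons, cds=cds,
        )


def load_gene_models(stream, fmt: Optional[str] = None) -> list[IsoformModel]:
    """Parse GTF or BED12 text into isoform models (internal 0-based half-open).

    ``stream`` is an iterable of lines (open file or list).  ``fmt`` is
    ``"gtf"``, ``"bed12"`` or None to sniff from the first data line.
    Isoforms whose CDS lies outside their exon union are rejected and logged.
    """
    lines = list(stream)
    if fmt is None:
        fmt = "gtf"
        for line in lines:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            nfields = len(line.rstrip("\n").split("\t"))
            fmt = "bed12" if nfields >= 12 else "gtf"
            break
    reader = _read_gtf if fmt == "gtf" else _read_bed12
    models = []
    for iso in reader(lines):
        if iso.cds is not None and not iso.cds_intervals():
            logger.warning(
                "isoform %s rejected: CDS %s outside exon union", iso.transcript_id, iso.cds
            )
            continue
        models.append(iso)
    return models


def union_isoforms(isoforms: Sequence[IsoformModel]) -> dict[str, UnionGeneModel]:
    """Collapse isoforms into one union model per gene.

    Genes whose isoforms disagree on reference or strand are dropped (logged),
    not merged, since merging would corrupt coordinates.
    """
    by_gene: dict[str, list[IsoformModel]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    out: dict[str, UnionGeneModel] = {}
    for gene_id, isos in by_gene.items():
        refs = {i.reference for i in isos}
        strands = {i.strand for i in isos}
        if len(refs) > 1 or len(strands) > 1:
            logger.warning(
                "gene %s dropped: isoforms disagree on reference/strand", gene_id
            )
            continue
        exon_union = merge_intervals(iv for i in isos for iv in i.exons)
        cds_ivs = [iv for i in isos for iv in i.cds_intervals()]
        cds_union = merge_intervals(cds_ivs) if cds_ivs else ()
        out[gene_id] = UnionGeneModel(
            gene_id=gene_id, reference=isos[0].reference, strand=isos[0].strand,
            exon_union=exon_union, cds_union=cds_union,
        )
    return out


def genomic_to_transcript(pos: int, model: UnionGeneModel) -> Optional[int]:
    """Map a genomic coordinate onto the spliced transcript (None if intronic)."""
    if pos < 0:
        raise ValueError("genomic position must be >= 0")
    starts, cum = model._offsets()
    i = bisect.bisect_right(starts, pos) - 1
    if i < 0:
        return None
    a, b = model.exon_union[i]
    if pos >= b:
        return None
    t = cum[i] + (pos - a)
    if model.strand == "-":
        t = model.transcript_length - 1 - t
    return t


def transcript_to_genomic(t: int, model: UnionGeneModel) -> int:
    """Inverse of :func:`genomic_to_transcript` for in-range coordinates."""
    length = model.transcript_length
    if not 0 <= t < length:
        raise ValueError(f"transcript coordinate {t} outside [0,{length})")
    if model.strand == "-":
        t = length - 1 - t
    starts, cum = model._offsets()
    i = bisect.bisect_right(cum, t) - 1
    a, _b = model.exon_union[i]
    return a + (t - cum[i])


def write_bed12(models: Iterable[UnionGeneModel], handle) -> None:
    """Write union models as BED12, one record per gene (blocks = exon union)."""
    for m in models:
        start = m.exon_union[0][0]
        end = m.exon_union[-1][1]
        thick = (m.cds_union[0][0], m.cds_union[-1][1]) if m.cds_union else (start, start)
        sizes = ",".join(str(b - a) for a, b in m.exon_union)
        rel = ",".join(str(a - start) for a, _ in m.exon_union)
        handle.write(
            "\t".join(
                [m.reference, str(start), str(end), m.gene_id, "0", m.strand,
                 str(thick[0]), str(thick[1]), "0", str(len(m.exon_union)), sizes, rel]
            )
            + "\n"
        )
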