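"""Transcript/gene models and overlap-based feature annotation.

Gene models are read from GTF (1-based inclusive on disk) and held internally
in 0-based half-open coordinates; the conversion happens only at I/O.  Exon and
junction quantification rows are identified by locus-encoded feature IDs
(``chr7:6414154-6414183:+`` for an exon, ``chr7:6414153:+,chr7:6414880:+`` for
a junction's donor/acceptor anchors) and are assigned to every transcript
isoform whose genomic span they overlap.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

STRAND_UNKNOWN = "."
_VALID_STRANDS = {"+", "-", STRAND_UNKNOWN}


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class FeatureIDError(ValueError):
    """A feature ID string does not match the documented grammar."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str = STRAND_UNKNOWN

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(_VALID_STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 bp of shared sequence on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def strands_compatible(self, other: "GenomicInterval") -> bool:
        """Unknown strand matches either; known-vs-known must agree."""
        if STRAND_UNKNOWN in (self.strand, other.strand):
            return True
        return self.strand == other.strand


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                f"chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    f"unsorted at {a}..{b}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        """First-exon start to last-exon end (the transcript's genomic range)."""
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    transcripts: tuple[TranscriptModel, ...]
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise ValueError(
                    f"transcript {t.transcript_id} references gene "
                    f"{t.gene_id!r}, not {self.gene_id!r}"
                )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        strands = {t.strand for t in self.transcripts}
        strand = strands.pop() if len(strands) == 1 else STRAND_UNKNOWN
        return GenomicInterval(self.chrom, start, end, strand)

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class FeatureAnnotation:
    feature_id: str
    kind: str  # "exon" | "junction"
    interval: GenomicInterval
    gene_id: str | None
    transcript_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.gene_id is None and self.transcript_ids:
            raise ValueError("unassigned feature cannot list transcripts")


# ---------------------------------------------------------------------------
# GTF I/O


def _parse_gtf_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GTFParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    try:
        int(fields[3]), int(fields[4])
    except ValueError:
        raise GTFParseError(
            f"line {lineno}: start/end columns must be integers "
            f"({fields[3]!r}, {fields[4]!r})"
        ) from None
    try:
        return feature_from_line(line, dialect=None)
    except Exception as exc:  # gffutils raises assorted types
        raise GTFParseError(f"line {lineno}: {exc}") from exc


def read_gene_models(gtf_path) -> list[GeneModel]:
    """Parse a GTF file into gene models.

    Only ``exon`` features are used to build transcript structure; a
    ``transcript`` line with no exon lines is skipped with a warning.  GTF
    coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention.  Book-ended or duplicated exons within a transcript
    are merged.  Output is sorted by gene_id then transcript_id.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_symbol: dict[str, str] = {}
    gene_aliases: dict[str, tuple[str, ...]] = {}
    declared_tx: dict[str, str] = {}  # transcript lines seen, even exon-less

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            feat = _parse_gtf_line(line, lineno)
            attrs = feat.attributes
            gid = (attrs.get("gene_id") or [None])[0]
            if gid is None:
                raise GTFParseError(f"line {lineno}: missing gene_id attribute")
            if "gene_name" in attrs:
                gene_symbol.setdefault(gid, attrs["gene_name"][0])
            if "gene_alias" in attrs:
                gene_aliases.setdefault(
                    gid, tuple(a for a in attrs["gene_alias"][0].split(",") if a)
                )
            if feat.featuretype == "transcript":
                tid = (attrs.get("transcript_id") or [None])[0]
                if tid is not None:
                    declared_tx.setdefault(tid, gid)
                continue
            if feat.featuretype != "exon":
                continue
            tid = (attrs.get("transcript_id") or [None])[0]
            if tid is None:
                raise GTFParseError(f"line {lineno}: exon missing transcript_id")
            if tid in tx_gene and tx_gene[tid] != gid:
                raise GTFParseError(
                    f"line {lineno}: transcript {tid!r} already assigned to "
                    f"gene {tx_gene[tid]!r}"
                )
            tx_gene[tid] = gid
            strand = feat.strand if feat.strand in _VALID_STRANDS else STRAND_UNKNOWN
            exons_by_tx.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            )

    for tid, gid in declared_tx.items():
        if tid not in exons_by_tx:
            warnings.warn(
                f"transcript {tid} of gene {gid} has zero exons; skipped",
                stacklevel=2,
            )

    transcripts_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid in sorted(exons_by_tx):
        exons = _merge_bookended(sorted(exons_by_tx[tid]))
        tx = TranscriptModel(tid, tx_gene[tid], tuple(exons))
        transcripts_by_gene.setdefault(tx_gene[tid], []).append(tx)

    genes = []
    for gid in sorted(transcripts_by_gene):
        txs = sorted(transcripts_by_gene[gid], key=lambda t: t.transcript_id)
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=gene_symbol.get(gid, gid),
                transcripts=tuple(txs),
                aliases=gene_aliases.get(gid, ()),
            )
        )
    return genes


def _merge_bookended(exons: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge duplicate or book-ended (abutting) exons; error on true overlap."""
    merged: list[GenomicInterval] = []
    for ex in exons:
        if merged and ex.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, ex.end), prev.strand
            )
        else:
            merged.append(ex)
    return merged


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write models back to the GTF dialect read_gene_models consumes."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for ex in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    if gene.aliases:
                        attrs += f' gene_alias "{",".join(gene.aliases)}";'
                    fh.write(
                        "\t".join(
                            [
                                ex.chrom,
                                "splicevis",
                                "exon",
                                str(ex.start + 1),
                                str(ex.end),
                                ".",
                                ex.strand if ex.strand != STRAND_UNKNOWN else ".",
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def to_bed12(genes: list[GeneModel]) -> str:
    """One BED12 line per transcript, for inspection in a genome browser."""
    lines = []
    for gene in genes:
        for tx in gene.transcripts:
            span = tx.span
            sizes = ",".join(str(e.length) for e in tx.exons) + ","
            starts = ",".join(str(e.start - span.start) for e in tx.exons) + ","
            lines.append(
                "\t".join(
                    [
                        span.chrom,
                        str(span.start),
                        str(span.end),
                        tx.transcript_id,
                        "0",
                        span.strand if span.strand != STRAND_UNKNOWN else ".",
                        str(span.start),
                        str(span.end),
                        "0",
                        str(len(tx.exons)),
                        sizes,
                        starts,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Feature-ID grammar

_EXON_ID = re.compile(r"^([^:\s]+):(\d+)-(\d+):([+\-.])$")
_ANCHOR = re.compile(r"^([^:\s]+):(\d+):([+\-.])$")

_GRAMMAR = (
    "exon: 'chrom:start-end:strand'; "
    "junction: 'chrom:pos:strand,chrom:pos:strand' "
    "(coordinates 1-based inclusive; strand one of + - .)"
)


def parse_feature_id(feature_id: str) -> tuple[str, tuple[GenomicInterval, ...]]:
    """Decode a locus-encoded feature ID.

    Returns ``("exon", (interval,))`` or ``("junction", (donor, acceptor))``
    where junction anchors are single-base intervals.  IDs are 1-based
    inclusive; returned intervals are 0-based half-open.
    """
    if "," in feature_id:
        parts = feature_id.split(",")
        if len(parts) != 2:
            raise FeatureIDError(
                f"cannot parse {feature_id!r}; expected grammar: {_GRAMMAR}"
            )
        anchors = []
        for part in parts:
            m = _ANCHOR.match(part)
            if not m:
                raise FeatureIDError(
                    f"cannot parse {feature_id!r}; expected grammar: {_GRAMMAR}"
                )
            chrom, pos, strand = m.group(1), int(m.group(2)), m.group(3)
            anchors.append(GenomicInterval(chrom, pos - 1, pos, strand))
        return "junction", tuple(anchors)
    m = _EXON_ID.match(feature_id)
    if not m:
        raise FeatureIDError(
            f"cannot parse {feature_id!r}; expected grammar: {_GRAMMAR}"
        )
    chrom, start, end, strand = (
        m.group(1),
        int(m.group(2)),
        int(m.group(3)),
        m.group(4),
    )
    if end < start:
        raise FeatureIDError(f"{feature_id!r}: end precedes start")
    return "exon", (GenomicInterval(chrom, start - 1, end, strand),)


def feature_interval(kind: str, parts: tuple[GenomicInterval, ...]) -> GenomicInterval:
    """The single interval recorded for a feature (junction: donor..acceptor)."""
    if kind == "exon":
        return parts[0]
    lo = min(p.start for p in parts)
    hi = max(p.end for p in parts)
    return GenomicInterval(parts[0].chrom, lo, hi, parts[0].strand)


# ---------------------------------------------------------------------------
# Overlap annotation


def annotate_features(
    features: list[tuple[str, str, tuple[GenomicInterval, ...]]],
    gene: GeneModel,
) -> list[FeatureAnnotation]:
    """Assign exon/junction features to a gene's transcript isoforms.

    An exon feature is assigned to every transcript whose span it overlaps by
    at least one base; a junction is assigned to every transcript whose span
    contains both anchors.  Strand must be compatible (unknown matches
    anything).  Output order matches input order; a feature matching no
    transcript gets ``gene_id=None``.
    """
    tree = IntervalTree()
    for idx, tx in enumerate(gene.transcripts):
        span = tx.span
        tree.addi(span.start, span.end, idx)

    out = []
    for feature_id, kind, parts in features:
        interval = feature_interval(kind, parts)
        hits: set[int] = set()
        if interval.chrom == gene.chrom:
            if kind == "exon":
                candidates = {iv.data for iv in tree.overlap(interval.start, interval.end)}
            else:
                per_anchor = [
                    {iv.data for iv in tree.overlap(a.start, a.end)} for a in parts
                ]
                candidates = set.intersection(*per_anchor) if per_anchor else set()
            for idx in candidates:
                tx = gene.transcripts[idx]
                if not tx.span.strands_compatible(interval):
                    continue
                if kind == "junction" and not all(
                    tx.span.contains(a) for a in parts
                ):
                    continue
                hits.add(idx)
        tx_ids = tuple(
            gene.transcripts[i].transcript_id for i in sorted(hits)
        )
        out.append(
            FeatureAnnotation(
                feature_id=feature_id,
                kind=kind,
                interval=interval,
                gene_id=gene.gene_id if tx_ids else None,
                transcript_ids=tx_ids,
            )
        )
    return out


def resolve_gene(genes: list[GeneModel], query: str) -> GeneModel:
    """Resolve a gene by symbol, numeric ID or alias.

    Precedence: exact symbol (case-insensitive) > exact gene_id > unique
    alias.  An alias shared by several genes is an error listing candidates;
    an unknown query is an error listing the nearest symbols.
    """
    q = query.strip()
    ql = q.lower()
    by_symbol = [g for g in genes if g.symbol.lower() == ql]
    if len(by_symbol) == 1:
        return by_symbol[0]
    if len(by_symbol) > 1:
        raise KeyError(
            f"symbol {query!r} matches several genes: "
            + ", ".join(g.gene_id for g in by_symbol)
        )
    by_id = [g for g in genes if g.gene_id == q]
    if by_id:
        return by_id[0]
    by_alias = [g for g in genes if ql in (a.lower() for a in g.aliases)]
    if len(by_alias) == 1:
        return by_alias[0]
    if len(by_alias) > 1:
        raise KeyError(
            f"alias {query!r} is ambiguous; candidates: "
            + ", ".join(f"{g.symbol} ({g.gene_id})" for g in by_alias)
        )
    nearest = sorted(
        (g.symbol for g in genes),
        key=lambda s: (0 if s.lower().startswith(ql[:3]) else 1, s),
    )[:5]
    raise KeyError(
        f"unknown gene {query!r}; nearest symbols: " + ", ".join(nearest)
    )
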