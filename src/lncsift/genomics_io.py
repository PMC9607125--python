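"""Genomic domain types, GTF/BED/broadPeak I/O, and strand-aware interval primitives.

All coordinates are internally 0-based half-open; conversion happens only at
the GTF boundary (GTF is 1-based closed, BED/broadPeak are already 0-based
half-open). All readers transparently handle gzip-compressed files.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .errors import ConfigurationError, IntegrityError, ParseError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Normalization of annotation biotype vocabulary (GENCODE-style) into the
#: coarse classes the filtering cascade distinguishes. Unlisted biotypes map
#: to ``other_ncRNA`` with a logged warning; callers may extend the table.
BIOTYPE_MAP = {
    "protein_coding": "protein_coding",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "transcribed_unitary_pseudogene": "pseudogene",
    "translated_processed_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "IG_pseudogene": "pseudogene",
    "IG_C_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    "TR_V_pseudogene": "pseudogene",
    "rRNA_pseudogene": "pseudogene",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
    "snoRNA": "snoRNA",
    "rRNA": "rRNA",
    "Mt_rRNA": "rRNA",
    "tRNA": "tRNA",
    "Mt_tRNA": "tRNA",
    "miRNA": "miRNA",
}

BIOTYPE_VOCABULARY = (
    "protein_coding",
    "pseudogene",
    "lncRNA",
    "snoRNA",
    "rRNA",
    "tRNA",
    "miRNA",
    "other_ncRNA",
)

#: Attribute keys tried, in order, when looking for a biotype in a GTF record.
BIOTYPE_ATTR_KEYS = ("gene_biotype", "gene_type", "biotype", "transcript_type")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise IntegrityError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap_bp(
    a: GenomicInterval, b: GenomicInterval, same_strand_required: bool = False
) -> int:
    """Number of bases shared by two intervals.

    Returns 0 across chromosomes, and — when ``same_strand_required`` — across
    strands. Half-open adjacency ([100,200) vs [200,300)) counts as 0.
    """
    if a.chrom != b.chrom:
        return 0
    if same_strand_required and a.strand != b.strand:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript: the unit the pipeline classifies."""

    transcript_id: str
    locus_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise IntegrityError(f"{self.transcript_id}: transcript has no exons")
        for e in self.exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise IntegrityError(
                    f"{self.transcript_id}: exon on {e.chrom}({e.strand}) does not "
                    f"match transcript {self.interval.chrom}({self.interval.strand})"
                )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise IntegrityError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )
        if (
            self.interval.start > self.exons[0].start
            or self.interval.end < self.exons[-1].end
        ):
            raise IntegrityError(
                f"{self.transcript_id}: span does not cover all exons"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


def five_prime_end(t: TranscriptModel) -> int:
    """Position of the 5'-most transcribed base (span start on +, last base on -)."""
    if t.strand == "+":
        return t.interval.start
    if t.strand == "-":
        return t.interval.end - 1
    raise IntegrityError(
        f"{t.transcript_id}: strandless transcripts have no defined 5' end"
    )


@dataclass
class GeneRecord:
    """A reference gene with its normalized biotype and strand-aware TSS."""

    gene_id: str
    biotype: str
    interval: GenomicInterval
    tss: int = field(init=False)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPE_VOCABULARY:
            raise IntegrityError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if self.interval.strand not in ("+", "-"):
            raise IntegrityError(f"{self.gene_id}: annotation genes must be stranded")
        self.tss = (
            self.interval.start
            if self.interval.strand == "+"
            else self.interval.end - 1
        )


class AnnotationSet:
    """Biotype-tagged reference genes, indexed for interval and TSS queries.

    Interval queries use one interval tree per chromosome; strand and biotype
    restrictions are applied on the (small) candidate set the tree returns.
    Results are guaranteed identical to a brute-force scan.
    """

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes: list[GeneRecord] = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        self._tss: dict[str, tuple[list[int], list[GeneRecord]]] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g)
        for chrom, recs in by_chrom.items():
            tree = IntervalTree()
            for g in recs:
                tree.addi(g.interval.start, g.interval.end, g)
            self._trees[chrom] = tree
            ordered = sorted(recs, key=lambda g: g.tss)
            self._tss[chrom] = ([g.tss for g in ordered], ordered)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(
        self,
        query: GenomicInterval,
        strand: str | None = None,
        biotypes: Sequence[str] | None = None,
    ) -> list[GeneRecord]:
        """Genes overlapping ``query`` by >= 1 bp, optionally restricted to a
        strand (``'+'``/``'-'``) and/or a set of biotypes."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(query.start, query.end)]
        if strand is not None:
            hits = [g for g in hits if g.interval.strand == strand]
        if biotypes is not None:
            wanted = set(biotypes)
            hits = [g for g in hits if g.biotype in wanted]
        return sorted(hits, key=lambda g: (g.interval.start, g.gene_id))

    def tss_within(
        self,
        chrom: str,
        position: int,
        window: int,
        strand: str | None = None,
        biotypes: Sequence[str] | None = None,
    ) -> list[GeneRecord]:
        """Genes whose TSS lies within ``window`` nt of ``position`` (inclusive)."""
        if chrom not in self._tss:
            return []
        positions, ordered = self._tss[chrom]
        lo = bisect_left(positions, position - window)
        hits = []
        for g in ordered[lo:]:
            if g.tss > position + window:
                break
            if strand is not None and g.interval.strand != strand:
                continue
            if biotypes is not None and g.biotype not in biotypes:
                continue
            hits.append(g)
        return hits


class PeakSet:
    """A strandless collection of peak intervals (e.g. H3K4me3 broad peaks)."""

    def __init__(self, peaks: Iterable[GenomicInterval]):
        self.peaks: list[GenomicInterval] = list(peaks)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        starts: dict[str, list[int]] = {}
        ends: dict[str, list[int]] = {}
        for p in self.peaks:
            starts.setdefault(p.chrom, []).append(p.start)
            ends.setdefault(p.chrom, []).append(p.end)
        for chrom in starts:
            self._by_chrom[chrom] = (
                np.asarray(starts[chrom]),
                np.asarray(ends[chrom]),
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def nearest_distance(self, chrom: str, position: int) -> float:
        """Distance in nt from a base to the nearest peak edge on ``chrom``.

        0 when the base lies inside a peak; ``inf`` when the chromosome has no
        peaks. Both directions are considered.
        """
        if chrom not in self._by_chrom:
            return float("inf")
        s, e = self._by_chrom[chrom]
        inside = (s <= position) & (position < e)
        if inside.any():
            return 0.0
        gap_right = np.where(s > position, s - position, np.inf)
        gap_left = np.where(e <= position, position - (e - 1), np.inf)
        return float(min(gap_right.min(), gap_left.min()))


# ---------------------------------------------------------------------------
# File readers / writers


def _open_text(path) -> Iterator[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        yield from fh


def _gtf_lines(path) -> Iterator[tuple[int, object]]:
    """Yield (line number, parsed gffutils Feature) for data lines of a GTF."""
    for lineno, line in enumerate(_open_text(path), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # malformed line
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        yield lineno, feat


def read_transcripts_gtf(path) -> list[TranscriptModel]:
    """Read assembled transcript models from a GTF of exon features.

    Exon rows are grouped by ``transcript_id``; the locus is taken from
    ``gene_id`` with ``transcript_id`` as fallback. GTF 1-based closed
    coordinates become 0-based half-open; the span is the exon envelope.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    locus: dict[str, str] = {}
    for lineno, feat in _gtf_lines(path):
        if feat.featuretype != "exon":
            continue
        tids = feat.attributes.get("transcript_id")
        if not tids:
            raise ParseError(
                f"{path}: line {lineno}: exon feature lacks transcript_id attribute"
            )
        tid = tids[0]
        if feat.strand not in ("+", "-"):
            raise IntegrityError(
                f"{path}: line {lineno}: transcript {tid} exon is unstranded; "
                "the pipeline assumes stranded assemblies"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        prior = exons.setdefault(tid, [])
        if prior and (prior[0].chrom != iv.chrom or prior[0].strand != iv.strand):
            raise IntegrityError(
                f"{path}: line {lineno}: transcript {tid} has exons on mixed "
                "chromosomes or strands"
            )
        prior.append(iv)
        gids = feat.attributes.get("gene_id")
        locus.setdefault(tid, gids[0] if gids else tid)
    out = []
    for tid, exs in exons.items():
        exs = sorted(exs, key=lambda e: e.start)
        span = GenomicInterval(
            exs[0].chrom, exs[0].start, exs[-1].end, exs[0].strand
        )
        out.append(TranscriptModel(tid, locus[tid], span, exs))
    return out


def write_transcripts_gtf(transcripts: Iterable[TranscriptModel], path) -> None:
    """Write transcript models as GTF (transcript + exon rows, 1-based closed)."""
    with open(path, "wt") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.locus_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "lncsift",
                        "transcript",
                        str(t.interval.start + 1),
                        str(t.interval.end),
                        ".",
                        t.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "lncsift",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def normalize_biotype(raw: str, extra_map: dict[str, str] | None = None) -> str:
    table = dict(BIOTYPE_MAP)
    if extra_map:
        table.update(extra_map)
    if raw in table:
        return table[raw]
    logger.warning("unknown biotype %r mapped to other_ncRNA", raw)
    return "other_ncRNA"


def read_annotation_gtf(
    path,
    biotype_attr: str | None = None,
    extra_biotype_map: dict[str, str] | None = None,
) -> AnnotationSet:
    """Read a GENCODE-style annotation GTF into an :class:`AnnotationSet`.

    Uses ``gene`` features when present, otherwise derives gene spans from
    ``transcript`` features grouped by ``gene_id``. The biotype is read from
    ``biotype_attr`` when given, else from the first matching key among
    ``gene_biotype``, ``gene_type``, ``biotype``, ``transcript_type``.
    """
    keys = (biotype_attr,) if biotype_attr else BIOTYPE_ATTR_KEYS

    def get_biotype(feat, lineno) -> str:
        for key in keys:
            vals = feat.attributes.get(key)
            if vals:
                return vals[0]
        raise ConfigurationError(
            f"{path}: line {lineno}: no biotype attribute found (tried "
            f"{', '.join(keys)}); pass biotype_attr= to name the attribute key"
        )

    genes: list[GeneRecord] = []
    txn: dict[str, dict] = {}
    saw_gene_feature = False
    for lineno, feat in _gtf_lines(path):
        if feat.featuretype == "gene":
            saw_gene_feature = True
            gid = feat.attributes.get("gene_id", [f"gene_at_line_{lineno}"])[0]
            biotype = normalize_biotype(get_biotype(feat, lineno), extra_biotype_map)
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            genes.append(GeneRecord(gid, biotype, iv))
        elif feat.featuretype == "transcript" and not saw_gene_feature:
            gid = feat.attributes.get("gene_id", [None])[0]
            if gid is None:
                raise ParseError(
                    f"{path}: line {lineno}: transcript feature lacks gene_id"
                )
            rec = txn.setdefault(
                gid,
                {
                    "chrom": feat.seqid,
                    "start": feat.start - 1,
                    "end": feat.end,
                    "strand": feat.strand,
                    "biotype": get_biotype(feat, lineno),
                },
            )
            rec["start"] = min(rec["start"], feat.start - 1)
            rec["end"] = max(rec["end"], feat.end)
    if not saw_gene_feature:
        for gid, rec in txn.items():
            iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"])
            genes.append(
                GeneRecord(gid, normalize_biotype(rec["biotype"], extra_biotype_map), iv)
            )
    return AnnotationSet(genes)


def read_peaks(path) -> PeakSet:
    """Read peaks from BED3+ / ENCODE broadPeak (0-based half-open, strandless).

    Columns beyond chrom/start/end are ignored; ``track``/``browser``/comment
    lines are skipped; an empty file yields an empty set.
    """
    peaks = []
    for lineno, line in enumerate(_open_text(path), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from exc
        if start >= end:
            raise ParseError(
                f"{path}: line {lineno}: start {start} >= end {end}"
            )
        if start < 0:
            raise ParseError(f"{path}: line {lineno}: negative start {start}")
        peaks.append(GenomicInterval(cols[0], start, end, "."))
    return PeakSet(peaks)
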