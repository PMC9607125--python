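"""Exclusion cascade reducing an assembled transcript set to putative lncRNAs.

A transcript survives when it (1) is called noncoding by every coding-potential
tool, (2) has no same-strand overlap with protein-coding genes or pseudogenes,
(3) has no same-strand overlap with annotated small noncoding RNAs
(snoRNA/rRNA/tRNA/miRNA/other), (4) has summed exon length strictly greater
than the minimum (default 200 nt), and (5) is expressed at or above the
abundance floor. The stages are independent predicates, so the retained set is
order-invariant; the per-stage audit report is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, IntegrityError
from .feature_extraction import summed_exon_length
from .genomics_io import AnnotationSet, TranscriptModel, overlap_bp

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 200  # exclusive: "long" means > 200 nt
DEFAULT_MIN_EXPRESSION = 0.1  # abundance floor; the field's common default

#: Canonical stage order (affects only how removals are attributed in reports).
STAGE_NAMES = (
    "coding_potential",
    "coding_pseudogene_overlap",
    "small_ncrna_overlap",
    "min_length",
    "min_expression",
)


@dataclass
class CodingCallTable:
    """Per-transcript binary coding calls from each coding-potential tool."""

    calls: dict[str, dict[str, int]]
    tools: list[str]

    @classmethod
    def read_tsv(cls, path) -> "CodingCallTable":
        df = pd.read_csv(path, sep="\t")
        if "transcript_id" not in df.columns:
            raise ConfigurationError(f"{path}: missing transcript_id column")
        if df["transcript_id"].duplicated().any():
            dups = df.loc[df["transcript_id"].duplicated(), "transcript_id"]
            raise IntegrityError(
                f"{path}: duplicate transcript_id rows: {', '.join(dups.head(5))}"
            )
        tools = [c for c in df.columns if c != "transcript_id"]
        if not tools:
            raise ConfigurationError(f"{path}: no tool columns")
        calls = {
            row.transcript_id: {tool: int(getattr(row, tool)) for tool in tools}
            for row in df.itertuples(index=False)
        }
        return cls(calls=calls, tools=tools)

    def is_coding_any(self, transcript_id: str) -> bool:
        """True when ANY tool calls the transcript coding."""
        return any(self.calls[transcript_id].values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.calls


@dataclass
class ExpressionTable:
    """Per-transcript abundance values (FPKM/TPM or similar, as provided)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [t for t, v in self.values.items() if v < 0]
        if bad:
            raise IntegrityError(f"negative expression for: {', '.join(bad[:5])}")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        cols = list(df.columns)
        if "transcript_id" not in cols or len(cols) < 2:
            raise ConfigurationError(
                f"{path}: expected transcript_id plus one value column"
            )
        value_col = [c for c in cols if c != "transcript_id"][0]
        return cls(values=dict(zip(df["transcript_id"], df[value_col].astype(float))))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.values


@dataclass
class FilterReport:
    """Audit trail: per-stage in/removed counts plus the final retained ids."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    retained_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_in", "n_removed"]
        )

    def validate(self) -> None:
        for (_, n_in, n_rm), (_, n_next, _) in zip(self.stages, self.stages[1:]):
            if n_in - n_rm != n_next:
                raise IntegrityError("inconsistent stage counts in report")


def _fails_coding(
    t: TranscriptModel, coding: CodingCallTable, missing_coding: str
) -> bool:
    if t.transcript_id not in coding:
        if missing_coding == "error":
            raise ConfigurationError(
                f"no coding call for transcript(s): {t.transcript_id} "
                "(pass missing_coding='noncoding' to treat as noncoding)"
            )
        logger.warning(
            "no coding call for %s; treated as noncoding", t.transcript_id
        )
        return False
    return coding.is_coding_any(t.transcript_id)


def _same_strand_overlap(
    t: TranscriptModel,
    annotation: AnnotationSet,
    biotypes: Sequence[str],
    level: str,
) -> bool:
    genes = annotation.overlapping(t.interval, strand=t.strand, biotypes=biotypes)
    if level == "span":
        return bool(genes)
    # exon-level: require >= 1 bp overlap between some exon and the gene span
    for g in genes:
        if any(overlap_bp(e, g.interval) > 0 for e in t.exons):
            return True
    return False


def filter_putative(
    transcripts: Iterable[TranscriptModel],
    annotation: AnnotationSet,
    coding: CodingCallTable,
    expression: ExpressionTable,
    min_length: int = DEFAULT_MIN_LENGTH,
    min_expression: float = DEFAULT_MIN_EXPRESSION,
    missing_coding: str = "error",
    remove_lncrna_overlap: bool = False,
    overlap_level: str = "span",
    stage_order: Sequence[str] = STAGE_NAMES,
) -> tuple[list[TranscriptModel], FilterReport]:
    """Apply the putative-lncRNA exclusion cascade.

    Parameters
    ----------
    min_length:
        Exclusive lower bound on summed exon length; a transcript of exactly
        ``min_length`` nt is removed.
    min_expression:
        Inclusive abundance floor.
    missing_coding:
        ``'error'`` (default) raises when a transcript has no coding call;
        ``'noncoding'`` treats it as noncoding with a warning.
    remove_lncrna_overlap:
        When True, same-strand overlap with annotated lncRNA genes also
        removes a transcript; by default only the small-ncRNA classes do.
    overlap_level:
        ``'span'`` tests transcript span vs gene span; ``'exon'`` requires an
        exonic base of the transcript inside the gene span.
    stage_order:
        Permutation of :data:`STAGE_NAMES`; changes report attribution only.

    Returns the retained transcripts (input order) and a :class:`FilterReport`.
    """
    transcripts = list(transcripts)
    if set(stage_order) != set(STAGE_NAMES) or len(stage_order) != len(STAGE_NAMES):
        raise ConfigurationError(f"stage_order must be a permutation of {STAGE_NAMES}")
    if overlap_level not in ("span", "exon"):
        raise ConfigurationError("overlap_level must be 'span' or 'exon'")

    small_classes = ["snoRNA", "rRNA", "tRNA", "miRNA", "other_ncRNA"]
    if remove_lncrna_overlap:
        small_classes.append("lncRNA")

    missing_expr = [
        t.transcript_id for t in transcripts if t.transcript_id not in expression
    ]
    if missing_expr:
        raise ConfigurationError(
            "no expression value for transcript(s): " + ", ".join(missing_expr[:10])
        )

    predicates = {
        "coding_potential": lambda t: _fails_coding(t, coding, missing_coding),
        "coding_pseudogene_overlap": lambda t: _same_strand_overlap(
            t, annotation, ["protein_coding", "pseudogene"], overlap_level
        ),
        "small_ncrna_overlap": lambda t: _same_strand_overlap(
            t, annotation, small_classes, overlap_level
        ),
        "min_length": lambda t: summed_exon_length(t) <= min_length,
        "min_expression": lambda t: expression.values[t.transcript_id]
        < min_expression,
    }

    report = FilterReport()
    current = transcripts
    for stage in stage_order:
        fails = predicates[stage]
        kept = [t for t in current if not fails(t)]
        report.stages.append((stage, len(current), len(current) - len(kept)))
        current = kept
    report.retained_ids = [t.transcript_id for t in current]
    report.validate()
    return current, report


def write_report(report: FilterReport, path) -> None:
    """Write the per-stage audit report as TSV (header row always present)."""
    report.to_frame().to_csv(path, sep="\t", index=False)
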