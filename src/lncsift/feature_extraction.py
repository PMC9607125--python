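"""The six model features: scaled transcript length, promoter signature,
multi-exon flag, and one-hot genomic-location category.

Location taxonomy (precedence divergent > antisense > intergenic):

* divergent — the transcript's 5' end lies within +/-2 kb of the TSS of a
  protein-coding gene on the opposite strand, the signature of divergent
  transcription from a shared promoter;
* antisense — the transcript span overlaps a protein-coding gene on the
  opposite strand by at least one base;
* intergenic — neither of the above.

Transcript length is log-transformed, clipped at mean +/- 3 sd, then min-max
scaled to [0, 1] with the post-clip extremes of the dataset the normalizer was
fitted on. The normalizer is fitted per dataset: assemblies from different
sequencing depths and read lengths are not length-comparable on a shared scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LncSiftError
from .genomics_io import (
    AnnotationSet,
    GenomicInterval,
    PeakSet,
    TranscriptModel,
    five_prime_end,
    overlap_bp,
)

#: Column order of every feature table in the package; models persist and
#: enforce this order.
FEATURE_ORDER = (
    "length_scaled",
    "promoter",
    "multiexon",
    "divergent",
    "antisense",
    "intergenic",
)

LOCATION_CATEGORIES = ("divergent", "antisense", "intergenic")

DEFAULT_PROMOTER_WINDOW = 1000
DEFAULT_DIVERGENT_WINDOW = 2000


def summed_exon_length(t: TranscriptModel) -> int:
    """Mature transcript length in nt: sum of exon lengths."""
    return sum(len(e) for e in t.exons)


@dataclass
class LengthNormalizer:
    """Log / 3-sigma-clip / min-max scaler for transcript lengths."""

    mean: float
    sd: float
    lo: float  # post-clip minimum of the fitted log-lengths
    hi: float  # post-clip maximum of the fitted log-lengths

    def transform(self, lengths) -> np.ndarray:
        """Map lengths to [0, 1]; unseen out-of-range values clip to 0 or 1.

        A degenerate fitted range (all lengths equal) maps everything to 0.5.
        """
        x = np.log(np.asarray(lengths, dtype=float))
        x = np.clip(x, self.mean - 3 * self.sd, self.mean + 3 * self.sd)
        if self.hi == self.lo:
            return np.full(x.shape, 0.5)
        return np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)

    def transform_one(self, length: float) -> float:
        return float(self.transform([length])[0])


def fit_length_normalizer(lengths: Iterable[float]) -> LengthNormalizer:
    """Fit the normalizer on a dataset's transcript lengths (natural log)."""
    arr = np.asarray(list(lengths), dtype=float)
    if arr.size == 0:
        raise LncSiftError("cannot fit a length normalizer on an empty collection")
    if (arr < 1).any():
        raise LncSiftError("lengths must be >= 1 nt")
    logs = np.log(arr)
    mean = float(logs.mean())
    sd = float(logs.std(ddof=0))
    clipped = np.clip(logs, mean - 3 * sd, mean + 3 * sd)
    return LengthNormalizer(
        mean=mean, sd=sd, lo=float(clipped.min()), hi=float(clipped.max())
    )


# ---------------------------------------------------------------------------
# Promoter signature


def _promoter_region(
    t: TranscriptModel, window: int, mode: str
) -> GenomicInterval:
    p = five_prime_end(t)
    if mode == "symmetric":
        start, end = p - window, p + window + 1
    elif mode == "upstream":
        if t.strand == "+":
            start, end = p - window, p + 1
        else:
            start, end = p, p + window + 1
    else:
        raise ConfigurationError(f"unknown promoter window mode {mode!r}")
    return GenomicInterval(t.chrom, max(0, start), max(1, end), ".")


def detect_promoter(
    t: TranscriptModel,
    promoter_calls: PeakSet | None = None,
    genome=None,
    window: int = DEFAULT_PROMOTER_WINDOW,
    mode: str = "symmetric",
    scorer: "PromoterScorer | None" = None,
) -> int:
    """Promoter-signature flag for the +/-``window`` nt around the 5' end.

    Interval mode (default): 1 iff any promoter-call interval overlaps the
    window region. Sequence mode: when ``genome`` (a FASTA path or mapping of
    chrom -> sequence) is given instead, the built-in
    :class:`PromoterScorer` scans the window. No evidence at all -> 0.
    """
    region = _promoter_region(t, window, mode)
    if promoter_calls is not None:
        return int(
            any(
                overlap_bp(region, p) > 0
                for p in promoter_calls.peaks
                if p.chrom == region.chrom
            )
        )
    if genome is not None:
        scorer = scorer or PromoterScorer()
        return scorer.scan(_fetch_sequence(genome, region))
    return 0


def _fetch_sequence(genome, region: GenomicInterval) -> str:
    if isinstance(genome, dict):
        seq = genome.get(region.chrom, "")
        return seq[region.start : region.end]
    if isinstance(genome, (str,)) or hasattr(genome, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        if region.chrom not in fa:
            return ""
        return str(fa[region.chrom][region.start : region.end])
    raise ConfigurationError(
        "sequence-mode promoter detection needs a genome FASTA path or a "
        "chrom -> sequence mapping"
    )


class PromoterScorer:
    """Sequence-based promoter heuristic: TATA-box weight-matrix scan plus a
    CpG-island style GC / CpG observed-to-expected score.

    This is a deliberately simple, documented scorer for when no external
    promoter predictions are available; it is a heuristic, not a replica of
    any published promoter predictor.
    """

    # Log-odds (base 2, vs uniform background) for the 8-mer TATA consensus
    # TATAWAWR, from canonical base preferences.
    TATA_PWM = np.log2(
        np.array(
            [
                # A     C     G     T
                [0.04, 0.10, 0.04, 0.82],  # T
                [0.91, 0.03, 0.03, 0.03],  # A
                [0.04, 0.10, 0.04, 0.82],  # T
                [0.91, 0.03, 0.03, 0.03],  # A
                [0.48, 0.02, 0.02, 0.48],  # W
                [0.91, 0.03, 0.03, 0.03],  # A
                [0.48, 0.02, 0.02, 0.48],  # W
                [0.40, 0.10, 0.40, 0.10],  # R
            ]
        )
        / 0.25
    )
    _INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

    def __init__(
        self,
        tata_threshold: float = 8.0,
        gc_threshold: float = 0.50,
        cpg_oe_threshold: float = 0.60,
    ):
        self.tata_threshold = tata_threshold
        self.gc_threshold = gc_threshold
        self.cpg_oe_threshold = cpg_oe_threshold

    def best_tata_score(self, seq: str) -> float:
        seq = seq.upper()
        w = self.TATA_PWM.shape[0]
        best = -math.inf
        for i in range(len(seq) - w + 1):
            s = 0.0
            for j, base in enumerate(seq[i : i + w]):
                idx = self._INDEX.get(base)
                if idx is None:
                    s = -math.inf
                    break
                s += self.TATA_PWM[j, idx]
            best = max(best, s)
        return best

    def cpg_stats(self, seq: str) -> tuple[float, float]:
        seq = seq.upper()
        n = len(seq)
        if n < 2:
            return 0.0, 0.0
        c = seq.count("C")
        g = seq.count("G")
        cpg = sum(1 for i in range(n - 1) if seq[i : i + 2] == "CG")
        gc = (c + g) / n
        expected = c * g / n
        oe = cpg / expected if expected > 0 else 0.0
        return gc, oe

    def scan(self, seq: str) -> int:
        """1 iff the window looks promoter-like (TATA hit or CpG-rich)."""
        if not seq:
            return 0
        if self.best_tata_score(seq) >= self.tata_threshold:
            return 1
        gc, oe = self.cpg_stats(seq)
        return int(gc >= self.gc_threshold and oe >= self.cpg_oe_threshold)


# ---------------------------------------------------------------------------
# Location taxonomy


def _opposite(strand: str) -> str:
    return "-" if strand == "+" else "+"


def classify_location(
    t: TranscriptModel,
    annotation: AnnotationSet,
    divergent_window: int = DEFAULT_DIVERGENT_WINDOW,
) -> str:
    """Assign divergent / antisense / intergenic (in that precedence)."""
    p = five_prime_end(t)
    opp = _opposite(t.strand)
    if annotation.tss_within(
        t.chrom, p, divergent_window, strand=opp, biotypes=["protein_coding"]
    ):
        return "divergent"
    if annotation.overlapping(t.interval, strand=opp, biotypes=["protein_coding"]):
        return "antisense"
    return "intergenic"


# ---------------------------------------------------------------------------
# Assembly into the model's feature table


def build_feature_vectors(
    transcripts: Sequence[TranscriptModel],
    annotation: AnnotationSet,
    promoter_calls: PeakSet | None = None,
    genome=None,
    normalizer: LengthNormalizer | None = None,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    promoter_mode: str = "symmetric",
    divergent_window: int = DEFAULT_DIVERGENT_WINDOW,
) -> tuple[pd.DataFrame, LengthNormalizer]:
    """Compute the six-feature table for a set of putative lncRNAs.

    The length normalizer is fitted on these transcripts unless one is given
    (per-dataset scope). Returns (table indexed by transcript_id with columns
    :data:`FEATURE_ORDER`, fitted normalizer).
    """
    transcripts = list(transcripts)
    lengths = [summed_exon_length(t) for t in transcripts]
    if normalizer is None:
        normalizer = fit_length_normalizer(lengths)
    scaled = normalizer.transform(lengths) if transcripts else np.array([])
    rows = []
    for t, ls in zip(transcripts, scaled):
        loc = classify_location(t, annotation, divergent_window)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "length_scaled": float(ls),
                "promoter": detect_promoter(
                    t,
                    promoter_calls=promoter_calls,
                    genome=genome,
                    window=promoter_window,
                    mode=promoter_mode,
                ),
                "multiexon": int(len(t.exons) >= 2),
                "divergent": int(loc == "divergent"),
                "antisense": int(loc == "antisense"),
                "intergenic": int(loc == "intergenic"),
            }
        )
    df = pd.DataFrame(rows, columns=["transcript_id", *FEATURE_ORDER])
    return df.set_index("transcript_id"), normalizer
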