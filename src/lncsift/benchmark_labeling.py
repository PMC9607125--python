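"""True/false lncRNA labels from H3K4me3 peak proximity.

H3K4me3 marks active transcription start sites, so a putative lncRNA whose 5'
end lies within 1 kb of an H3K4me3 peak carries evidence of being a genuine
full-length transcript (``true_lnc``); one without such evidence is treated as
a fragment or transcriptional noise (``false_lnc``). Distance is measured from
the 5'-end base to the nearest peak edge in either direction (0 when the base
is inside a peak) and the window bound is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genomics_io import PeakSet, TranscriptModel, five_prime_end

DEFAULT_LABEL_WINDOW = 1000

TRUE_LNC = "true_lnc"
FALSE_LNC = "false_lnc"


@dataclass
class LabeledExample:
    transcript_id: str
    label: str
    distance_to_nearest_peak: float

    @property
    def is_true(self) -> bool:
        return self.label == TRUE_LNC


def label_transcript(
    t: TranscriptModel, peaks: PeakSet, window: int = DEFAULT_LABEL_WINDOW
) -> LabeledExample:
    """Label one transcript; no peaks on its chromosome gives distance inf."""
    d = peaks.nearest_distance(t.chrom, five_prime_end(t))
    return LabeledExample(
        transcript_id=t.transcript_id,
        label=TRUE_LNC if d <= window else FALSE_LNC,
        distance_to_nearest_peak=d,
    )


def label_dataset(
    transcripts: Iterable[TranscriptModel],
    peaks: PeakSet,
    window: int = DEFAULT_LABEL_WINDOW,
) -> tuple[list[LabeledExample], dict]:
    """Label every transcript and summarize the class balance."""
    examples = [label_transcript(t, peaks, window) for t in transcripts]
    n_true = sum(e.is_true for e in examples)
    n = len(examples)
    summary = {
        "n": n,
        "n_true": n_true,
        "n_false": n - n_true,
        "true_fraction": n_true / n if n else math.nan,
    }
    return examples, summary


def labels_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [e.transcript_id for e in examples],
            "label": [e.label for e in examples],
            "distance": [e.distance_to_nearest_peak for e in examples],
        }
    )


def write_labels(examples: Sequence[LabeledExample], path) -> None:
    labels_to_frame(examples).to_csv(path, sep="\t", index=False)
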