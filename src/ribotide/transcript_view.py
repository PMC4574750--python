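"""Per-transcript profile data: frame-coloured 5'-end histograms, RNA-seq
coverage underlay, ORF tracks, and sliding-window translation summaries.

Unlike the framing statistics (phase relative to each CDS's own start),
the transcript view bins 5' ends by frame relative to transcript nt 1
(position mod 3), which is the convention for whole-transcript displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import ReadStore, Transcript
from .orfs import OrfCandidate


@dataclass
class TranscriptProfile:
    """Everything needed to draw one transcript's translation landscape."""

    transcript_id: str
    frame_series: np.ndarray       # shape (3, L): 5'-end counts by frame
    rna_coverage: np.ndarray       # shape (L,)
    orf_track: list[tuple[OrfCandidate, bool]] = field(default_factory=list)

    @property
    def total_counts(self) -> int:
        return int(self.frame_series.sum())

    def to_frame(self) -> pd.DataFrame:
        L = self.frame_series.shape[1]
        return pd.DataFrame({
            "position": np.arange(L),
            "frame0": self.frame_series[0],
            "frame1": self.frame_series[1],
            "frame2": self.frame_series[2],
            "rna_coverage": self.rna_coverage,
        })


def transcript_profile(
    store_ribo: ReadStore,
    store_rna: Optional[ReadStore],
    transcript: Transcript,
    orf_track: Iterable[tuple[OrfCandidate, bool]] = (),
    length: Optional[int] = None,
    rna_mode: str = "coverage",
) -> TranscriptProfile:
    """Assemble the per-position series for one transcript.

    Ribo-seq 5' ends are split into three series by position mod 3
    (optionally restricted to one footprint length). RNA-seq contributes
    full-read coverage by default, or 5'-end counts with
    ``rna_mode="five_prime"``. An empty RNA store yields all-zero coverage.
    """
    L = len(transcript)
    frames = np.zeros((3, L))
    df = store_ribo.df[store_ribo.df["transcript_id"] == transcript.id]
    if length is not None:
        df = df[df["length"] == length]
    for row in df.itertuples(index=False):
        frames[row.five_prime % 3, row.five_prime] += row.weight

    rna = np.zeros(L)
    if store_rna is not None and len(store_rna):
        rdf = store_rna.df[store_rna.df["transcript_id"] == transcript.id]
        for row in rdf.itertuples(index=False):
            if rna_mode == "five_prime":
                rna[row.five_prime] += row.weight
            else:
                rna[row.five_prime:row.five_prime + row.length] += row.weight
    return TranscriptProfile(transcript.id, frames, rna, list(orf_track))


def codon_counts(profile: TranscriptProfile, frame: int) -> np.ndarray:
    """Collapse one frame's 5'-end series to per-codon counts."""
    series = profile.frame_series[frame]
    L = len(series)
    n_codons = (L - frame) // 3
    return series[frame:frame + 3 * n_codons].reshape(n_codons, 3).sum(axis=1)


def sliding_window_mean(counts: np.ndarray, window_codons: int = 15,
                        edge: str = "truncate") -> np.ndarray:
    """Centred moving average over per-codon counts.

    Edges use truncated windows by default (mean over the codons that are
    available); ``edge="reflect"`` mirror-pads instead. A window wider than
    the series collapses to the global mean.
    """
    counts = np.asarray(counts, dtype=float)
    if window_codons % 2 != 1:
        raise ValueError("window_codons must be odd")
    n = len(counts)
    if n == 0:
        return counts.copy()
    if window_codons >= 2 * n - 1 and edge == "reflect":
        return np.full(n, counts.mean())
    if window_codons > n and edge == "truncate":
        return np.full(n, counts.mean())
    kernel = np.ones(window_codons)
    if edge == "truncate":
        num = np.convolve(counts, kernel, mode="same")
        den = np.convolve(np.ones(n), kernel, mode="same")
        return num / den
    if edge == "reflect":
        half = window_codons // 2
        padded = np.concatenate([counts[half:0:-1], counts, counts[-2:-half - 2:-1]])
        return np.convolve(padded, kernel / window_codons, mode="valid")
    raise ValueError(f"unknown edge mode {edge!r}")


def filtered_codon_counts(profile: TranscriptProfile, transcript: Transcript,
                          main_cds: tuple[int, int], predominant_length: int,
                          store: ReadStore, called_phase: int) -> np.ndarray:
    """Per-codon counts of the predominant size class in its called frame.

    This is the series the sliding-window summary is drawn from: reads of
    the predominant length whose 5' ends fall in the called phase relative
    to the main CDS start, binned per codon over the whole transcript.
    """
    df = store.df[(store.df["transcript_id"] == transcript.id)
                  & (store.df["length"] == predominant_length)]
    start = main_cds[0]
    frame = (start + called_phase) % 3
    series = np.zeros(len(transcript))
    for row in df.itertuples(index=False):
        if row.five_prime % 3 == frame:
            series[row.five_prime] += row.weight
    n_codons = (len(transcript) - frame) // 3
    return series[frame:frame + 3 * n_codons].reshape(n_codons, 3).sum(axis=1)
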