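"""Frame calling from triplet periodicity.

Elongating ribosomes step three nucleotides at a time, so footprint 5' ends
concentrate at one codon position per read-length class. These routines
restrict to *interior* reads (entirely contained within a CDS, excluding
most initiating/terminating ribosomes), tally 5'-end codon positions per
length class, and call the predominant phase.

Phase here is always relative to the CDS's own start: a read at the first
nucleotide of a codon has phase 0 (displayed as codon position 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import ReadStore

logger = logging.getLogger(__name__)


@dataclass
class PhaseHistogram:
    """Counts of read 5' ends by (length, phase), phase in {0,1,2}."""

    counts: pd.DataFrame  # index: length, columns: 0,1,2
    universe: str = ""

    def to_tsv(self, path) -> None:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["length", "phase", "count"]
        long.to_csv(path, sep="\t", index=False)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class FrameCall:
    """Per length class: the predominant phase and its fraction."""

    table: pd.DataFrame  # index: length; columns: phase, fraction, n_reads

    @property
    def predominant_length(self) -> int:
        """The most abundant length class overall."""
        return int(self.table["n_reads"].idxmax())

    def phase_of(self, length: int) -> int:
        return int(self.table.loc[length, "phase"])


def interior_reads(store: ReadStore, cds_map: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Reads entirely contained within their transcript's CDS.

    Returns the store frame restricted to reads with
    ``cds_start <= five_prime`` and ``five_prime + length <= cds_end``,
    with ``cds_start``, ``cds_end`` and ``phase`` columns appended.
    """
    if not cds_map:
        raise ValueError("empty CDS set")
    df = store.df
    df = df[df["transcript_id"].isin(cds_map)].copy()
    if df.empty:
        df["cds_start"] = pd.Series(dtype=int)
        df["cds_end"] = pd.Series(dtype=int)
        df["phase"] = pd.Series(dtype=int)
        return df
    starts = df["transcript_id"].map({k: v[0] for k, v in cds_map.items()})
    ends = df["transcript_id"].map({k: v[1] for k, v in cds_map.items()})
    keep = (starts <= df["five_prime"]) & (df["five_prime"] + df["length"] <= ends)
    df = df[keep].copy()
    df["cds_start"] = starts[keep].astype(int)
    df["cds_end"] = ends[keep].astype(int)
    df["phase"] = ((df["five_prime"] - df["cds_start"]) % 3).astype(int)
    return df


def phase_by_length(interior: pd.DataFrame, length_window: tuple[int, int] = (20, 40),
                    universe: str = "") -> PhaseHistogram:
    """Tally interior-read 5' ends by (length, codon-position phase)."""
    if "phase" not in interior.columns:
        raise ValueError("phase_by_length requires the frame produced by interior_reads")
    lo, hi = length_window
    df = interior[(interior["length"] >= lo) & (interior["length"] <= hi)]
    counts = (
        df.groupby(["length", "phase"])["weight"].sum()
        .unstack(fill_value=0)
        .reindex(columns=[0, 1, 2], fill_value=0)
    )
    counts.index = counts.index.astype(int)
    return PhaseHistogram(counts=counts.astype(int), universe=universe)


def length_distribution(interior: pd.DataFrame, groups: Mapping[str, set],
                        length_window: tuple[int, int] = (20, 40)) -> pd.DataFrame:
    """Per-group normalised read-length histograms over the length window.

    ``groups`` maps a label (e.g. compartment) to a set of transcript ids.
    Each non-empty group's histogram sums to 1; empty groups yield all-NaN
    columns and a logged flag.
    """
    lo, hi = length_window
    idx = pd.RangeIndex(lo, hi + 1, name="length")
    out = pd.DataFrame(index=idx)
    for label, tids in groups.items():
        sub = interior[interior["transcript_id"].isin(tids)]
        sub = sub[(sub["length"] >= lo) & (sub["length"] <= hi)]
        total = sub["weight"].sum()
        if total == 0:
            logger.warning("length_distribution: group %r has no reads in window", label)
            out[label] = np.nan
            continue
        hist = sub.groupby("length")["weight"].sum().reindex(idx, fill_value=0)
        out[label] = hist / total
    return out


def frame_call(hist: PhaseHistogram) -> FrameCall:
    """Call the predominant phase per length class.

    Ties break toward the smallest phase index with a logged warning.
    """
    if hist.counts.empty or hist.total == 0:
        raise ValueError("frame_call on empty histogram")
    rows = []
    for length, row in hist.counts.iterrows():
        n = int(row.sum())
        if n == 0:
            continue
        best = int(row.idxmax())  # idxmax takes the first (smallest) on ties
        if (row == row.max()).sum() > 1:
            logger.warning("frame_call: tie at length %d, breaking toward phase %d", length, best)
        rows.append((int(length), best, row.max() / n, n))
    table = pd.DataFrame(rows, columns=["length", "phase", "fraction", "n_reads"]).set_index("length")
    return FrameCall(table=table)
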