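"""Core data model: transcripts, mapped reads, and the read store.

Coordinates are 0-based, half-open throughout the library; display layers
convert to 1-based positions and codon positions {1,2,3}. A CDS interval
includes its stop codon, so the first nucleotide of the stop codon sits at
``cds_end - 3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

CATEGORIES = ("mRNA", "rRNA", "gDNA", "ncRNA", "other")

_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass
class Transcript:
    """A transcript sequence with an optional annotated CDS interval.

    The CDS interval ``(start, end)`` is 0-based half-open, includes the
    stop codon, and must span a whole number of codons.
    """

    id: str
    sequence: str
    cds: Optional[tuple[int, int]] = None
    category: str = "mRNA"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().translate(_U_TO_T)
        if len(self.sequence) < 1:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if self.category not in CATEGORIES:
            raise ValueError(f"transcript {self.id!r}: unknown category {self.category!r}")
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"transcript {self.id!r}: CDS ({start}, {end}) out of bounds "
                    f"for length {len(self.sequence)}"
                )
            if (end - start) % 3 != 0:
                raise ValueError(
                    f"transcript {self.id!r}: CDS length {end - start} not a multiple of 3"
                )
            self.cds = (int(start), int(end))

    def __len__(self) -> int:
        return len(self.sequence)


class Transcriptome(dict):
    """Mapping of transcript id -> :class:`Transcript` preserving insertion order."""

    @classmethod
    def from_transcripts(cls, transcripts: Iterable[Transcript]) -> "Transcriptome":
        obj = cls()
        for t in transcripts:
            if t.id in obj:
                raise ValueError(f"duplicate transcript id {t.id!r}")
            obj[t.id] = t
        return obj

    def cds_map(self) -> dict[str, tuple[int, int]]:
        """Annotated CDS intervals, keyed by transcript id."""
        return {t.id: t.cds for t in self.values() if t.cds is not None}

    def lengths(self) -> dict[str, int]:
        return {t.id: len(t) for t in self.values()}


@dataclass(frozen=True)
class MappedRead:
    """A single aligned footprint or RNA-seq read in transcript coordinates."""

    transcript_id: str
    five_prime: int
    length: int
    sample: str
    weight: int = 1


_COLUMNS = ("transcript_id", "five_prime", "length", "sample", "weight")


class ReadStore:
    """Aligned reads grouped by sample, backed by a :class:`pandas.DataFrame`.

    Columns: transcript_id, five_prime (0-based), length, sample, weight.
    """

    def __init__(self, df: pd.DataFrame, seed: Optional[int] = None):
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"ReadStore frame missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)
        self.seed = seed

    @classmethod
    def from_reads(cls, reads: Iterable[MappedRead], seed: Optional[int] = None) -> "ReadStore":
        rows = [(r.transcript_id, r.five_prime, r.length, r.sample, r.weight) for r in reads]
        df = pd.DataFrame(rows, columns=list(_COLUMNS))
        if df.empty:
            df = df.astype({"five_prime": int, "length": int, "weight": int})
        return cls(df, seed=seed)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def totals(self) -> pd.Series:
        """Total read weight per sample."""
        if self.df.empty:
            return pd.Series(dtype=int)
        return self.df.groupby("sample")["weight"].sum()

    def subset(self, sample: Optional[str] = None, length: Optional[int] = None) -> "ReadStore":
        df = self.df
        if sample is not None:
            df = df[df["sample"] == sample]
        if length is not None:
            df = df[df["length"] == length]
        return ReadStore(df.copy(), seed=self.seed)

    def validate_against(self, transcriptome: Mapping[str, Transcript]) -> None:
        """Check every read resolves against the transcriptome and stays in bounds."""
        lengths = {tid: len(t) for tid, t in transcriptome.items()}
        unknown = set(self.df["transcript_id"]) - set(lengths)
        if unknown:
            raise ValueError(f"reads reference unknown transcripts: {sorted(unknown)[:5]}")
        tlen = self.df["transcript_id"].map(lengths).to_numpy()
        fp = self.df["five_prime"].to_numpy()
        rl = self.df["length"].to_numpy()
        bad = (fp < 0) | (fp + rl > tlen)
        if bad.any():
            row = self.df[bad].iloc[0]
            raise ValueError(
                f"read out of bounds on {row.transcript_id!r}: "
                f"5'={row.five_prime} len={row.length}"
            )

    def read_multiset(self) -> list[tuple[str, int, int]]:
        """(transcript_id, five_prime, length) tuples, one per unit of weight."""
        out: list[tuple[str, int, int]] = []
        for row in self.df.itertuples(index=False):
            out.extend([(row.transcript_id, row.five_prime, row.length)] * int(row.weight))
        return sorted(out)
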