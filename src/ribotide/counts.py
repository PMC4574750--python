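"""Count-matrix export over (length, frame) combinations.

Downstream differential-translation tools want per-CDS counts summed over
chosen footprint size-class/frame combinations, paired with RNA-seq counts
from the same samples. Nothing statistical happens here: the output is a
plain TSV count matrix plus a JSON sidecar recording the combination spec
and filters for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .framing import FrameCall
from .model import ReadStore
from .orfs import OrfCandidate

# a combo is (length, frame_spec) with frame_spec "in-frame", "any", or a phase int
Combo = tuple[int, Union[str, int]]


@dataclass
class CountMatrix:
    counts: pd.DataFrame          # rows: CDS labels, columns: samples
    metadata: pd.DataFrame        # per-CDS transcript id, interval, length
    combos: list[Combo]

    def to_tsv(self, path, sidecar_path=None, extra_provenance: Optional[dict] = None) -> None:
        self.counts.rename_axis("cds").to_csv(path, sep="\t")
        if sidecar_path is not None:
            payload = {"combos": [[c[0], c[1]] for c in self.combos]}
            payload.update(extra_provenance or {})
            with open(sidecar_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _cds_label(c: OrfCandidate) -> str:
    return f"{c.transcript_id}:{c.start}-{c.end}"


def export_counts(
    store: ReadStore,
    passing_cds: Sequence[OrfCandidate],
    combos: Sequence[Combo],
    frame_call: Optional[FrameCall] = None,
    length_window: tuple[int, int] = (20, 40),
) -> CountMatrix:
    """Sum interior reads per CDS and sample over the given combinations.

    A read contributes when it is wholly contained in the CDS and matches
    any combo: exact length plus either any phase ("any"), a literal phase
    index, or "in-frame" meaning the called phase for that length class
    (requires a frame call).
    """
    if not combos:
        raise ValueError("export_counts needs at least one (length, frame) combo")
    lo, hi = length_window
    resolved: list[tuple[int, Optional[int]]] = []
    for length, fspec in combos:
        if not (lo <= length <= hi):
            raise ValueError(f"combo length {length} outside window {length_window}")
        if fspec == "any":
            resolved.append((length, None))
        elif fspec == "in-frame":
            if frame_call is None or length not in frame_call.table.index:
                raise ValueError(f"'in-frame' combo for length {length} needs a frame call")
            resolved.append((length, frame_call.phase_of(length)))
        else:
            resolved.append((length, int(fspec)))

    samples = store.samples or ["sample"]
    labels = [_cds_label(c) for c in passing_cds]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate CDS labels in export")
    mat = pd.DataFrame(0, index=labels, columns=samples, dtype=int)
    df = store.df
    for c, label in zip(passing_cds, labels):
        sub = df[(df["transcript_id"] == c.transcript_id)
                 & (df["five_prime"] >= c.start)
                 & (df["five_prime"] + df["length"] <= c.end)]
        if sub.empty:
            continue
        phase = ((sub["five_prime"] - c.start) % 3).astype(int)
        match = pd.Series(False, index=sub.index)
        for length, ph in resolved:
            m = sub["length"] == length
            if ph is not None:
                m &= phase == ph
            match |= m
        got = sub[match].groupby("sample")["weight"].sum()
        for s, v in got.items():
            mat.at[label, s] = int(v)
    meta = pd.DataFrame({
        "transcript_id": [c.transcript_id for c in passing_cds],
        "start": [c.start for c in passing_cds],
        "end": [c.end for c in passing_cds],
        "cds_length": [c.end - c.start for c in passing_cds],
    }, index=labels)
    return CountMatrix(counts=mat, metadata=meta, combos=list(combos))


def pair_with_rna(
    ribo_matrix: CountMatrix,
    rna_store: ReadStore,
    cds_set: Sequence[OrfCandidate],
    interior_only: bool = False,
) -> pd.DataFrame:
    """Pair Ribo-seq counts with RNA-seq counts over the same CDS universe.

    RNA reads count toward a CDS when they overlap its interval at all
    (any frame, any length); ``interior_only`` restricts to fully
    contained reads. Sample names must match between the two assays.
    Returns a frame with hierarchical columns (assay, sample).
    """
    labels = [_cds_label(c) for c in cds_set]
    if set(labels) != set(ribo_matrix.counts.index):
        raise ValueError("CDS universe differs between ribo matrix and rna pairing")
    ribo_samples = set(ribo_matrix.counts.columns)
    rna_samples = set(rna_store.samples)
    if ribo_samples != rna_samples:
        raise ValueError(
            f"sample-name mismatch: ribo-only {sorted(ribo_samples - rna_samples)}, "
            f"rna-only {sorted(rna_samples - ribo_samples)}")

    rna = pd.DataFrame(0, index=labels, columns=sorted(rna_samples), dtype=int)
    df = rna_store.df
    for c, label in zip(cds_set, labels):
        sub = df[df["transcript_id"] == c.transcript_id]
        if interior_only:
            m = (sub["five_prime"] >= c.start) & (sub["five_prime"] + sub["length"] <= c.end)
        else:
            m = (sub["five_prime"] < c.end) & (sub["five_prime"] + sub["length"] > c.start)
        got = sub[m].groupby("sample")["weight"].sum()
        for s, v in got.items():
            rna.at[label, s] = int(v)
    ribo = ribo_matrix.counts.loc[labels]
    out = pd.concat({"ribo": ribo, "rna": rna}, axis=1)
    zero_rna = rna.sum(axis=1) == 0
    out[("flags", "no_rna")] = zero_rna
    return out
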