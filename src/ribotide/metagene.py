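"""Weighted metagene profiles and footprint-geometry inference.

For each read-length class n, 5'-end positions are histogrammed in windows
anchored at the first nucleotide of the start and stop codons, averaged
over selected transcripts. Each coding sequence's contribution is
down-weighted by its mean per-nucleotide density of n-nt reads (total n-nt
reads within the CDS divided by CDS length), so highly translated regions
do not dominate the profile.

Geometry is read off the profile maxima. An initiating ribosome holds the
start codon in its P-site, so the start-window maximum sits at offset
-L5, the number of nucleotides protected 5' of the P-site codon. A
terminating ribosome pauses with the stop codon in its A-site, so the
stop-window maximum sits at -(L5 + 3); the 3'-protected length follows
from L5 + 6 + L3 = n (P-site and A-site codons make up the 6). Terminating
ribosomes protect 1-2 nt more than elongating ones, which shows up as
end-extensions of the termination classes relative to the reference
elongation class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .filtering import FilterConfig, support_counts
from .framing import FrameCall
from .model import ReadStore
from .orfs import OrfCandidate

logger = logging.getLogger(__name__)


@dataclass
class MetageneProfile:
    """Weighted mean 5'-end density around start and stop codons for one n.

    Offset 0 is the first nucleotide of the start (resp. stop) codon.
    """

    length: int
    start_offsets: np.ndarray
    start_profile: np.ndarray
    stop_offsets: np.ndarray
    stop_profile: np.ndarray
    n_transcripts: int

    def to_frame(self) -> pd.DataFrame:
        a = pd.DataFrame({"length": self.length, "anchor": "start",
                          "offset": self.start_offsets, "weighted_density": self.start_profile})
        b = pd.DataFrame({"length": self.length, "anchor": "stop",
                          "offset": self.stop_offsets, "weighted_density": self.stop_profile})
        return pd.concat([a, b], ignore_index=True)


@dataclass
class FootprintGeometry:
    """Per (length, state) protected lengths flanking the ribosome's codons.

    ``L5`` is the number of nucleotides protected 5' of the P-site codon,
    ``L3`` the number protected 3' of the A-site codon; for the canonical
    two-codon core, L5 + 3 + 3 + L3 = n.
    """

    table: pd.DataFrame  # columns: length, state, L5, L3, ambiguous

    def get(self, length: int, state: str) -> tuple[int, int]:
        row = self.table[(self.table["length"] == length) & (self.table["state"] == state)]
        if row.empty:
            raise KeyError(f"no geometry for ({length}, {state})")
        return int(row["L5"].iloc[0]), int(row["L3"].iloc[0])


def select_metagene_transcripts(
    store: ReadStore,
    cds_map: Mapping[str, tuple[int, int]],
    frame_call: FrameCall,
    config: Optional[FilterConfig] = None,
) -> list[str]:
    """Transcripts with solid in-frame support in the most abundant size class.

    Keeps CDSs with at least ``min_reads`` reads of the predominant length
    class mapping in frame at ``min_locations`` or more distinct positions.
    """
    config = config or FilterConfig()
    focal = (config.focal_length if config.focal_length is not None
             else frame_call.predominant_length)
    phase = frame_call.phase_of(focal) if focal in frame_call.table.index else 0
    selected = []
    for tid, (start, end) in cds_map.items():
        cand = OrfCandidate(tid, start, end, provenance="annotated")
        rif, nloc, _ = support_counts(cand, store, focal, phase)
        if rif >= config.min_reads and nloc >= config.min_locations:
            selected.append(tid)
    if not selected:
        logger.warning("select_metagene_transcripts: no transcript met the support criteria")
    return selected


def metagene_profile(
    store: ReadStore,
    cds_map: Mapping[str, tuple[int, int]],
    selected: Iterable[str],
    length: int,
    start_window: tuple[int, int] = (-30, 60),
    stop_window: tuple[int, int] = (-60, 30),
    average: str = "mean",
) -> MetageneProfile:
    """Build the weighted average 5'-end profile for one length class.

    Each CDS's positional counts are divided by its mean per-nt density of
    ``length``-nt reads (5' ends within the CDS / CDS length); the
    density-normalised profiles are then averaged across CDSs (simple mean
    by default; ``average="read_weighted"`` weights each CDS by its read
    count). CDSs with zero reads of this length contribute nothing.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("metagene_profile: empty transcript selection")
    if average not in ("mean", "read_weighted"):
        raise ValueError(f"unknown averaging mode {average!r}")
    s_lo, s_hi = start_window
    e_lo, e_hi = stop_window
    start_offsets = np.arange(s_lo, s_hi + 1)
    stop_offsets = np.arange(e_lo, e_hi + 1)
    start_acc = np.zeros(len(start_offsets))
    stop_acc = np.zeros(len(stop_offsets))
    weights_acc = 0.0
    n_used = 0

    df = store.df
    df = df[(df["length"] == length) & (df["transcript_id"].isin(selected))]
    by_tid = dict(tuple(df.groupby("transcript_id"))) if not df.empty else {}
    for tid in selected:
        if tid not in cds_map or tid not in by_tid:
            continue
        start, end = cds_map[tid]
        sub = by_tid[tid]
        pos = sub["five_prime"].to_numpy()
        w = sub["weight"].to_numpy().astype(float)
        in_cds = (pos >= start) & (pos < end)  # 5' end within the CDS
        total_in_cds = w[in_cds].sum()
        if total_in_cds == 0:
            continue
        density = total_in_cds / (end - start)
        rel_start = pos - start
        rel_stop = pos - (end - 3)
        s_hist = np.zeros(len(start_offsets))
        np.add.at(s_hist, (rel_start - s_lo)[(rel_start >= s_lo) & (rel_start <= s_hi)],
                  w[(rel_start >= s_lo) & (rel_start <= s_hi)])
        e_hist = np.zeros(len(stop_offsets))
        np.add.at(e_hist, (rel_stop - e_lo)[(rel_stop >= e_lo) & (rel_stop <= e_hi)],
                  w[(rel_stop >= e_lo) & (rel_stop <= e_hi)])
        cw = total_in_cds if average == "read_weighted" else 1.0
        start_acc += cw * s_hist / density
        stop_acc += cw * e_hist / density
        weights_acc += cw
        n_used += 1
    if n_used == 0:
        logger.warning("metagene_profile: no CDS carried %d-nt reads", length)
        weights_acc = 1.0
    return MetageneProfile(
        length=length,
        start_offsets=start_offsets,
        start_profile=start_acc / weights_acc,
        stop_offsets=stop_offsets,
        stop_profile=stop_acc / weights_acc,
        n_transcripts=n_used,
    )


def _locate_max(offsets: np.ndarray, profile: np.ndarray, window: tuple[int, int],
                canonical: int) -> tuple[int, bool]:
    """Argmax offset within a search window; ties break toward ``canonical``."""
    mask = (offsets >= window[0]) & (offsets <= window[1])
    if not mask.any() or np.all(profile[mask] == 0):
        raise ValueError("no signal in the search window")
    sub_off = offsets[mask]
    sub_prof = profile[mask]
    peak = sub_prof.max()
    tied = sub_off[sub_prof == peak]
    ambiguous = len(tied) > 1
    best = int(tied[np.argmin(np.abs(tied - canonical))])
    if ambiguous:
        logger.warning("metagene maximum tied at offsets %s; using %d", tied.tolist(), best)
    return best, ambiguous


def infer_offsets(profiles: Iterable[MetageneProfile]) -> FootprintGeometry:
    """Infer (L5, L3) per length class from start- and stop-window maxima.

    Elongation geometry anchors on the initiation peak (start codon in the
    P-site): L5 = -offset of the start-window maximum, L3 = n - L5 - 6.
    Termination geometry anchors on the stop-codon pause (stop codon in
    the A-site): the stop-window maximum at offset o gives L5 = -o - 3 and
    L3 = n + o - 3. Tied maxima are resolved toward the canonical
    expectation and flagged ambiguous.
    """
    rows = []
    for prof in profiles:
        n = prof.length
        search = (-(n + 5), n + 5)
        try:
            o_start, amb_s = _locate_max(prof.start_offsets, prof.start_profile,
                                         search, canonical=-12)
            l5_e = -o_start
            rows.append({"length": n, "state": "elongation", "L5": l5_e,
                         "L3": n - l5_e - 6, "ambiguous": amb_s})
        except ValueError:
            logger.warning("no start-window maximum for %d-nt class", n)
        try:
            o_stop, amb_e = _locate_max(prof.stop_offsets, prof.stop_profile,
                                        search, canonical=-15)
            l5_t = -o_stop - 3
            rows.append({"length": n, "state": "termination", "L5": l5_t,
                         "L3": n + o_stop - 3, "ambiguous": amb_e})
        except ValueError:
            logger.warning("no stop-window maximum for %d-nt class", n)
    return FootprintGeometry(table=pd.DataFrame(rows))


def termination_extension(
    geometry: FootprintGeometry,
    reference: Optional[tuple[int, str]] = None,
) -> pd.DataFrame:
    """Express each (length, state) as end-extensions over a reference class.

    The reference defaults to the shortest elongation class. Returns a
    frame with (length, state, delta5, delta3) where delta5/delta3 are the
    extra nucleotides protected at the 5' and 3' ends relative to the
    reference elongation footprint.
    """
    t = geometry.table
    if reference is None:
        elong = t[t["state"] == "elongation"]
        if elong.empty:
            raise ValueError("no elongation reference class available")
        reference = (int(elong["length"].min()), "elongation")
    try:
        ref_l5, ref_l3 = geometry.get(*reference)
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    rows = []
    for r in t.itertuples(index=False):
        rows.append({"length": int(r.length), "state": r.state,
                     "delta5": int(r.L5) - ref_l5, "delta3": int(r.L3) - ref_l3})
    return pd.DataFrame(rows)
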