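"""Selection of credibly translated coding regions.

A candidate coding region is retained when it carries enough in-frame
footprint support: at least ``min_reads`` reads of the focal length class
in the expected phase (default fifty), mapping to at least
``min_locations`` distinct 5'-end positions (default ten). Highly
translated regions shed enough out-of-phase reads that overlapping,
out-of-phase candidates can clear those counts; candidates whose maximal
phase is not the expected phase are therefore additionally required to
show an expected:maximal read ratio significantly exceeding the ratio
pooled over all supported regions (Pearson chi-square on a 2x2 table,
df=1, significance threshold 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .framing import FrameCall
from .model import ReadStore
from .orfs import OrfCandidate

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for coding-region selection.

    ``focal_length`` defaults to the predominant length class from the
    frame call when left ``None``. ``always_test`` applies the phase-
    consistency test to every candidate rather than only to those whose
    maximal phase differs from the expected phase.
    """

    min_reads: int = 50
    min_locations: int = 10
    focal_length: Optional[int] = None
    alpha: float = 0.05
    always_test: bool = False
    continuity_correction: bool = False

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_locations < 1:
            raise ValueError("min_reads and min_locations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def support_counts(
    candidate: OrfCandidate,
    store: ReadStore,
    focal_length: int,
    expected_phase: int,
) -> tuple[int, int, np.ndarray]:
    """In-frame support for one candidate.

    Counts focal-length reads wholly contained in the candidate interval.
    Returns ``(reads_in_frame, distinct_locations, per_phase_counts)``
    where phase is relative to the candidate's own start, reads_in_frame
    is the expected-phase count, and distinct_locations the number of
    unique 5'-end positions among expected-phase reads.
    """
    df = store.df
    sub = df[(df["transcript_id"] == candidate.transcript_id)
             & (df["length"] == focal_length)
             & (df["five_prime"] >= candidate.start)
             & (df["five_prime"] + df["length"] <= candidate.end)]
    if sub.empty:
        return 0, 0, np.zeros(3, dtype=int)
    phases = ((sub["five_prime"] - candidate.start) % 3).astype(int)
    per_phase = np.zeros(3, dtype=int)
    for ph, w in zip(phases, sub["weight"]):
        per_phase[ph] += int(w)
    in_frame = sub[phases == expected_phase]
    reads_in_frame = int(in_frame["weight"].sum())
    distinct = int(in_frame["five_prime"].nunique())
    return reads_in_frame, distinct, per_phase


def phase_consistency_test(
    candidate_counts: Sequence[int],
    global_counts: Sequence[int],
    alpha: float = 0.05,
    continuity_correction: bool = False,
) -> tuple[float, float, bool]:
    """Pearson chi-square comparison of expected:maximal phase ratios.

    ``candidate_counts`` and ``global_counts`` are (expected-phase,
    maximal-phase) read counts for the candidate and pooled over all
    supported coding regions. Passes only when the candidate's
    expected:maximal ratio exceeds the global ratio *and* the 2x2 Pearson
    chi-square (df=1) is significant at ``alpha``.
    """
    ce, cm = (int(x) for x in candidate_counts)
    ge, gm = (int(x) for x in global_counts)
    if ge + gm == 0:
        raise ValueError("global phase counts are all zero; cannot normalize")
    table = np.array([[ce, cm], [ge, gm]], dtype=float)
    if table[0].sum() == 0:
        return 0.0, 1.0, False
    if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    # direction: candidate enriched for the expected phase relative to global
    enriched = ce * gm > cm * ge
    return float(chi2), float(p), bool(enriched and p < alpha)


@dataclass
class FilterReport:
    """Per-candidate filtering outcome plus run provenance."""

    table: pd.DataFrame
    config: FilterConfig
    expected_phase: int
    focal_length: int
    global_counts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=int))

    def passing(self) -> list[OrfCandidate]:
        return [c for c, ok in zip(self.table["candidate"], self.table["pass"]) if ok]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["transcript_id"] = [c.transcript_id for c in df["candidate"]]
        df["start"] = [c.start for c in df["candidate"]]
        df["end"] = [c.end for c in df["candidate"]]
        cols = ["transcript_id", "start", "end", "reads_in_frame", "distinct_locations",
                "maximal_phase", "expected_phase", "chi2_statistic", "p_value",
                "pass", "failure_reason"]
        df[cols].to_csv(path, sep="\t", index=False)


def filter_cds(
    candidates: Iterable[OrfCandidate],
    store: ReadStore,
    config: FilterConfig,
    frame_call: Optional[FrameCall] = None,
) -> FilterReport:
    """Apply count, location and phase-consistency filters to candidates.

    The focal length and expected phase default to the predominant length
    class and its called phase. Global reference counts for the phase test
    are pooled over candidates that pass the count/location filters, which
    avoids conditioning the reference on the test's own outcome.
    """
    candidates = list(candidates)
    if config.focal_length is not None:
        focal_length = config.focal_length
        expected_phase = (frame_call.phase_of(focal_length)
                          if frame_call is not None and focal_length in frame_call.table.index
                          else 0)
    elif frame_call is not None:
        focal_length = frame_call.predominant_length
        expected_phase = frame_call.phase_of(focal_length)
    else:
        raise ValueError("filter_cds needs a focal_length in config or a frame call")

    rows = []
    for cand in candidates:
        rif, nloc, per_phase = support_counts(cand, store, focal_length, expected_phase)
        rows.append({"candidate": cand, "reads_in_frame": rif, "distinct_locations": nloc,
                     "per_phase": per_phase})

    counts_ok = [r["reads_in_frame"] >= config.min_reads
                 and r["distinct_locations"] >= config.min_locations for r in rows]
    global_counts = np.zeros(3, dtype=int)
    for r, ok in zip(rows, counts_ok):
        if ok:
            global_counts += r["per_phase"]
    logger.info("filter_cds: global phase counts pooled over %d count-passing candidates: %s",
                sum(counts_ok), global_counts.tolist())

    out = []
    for r, ok in zip(rows, counts_ok):
        per_phase = r["per_phase"]
        maximal_phase = int(np.argmax(per_phase))
        chi2 = np.nan
        p = np.nan
        reason = ""
        passed = True
        if r["reads_in_frame"] < config.min_reads:
            passed, reason = False, "min_reads"
        elif r["distinct_locations"] < config.min_locations:
            passed, reason = False, "min_locations"
        elif (maximal_phase != expected_phase or config.always_test) and global_counts.sum() > 0:
            cand_pair = (per_phase[expected_phase], per_phase[maximal_phase])
            glob_pair = (global_counts[expected_phase], global_counts[maximal_phase])
            if maximal_phase == expected_phase:
                # always_test on a concordant candidate: compare against the
                # strongest competing phase instead
                competing = int(np.argsort(per_phase)[-2])
                cand_pair = (per_phase[expected_phase], per_phase[competing])
                glob_pair = (global_counts[expected_phase], global_counts[competing])
            chi2, p, ok_phase = phase_consistency_test(
                cand_pair, glob_pair, config.alpha, config.continuity_correction)
            if not ok_phase:
                passed, reason = False, "phase_consistency"
        out.append({"candidate": r["candidate"], "reads_in_frame": r["reads_in_frame"],
                    "distinct_locations": r["distinct_locations"],
                    "maximal_phase": maximal_phase, "expected_phase": expected_phase,
                    "chi2_statistic": chi2, "p_value": p,
                    "pass": passed, "failure_reason": reason})
    table = pd.DataFrame(out)
    return FilterReport(table=table, config=config, expected_phase=expected_phase,
                        focal_length=focal_length, global_counts=global_counts)
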