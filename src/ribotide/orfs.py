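"""De novo ORF discovery and classification.

An ORF candidate runs from a canonical start codon (ATG by default; near-
cognate starts can be allowed by configuration) to the nearest downstream
in-frame stop (TAG, TAA, TGA), stop codon included in the interval. Nested
in-frame starts sharing a stop yield distinct candidates. Codons containing
N never match start or stop.

Classification of a candidate relative to a designated main CDS follows the
standard uORF vocabulary: uORF (entirely within the 5' leader),
overlapping uORF (starts in the leader, overlaps the main start out of
frame), internal overlapping ORF (contained within the main CDS, different
frame), dORF (entirely 3' of the main stop), and readthrough extension
(in frame, beginning at the main stop codon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import Transcript

STOP_CODONS = ("TAG", "TAA", "TGA")
START_CODONS = ("ATG",)

RELATIONS = (
    "main",
    "uORF",
    "overlapping_uORF",
    "internal_overlapping",
    "dORF",
    "readthrough_extension",
    "other",
)


@dataclass(frozen=True)
class OrfCandidate:
    """A candidate coding region in transcript coordinates (stop included)."""

    transcript_id: str
    start: int
    end: int
    start_codon: str = "ATG"
    provenance: str = "de_novo"  # or "annotated"

    @property
    def frame(self) -> int:
        """Reading frame relative to transcript nt 1 (position 0)."""
        return self.start % 3

    @property
    def codon_length(self) -> int:
        """Number of sense codons, stop codon excluded."""
        return (self.end - self.start) // 3 - 1

    def validate(self, transcript: Optional[Transcript] = None) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"ORF span {self.start}-{self.end} not a multiple of 3")
        if self.end - self.start < 6:
            raise ValueError("ORF must contain at least one sense codon plus a stop")
        if transcript is not None:
            if not (0 <= self.start < self.end <= len(transcript)):
                raise ValueError(f"ORF {self.start}-{self.end} out of bounds on {transcript.id}")
            if self.provenance == "de_novo":
                stop = transcript.sequence[self.end - 3:self.end]
                if stop not in STOP_CODONS:
                    raise ValueError(f"de novo ORF ends in {stop!r}, not a stop codon")


@dataclass(frozen=True)
class OrfClassification:
    relation: str
    codon_length: int


def scan_orfs(
    transcript: Transcript,
    min_codons: int = 1,
    start_codons: Sequence[str] = START_CODONS,
) -> list[OrfCandidate]:
    """Scan all three frames for start..in-frame-stop ORFs.

    Every start codon is paired with the nearest downstream in-frame stop;
    starts with no in-frame stop are omitted. Output is ordered by start
    position. ``min_codons`` counts sense codons (stop excluded).
    """
    seq = transcript.sequence
    starts = set(c.upper().replace("U", "T") for c in start_codons)
    found: list[OrfCandidate] = []
    for frame in range(3):
        open_starts: list[tuple[int, str]] = []
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                for s, sc in open_starts:
                    if (pos + 3 - s) // 3 - 1 >= min_codons:
                        found.append(OrfCandidate(transcript.id, s, pos + 3, start_codon=sc))
                open_starts.clear()
            elif codon in starts:
                open_starts.append((pos, codon))
    return sorted(found, key=lambda o: (o.start, o.end))


def annotated_candidates(transcriptome) -> list[OrfCandidate]:
    """Wrap annotated CDS intervals as candidates with provenance 'annotated'."""
    out = []
    for t in transcriptome.values():
        if t.cds is not None:
            start, end = t.cds
            out.append(OrfCandidate(t.id, start, end,
                                    start_codon=t.sequence[start:start + 3],
                                    provenance="annotated"))
    return out


def match_annotation(
    de_novo_pass: Iterable[OrfCandidate],
    annotated_pass: Iterable[OrfCandidate],
    n_annotated_total: Optional[int] = None,
) -> dict[str, float]:
    """Compare filtered de novo candidates against filtered annotated CDSs.

    Recovery means some de novo candidate shares the annotated CDS's stop
    (same transcript, same ``end``, same frame); an exact match shares the
    start as well. Returns the recovered fraction, the exact-match fraction
    among recovered, and (when ``n_annotated_total`` is given) the fraction
    of all annotated CDSs that passed filtering.
    """
    annotated_pass = list(annotated_pass)
    de_novo_by_stop = {}
    de_novo_starts: dict[tuple[str, int, int], set[int]] = {}
    for c in de_novo_pass:
        key = (c.transcript_id, c.end, c.frame)
        de_novo_by_stop[key] = True
        de_novo_starts.setdefault(key, set()).add(c.start)
    recovered = 0
    exact = 0
    for a in annotated_pass:
        key = (a.transcript_id, a.end, a.frame)
        if key in de_novo_by_stop:
            recovered += 1
            if a.start in de_novo_starts[key]:
                exact += 1
    n_ann = len(annotated_pass)
    return {
        "recovered_fraction": recovered / n_ann if n_ann else float("nan"),
        "exact_fraction": exact / recovered if recovered else float("nan"),
        "annotated_pass_fraction": (
            n_ann / n_annotated_total if n_annotated_total else float("nan")
        ),
        "n_annotated_pass": n_ann,
        "n_recovered": recovered,
        "n_exact": exact,
    }


def classify_relative(candidate: OrfCandidate, main_cds: OrfCandidate) -> OrfClassification:
    """Classify a candidate ORF relative to the designated main CDS.

    Total over valid inputs: every candidate receives exactly one relation;
    configurations outside the standard vocabulary fall back to "other".
    """
    if candidate.transcript_id != main_cds.transcript_id:
        raise ValueError(
            f"candidate on {candidate.transcript_id!r} but main CDS on "
            f"{main_cds.transcript_id!r}"
        )
    c, m = candidate, main_cds
    same_frame = c.frame == m.frame
    if (c.start, c.end) == (m.start, m.end):
        relation = "main"
    elif c.end <= m.start:
        relation = "uORF"
    elif c.start < m.start and c.end > m.start and not same_frame:
        relation = "overlapping_uORF"
    elif m.start <= c.start and c.end <= m.end and not same_frame:
        relation = "internal_overlapping"
    elif c.start >= m.end:
        relation = "dORF"
    elif same_frame and c.start == m.end - 3:
        relation = "readthrough_extension"
    else:
        relation = "other"
    return OrfClassification(relation=relation, codon_length=c.codon_length)


def write_candidates_tsv(candidates: Iterable[OrfCandidate], path) -> None:
    """3-column CDS TSV that round-trips through the annotation reader."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.transcript_id}\t{c.start}\t{c.end}\n")


def write_candidates_bed(candidates: Iterable[OrfCandidate], path) -> None:
    """BED in transcript space, one line per candidate."""
    with open(path, "w") as fh:
        for c in candidates:
            name = f"{c.provenance}:{c.start_codon}"
            fh.write(f"{c.transcript_id}\t{c.start}\t{c.end}\t{name}\t0\t+\n")
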