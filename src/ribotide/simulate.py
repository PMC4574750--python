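"""Synthetic transcriptomes and footprint/RNA-seq read simulation.

The generator plants known ORF structures (main CDS, uORFs, overlapping
uORFs) into random transcripts and emits footprints with configurable
geometry so every pipeline stage can be checked against ground truth:

* elongation footprints place the P-site uniformly over sense codons
  (with an elevated density at the initiation codon, as real libraries
  show), with 5' end = P-site first nt - L5 and length drawn from the
  preset's mixture;
* termination footprints pause with the stop codon in the A-site at a
  configurable multiple of the interior density, and are 1-2 nt larger
  than elongation footprints, mirroring the release-factor-bound state;
* phase fidelity f < 1 jitters the 5' end by +/-1 nt with probability
  (1-f)/2 each side, emulating imperfect nuclease trimming;
* rRNA contaminant reads are drawn uniformly from designated rRNA
  transcripts, and RNA-seq reads uniformly over transcripts.

Two presets encode the published footprint geometries: ``cr-27``
(Chlamydomonas-like, 27-28 nt footprints, 27-nt class protecting 11 nt 5'
of the P-site codon and 10 nt 3' of the A-site codon) and ``mm-29``
(mouse-like, 28-30 nt footprints, 29-nt class protecting 12 and 11 nt).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .model import MappedRead, ReadStore, Transcript, Transcriptome

STOPS = ("TAG", "TAA", "TGA")


# ------------------------------------------------------------------ presets

@dataclass
class GeometryPreset:
    """Footprint geometry and mixture for one simulated organism/protocol.

    ``elongation`` and ``termination`` map length class n -> (L5, L3,
    mixture weight), with L5 + 6 + L3 = n for every entry. ``fidelity`` is
    the probability that a 5' end lands exactly in phase. ``pause_factor``
    is the termination-site density relative to one interior codon;
    ``init_factor`` likewise for the initiation codon.
    """

    name: str
    elongation: dict[int, tuple[int, int, float]]
    termination: dict[int, tuple[int, int, float]]
    fidelity: float = 0.95
    pause_factor: float = 5.0
    init_factor: float = 3.0

    def __post_init__(self) -> None:
        for state, classes in (("elongation", self.elongation),
                               ("termination", self.termination)):
            total = 0.0
            for n, (l5, l3, w) in classes.items():
                if l5 + 6 + l3 != n:
                    raise ValueError(
                        f"{self.name}/{state}/{n}: L5+6+L3 = {l5 + 6 + l3} != {n}")
                if l5 < 0 or l3 < 0 or w < 0:
                    raise ValueError(f"{self.name}/{state}/{n}: negative parameter")
                total += w
            if classes and abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.name}/{state}: mixture weights sum to {total}")
        if not (1 / 3 < self.fidelity <= 1):
            raise ValueError("fidelity must lie in (1/3, 1]")


CR27 = GeometryPreset(
    name="cr-27",
    # 27-nt elongation footprints protect 11 nt 5' of the P-site codon and
    # 10 nt 3' of the A-site codon; 28-nt elongation adds 1 nt at the 5' end
    elongation={27: (11, 10, 0.75), 28: (12, 10, 0.25)},
    # termination footprints add 1 nt (28) or 1 nt each end (29)
    termination={28: (11, 11, 0.6), 29: (12, 11, 0.4)},
)

MM29 = GeometryPreset(
    name="mm-29",
    # 29-nt class protects 12 nt 5' of the P-site codon, 11 nt 3' of the A-site
    elongation={28: (11, 11, 0.2), 29: (12, 11, 0.65), 30: (13, 11, 0.15)},
    # termination adds a nucleotide at the 3' end
    termination={29: (12, 11, 0.3), 30: (12, 12, 0.7)},
)

PRESETS = {"cr-27": CR27, "mm-29": MM29}


def get_preset(name: str) -> GeometryPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ------------------------------------------------------------- transcriptome

@dataclass
class SimConfig:
    """Shape of the synthetic transcriptome."""

    n_transcripts: int = 100
    cds_codons: tuple[int, int] = (60, 250)     # sense codons incl. start, excl. stop
    utr5: tuple[int, int] = (30, 70)
    utr3: tuple[int, int] = (30, 90)
    gc: float = 0.5
    uorf_prob: float = 0.2
    uorf_codons: tuple[int, int] = (3, 20)
    overlap_prob: float = 0.1
    n_rrna: int = 2
    rrna_length: int = 1200


@dataclass
class OrfTruth:
    start: int
    end: int                      # stop codon included
    level: float
    kind: str = "main"            # main | uORF | overlapping_uORF


@dataclass
class TranscriptTruth:
    orfs: list[OrfTruth]
    rna_level: float

    @property
    def main(self) -> OrfTruth:
        return next(o for o in self.orfs if o.kind == "main")


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated data set."""

    transcripts: dict[str, TranscriptTruth]
    rrna_ids: list[str]
    contamination: float
    seed: int
    config: SimConfig = field(default_factory=SimConfig)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "contamination": self.contamination,
            "rrna_ids": self.rrna_ids,
            "config": asdict(self.config),
            "transcripts": {
                tid: {"rna_level": t.rna_level,
                      "orfs": [asdict(o) for o in t.orfs]}
                for tid, t in self.transcripts.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        transcripts = {
            tid: TranscriptTruth(
                orfs=[OrfTruth(**o) for o in spec["orfs"]],
                rna_level=spec["rna_level"],
            )
            for tid, spec in payload["transcripts"].items()
        }
        return cls(transcripts=transcripts, rrna_ids=payload["rrna_ids"],
                   contamination=payload["contamination"], seed=payload["seed"],
                   config=SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                       for k, v in payload["config"].items()}))


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=_base_probs(gc))


_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = np.array([c for c in _ALL_CODONS if c not in STOPS])


def _sense_codon_probs(gc: float) -> np.ndarray:
    bp = dict(zip("ACGT", _base_probs(gc)))
    w = np.array([bp[c[0]] * bp[c[1]] * bp[c[2]] for c in _SENSE_CODONS])
    return w / w.sum()


def _random_orf_seq(rng: np.random.Generator, sense_codons: int, gc: float) -> str:
    """ATG + (sense_codons - 1) random non-stop codons + a random stop."""
    probs = _sense_codon_probs(gc)
    body = rng.choice(_SENSE_CODONS, size=sense_codons - 1, p=probs)
    stop = rng.choice(np.array(STOPS))
    return "ATG" + "".join(body) + stop


def make_transcriptome(config: SimConfig, seed: int) -> tuple[Transcriptome, SimTruth]:
    """Generate a transcriptome with planted ORFs and its ground truth.

    Planted ORFs start with ATG, end with an in-frame canonical stop, and
    contain no premature in-frame stop. uORFs sit wholly in the 5' leader;
    overlapping uORFs start in the leader out of frame with the main CDS
    and run to the first natural in-frame stop inside it (skipped when the
    leader sequence does not cooperate). Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    transcripts = []
    truth: dict[str, TranscriptTruth] = {}

    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        utr5 = int(rng.integers(config.utr5[0], config.utr5[1] + 1))
        utr3 = int(rng.integers(config.utr3[0], config.utr3[1] + 1))
        cds_len = 3 * n_codons + 3
        if cds_len + 6 > cds_len + utr5 + utr3:
            raise ValueError("infeasible transcript constraints")
        leader = _random_bases(rng, utr5, config.gc)
        cds_seq = _random_orf_seq(rng, n_codons, config.gc)
        trailer = _random_bases(rng, utr3, config.gc)
        seq = np.array(list("".join(leader) + cds_seq + "".join(trailer)))
        start, end = utr5, utr5 + cds_len

        orfs = [OrfTruth(start, end, level=float(rng.lognormal(0.0, 1.0)), kind="main")]

        # plain uORFs, 5'-most region of the leader
        cursor = 0
        if rng.random() < config.uorf_prob:
            k = int(rng.integers(config.uorf_codons[0], config.uorf_codons[1] + 1))
            span = 3 * (k + 1)
            if span + 6 <= utr5:
                s = int(rng.integers(0, utr5 - span - 3))
                useq = _random_orf_seq(rng, k, config.gc)
                seq[s:s + span] = list(useq)
                orfs.append(OrfTruth(s, s + span, level=float(rng.lognormal(-1.0, 1.0)),
                                     kind="uORF"))
                cursor = s + span

        # overlapping uORF: out-of-frame ATG late in the leader, running to
        # the first natural in-frame stop inside the CDS
        if rng.random() < config.overlap_prob and utr5 - cursor >= 12:
            frame_shift = int(rng.integers(1, 3))
            s = start - 3 * int(rng.integers(2, max(3, (utr5 - cursor) // 3))) + frame_shift
            if s >= cursor:
                seq[s:s + 3] = list("ATG")
                # clear stops in the leader part of this frame
                p = s + 3
                while p + 3 <= start:
                    if "".join(seq[p:p + 3]) in STOPS:
                        seq[p:p + 3] = list("GCT")
                    p += 3
                # find the first in-frame stop from p onward (inside the CDS)
                stop_at = None
                q = p
                while q + 3 <= len(seq):
                    if "".join(seq[q:q + 3]) in STOPS:
                        stop_at = q
                        break
                    q += 3
                if stop_at is not None and stop_at + 3 > start and stop_at + 3 <= end:
                    orfs.append(OrfTruth(s, stop_at + 3,
                                         level=float(rng.lognormal(-1.0, 1.0)),
                                         kind="overlapping_uORF"))
                else:
                    seq[s:s + 3] = _random_bases(rng, 3, config.gc)

        transcripts.append(Transcript(tid, "".join(seq), cds=(start, end), category="mRNA"))
        truth[tid] = TranscriptTruth(orfs=orfs, rna_level=float(rng.lognormal(0.0, 1.0)))

    rrna_ids = []
    for j in range(config.n_rrna):
        rid = f"rrna{j:02d}"
        rrna_ids.append(rid)
        transcripts.append(Transcript(
            rid, "".join(_random_bases(rng, config.rrna_length, config.gc + 0.05)),
            category="rRNA"))

    transcriptome = Transcriptome.from_transcripts(transcripts)
    sim_truth = SimTruth(transcripts=truth, rrna_ids=rrna_ids,
                         contamination=0.1, seed=seed, config=config)
    return transcriptome, sim_truth


# ------------------------------------------------------------------- reads

def simulate_footprints(
    transcriptome: Transcriptome,
    truth: SimTruth,
    preset: GeometryPreset,
    n_reads: int,
    seed: int,
    sample: str = "ribo",
    contamination: Optional[float] = None,
) -> ReadStore:
    """Draw ribosome footprints (plus rRNA contaminants) as a ReadStore.

    P-sites are uniform over sense codons of every planted ORF weighted by
    its translation level, with the initiation codon and the termination
    site (stop codon in the A-site) elevated by the preset's factors.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    contamination = truth.contamination if contamination is None else contamination

    tids, site_pos, site_term, site_w = [], [], [], []
    tid_index: dict[str, int] = {}
    tlen = []
    for tid, ttruth in truth.transcripts.items():
        if tid not in tid_index:
            tid_index[tid] = len(tid_index)
            tlen.append(len(transcriptome[tid]))
        ti = tid_index[tid]
        for orf in ttruth.orfs:
            m = (orf.end - orf.start) // 3 - 1  # sense codons
            # elongation needs a sense codon in the A-site: P-site runs over
            # codons 0..m-2; P-site = last sense codon IS the termination state
            for i in range(m - 1):
                tids.append(ti)
                site_pos.append(orf.start + 3 * i)
                site_term.append(False)
                site_w.append(orf.level * (preset.init_factor if i == 0 else 1.0))
            # termination: stop codon in the A-site, P-site on the last sense codon
            tids.append(ti)
            site_pos.append(orf.end - 6)
            site_term.append(True)
            site_w.append(orf.level * preset.pause_factor)
    index_tid = {v: k for k, v in tid_index.items()}
    site_tid = np.array(tids)
    site_pos = np.array(site_pos)
    site_term = np.array(site_term)
    site_w = np.array(site_w, dtype=float)
    site_w /= site_w.sum()
    tlen = np.array(tlen)

    n_rrna = rng.binomial(n_reads, contamination) if truth.rrna_ids and contamination > 0 else 0
    n_mrna = n_reads - n_rrna

    e_lengths = np.array(sorted(preset.elongation))
    e_l5 = np.array([preset.elongation[n][0] for n in e_lengths])
    e_w = np.array([preset.elongation[n][2] for n in e_lengths])
    t_lengths = np.array(sorted(preset.termination))
    t_l5 = np.array([preset.termination[n][0] for n in t_lengths])
    t_w = np.array([preset.termination[n][2] for n in t_lengths])
    f = preset.fidelity
    jitter_vals = np.array([-1, 0, 1])
    jitter_p = np.array([(1 - f) / 2, f, (1 - f) / 2])

    def draw(k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = rng.choice(len(site_w), size=k, p=site_w)
        term = site_term[idx]
        lengths = np.empty(k, dtype=int)
        l5 = np.empty(k, dtype=int)
        if (~term).any():
            ci = rng.choice(len(e_lengths), size=int((~term).sum()), p=e_w)
            lengths[~term] = e_lengths[ci]
            l5[~term] = e_l5[ci]
        if term.any():
            ci = rng.choice(len(t_lengths), size=int(term.sum()), p=t_w)
            lengths[term] = t_lengths[ci]
            l5[term] = t_l5[ci]
        fp = site_pos[idx] - l5 + rng.choice(jitter_vals, size=k, p=jitter_p)
        return site_tid[idx], fp, lengths

    tid_arr = np.empty(n_mrna, dtype=int)
    fp_arr = np.empty(n_mrna, dtype=int)
    len_arr = np.empty(n_mrna, dtype=int)
    pending = np.arange(n_mrna)
    for _ in range(200):
        if len(pending) == 0:
            break
        ti, fp, ln = draw(len(pending))
        ok = (fp >= 0) & (fp + ln <= tlen[ti])
        tid_arr[pending[ok]] = ti[ok]
        fp_arr[pending[ok]] = fp[ok]
        len_arr[pending[ok]] = ln[ok]
        pending = pending[~ok]
    if len(pending):
        raise RuntimeError("could not place all footprints; UTRs too short for preset")

    rows = {
        "transcript_id": [index_tid[t] for t in tid_arr],
        "five_prime": fp_arr,
        "length": len_arr,
    }

    if n_rrna:
        r_ids = [truth.rrna_ids[i] for i in rng.integers(len(truth.rrna_ids), size=n_rrna)]
        r_len = e_lengths[rng.choice(len(e_lengths), size=n_rrna, p=e_w)]
        r_fp = np.array([rng.integers(0, len(transcriptome[rid]) - ln + 1)
                         for rid, ln in zip(r_ids, r_len)])
        rows["transcript_id"] = rows["transcript_id"] + r_ids
        rows["five_prime"] = np.concatenate([rows["five_prime"], r_fp])
        rows["length"] = np.concatenate([rows["length"], r_len])

    df = pd.DataFrame(rows)
    df["sample"] = sample
    df["weight"] = 1
    return ReadStore(df, seed=seed)


def simulate_rna(
    transcriptome: Transcriptome,
    truth: SimTruth,
    n_reads: int,
    seed: int,
    sample: str = "rna",
    read_length: int = 30,
) -> ReadStore:
    """Uniform-coverage RNA-seq reads (alkaline-fragmentation-like model)."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    tids = [tid for tid in truth.transcripts if len(transcriptome[tid]) > read_length]
    w = np.array([truth.transcripts[t].rna_level * len(transcriptome[t]) for t in tids])
    w /= w.sum()
    choice = rng.choice(len(tids), size=n_reads, p=w)
    fp = np.array([rng.integers(0, len(transcriptome[tids[c]]) - read_length + 1)
                   for c in choice])
    df = pd.DataFrame({
        "transcript_id": [tids[c] for c in choice],
        "five_prime": fp,
        "length": read_length,
        "sample": sample,
        "weight": 1,
    })
    return ReadStore(df, seed=seed)


# --------------------------------------------------------------- depletion

def simulate_depletion(
    store: ReadStore,
    survival: Union[Mapping[str, float], Callable[[str], float]],
    transcripts: Mapping[str, Transcript],
    seed: int,
) -> ReadStore:
    """Binomially thin a read store to emulate a depletion treatment.

    ``survival`` maps a transcript category (dict) or a read sequence
    (callable) to a survival probability in [0, 1]; each unit of read
    weight survives independently.
    """
    rng = np.random.default_rng(seed)
    df = store.df.copy()
    if callable(survival):
        probs = np.array([
            survival(transcripts[r.transcript_id].sequence[r.five_prime:r.five_prime + r.length])
            for r in df.itertuples(index=False)])
    else:
        cats = {tid: t.category for tid, t in transcripts.items()}
        probs = df["transcript_id"].map(cats).map(survival).fillna(1.0).to_numpy(dtype=float)
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    new_w = rng.binomial(df["weight"].to_numpy(dtype=int), probs)
    df["weight"] = new_w
    return ReadStore(df[df["weight"] > 0].copy(), seed=seed)


def deplete_species_table(counts: pd.DataFrame, survival: Callable[[str], float],
                          seed: int, column: str = "b") -> pd.DataFrame:
    """Thin one column of a species count table by per-species survival."""
    rng = np.random.default_rng(seed)
    out = counts.copy()
    probs = np.array([survival(s) for s in out.index])
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("survival probabilities must lie in [0, 1]")
    out[column] = rng.binomial(out[column].to_numpy(dtype=int), probs)
    return out
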