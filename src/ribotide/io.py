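"""Readers and writers for the external formats the pipeline touches.

FASTA transcriptomes (via Biopython), CDS annotations as 3-column TSV
(transcript_id, start, end; 0-based half-open, stop codon included),
SAM/BAM alignments against the transcriptome (via pysam), per-read-species
property tables, and transcript category maps.

Alignments are assumed to be transcriptome-space and sense-strand:
reverse-strand and unmapped records are dropped and counted. A read whose
SAM 1-based POS is ``p`` gets ``five_prime = p - 1``. Multimapping reads
(same query name aligned to several places) are assigned uniformly at
random to one alignment under an explicit seed, or duplicated to all under
policy ``"all"`` for diagnostics.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .model import CATEGORIES, MappedRead, ReadStore, Transcript, Transcriptome

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_annotation(path: PathLike) -> dict[str, tuple[int, int]]:
    """Read a 3-column CDS annotation TSV into {transcript_id: (start, end)}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "start", "end"],
                     comment="#", dtype={"transcript_id": str})
    out: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        out[row.transcript_id] = (int(row.start), int(row.end))
    return out


def read_bed_annotation(path: PathLike) -> dict[str, tuple[int, int]]:
    """Import shim: BED (chrom, chromStart, chromEnd, ...) -> CDS intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {str(r[0]): (int(r[1]), int(r[2])) for r in df.itertuples(index=False)}


def read_transcriptome(
    fasta_path: PathLike,
    annotation_path: Optional[PathLike] = None,
    category_map: Optional[Mapping[str, str]] = None,
) -> Transcriptome:
    """Load a FASTA transcriptome, attaching CDS annotations where given.

    U is normalised to T. Duplicate ids and out-of-bounds annotation
    intervals raise ``ValueError`` naming the offending transcript.
    """
    annotation = read_annotation(annotation_path) if annotation_path else {}
    categories = dict(category_map) if category_map else {}
    transcripts = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        transcripts.append(
            Transcript(
                id=rec.id,
                sequence=str(rec.seq),
                cds=annotation.get(rec.id),
                category=categories.get(rec.id, "mRNA"),
            )
        )
    missing = set(annotation) - seen
    if missing:
        raise ValueError(f"annotation references unknown transcripts: {sorted(missing)[:5]}")
    return Transcriptome.from_transcripts(transcripts)


def write_transcriptome(transcriptome: Transcriptome, fasta_path: PathLike,
                        annotation_path: Optional[PathLike] = None) -> None:
    with open(fasta_path, "w") as fh:
        for t in transcriptome.values():
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i:i + 70] + "\n")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            for t in transcriptome.values():
                if t.cds is not None:
                    fh.write(f"{t.id}\t{t.cds[0]}\t{t.cds[1]}\n")


def read_category_map(path: PathLike) -> dict[str, str]:
    """2-column TSV (transcript_id, category) -> dict; unknown categories error."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "category"],
                     dtype=str, comment="#")
    out = {}
    for row in df.itertuples(index=False):
        if row.category not in CATEGORIES:
            raise ValueError(f"unknown category {row.category!r} for {row.transcript_id!r}")
        out[row.transcript_id] = row.category
    return out


def read_alignments(
    sam_path: PathLike,
    transcripts: Mapping[str, Transcript],
    seed: int,
    multimap_policy: str = "random",
    sample: Optional[str] = None,
    length_window: tuple[int, int] = (20, 40),
) -> tuple[ReadStore, dict[str, int]]:
    """Parse a SAM/BAM of transcriptome alignments into a :class:`ReadStore`.

    Returns ``(store, log)`` where ``log`` counts dropped record classes.
    The aligned length excludes soft clips; the 5' position anchors on the
    leftmost aligned base. Multimapping reads are resolved per
    ``multimap_policy`` ("random" assigns exactly one alignment, uniformly,
    reproducible under ``seed``; "all" keeps every alignment).
    """
    if multimap_policy not in ("random", "all"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    if sample is None:
        sample = Path(str(sam_path)).stem

    lengths = {tid: len(t) for tid, t in transcripts.items()}
    log = {"unmapped": 0, "reverse_strand": 0, "malformed": 0, "length_out_of_window": 0,
           "multimapped_reads": 0}
    # qname -> list of candidate placements
    placements: dict[str, list[tuple[str, int, int]]] = defaultdict(list)

    lo, hi = length_window
    mode = "rb" if str(sam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(sam_path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                log["unmapped"] += 1
                continue
            if rec.is_reverse:
                log["reverse_strand"] += 1
                continue
            ref = rec.reference_name
            if ref not in lengths:
                raise ValueError(f"alignment reference {ref!r} absent from transcriptome")
            try:
                aln_len = rec.query_alignment_length
                pos = rec.reference_start
            except Exception:
                log["malformed"] += 1
                continue
            if aln_len is None or aln_len <= 0:
                log["malformed"] += 1
                continue
            if not (lo <= aln_len <= hi):
                log["length_out_of_window"] += 1
                continue
            placements[rec.query_name].append((ref, pos, aln_len))

    rng = np.random.default_rng(seed)
    reads = []
    for qname in placements:  # insertion order: deterministic
        cands = placements[qname]
        if len(cands) == 1:
            chosen = cands
        elif multimap_policy == "all":
            log["multimapped_reads"] += 1
            chosen = cands
        else:
            log["multimapped_reads"] += 1
            chosen = [cands[rng.integers(len(cands))]]
        for ref, pos, aln_len in chosen:
            reads.append(MappedRead(ref, pos, aln_len, sample))
    store = ReadStore.from_reads(reads, seed=seed)
    logger.info("read_alignments(%s): kept %d reads, dropped %s", sam_path, len(store), log)
    return store, log


def write_sam(store: ReadStore, transcripts: Mapping[str, Transcript], sam_path: PathLike) -> None:
    """Write a ReadStore as a plain-text SAM aligned to the transcriptome.

    Round-trip contract: re-reading reproduces identical
    (transcript_id, five_prime, length) multisets.
    """
    ids = list(transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tid, "LN": len(transcripts[tid])} for tid in ids],
    }
    tid_index = {tid: i for i, tid in enumerate(ids)}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        i = 0
        for row in store.df.itertuples(index=False):
            seq = transcripts[row.transcript_id].sequence[row.five_prime:row.five_prime + row.length]
            for _ in range(int(row.weight)):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i:09d}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = tid_index[row.transcript_id]
                a.reference_start = int(row.five_prime)
                a.mapping_quality = 255
                a.cigarstring = f"{int(row.length)}M"
                out.write(a)
                i += 1


def read_property_table(tsv_path: PathLike) -> pd.DataFrame:
    """Read a per-read-species property table (species, property, value).

    Returns a wide frame indexed by species sequence, one column per
    property. Non-numeric values raise with the offending line number.
    """
    df = pd.read_csv(tsv_path, sep="\t", header=None,
                     names=["species", "property", "value"], dtype=str, comment="#")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise ValueError(f"non-numeric property value at line {line}: {df['value'][bad.idxmax()]!r}")
    df["value"] = values
    return df.pivot_table(index="species", columns="property", values="value", aggfunc="first")


def lookup_property(table: pd.DataFrame, species: str, prop: str):
    """Value for one species/property, or ``None`` when absent (never zero)."""
    if species not in table.index or prop not in table.columns:
        return None
    v = table.at[species, prop]
    return None if pd.isna(v) else float(v)


def property_coverage(table: pd.DataFrame, species: list[str], prop: str) -> float:
    """Fraction of queried species that have a value for ``prop``."""
    if not species:
        return float("nan")
    have = [s for s in species if s in table.index and not pd.isna(table.at[s, prop])] \
        if prop in table.columns else []
    return len(have) / len(species)
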