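import numpy as np
import pandas as pd
import pytest

from ribotide.framing import frame_call, interior_reads, phase_by_length
from ribotide.model import MappedRead, ReadStore, Transcript, Transcriptome
from ribotide.simulate import CR27, SimConfig, make_transcriptome, simulate_footprints


@pytest.fixture
def tiny_transcriptome():
    """Three hand-made transcripts with known CDS structure."""
    return Transcriptome.from_transcripts([
        # 12 nt leader, 30 nt CDS (9 sense codons + stop), 12 nt trailer
        Transcript("txA", "GCGCGCGCGCGC" + "ATG" + "GCT" * 8 + "TAA" + "ACACACACACAC",
                   cds=(12, 42)),
        Transcript("txB", "A" * 10 + "ATG" + "CCT" * 20 + "TGA" + "G" * 20,
                   cds=(10, 76)),
        Transcript("rrnaX", "GC" * 50, category="rRNA"),
    ])


def make_store(reads, seed=None):
    return ReadStore.from_reads(reads, seed=seed)


@pytest.fixture(scope="session")
def cr_sim():
    """A Chlamydomonas-like simulated data set shared across tests."""
    transcriptome, truth = make_transcriptome(SimConfig(), seed=101)
    store = simulate_footprints(transcriptome, truth, CR27, 80_000, seed=102)
    return transcriptome, truth, store


@pytest.fixture(scope="session")
def cr_frame_call(cr_sim):
    transcriptome, _, store = cr_sim
    interior = interior_reads(store, transcriptome.cds_map())
    return frame_call(phase_by_length(interior))
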