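import numpy as np
import pytest

from ribotide.filtering import FilterConfig
from ribotide.framing import frame_call, interior_reads, phase_by_length
from ribotide.metagene import infer_offsets, metagene_profile, \
    select_metagene_transcripts, termination_extension, FootprintGeometry
from ribotide.model import MappedRead, ReadStore
from ribotide.simulate import CR27, GeometryPreset, SimConfig, make_transcriptome, \
    simulate_footprints

import pandas as pd


def uniform_cds_store(tx="tx", start=30, end=330, length=27, per_site=2):
    """Every in-CDS 5' position occupied equally."""
    reads = []
    for p in range(start, end):
        reads += [MappedRead(tx, p, length, "s")] * per_site
    return ReadStore.from_reads(reads)


class TestSelectTranscripts:
    def test_selection_by_construction(self, cr_sim, cr_frame_call):
        """With 12 well-covered CDSs constructed explicitly, exactly 12 are
        selected."""
        reads = []
        cds_map = {}
        for i in range(12):
            tx = f"good{i}"
            cds_map[tx] = (0, 300)
            reads += [MappedRead(tx, 3 * (j % 20), 27, "s") for j in range(60)]
        for i in range(5):
            tx = f"weak{i}"
            cds_map[tx] = (0, 300)
            reads += [MappedRead(tx, 3 * (j % 20), 27, "s") for j in range(30)]
        store = ReadStore.from_reads(reads)
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        sel = select_metagene_transcripts(store, cds_map, call)
        assert sorted(sel) == sorted(f"good{i}" for i in range(12))

    def test_out_of_frame_reads_do_not_count(self):
        cds_map = {"tx": (0, 300)}
        # 200 reads, all phase 1 while the (degenerate) call expects phase 1;
        # then shift the probe CDS so they are out of frame for it
        reads = [MappedRead("tx", 1 + 3 * (j % 20), 27, "s") for j in range(200)]
        store = ReadStore.from_reads(reads)
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        assert call.phase_of(27) == 1
        shifted_map = {"tx": (2, 299)}  # expected phase 1 rel. start 2 = abs pos 3k
        sel = select_metagene_transcripts(store, shifted_map, call)
        assert sel == []


class TestMetageneProfile:
    def test_uniform_density_is_flat_at_one(self):
        store = uniform_cds_store()
        prof = metagene_profile(store, {"tx": (30, 330)}, ["tx"], 27)
        interior = (prof.start_offsets >= 0) & (prof.start_offsets <= 60)
        assert np.allclose(prof.start_profile[interior], 1.0)

    def test_depth_invariance(self):
        """Two CDSs with identical shape but 10x different depth contribute
        identically; the profile equals the single-CDS profile."""
        r1 = uniform_cds_store("t1", per_site=1)
        r10 = uniform_cds_store("t2", per_site=10)
        both = ReadStore(pd.concat([r1.df, r10.df], ignore_index=True))
        cds = {"t1": (30, 330), "t2": (30, 330)}
        prof_both = metagene_profile(both, cds, ["t1", "t2"], 27)
        prof_one = metagene_profile(r1, {"t1": (30, 330)}, ["t1"], 27)
        assert np.allclose(prof_both.start_profile, prof_one.start_profile)

    def test_scaling_one_cds_leaves_profile_unchanged(self):
        """Weighting invariance: multiplying one CDS's counts by any
        positive constant does not move the metagene."""
        r1 = uniform_cds_store("t1", per_site=1)
        r2 = uniform_cds_store("t2", per_site=1)
        both = ReadStore(pd.concat([r1.df, r2.df], ignore_index=True))
        scaled_df = pd.concat([r1.df, r2.df.assign(weight=7)], ignore_index=True)
        cds = {"t1": (30, 330), "t2": (30, 330)}
        a = metagene_profile(both, cds, ["t1", "t2"], 27)
        b = metagene_profile(ReadStore(scaled_df), cds, ["t1", "t2"], 27)
        assert np.allclose(a.start_profile, b.start_profile)
        assert np.allclose(a.stop_profile, b.stop_profile)

    def test_periodicity_and_stop_peak_from_generator(self):
        """With 3-periodic placement and a termination pause, the profile
        shows period-3 structure and a stop-proximal maximum."""
        tr, truth = make_transcriptome(SimConfig(n_transcripts=40), seed=21)
        store = simulate_footprints(tr, truth, CR27, 60_000, seed=22, contamination=0.0)
        cds_map = tr.cds_map()
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        sel = select_metagene_transcripts(store, cds_map, call)
        prof = metagene_profile(store, cds_map, sel, 27)
        interior = prof.start_profile[(prof.start_offsets >= 10)
                                      & (prof.start_offsets <= 58)]
        lags = {k: np.corrcoef(interior[:-k], interior[k:])[0, 1] for k in (1, 2, 3)}
        assert lags[3] > lags[1] and lags[3] > lags[2]
        # termination footprints are 28/29 nt: their stop-window peak dwarfs
        # the interior of that class's profile
        prof28 = metagene_profile(store, cds_map, sel, 28)
        peak = prof28.stop_profile.max()
        interior28 = prof28.stop_profile[prof28.stop_offsets < -31]
        assert peak > 3 * interior28.mean()


class TestInferOffsets:
    def test_published_geometries_recovered(self, cr_sim):
        transcriptome, _, store = cr_sim
        cds_map = transcriptome.cds_map()
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        sel = select_metagene_transcripts(store, cds_map, call)
        profs = [metagene_profile(store, cds_map, sel, n) for n in (27, 28)]
        geo = infer_offsets(profs)
        assert geo.get(27, "elongation") == (11, 10)
        assert geo.get(28, "elongation") == (12, 10)
        assert geo.get(28, "termination") == (11, 11)

    def test_arbitrary_geometry_recovered(self):
        """Parameter recovery: a custom preset with (L5, L3) = (13, 9) at
        n=28 is inferred exactly."""
        preset = GeometryPreset("custom", elongation={28: (13, 9, 1.0)},
                                termination={29: (13, 10, 1.0)}, fidelity=0.95)
        tr, truth = make_transcriptome(SimConfig(n_transcripts=60), seed=31)
        store = simulate_footprints(tr, truth, preset, 60_000, seed=32,
                                    contamination=0.0)
        cds_map = tr.cds_map()
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        sel = select_metagene_transcripts(store, cds_map, call)
        geo = infer_offsets([metagene_profile(store, cds_map, sel, 28)])
        assert geo.get(28, "elongation") == (13, 9)

    def test_geometry_consistency_invariant(self, cr_sim, cr_frame_call):
        """L5 + 6 + L3 = n for every inferred (n, state)."""
        transcriptome, _, store = cr_sim
        cds_map = transcriptome.cds_map()
        sel = select_metagene_transcripts(store, cds_map, cr_frame_call)
        profs = [metagene_profile(store, cds_map, sel, n) for n in (27, 28)]
        geo = infer_offsets(profs)
        for r in geo.table.itertuples(index=False):
            assert r.L5 + 6 + r.L3 == r.length


class TestTerminationExtension:
    def geometry(self, rows):
        return FootprintGeometry(table=pd.DataFrame(
            rows, columns=["length", "state", "L5", "L3", "ambiguous"]))

    def test_three_prime_addition(self):
        geo = self.geometry([(27, "elongation", 11, 10, False),
                             (28, "termination", 11, 11, False)])
        ext = termination_extension(geo)
        row = ext[(ext["length"] == 28) & (ext["state"] == "termination")].iloc[0]
        assert (row.delta5, row.delta3) == (0, 1)

    def test_five_prime_addition(self):
        geo = self.geometry([(27, "elongation", 11, 10, False),
                             (28, "elongation", 12, 10, False)])
        ext = termination_extension(geo)
        row = ext[(ext["length"] == 28) & (ext["state"] == "elongation")].iloc[0]
        assert (row.delta5, row.delta3) == (1, 0)

    def test_both_end_addition_recovered_from_simulation(self):
        """A termination class configured 1 nt larger at each end than the
        reference elongation class comes back as (+1, +1)."""
        preset = GeometryPreset("x", elongation={27: (11, 10, 1.0)},
                                termination={29: (12, 11, 1.0)}, fidelity=0.95)
        tr, truth = make_transcriptome(SimConfig(n_transcripts=60), seed=41)
        store = simulate_footprints(tr, truth, preset, 60_000, seed=42,
                                    contamination=0.0)
        cds_map = tr.cds_map()
        call = frame_call(phase_by_length(interior_reads(store, cds_map)))
        sel = select_metagene_transcripts(store, cds_map, call)
        profs = [metagene_profile(store, cds_map, sel, n) for n in (27, 29)]
        geo = infer_offsets(profs)
        ext = termination_extension(geo, reference=(27, "elongation"))
        row = ext[(ext["length"] == 29) & (ext["state"] == "termination")].iloc[0]
        assert (row.delta5, row.delta3) == (1, 1)

    def test_missing_reference_errors(self):
        geo = self.geometry([(28, "termination", 11, 11, False)])
        with pytest.raises(ValueError):
            termination_extension(geo, reference=(27, "elongation"))
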