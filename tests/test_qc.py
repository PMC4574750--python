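import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ribotide.model import MappedRead, ReadStore, Transcript, Transcriptome
from ribotide.qc import SpeciesTable, chi2_envelope, chi2_envelope_bounds, composition, \
    fixed_slope_r2, fpkm, gc_content, mrna_enrichment, property_distributions, \
    species_chi2, total_variation


def store_on(tx_counts, sample="s"):
    reads = []
    for tx, n in tx_counts.items():
        reads += [MappedRead(tx, 0, 27, sample)] * n
    return ReadStore.from_reads(reads)


CATS = {"m1": "mRNA", "m2": "mRNA", "r1": "rRNA"}


class TestComposition:
    def test_all_mrna(self):
        rep = composition({"s": store_on({"m1": 10})}, CATS)
        assert rep.loc["s", "mRNA"] == 1.0

    def test_fractions_sum_to_one(self):
        rep = composition({"s": store_on({"m1": 10, "r1": 30, "m2": 5})}, CATS)
        assert rep.loc["s"].sum() == pytest.approx(1.0)

    def test_fourfold_enrichment(self):
        # untreated 5% mRNA, treated 20% -> enrichment 4.0
        untreated = store_on({"m1": 5, "r1": 95}, "untreated")
        treated = store_on({"m1": 20, "r1": 80}, "treated")
        rep = composition({"untreated": untreated, "treated": treated}, CATS)
        assert mrna_enrichment(rep, "treated", "untreated") == pytest.approx(4.0)

    def test_depletion_arithmetic_oracle(self):
        """Removing 90% of rRNA reads: fractions follow the closed form
        m / (m + 0.1 r)."""
        m, r = 200, 1000
        before = store_on({"m1": m, "r1": r})
        after = store_on({"m1": m, "r1": r // 10})
        rep = composition({"b": before, "a": after}, CATS)
        assert rep.loc["a", "mRNA"] == pytest.approx(m / (m + 0.1 * r))

    def test_uncategorized_goes_to_other(self):
        rep = composition({"s": store_on({"m1": 5, "ghost": 5})}, CATS)
        assert rep.loc["s", "other"] == pytest.approx(0.5)


class TestFpkm:
    def transcripts(self):
        return {"t1": Transcript("t1", "A" * 1000), "t2": Transcript("t2", "A" * 500)}

    def test_unit_definition(self):
        # 10 reads on a 1 kb transcript against a 1e6 total -> FPKM 10
        reads = [MappedRead("t1", 0, 27, "s")] * 10
        reads += [MappedRead("t2", 0, 27, "s", weight=999_990)]
        store = ReadStore.from_reads(reads)
        assert fpkm(store, self.transcripts())["t1"] == pytest.approx(10.0)

    def test_invariant_under_doubling(self):
        reads = [MappedRead("t1", 0, 27, "s", weight=40),
                 MappedRead("t2", 3, 27, "s", weight=60)]
        one = fpkm(ReadStore.from_reads(reads), self.transcripts())
        doubled = [MappedRead(r.transcript_id, r.five_prime, r.length, r.sample,
                              r.weight * 2) for r in reads]
        two = fpkm(ReadStore.from_reads(doubled), self.transcripts())
        assert np.allclose(one, two)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        reads = [MappedRead(rng.choice(["t1", "t2"]), 0, 27, "s")
                 for _ in range(500)]
        store = ReadStore.from_reads(reads)
        got = fpkm(store, self.transcripts())
        total = len(reads)
        for tid, length in (("t1", 1000), ("t2", 500)):
            count = sum(1 for r in reads if r.transcript_id == tid)
            assert got[tid] == pytest.approx(count / (length / 1e3) / (total / 1e6))


def table_of(a, b, total_a=None, total_b=None):
    counts = pd.DataFrame({"a": a, "b": b},
                          index=[f"sp{i}" for i in range(len(a))])
    return SpeciesTable(counts, float(total_a if total_a is not None else sum(a)),
                        float(total_b if total_b is not None else sum(b)))


class TestFixedSlopeR2:
    def test_perfect_line_gives_one(self):
        a = np.arange(10, 100, 10)
        t = table_of(a, 2 * a, total_a=a.sum(), total_b=2 * a.sum())
        slope, r2 = fixed_slope_r2(t)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_y_nonpositive(self):
        a = np.arange(10, 100, 10)
        t = table_of(a, np.full(len(a), 50), total_a=a.sum(), total_b=50 * len(a))
        _, r2 = fixed_slope_r2(t)
        assert r2 <= 0

    def test_matches_brute_force_formula(self):
        """Binomially split counts across 10,000 species: R^2 equals the
        from-scratch formula to 1e-12."""
        rng = np.random.default_rng(12)
        n = rng.integers(1, 500, size=10_000)
        x = rng.binomial(n, 0.5)
        y = n - x
        t = table_of(x, y)
        slope, r2 = fixed_slope_r2(t, min_count=5)
        sel = x > 5
        s = t.total_b / t.total_a
        brute = 1 - np.sum((y[sel] - s * x[sel]) ** 2) / \
            np.sum((y[sel] - y[sel].mean()) ** 2)
        assert abs(r2 - brute) < 1e-12

    def test_invariant_under_joint_rescaling(self):
        rng = np.random.default_rng(13)
        x = rng.integers(6, 100, 50)
        y = rng.integers(0, 100, 50)
        t1 = table_of(x, y)
        t2 = table_of(3 * x, 3 * y)
        s1, r1 = fixed_slope_r2(t1, min_count=5)
        s2, r2 = fixed_slope_r2(t2, min_count=5 * 3)
        assert s1 == pytest.approx(s2)
        assert r1 == pytest.approx(r2)


class TestChi2Envelope:
    def test_on_expected_split_inside(self):
        t = table_of([100], [100])
        env = chi2_envelope(t)
        assert env["chi2"].iloc[0] == 0.0
        assert bool(env["inside"].iloc[0])

    def test_threshold_is_chi2_quantile(self):
        # the 95% cut equals the df=1 chi-square quantile, 3.841 to 3 dp
        assert stats.chi2.ppf(0.95, 1) == pytest.approx(3.841, abs=5e-4)
        t = table_of([100, 100], [100, 140])
        env = chi2_envelope(t, coverage=0.95)
        boundary = species_chi2(np.array([100]), np.array([140]), t.total_a, t.total_b)
        assert bool(env["inside"].iloc[1]) == (boundary[0] <= 3.8415)

    def test_coverage_matches_nominal_under_null(self):
        """Simulation oracle: binomial no-depletion splits give ~95% of
        species inside the envelope (3 sigma of binomial error)."""
        rng = np.random.default_rng(77)
        n_species = 10_000
        totals = np.maximum(rng.negative_binomial(2, 0.01, size=n_species), 20)
        x = rng.binomial(totals, 0.5)
        y = totals - x
        t = table_of(x, y)
        env = chi2_envelope(t, coverage=0.95)
        frac = env["inside"].mean()
        assert abs(frac - 0.95) < 3 * np.sqrt(0.95 * 0.05 / n_species) + 0.005

    def test_bounds_bracket_expectation(self):
        t = table_of([100, 200], [100, 200])
        band = chi2_envelope_bounds(np.array([50, 100, 200]), t.total_a, t.total_b)
        for r in band.itertuples(index=False):
            assert r.b_lo <= r.a <= r.b_hi  # expectation y = x here


class TestPropertyDistributions:
    def transcriptome(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(4)]
        return Transcriptome.from_transcripts(
            [Transcript(f"t{i}", s) for i, s in enumerate(seqs)])

    def test_gc_content(self):
        assert gc_content("ATGC") == 0.5

    def test_identical_stores_zero_divergence(self):
        tr = self.transcriptome()
        reads = [MappedRead("t0", 5 * i, 27, "s") for i in range(20)]
        a = ReadStore.from_reads(reads)
        b = ReadStore.from_reads([MappedRead(r.transcript_id, r.five_prime,
                                             r.length, "b") for r in reads])
        hists, div = property_distributions({"A": a, "B": b}, tr)
        assert (div["tv_distance"] == 0).all()

    def test_gc_biased_depletion_detected(self):
        """Dropping high-GC reads at a higher rate shifts the GC histogram;
        the TV distance matches a brute-force computation on the truth."""
        tr = self.transcriptome()
        rng = np.random.default_rng(6)
        reads = [MappedRead(f"t{rng.integers(0, 4)}", int(rng.integers(0, 170)),
                            27, "a") for _ in range(2000)]
        a = ReadStore.from_reads(reads)

        def gc_of(r):
            return gc_content(tr[r.transcript_id].sequence[r.five_prime:r.five_prime + 27])

        kept = [r for r in reads
                if rng.random() < (0.4 if gc_of(r) > 0.5 else 0.8)]
        b = ReadStore.from_reads([MappedRead(r.transcript_id, r.five_prime,
                                             r.length, "b") for r in kept])
        hists, div = property_distributions({"A": a, "B": b}, tr)
        gc_tv = div[div["property"] == "gc"]["tv_distance"].iloc[0]
        assert gc_tv > 0.02
        # brute-force TV on the same bins
        brute = total_variation(hists["gc"]["A"].to_numpy(), hists["gc"]["B"].to_numpy())
        assert gc_tv == pytest.approx(brute)

    def test_missing_energy_skipped(self):
        tr = self.transcriptome()
        a = ReadStore.from_reads([MappedRead("t0", 0, 27, "a")])
        hists, _ = property_distributions({"A": a}, tr, energy_table=None)
        assert "energy" not in hists
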