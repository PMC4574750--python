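# Methods

## Scope and data model

ribotide analyses ribosome profiling (Ribo-seq) data that have already been
aligned to a transcriptome. Footprint reads are reduced to
`(transcript_id, five_prime, length, sample, weight)` records; transcripts
carry a sequence and an optional CDS interval. All internal coordinates are
0-based, half-open; display layers convert to 1-based positions and codon
positions {1, 2, 3}. A CDS interval includes its stop codon, so the first
nucleotide of the stop codon is addressable at `cds_end - 3` — the
stop-anchored metagene and the termination-peak geometry depend on this.

Alignments are sense-only: a footprint on a transcript is by definition on
the sense strand, so reverse-strand records are dropped and counted.
Reads mapping to several transcripts are assigned uniformly at random to
one of them under a mandatory seed (policy `random`), or duplicated to all
(policy `all`, diagnostics only). Soft-clipped bases are excluded from the
read length; the 5' position anchors on the leftmost aligned base, which
may differ from tools that re-anchor across indels.

## Frame calling

Triplet periodicity is measured on *interior* reads — reads wholly
contained in a CDS, which excludes most initiating and terminating
ribosomes. For a read at 5' position p in a CDS starting at s, the phase
is (p − s) mod 3. Phases are tallied per read-length class and the
predominant phase per class is called by argmax (ties break to the
smallest phase index, with a warning). Framing statistics always use
phase relative to the CDS's own start; the per-transcript view instead
bins 5' ends by position mod 3 relative to transcript nt 1. The two
conventions are never mixed within one operation.

The default read-length window is 20–40 nt (configurable); analysis
figures typically concentrate on 25–31 nt where cytoplasmic footprints
peak.

## Coding-region selection

A candidate coding region passes when it has at least `min_reads`
(default 50) focal-length reads in the expected phase, at `min_locations`
(default 10) or more distinct 5' positions. The focal length defaults to
the most abundant length class; the expected phase is that class's called
phase. Highly translated regions leak enough out-of-phase reads that
overlapping, out-of-phase candidates can clear the count filter, so a
candidate whose maximal phase differs from the expected phase must
additionally show an expected:maximal count ratio that significantly
exceeds the ratio pooled over supported regions — a Pearson chi-square on
the 2x2 table [(candidate expected, candidate maximal), (pooled expected,
pooled maximal)], df = 1, alpha 0.05, continuity correction off by
default (both switchable). Design choices that were genuinely open:

* the phase test applies only to discordant candidates (maximal ≠
  expected); `always_test=True` applies it to all, comparing against the
  strongest competing phase when the candidate is concordant;
* the pooled reference counts come from candidates passing the
  count/location filters, so the reference does not condition on the
  phase test's own outcome;
* no multiple-testing correction across candidates — the threshold is a
  plain 0.05;
* passing requires both direction (candidate ratio strictly greater,
  checked by cross-multiplication so zero counts are safe) and
  significance.

## De novo ORF discovery

Each frame of each transcript is scanned for ATG codons (near-cognate
starts can be enabled by configuration, default canonical only); every
start pairs with the nearest downstream in-frame canonical stop (TAG,
TAA, TGA). Codons containing N never match start or stop. Nested in-frame
starts sharing a stop yield distinct candidates; starts with no in-frame
stop are dropped. `codon_length` counts sense codons including the start
codon and excluding the stop, so the classic very-short regulatory uORF
of "three codons" spans 12 nt.

Annotation matching calls an annotated CDS *recovered* when any de novo
candidate shares its transcript, stop coordinate and frame, and *exact*
when the start agrees too. Classification relative to a designated main
CDS uses interval/frame arithmetic only: uORF, overlapping uORF,
internal overlapping ORF, dORF, readthrough extension (in-frame,
beginning at the main stop codon), main. The published vocabulary is not
exhaustive (e.g. in-frame nested starts, out-of-frame 3' overlaps), so a
residual `other` relation keeps the classifier total.

## Metagene profiles and footprint geometry

For one length class n, 5'-end counts are histogrammed in windows
anchored at the first nucleotide of the start codon (default −30..+60)
and of the stop codon (default −60..+30), per selected CDS. Each CDS's
histogram is divided by its mean per-nt density of n-nt reads (5' ends
within the CDS / CDS length), which makes the contribution of a CDS
invariant to its expression level; the normalised profiles are then
averaged with a simple mean over CDSs (a read-weighted mean is available
as `average="read_weighted"`). Transcript selection mirrors the filter:
at least 50 in-frame reads of the most abundant class at 10+ distinct
positions.

Geometry is read off profile maxima inside a ±(n+5) nt search window:

* initiation: the initiating ribosome holds the start codon in its
  P-site, so the start-window maximum sits at −L5, giving L5 directly;
* termination: the terminating ribosome pauses with the stop codon in
  its A-site, so the stop-window maximum sits at −(L5 + 3);
* the protected span decomposes as L5 + 3 (P-site) + 3 (A-site) + L3 = n,
  so L3 follows from n and L5.

Tied maxima are broken toward the canonical expectation (−12 for start
windows, −15 for stop windows, typical eukaryotic values) and flagged
ambiguous. Length classes that a preset emits only in one state still
produce a row for the other state from jitter leakage; these rows carry
negligible signal and callers should read the classes they care about.
Ligation/nuclease biases that distort peaks 3–4 codons from the anchors
in real data are not modelled; an optional mask of ±2 codons around the
anchor is available when locating interior periodic phase.
`termination_extension` expresses every (length, state) as (Δ5', Δ3')
relative to a reference elongation class (default: the shortest).

## Depletion QC

Library composition is the per-sample read fraction over transcript
categories {rRNA, mRNA, gDNA, ncRNA, other}; enrichment is the ratio of
mRNA fractions between treated and untreated samples. FPKM is
count / (kb length) / (millions of mapped reads). Species-level
concordance between two samples uses the exact read sequence as the
species identity (no mismatch collapsing) and compares counts against
the fixed-slope expectation y = (N_b/N_a)·x — a ratio of totals, not a
regression — with R² = 1 − Σ(y − s·x)²/Σ(y − ȳ)² over species exceeding
a reference-sample count threshold (default > 5). R² can be negative; a
zero-variance comparison sample returns the −∞ limit (or 1 when the fit
is also exact). R² is computed in linear count space; a log-space
variant sits behind a flag. The 95% envelope is pointwise per species:
with n = x + y and p_a = N_a/(N_a + N_b), a species is inside when its
Pearson statistic (x − p_a n)²/(p_a n) + (y − p_b n)²/(p_b n) does not
exceed the chi-square(df=1) quantile (3.841 at 95%). Pointwise coverage
is verified by simulation rather than asserted. Folding/binding energies
are consumed from an external per-species table (they are produced by
dedicated folding software); absent species report as missing, never as
zero.

## Count export

Per-CDS counts sum interior reads over configured (length, frame)
combinations, where "in-frame" resolves to the called phase for that
length class. RNA-seq pairing counts any-overlap reads by default
(interior-only behind a flag). No differential testing is included; the
output is a TSV matrix plus a JSON sidecar with the combination spec and
seeds.

## The synthetic generator

The simulator is the test bed for every stage, with defaults chosen to
mirror the data the analysis targets:

* transcripts: 100 per set, main CDS of 60–250 sense codons, UTRs of
  30–70 nt (5') and 30–90 nt (3'), GC 0.5; uORFs planted in the leader
  with probability 0.2 (3–20 codons), overlapping uORFs attempted with
  probability 0.1 by opening an out-of-frame start late in the leader and
  running to the first natural in-frame stop inside the CDS (skipped when
  the sequence does not cooperate); two rRNA transcripts of 1,200 nt;
* footprints: the P-site is uniform over sense codons (weighted by each
  ORF's lognormal translation level), excluding the last sense codon,
  whose P-site occupancy is the termination state (stop codon in the
  A-site) at `pause_factor` (default 5) times the interior density. The
  initiation codon is elevated by `init_factor` (default 3): real
  libraries show an initiation peak, and without one the start-anchored
  profile is a flat period-3 comb with no identifiable maximum;
* geometry presets: `cr-27` (elongation 27 nt (L5 11, L3 10) 75% / 28 nt
  (12, 10) 25%; termination 28 nt (11, 11) 60% / 29 nt (12, 11) 40%) and
  `mm-29` (elongation 28 (11, 11) 20% / 29 (12, 11) 65% / 30 (13, 11)
  15%; termination 29 (12, 11) 30% / 30 (12, 12) 70%). Default phase
  fidelity 0.95, within the 85–96% framing range typical of
  well-digested libraries; imperfect framing is modelled as ±1 nt 5'-end
  jitter with probability (1 − f)/2 per side (asymmetry configurable);
* contaminants and RNA-seq: 10% of footprints are drawn uniformly from
  the rRNA transcripts; RNA-seq reads are 30 nt placed uniformly
  (fragmentation-like), with per-transcript lognormal abundances.
  Depletion treatments are binomial thinning with per-category or
  per-sequence survival probabilities.

The generator does not model sequencer errors, ligation bias, codon-level
dwell-time variation, nucleotide composition of real genomes, or isoform
structure. Passing tests therefore demonstrate that the estimators
recover the quantities they claim from data obeying the stated geometry
— not that real libraries obey it.

## Problem sizes and numerics

Simulation-backed tests use 100 transcripts and 60k–100k footprints,
sizes at which offset recovery is exact and stochastic checks sit
comfortably inside their 3σ bands. Stochastic assertions always state
the binomial/multinomial oracle and a 3σ tolerance; exact assertions
(chi-square vs. brute-force Pearson, R² vs. its formula) use 1e−9/1e−12.
Degenerate inputs are defined rather than left to chance: empty groups
flag and return NaN histograms, sliding windows wider than the series
return the global mean, envelope species with zero totals count as
inside (statistic 0), and a frame-call tie logs its tie-break.
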