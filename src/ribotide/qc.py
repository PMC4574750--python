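"""Library-composition and depletion-bias diagnostics.

rRNA-depletion treatments (duplex-specific nuclease, RiboZero,
hybridisation-subtraction) raise the mRNA fraction of a footprint library
but can bias individual read species. These diagnostics quantify both
sides: category composition and mRNA enrichment; per-transcript FPKM
concordance between treated and untreated samples against a fixed-slope
expectation (the slope being the ratio of mapped mRNA read totals, not a
fitted regression, so R-squared can go negative); a species-level scatter
with a theoretical 95% envelope from the Pearson chi-square statistic with
one degree of freedom; and distributions of read length, GC content and
externally supplied folding energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import ReadStore, Transcript

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- composition

def composition(stores: Mapping[str, ReadStore],
                category_map: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample read fractions in {rRNA, mRNA, gDNA, ncRNA, other}.

    Transcripts missing from the category map are counted as "other" and
    logged. Fractions sum to 1 per sample.
    """
    cats = ("rRNA", "mRNA", "gDNA", "ncRNA", "other")
    rows = {}
    for sample, store in stores.items():
        df = store.df
        assigned = df["transcript_id"].map(category_map)
        n_missing = int(assigned.isna().sum())
        if n_missing:
            logger.warning("composition: %d reads on uncategorized transcripts -> 'other'",
                           n_missing)
        assigned = assigned.fillna("other")
        totals = df.groupby(assigned)["weight"].sum()
        total = totals.sum()
        rows[sample] = {c: float(totals.get(c, 0)) / total if total else np.nan for c in cats}
    return pd.DataFrame(rows).T[list(cats)]


def mrna_enrichment(report: pd.DataFrame, treated: str, untreated: str) -> float:
    """Fold-enrichment of the mRNA fraction in the treated sample."""
    return float(report.loc[treated, "mRNA"] / report.loc[untreated, "mRNA"])


# ----------------------------------------------------------------------- FPKM

def fpkm(store: ReadStore, transcripts: Mapping[str, Transcript],
         sample: Optional[str] = None) -> pd.Series:
    """Fragments per kilobase of transcript per million mapped reads."""
    df = store.df if sample is None else store.df[store.df["sample"] == sample]
    total = df["weight"].sum()
    if total == 0:
        raise ValueError("fpkm: no mapped reads")
    counts = df.groupby("transcript_id")["weight"].sum()
    out = {}
    for tid, t in transcripts.items():
        if len(t) == 0:
            raise ValueError(f"zero-length transcript {tid!r}")
        out[tid] = counts.get(tid, 0) / (len(t) / 1e3) / (total / 1e6)
    return pd.Series(out, name="fpkm")


# --------------------------------------------------------------- species QC

@dataclass
class SpeciesTable:
    """Distinct read species with counts in two samples.

    ``counts`` is indexed by species sequence with columns ``[a, b]``;
    ``total_a``/``total_b`` are the totals of mapped mRNA-derived reads per
    sample (at least the column sums).
    """

    counts: pd.DataFrame
    total_a: float
    total_b: float

    def __post_init__(self) -> None:
        if list(self.counts.columns) != ["a", "b"]:
            self.counts = self.counts.rename(
                columns=dict(zip(self.counts.columns, ["a", "b"])))
        if (self.counts < 0).any().any():
            raise ValueError("negative species counts")

    @classmethod
    def from_stores(cls, store_a: ReadStore, store_b: ReadStore,
                    transcripts: Mapping[str, Transcript],
                    mrna_only: bool = True) -> "SpeciesTable":
        """Build a species table keyed by exact read sequence."""
        def species_counts(store: ReadStore) -> pd.Series:
            df = store.df
            if mrna_only:
                cats = {tid: t.category for tid, t in transcripts.items()}
                df = df[df["transcript_id"].map(cats) == "mRNA"]
            seqs = [transcripts[r.transcript_id].sequence[r.five_prime:r.five_prime + r.length]
                    for r in df.itertuples(index=False)]
            w = df["weight"].to_numpy()
            return pd.Series(w, index=seqs).groupby(level=0).sum()

        ca = species_counts(store_a)
        cb = species_counts(store_b)
        counts = pd.DataFrame({"a": ca, "b": cb}).fillna(0).astype(int)
        return cls(counts=counts, total_a=float(ca.sum()), total_b=float(cb.sum()))

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("species").to_csv(path, sep="\t")


def fixed_slope_r2(table: SpeciesTable, min_count: int = 5) -> tuple[float, float]:
    """Concordance of species counts against the fixed-slope expectation.

    The expected relationship under no depletion is ``y = s x`` with
    ``s = N_b / N_a`` (the ratio of mapped mRNA read totals), not a fitted
    line. R-squared is computed for species with more than ``min_count``
    occurrences in the reference (a) sample, as
    ``1 - sum((y - s x)^2) / sum((y - mean(y))^2)``, and can be negative.
    """
    sel = table.counts[table.counts["a"] > min_count]
    if sel.empty:
        raise ValueError("no species exceed the reference-count threshold")
    s = table.total_b / table.total_a
    x = sel["a"].to_numpy(dtype=float)
    y = sel["b"].to_numpy(dtype=float)
    ss_res = np.sum((y - s * x) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        # degenerate: no variance around the mean; the limit of the
        # definition is -inf unless the fixed-slope fit is also exact
        logger.warning("fixed_slope_r2: zero variance in the comparison sample")
        return float(s), (1.0 if ss_res == 0 else float("-inf"))
    r2 = 1.0 - ss_res / ss_tot
    return float(s), float(r2)


def species_chi2(x: np.ndarray, y: np.ndarray, total_a: float, total_b: float) -> np.ndarray:
    """Pearson chi-square of each species' (x, y) split against expectation.

    With n = x + y and p_a = N_a / (N_a + N_b), the expected split is
    (p_a n, p_b n); the statistic has one degree of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p_a = total_a / (total_a + total_b)
    p_b = 1.0 - p_a
    n = x + y
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (x - p_a * n) ** 2 / (p_a * n) + (y - p_b * n) ** 2 / (p_b * n)
    return np.where(n > 0, chi2, 0.0)


def chi2_envelope(table: SpeciesTable, coverage: float = 0.95) -> pd.DataFrame:
    """Theoretical envelope for the two-sample species scatter.

    A species is inside the envelope when its Pearson chi-square against
    the expected binomial split does not exceed the chi-square(df=1)
    quantile at ``coverage``. Returns per-species (a, b, chi2, inside)
    for plotting and coverage checks.
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must lie in (0, 1)")
    q = stats.chi2.ppf(coverage, df=1)
    chi2 = species_chi2(table.counts["a"].to_numpy(), table.counts["b"].to_numpy(),
                        table.total_a, table.total_b)
    out = table.counts.copy()
    out["chi2"] = chi2
    out["inside"] = chi2 <= q
    return out


def chi2_envelope_bounds(x_values: np.ndarray, total_a: float, total_b: float,
                         coverage: float = 0.95) -> pd.DataFrame:
    """y-bounds of the envelope per x, for drawing the envelope band.

    For fixed x, the statistic is monotone in the deviation of y from the
    expected ``x p_b / p_a``; the two roots of chi2(x, y) = q bound the
    band. Solved per x with Brent's method.
    """
    from scipy.optimize import brentq

    q = stats.chi2.ppf(coverage, df=1)
    p_a = total_a / (total_a + total_b)
    rows = []
    for x in np.asarray(x_values, dtype=float):
        if x <= 0:
            continue
        y_exp = x * (1 - p_a) / p_a

        def f(y, x=x):
            return species_chi2(np.array([x]), np.array([y]), total_a, total_b)[0] - q

        y_hi = brentq(f, y_exp, y_exp + 10 * np.sqrt(q * max(y_exp, 1.0)) + 10 * q)
        y_lo = brentq(f, 0.0, y_exp) if f(0.0) > 0 else 0.0
        rows.append({"a": x, "b_lo": y_lo, "b_hi": y_hi})
    return pd.DataFrame(rows)


# ------------------------------------------------------ property distributions

def gc_content(seq: str) -> float:
    """Fraction of G/C bases in a sequence."""
    if not seq:
        return float("nan")
    return sum(1 for c in seq.upper() if c in "GC") / len(seq)


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    """Total variation distance between two normalised histograms."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def property_distributions(
    stores: Mapping[str, ReadStore],
    transcripts: Mapping[str, Transcript],
    energy_table: Optional[pd.DataFrame] = None,
    energy_column: str = "mfe",
    n_bins: int = 20,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-sample distributions of read length, GC and folding energy.

    Returns ``(histograms, divergences)``: for each property a frame of
    normalised per-sample histograms on shared bins, and a long frame of
    pairwise total-variation distances. Folding energies come from an
    external property table keyed by read sequence; when absent the
    property is skipped with a coverage note.
    """
    per_sample_values: dict[str, dict[str, np.ndarray]] = {}
    for sample, store in stores.items():
        lengths, gcs, energies = [], [], []
        for r in store.df.itertuples(index=False):
            seq = transcripts[r.transcript_id].sequence[r.five_prime:r.five_prime + r.length]
            for _ in range(int(r.weight)):
                lengths.append(r.length)
                gcs.append(gc_content(seq))
                if energy_table is not None and energy_column in getattr(energy_table, "columns", []):
                    if seq in energy_table.index and not pd.isna(energy_table.at[seq, energy_column]):
                        energies.append(float(energy_table.at[seq, energy_column]))
        per_sample_values[sample] = {
            "length": np.array(lengths, dtype=float),
            "gc": np.array(gcs, dtype=float),
            "energy": np.array(energies, dtype=float),
        }

    histograms: dict[str, pd.DataFrame] = {}
    div_rows = []
    for prop in ("length", "gc", "energy"):
        all_vals = np.concatenate([v[prop] for v in per_sample_values.values()]) \
            if per_sample_values else np.array([])
        if all_vals.size == 0:
            if prop == "energy":
                logger.info("property_distributions: no folding energies supplied; skipped")
            continue
        if prop == "length":
            lo, hi = all_vals.min(), all_vals.max()
            bins = np.arange(lo, hi + 2) - 0.5
        else:
            bins = np.histogram_bin_edges(all_vals, bins=n_bins)
        hist = {}
        for sample, vals in per_sample_values.items():
            h, _ = np.histogram(vals[prop], bins=bins)
            hist[sample] = h / h.sum() if h.sum() else h.astype(float)
        centers = 0.5 * (bins[:-1] + bins[1:])
        histograms[prop] = pd.DataFrame(hist, index=pd.Index(centers, name=prop))
        samples = list(per_sample_values)
        for i, sa in enumerate(samples):
            for sb in samples[i + 1:]:
                div_rows.append({"property": prop, "sample_a": sa, "sample_b": sb,
                                 "tv_distance": total_variation(hist[sa], hist[sb])})
    return histograms, pd.DataFrame(div_rows)
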