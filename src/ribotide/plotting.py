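"""Static figure rendering for the pipeline's reports.

Frame colours follow the red/green/blue codon-position convention used
throughout: codon position 1 red, 2 green, 3 blue.
"""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .framing import PhaseHistogram  # noqa: E402
from .metagene import MetageneProfile  # noqa: E402
from .qc import SpeciesTable, chi2_envelope_bounds  # noqa: E402
from .transcript_view import TranscriptProfile, sliding_window_mean  # noqa: E402

FRAME_COLORS = ("#d62728", "#2ca02c", "#1f77b4")  # codon positions 1, 2, 3


def plot_phase_histogram(hist: PhaseHistogram, path=None, ax=None):
    """Stacked bars of 5'-end codon positions per read-length class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    lengths = hist.counts.index.to_numpy()
    bottom = np.zeros(len(lengths))
    for phase in (0, 1, 2):
        vals = hist.counts[phase].to_numpy()
        ax.bar(lengths, vals, bottom=bottom, color=FRAME_COLORS[phase],
               label=f"codon position {phase + 1}")
        bottom += vals
    ax.set_xlabel("footprint length (nt)")
    ax.set_ylabel("5' end count")
    ax.legend(frameon=False)
    if path:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_metagene(profile: MetageneProfile, path=None):
    """Start- and stop-anchored weighted 5'-end densities, coloured by phase."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 3.5), sharey=True)
    for ax, offs, prof, anchor in (
            (ax1, profile.start_offsets, profile.start_profile, "start"),
            (ax2, profile.stop_offsets, profile.stop_profile, "stop")):
        colors = [FRAME_COLORS[o % 3] for o in offs]
        ax.bar(offs, prof, color=colors, width=1.0)
        ax.axvline(0, color="k", lw=0.5, ls="--")
        ax.set_xlabel(f"offset from {anchor} codon (nt)")
    ax1.set_ylabel(f"weighted density ({profile.length} nt)")
    fig.suptitle(f"{profile.length}-nt footprints, {profile.n_transcripts} transcripts")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_transcript(profile: TranscriptProfile, path=None, window_codons: int = 15,
                    smoothed: Optional[np.ndarray] = None):
    """Per-transcript view: frame-coloured 5' ends over RNA coverage, ORF
    track above, sliding-window summary below."""
    fig, (ax_orf, ax_main, ax_win) = plt.subplots(
        3, 1, figsize=(10, 6), sharex=True,
        gridspec_kw={"height_ratios": [1, 4, 2]})
    L = profile.frame_series.shape[1]
    x = np.arange(L)
    if profile.rna_coverage.max() > 0:
        scale = profile.frame_series.max() / profile.rna_coverage.max() \
            if profile.frame_series.max() > 0 else 1.0
        ax_main.fill_between(x, profile.rna_coverage * scale, color="0.8",
                             label="RNA-seq")
    for frame in range(3):
        ax_main.vlines(x, 0, profile.frame_series[frame],
                       color=FRAME_COLORS[frame], lw=1.0)
    ax_main.set_ylabel("5' end count")

    for i, (orf, ok) in enumerate(profile.orf_track):
        y = 0.2 + 0.25 * (i % 3)
        ax_orf.plot([orf.start, orf.end], [y, y],
                    color=FRAME_COLORS[orf.frame], lw=3 if ok else 1,
                    alpha=1.0 if ok else 0.4)
    ax_orf.set_ylim(0, 1)
    ax_orf.set_yticks([])

    if smoothed is not None:
        ax_win.plot(np.arange(len(smoothed)) * 3, smoothed, color="k", lw=1)
        ax_win.set_ylabel(f"{window_codons}-codon mean")
    ax_win.set_xlabel(f"{profile.transcript_id} position (nt)")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_species_scatter(table: SpeciesTable, path=None, coverage: float = 0.95):
    """Two-sample species scatter with fixed-slope guide and chi-square envelope."""
    fig, ax = plt.subplots(figsize=(5, 5))
    c = table.counts
    ax.scatter(c["a"] + 0.5, c["b"] + 0.5, s=4, alpha=0.3, color="k")
    xs = np.unique(np.round(np.geomspace(1, max(2, c["a"].max()), 50)).astype(int))
    band = chi2_envelope_bounds(xs, table.total_a, table.total_b, coverage)
    if not band.empty:
        ax.fill_between(band["a"] + 0.5, band["b_lo"] + 0.5, band["b_hi"] + 0.5,
                        color="pink", alpha=0.5, label=f"{coverage:.0%} envelope")
    s = table.total_b / table.total_a
    ax.plot(xs, s * xs, color="0.5", lw=1, label=f"slope {s:.2f}")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("species count, sample A")
    ax.set_ylabel("species count, sample B")
    ax.legend(frameon=False)
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
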