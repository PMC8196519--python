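"""Rainfall, spectrum and nucleotide-content plots.

Every plot function first builds a tidy data table, writes it next to the
image as ``<out>.data.tsv``, then renders with matplotlib.  Assertions in
analyses should target the exported tables; the images are illustrative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .imd import ImdTable
from .pcf import KataegisFocus
from .spectra import SUBSTITUTION_CLASSES, ContentProfile, SpectrumCounts

#: Fixed class palette (COSMIC-style rainfall colours).
CLASS_COLORS = {
    "C>A": "#2EBAED",
    "C>G": "#000000",
    "C>T": "#DE1C14",
    "T>A": "#ADADAD",
    "T>C": "#40B349",
    "T>G": "#E98C7B",
}

BASE_COLORS = {"A": "#40B349", "C": "#2EBAED", "G": "#F5A623", "T": "#DE1C14"}


@dataclass
class PlotSpec:
    """Output format and geometry of a plot."""

    out_path: str | Path = "plot.png"
    fmt: str = "png"  # png, pdf or svg
    width: float = 11.0   # inches
    height: float = 4.0
    chrom_filter: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.fmt not in {"png", "pdf", "svg"}:
            raise ValueError(f"unsupported format {self.fmt!r}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")


def _data_path(out_path: str | Path) -> Path:
    return Path(f"{out_path}.data.tsv")


def rainfall_frame(
    imd: ImdTable,
    chrom_sizes: Mapping[str, int],
    chrom_filter: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tidy table behind a rainfall plot: one row per defined-IMD record.

    ``x_cum`` is the position on a cumulative axis that concatenates the
    chromosomes in ``chrom_sizes`` order (restricted to ``chrom_filter``
    when given).
    """
    chroms = list(chrom_filter) if chrom_filter else list(chrom_sizes)
    for chrom in imd.chromosomes():
        if chrom_filter and chrom not in chroms:
            continue
        if chrom not in chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} missing from chrom sizes")
    offsets = {}
    cum = 0
    for chrom in chroms:
        offsets[chrom] = cum
        cum += int(chrom_sizes[chrom])
    df = imd.df[imd.df["imd"].notna() & imd.df["chrom"].isin(chroms)].copy()
    df["x_cum"] = df["pos"] + df["chrom"].map(offsets)
    df["log10_imd"] = np.log10(df["imd"])
    return df[["chrom", "pos", "x_cum", "imd", "log10_imd", "subst_class"]]


def plot_rainfall(
    imd: ImdTable,
    chrom_sizes: Mapping[str, int],
    foci: Optional[Sequence[KataegisFocus]] = None,
    spec: Optional[PlotSpec] = None,
) -> Path:
    """Genome-wide (or per-chromosome) rainfall plot.

    x: cumulative genomic position with chromosome boundaries marked;
    y: log10 inter-mutational distance; colour: substitution class.
    Called foci, when given, are shaded.
    """
    spec = spec or PlotSpec()
    if imd.df.empty:
        raise ValueError("cannot draw a rainfall plot from an empty IMD table")
    data = rainfall_frame(imd, chrom_sizes, spec.chrom_filter)
    data.to_csv(_data_path(spec.out_path), sep="\t", index=False)

    chroms = list(spec.chrom_filter) if spec.chrom_filter else list(chrom_sizes)
    offsets = {}
    cum = 0
    for chrom in chroms:
        offsets[chrom] = cum
        cum += int(chrom_sizes[chrom])

    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    for cls in SUBSTITUTION_CLASSES:
        sub = data[data["subst_class"] == cls]
        ax.scatter(sub["x_cum"], sub["log10_imd"], s=8, color=CLASS_COLORS[cls],
                   label=cls, linewidths=0)
    for chrom in chroms[1:]:
        ax.axvline(offsets[chrom], color="0.85", lw=0.8, zorder=0)
    if foci:
        for f in foci:
            if f.chrom in offsets:
                off = offsets[f.chrom]
                ax.axvspan(off + f.start_pos, off + f.end_pos, color="gold",
                           alpha=0.35, zorder=0)
    ax.set_xlim(0, cum)
    ax.set_xlabel("genomic position" + ("" if len(chroms) > 1 else f" on {chroms[0]}"))
    ax.set_ylabel("log10 inter-mutational distance (bp)")
    mids = [offsets[c] + chrom_sizes[c] / 2 for c in chroms]
    ax.set_xticks(mids)
    ax.set_xticklabels(chroms, rotation=90 if len(chroms) > 5 else 0, fontsize=7)
    ax.legend(frameon=False, fontsize=7, markerscale=1.5, ncol=6,
              loc="upper center", bbox_to_anchor=(0.5, 1.12))
    fig.tight_layout()
    fig.savefig(spec.out_path, format=spec.fmt, dpi=150)
    plt.close(fig)
    return Path(spec.out_path)


def plot_spectrum(counts: SpectrumCounts, spec: Optional[PlotSpec] = None) -> Path:
    """Horizontal bar plot of the six substitution-class counts."""
    spec = spec or PlotSpec(width=6.0, height=3.5)
    data = pd.DataFrame(
        {"subst_class": list(SUBSTITUTION_CLASSES),
         "count": [counts.counts[c] for c in SUBSTITUTION_CLASSES]}
    )
    data.to_csv(_data_path(spec.out_path), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    y = np.arange(len(SUBSTITUTION_CLASSES))[::-1]
    ax.barh(y, data["count"], color=[CLASS_COLORS[c] for c in data["subst_class"]])
    ax.set_yticks(y)
    ax.set_yticklabels(data["subst_class"])
    ax.set_xlabel(f"SNV count ({counts.scope})")
    fig.tight_layout()
    fig.savefig(spec.out_path, format=spec.fmt, dpi=150)
    plt.close(fig)
    return Path(spec.out_path)


def plot_content(
    profiles: Sequence[ContentProfile], spec: Optional[PlotSpec] = None
) -> Path:
    """Stacked A/C/G/T composition bars, one per region (focus, flank)."""
    if not profiles:
        raise ValueError("need at least one content profile")
    spec = spec or PlotSpec(width=4.0, height=4.0)
    data = pd.DataFrame(
        [
            {"region": p.region, "base": b, "fraction": p.fractions[b],
             "n_bases": p.n_bases}
            for p in profiles
            for b in "ACGT"
        ]
    )
    data.to_csv(_data_path(spec.out_path), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    x = np.arange(len(profiles))
    bottom = np.zeros(len(profiles))
    for b in "ACGT":
        vals = np.array([p.fractions[b] for p in profiles])
        ax.bar(x, vals, bottom=bottom, color=BASE_COLORS[b], label=b, width=0.6)
        bottom += vals
    ax.set_xticks(x)
    ax.set_xticklabels([p.region for p in profiles])
    ax.set_ylabel("fraction of bases")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(spec.out_path, format=spec.fmt, dpi=150)
    plt.close(fig)
    return Path(spec.out_path)
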