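"""Inter-mutational distances (IMD).

After sorting variants by genomic coordinate, the IMD of a variant is its
distance in bp to the preceding variant on the same chromosome.  The first
variant of each chromosome has no IMD (NaN): distances are defined only
between neighbouring variants and never cross chromosome boundaries.
Kataegis appears as runs of anomalously small IMDs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectra import classify_substitution
from .variant_io import SampleSet, VariantTable, chrom_sort_key


class ImdWarning(UserWarning):
    pass


class ImdTable:
    """Per-variant inter-mutational distances for one sample.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt, imd,
    subst_class``; ``imd`` is NaN for the first variant of each chromosome.
    Variants sharing a position are collapsed (first by alt order) so every
    defined IMD is >= 1 and log10(IMD) is finite.
    """

    def __init__(self, df: pd.DataFrame, sample_id: str,
                 n_duplicates_collapsed: int = 0) -> None:
        self.df = df.reset_index(drop=True)
        self.sample_id = sample_id
        self.n_duplicates_collapsed = n_duplicates_collapsed

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_defined(self) -> int:
        """Number of records with a defined IMD."""
        return int(self.df["imd"].notna().sum())

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        return path


def compute_imd(table: VariantTable) -> ImdTable:
    """Sort a variant table genomically and attach inter-mutational distances.

    Per chromosome, record i > 1 gets ``imd = pos_i - pos_{i-1}``; the first
    record's IMD is undefined (NaN).  Duplicate positions — which would give
    an IMD of 0 — are collapsed to the first variant in alt order and the
    collapsed count is reported on the result.
    """
    df = table.df
    if df.empty:
        warnings.warn(f"sample {table.sample_id}: empty variant table", ImdWarning)
        return ImdTable(
            pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "imd", "subst_class"]),
            sample_id=table.sample_id,
        )
    before = len(df)
    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first").copy()
    n_collapsed = before - len(df)
    if n_collapsed:
        warnings.warn(
            f"sample {table.sample_id}: collapsed {n_collapsed} duplicate-position variants",
            ImdWarning,
        )
    # table is already sorted by (chrom key, pos); diff within chromosome
    df["imd"] = df.groupby("chrom", sort=False)["pos"].diff()
    df["subst_class"] = [
        classify_substitution(r, a) for r, a in zip(df["ref"], df["alt"])
    ]
    df = df[["chrom", "pos", "ref", "alt", "imd", "subst_class"]]
    return ImdTable(df, sample_id=table.sample_id, n_duplicates_collapsed=n_collapsed)


def drop_sparse_samples(samples: SampleSet, min_variants: int = 2) -> SampleSet:
    """Remove samples with too few SNVs to yield inter-mutational distances.

    A warning names every removed sample.  ``min_variants`` defaults to 2,
    the minimum for a single distance; focus calling additionally needs
    enough points for segmentation.
    """
    if min_variants < 2:
        raise ValueError("min_variants must be >= 2")
    kept = {sid: t for sid, t in samples.items() if len(t) >= min_variants}
    dropped = sorted(set(samples) - set(kept))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} sample(s) with < {min_variants} variants: "
            + ", ".join(dropped),
            ImdWarning,
        )
    if not kept:
        warnings.warn("all samples dropped as too sparse", ImdWarning)
    return kept
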