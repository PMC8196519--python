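"""Reading and writing somatic variant tables (VCF, MAF, chrom sizes).

Only single-nucleotide substitutions enter the kataegis pipeline: the
localized-hypermutation definition and the substitution spectra are both
SNV-based.  Indels, MNVs and symbolic alleles are dropped with a count.
Coordinates are 1-based (VCF convention) throughout the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import pysam

_BASES = frozenset("ACGT")

#: Columns every MAF must provide.
MAF_REQUIRED = (
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
)


class VariantIOWarning(UserWarning):
    """Raised for recoverable input conditions (empty tables, dropped rows)."""


@dataclass(frozen=True)
class Variant:
    """One somatic single-base substitution (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Karyotype-aware sort key: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


class VariantTable:
    """An ordered, de-duplicated table of SNVs for one sample.

    The table is backed by a :class:`pandas.DataFrame` with columns
    ``chrom, pos, ref, alt, filter_status``, sorted by (chrom, pos, alt)
    with duplicate (chrom, pos, alt) rows removed.
    """

    COLUMNS = ("chrom", "pos", "ref", "alt", "filter_status")

    def __init__(
        self,
        df: pd.DataFrame,
        sample_id: str,
        source_format: str = "vcf",
        n_dropped_non_snv: int = 0,
    ) -> None:
        if source_format not in {"vcf", "maf", "simulated"}:
            raise ValueError(f"unknown source_format {source_format!r}")
        df = df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                if col == "filter_status":
                    df[col] = "PASS"
                else:
                    raise ValueError(f"variant frame is missing column {col!r}")
        df = df[list(self.COLUMNS)]
        df["pos"] = df["pos"].astype(int)
        order = df["chrom"].map(chrom_sort_key)
        df = (
            df.assign(_key=order)
            .sort_values(["_key", "pos", "alt"], kind="mergesort")
            .drop(columns="_key")
            .drop_duplicates(subset=["chrom", "pos", "alt"], keep="first")
            .reset_index(drop=True)
        )
        self.df = df
        self.sample_id = sample_id
        self.source_format = source_format
        self.n_dropped_non_snv = n_dropped_non_snv

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"VariantTable(sample_id={self.sample_id!r}, n={len(self)}, "
            f"source={self.source_format!r})"
        )

    @property
    def variants(self) -> list[Variant]:
        return [
            Variant(self.sample_id, r.chrom, int(r.pos), r.ref, r.alt, r.filter_status)
            for r in self.df.itertuples()
        ]

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, int, str, str]] | list[tuple[str, int, str, str, str]],
        sample_id: str,
        source_format: str = "simulated",
    ) -> "VariantTable":
        cols = ["chrom", "pos", "ref", "alt", "filter_status"][: len(records[0])] if records else ["chrom", "pos", "ref", "alt"]
        df = pd.DataFrame(records, columns=cols)
        return cls(df, sample_id=sample_id, source_format=source_format)


#: A SampleSet is a plain mapping sample_id -> VariantTable.
SampleSet = dict


def _filter_passes(filter_status: str) -> bool:
    # "crude" FILTER rule: keep PASS and missing ("." in VCF, empty in MAF)
    return filter_status in {"PASS", ".", ""}


def _is_snv(ref: Optional[str], alt: Optional[str]) -> bool:
    return (
        ref is not None
        and alt is not None
        and len(ref) == 1
        and len(alt) == 1
        and ref.upper() in _BASES
        and alt.upper() in _BASES
    )


def read_vcf(path: str | Path, apply_filter: bool = True) -> VariantTable:
    """Read somatic SNVs from a VCF v4.x file (plain or bgzipped).

    Multi-allelic records are expanded into one variant per SNV allele.
    Records whose REF or any ALT is not a single A/C/G/T base (indels,
    MNVs, symbolic alleles) are dropped and counted in
    ``VariantTable.n_dropped_non_snv``.

    Parameters
    ----------
    path
        VCF file path.
    apply_filter
        When true (default), keep only records whose FILTER is ``PASS`` or
        missing (``.``) — the crude quality filter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such VCF: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_id = next(iter(vf.header.samples), None) or _stem(path)
    rows = []
    n_dropped = 0
    try:
        for rec in vf:
            filters = list(rec.filter.keys())
            status = "." if not filters else ";".join(filters)
            if apply_filter and not (not filters or filters == ["PASS"]):
                continue
            alts = rec.alts or ()
            any_snv = False
            for alt in alts:
                if _is_snv(rec.ref, alt):
                    any_snv = True
                    rows.append((rec.contig, rec.pos, rec.ref.upper(), alt.upper(), status))
            if not any_snv:
                n_dropped += 1
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed record in VCF {path}: {exc}") from exc
    finally:
        vf.close()
    if not rows:
        warnings.warn(f"no SNVs retained from {path}", VariantIOWarning)
        df = pd.DataFrame(columns=list(VariantTable.COLUMNS))
    else:
        df = pd.DataFrame(rows, columns=list(VariantTable.COLUMNS))
    return VariantTable(df, sample_id=sample_id, source_format="vcf",
                        n_dropped_non_snv=n_dropped)


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".gz", ".vcf", ".maf"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def read_maf(
    path: str | Path,
    separate_samples: bool = True,
    apply_filter: bool = False,
    filter_column: str = "FILTER",
) -> "SampleSet | VariantTable":
    """Read somatic SNVs from a TCGA-style MAF file.

    Only ``Variant_Type == "SNP"`` rows are kept (or, when that column is
    absent, rows whose alleles are both single bases).  MAF files have no
    mandatory quality field, so no filtering is applied by default; set
    ``apply_filter=True`` to keep only rows whose ``filter_column`` is
    ``PASS`` or empty, when such a column exists.

    Returns
    -------
    dict[str, VariantTable]
        One table per ``Tumor_Sample_Barcode`` when ``separate_samples``.
    VariantTable
        A single merged table (``sample_id="merged"``) otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such MAF: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in MAF_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"MAF {path} lacks mandatory column {col!r}")
    if "Variant_Type" in df.columns:
        df = df[df["Variant_Type"] == "SNP"]
    df = df[
        df["Reference_Allele"].str.upper().isin(_BASES)
        & df["Tumor_Seq_Allele2"].str.upper().isin(_BASES)
        & (df["Reference_Allele"].str.upper() != df["Tumor_Seq_Allele2"].str.upper())
    ]
    status = df[filter_column] if filter_column in df.columns else pd.Series("PASS", index=df.index)
    if apply_filter and filter_column in df.columns:
        keep = status.map(_filter_passes)
        df = df[keep]
        status = status[keep]
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"],
            "pos": df["Start_Position"].astype(int),
            "ref": df["Reference_Allele"].str.upper(),
            "alt": df["Tumor_Seq_Allele2"].str.upper(),
            "filter_status": status.values if len(df) else [],
            "sample": df["Tumor_Sample_Barcode"],
        }
    )
    if not separate_samples:
        return VariantTable(out.drop(columns="sample"), sample_id="merged",
                            source_format="maf")
    samples: SampleSet = {}
    for sid, group in out.groupby("sample", sort=True):
        samples[str(sid)] = VariantTable(
            group.drop(columns="sample"), sample_id=str(sid), source_format="maf"
        )
    if not samples:
        warnings.warn(f"no SNVs retained from {path}", VariantIOWarning)
    return samples


def write_vcf(
    table: VariantTable,
    path: str | Path,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> Path:
    """Write a minimal sites-only VCF v4.2 (all records FILTER=PASS).

    ``read_vcf(write_vcf(t))`` reproduces (chrom, pos, ref, alt) exactly.
    Contig header lines carry lengths when ``chrom_sizes`` is given.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(table.df["chrom"]))
    if chrom_sizes:
        for chrom in chrom_sizes:
            header.contigs.add(chrom, length=int(chrom_sizes[chrom]))
    for chrom in chroms:
        if chrom not in header.contigs:
            header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in table.df.itertuples():
            rec = out.new_record(
                contig=r.chrom, start=int(r.pos) - 1, stop=int(r.pos),
                alleles=(r.ref, r.alt),
            )
            rec.filter.add("PASS")
            out.write(rec)
    return path


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column tab-delimited chromosome-sizes table.

    Order of appearance is preserved (it fixes the x-axis layout of
    genome-wide plots).  Duplicate chromosome names or non-integer sizes
    are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such chrom-sizes file: {path}")
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            chrom, size_str = fields[0], fields[1]
            try:
                size = int(size_str)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer size {size_str!r}") from None
            if size <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive size {size}")
            if chrom in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
            sizes[chrom] = size
    return sizes
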