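"""Substitution spectra and nucleotide content of hypermutated regions.

Somatic single-base substitutions are conventionally collapsed onto the
pyrimidine of the mutated base pair, giving six classes (C>A, C>G, C>T,
T>A, T>C, T>G).  This module classifies substitutions, tabulates class
counts genome-wide or restricted to called kataegis foci, and measures the
A/C/G/T composition of foci and of their flanking sequence.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

from pyfaidx import Fasta

if TYPE_CHECKING:  # pragma: no cover
    from .pcf import KataegisFocus
    from .variant_io import VariantTable

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SpectraWarning(UserWarning):
    """Raised for recoverable issues (empty flanks, REF mismatches)."""


def classify_substitution(ref: str, alt: str) -> str:
    """Return the pyrimidine-collapsed class of a single-base substitution.

    Purine-reference changes are reverse-complemented so that the reported
    reference base is C or T: e.g. G>T collapses to C>A, A>G to T>C.

    Raises
    ------
    ValueError
        If either base is not one of A/C/G/T or if ``ref == alt``.
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumCounts:
    """Counts of the six substitution classes over a scope of SNVs."""

    counts: dict[str, int]
    scope: str = "all"  # one of {"all", "foci", "flank"}

    def __post_init__(self) -> None:
        full = {c: 0 for c in SUBSTITUTION_CLASSES}
        full.update(self.counts)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class ContentProfile:
    """Base composition of a region class (focus or flank).

    ``fractions`` are over counted A/C/G/T bases only; N and other ambiguity
    codes are excluded from ``n_bases``.
    """

    region: str  # "focus" or "flank"
    fractions: dict[str, float]
    n_bases: int

    def __post_init__(self) -> None:
        if self.n_bases > 0:
            total = sum(self.fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"fractions sum to {total}, expected 1")


def spectrum(
    table: "VariantTable",
    foci: Optional[Sequence["KataegisFocus"]] = None,
) -> SpectrumCounts:
    """Tabulate substitution classes, optionally restricted to focus SNVs.

    When ``foci`` is given, only variants lying inside a focus interval
    (1-based inclusive, matching chromosome) are counted and the scope is
    reported as ``"foci"``.
    """
    df = table.df
    if foci is not None:
        keep = [
            any(
                f.chrom == row.chrom and f.start_pos <= row.pos <= f.end_pos
                for f in foci
            )
            for row in df.itertuples()
        ]
        df = df[keep]
        scope = "foci"
    else:
        scope = "all"
    counts = Counter(
        classify_substitution(r, a) for r, a in zip(df["ref"], df["alt"])
    )
    return SpectrumCounts(dict(counts), scope=scope)


def _merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Union of 1-based inclusive intervals, merged per chromosome."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    merged: list[tuple[str, int, int]] = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def _subtract_intervals(
    minuend: list[tuple[str, int, int]],
    subtrahend: list[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Remove (per chromosome) subtrahend intervals from minuend intervals."""
    sub_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in subtrahend:
        sub_by_chrom.setdefault(chrom, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in minuend:
        pieces = [(s, e)]
        for bs, be in sub_by_chrom.get(chrom, []):
            next_pieces = []
            for ps, pe in pieces:
                if be < ps or bs > pe:
                    next_pieces.append((ps, pe))
                    continue
                if ps < bs:
                    next_pieces.append((ps, bs - 1))
                if be < pe:
                    next_pieces.append((be + 1, pe))
            pieces = next_pieces
        out.extend((chrom, ps, pe) for ps, pe in pieces)
    return out


def _count_bases(fasta: Fasta, intervals: list[tuple[str, int, int]]) -> Counter:
    counts: Counter = Counter()
    for chrom, start, end in intervals:
        seq = str(fasta[chrom][start - 1 : end]).upper()
        counts.update(seq)
    return Counter({b: counts.get(b, 0) for b in "ACGT"})


def nucleotide_content(
    foci: Sequence["KataegisFocus"],
    fasta: str | Fasta,
    flank_bp: int = 1000,
) -> list[ContentProfile]:
    """Base composition of kataegis foci and of their flanking sequence.

    The focus profile covers the union of all focus intervals.  The flank
    profile covers ``flank_bp`` on each side of every focus, clipped to
    chromosome bounds, unioned, and with focus bases removed so that no base
    is counted in both regions.

    Parameters
    ----------
    foci
        Called foci with ``chrom``/``start_pos``/``end_pos`` (1-based
        inclusive) attributes.
    fasta
        Path to an indexed FASTA, or an open :class:`pyfaidx.Fasta`.
    flank_bp
        Width of the flank on each side of a focus, in bp (>= 1).
    """
    if flank_bp < 1:
        raise ValueError("flank_bp must be >= 1")
    if not foci:
        raise ValueError("no foci supplied")
    fa = fasta if isinstance(fasta, Fasta) else Fasta(str(fasta))
    chrom_lens = {name: len(fa[name]) for name in fa.keys()}
    for f in foci:
        if f.chrom not in chrom_lens:
            raise ValueError(f"chromosome {f.chrom!r} absent from FASTA")

    focus_ivs = _merge_intervals((f.chrom, f.start_pos, f.end_pos) for f in foci)
    flank_raw = []
    for f in foci:
        clen = chrom_lens[f.chrom]
        left = (f.chrom, max(1, f.start_pos - flank_bp), f.start_pos - 1)
        right = (f.chrom, f.end_pos + 1, min(clen, f.end_pos + flank_bp))
        for iv in (left, right):
            if iv[1] <= iv[2]:
                flank_raw.append(iv)
    flank_ivs = _subtract_intervals(_merge_intervals(flank_raw) if flank_raw else [], focus_ivs)

    profiles = []
    for region, ivs in (("focus", focus_ivs), ("flank", flank_ivs)):
        counts = _count_bases(fa, ivs)
        n = sum(counts.values())
        if n == 0:
            warnings.warn(
                f"{region} region is empty after clipping; profile omitted",
                SpectraWarning,
            )
            continue
        fractions = {b: counts[b] / n for b in "ACGT"}
        profiles.append(ContentProfile(region=region, fractions=fractions, n_bases=n))
    return profiles
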