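"""Benchmark simulator: mutate a sequence with or without planted kataegis.

The simulator emulates a somatic SNV caller's output on a single
chromosome.  It places ``round(tmb * length / 1e6)`` background mutations
and, in kataegis mode, additionally plants ``n_foci`` non-overlapping
windows of at most ``focus_window_bp`` (default 1000 bp), each holding more
than six mutations (a uniform count in ``focus_mut_range``, default 7-20,
matching the "occasional, small (< 20 mutations)" foci reported in
cancer genomes).  In non-kataegis mode, background positions keep a
minimum gap of ``focus_window_bp + 1`` so that no 1-kb window can hold
more than one mutation — a deliberately conservative guarantee that the
kataegis definition is never triggered by chance.

Identical configurations (including the seed) give byte-identical VCFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .imd import compute_imd
from .pcf import KataegisResult, PcfParams, kata
from .variant_io import VariantTable, write_vcf

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated chromosome.

    The defaults are the benchmark conditions: a 10-Mb uniform-random
    chromosome at TMB 10 mutations/Mb, with (in kataegis mode) three
    planted foci of 7-20 mutations inside 1-kb windows.
    """

    chrom_name: str = "chr_sim"
    seq_length: int = 10_000_000
    tmb: float = 10.0
    kataegis_mode: bool = False
    n_foci: int = 3
    focus_mut_range: tuple[int, int] = (7, 20)
    focus_window_bp: int = 1000
    seed: int = 0
    fasta: Optional[str] = None  # optional real sequence instead of random

    def __post_init__(self) -> None:
        if self.tmb <= 0:
            raise SimulationError("tmb must be positive")
        if self.focus_mut_range[0] < 7:
            raise SimulationError(
                "focus_mut_range low bound must be >= 7 (more than six mutations)"
            )
        if self.focus_mut_range[0] > self.focus_mut_range[1]:
            raise SimulationError("focus_mut_range must be (low, high) with low <= high")
        if not 1 <= self.focus_window_bp <= 1000:
            raise SimulationError("focus_window_bp must be in [1, 1000]")
        if self.kataegis_mode and self.n_foci < 1:
            raise SimulationError("kataegis mode requires n_foci >= 1")


@dataclass
class SimTruth:
    """Ground-truth planted foci: (chrom, start, end, n_mut), 1-based inclusive."""

    foci: list[tuple[str, int, int, int]]
    total_mutations: int

    def write_bed(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for k, (chrom, start, end, n_mut) in enumerate(self.foci, start=1):
                fh.write(f"{chrom}\t{start - 1}\t{end}\ttruth_{k}\t{n_mut}\n")
        return path


@dataclass
class SimResult:
    variants: VariantTable
    truth: SimTruth
    reference: np.ndarray  # uint8 base codes 0..3 of the unmutated sequence
    sequence: np.ndarray   # uint8 base codes of the mutated sequence

    def reference_str(self) -> str:
        return _BASE_CODES[self.reference].tobytes().decode()

    def sequence_str(self) -> str:
        return _BASE_CODES[self.sequence].tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random base codes (0..3 for A/C/G/T)."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _load_fasta_codes(path: str, chrom: str) -> np.ndarray:
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    name = chrom if chrom in fa.keys() else next(iter(fa.keys()))
    seq = str(fa[name][:]).upper()
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    out = lut[codes]
    if np.any(out == 255):
        # replace ambiguity codes with A so every position is mutable
        out[out == 255] = 0
    return out


def _spaced_positions(n: int, length: int, gap: int, rng: np.random.Generator) -> np.ndarray:
    """n sorted 1-based positions in [1, length] with pairwise differences > gap."""
    slack = length - (n - 1) * gap
    if slack < n:
        raise SimulationError(
            f"sequence of {length} bp cannot host {n} mutations spaced > {gap} bp apart"
        )
    x = np.sort(rng.choice(slack, size=n, replace=False)) + 1
    return x + gap * np.arange(n)


def _positions_outside_windows(
    n: int, length: int, windows: list[tuple[int, int]], rng: np.random.Generator
) -> np.ndarray:
    """n distinct 1-based positions uniform over [1, length] minus the windows."""
    gaps = []  # complement intervals, 1-based inclusive
    cursor = 1
    for ws, we in sorted(windows):
        if ws > cursor:
            gaps.append((cursor, ws - 1))
        cursor = we + 1
    if cursor <= length:
        gaps.append((cursor, length))
    lens = np.array([e - s + 1 for s, e in gaps], dtype=np.int64)
    total = int(lens.sum())
    if total < n:
        raise SimulationError("not enough sequence outside focus windows")
    u = np.sort(rng.choice(total, size=n, replace=False))
    starts = np.array([s for s, _ in gaps], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(lens)))[:-1]
    idx = np.searchsorted(offsets, u, side="right") - 1
    return starts[idx] + (u - offsets[idx])


def simulate(config: SimConfig) -> SimResult:
    """Mutate a (random or supplied) sequence under the configured conditions.

    Returns the emitted variant table, the planted-focus ground truth, and
    both the original and mutated sequences.  All randomness flows from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if config.fasta is not None:
        ref = _load_fasta_codes(config.fasta, config.chrom_name)
    else:
        ref = random_sequence(config.seq_length, rng)
    length = ref.size
    n_bg = int(round(config.tmb * length / 1e6))
    if n_bg < 1:
        raise SimulationError("tmb * length yields zero mutations")

    truth_foci: list[tuple[str, int, int, int]] = []
    w = config.focus_window_bp
    if config.kataegis_mode:
        # non-overlapping window starts (separation > w guarantees it)
        starts = _spaced_positions(config.n_foci, length - w + 1, w, rng)
        windows = [(int(s), int(s) + w - 1) for s in starts]
        focus_pos: list[np.ndarray] = []
        for ws, we in windows:
            c = int(rng.integers(config.focus_mut_range[0], config.focus_mut_range[1] + 1))
            p = np.sort(rng.choice(w, size=c, replace=False)) + ws
            focus_pos.append(p)
            truth_foci.append((config.chrom_name, int(p[0]), int(p[-1]), c))
        bg = _positions_outside_windows(n_bg, length, windows, rng)
        positions = np.sort(np.concatenate([bg] + focus_pos))
    else:
        positions = _spaced_positions(n_bg, length, w, rng)

    ref_codes = ref[positions - 1]
    shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
    alt_codes = (ref_codes + shift) % 4
    mutated = ref.copy()
    mutated[positions - 1] = alt_codes

    bases = np.array(list("ACGT"))
    df = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "pos": positions,
            "ref": bases[ref_codes],
            "alt": bases[alt_codes],
            "filter_status": "PASS",
        }
    )
    table = VariantTable(
        df, sample_id=f"sim_seed{config.seed}", source_format="simulated"
    )
    truth = SimTruth(foci=truth_foci, total_mutations=int(positions.size))
    return SimResult(variants=table, truth=truth, reference=ref, sequence=mutated)


def simulate_to_vcf(config: SimConfig, out_prefix: str | Path) -> tuple[Path, Path]:
    """Run :func:`simulate` and write ``<prefix>.vcf`` plus ``<prefix>.truth.bed``."""
    out_prefix = Path(out_prefix)
    res = simulate(config)
    vcf = write_vcf(
        res.variants,
        Path(f"{out_prefix}.vcf"),
        chrom_sizes={config.chrom_name: res.reference.size},
    )
    bed = res.truth.write_bed(Path(f"{out_prefix}.truth.bed"))
    return vcf, bed


@dataclass
class BenchmarkResult:
    report: pd.DataFrame
    n_pos: int
    n_neg: int
    n_detected: int        # positive files with >= 1 called focus
    n_false_positive: int  # negative files with >= 1 called focus

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        return 1.0 - self.n_false_positive / self.n_neg if self.n_neg else float("nan")


def run_benchmark(
    n_pos: int,
    n_neg: int,
    config: Optional[SimConfig] = None,
    params: Optional[PcfParams] = None,
    out_dir: Optional[str | Path] = None,
) -> BenchmarkResult:
    """Simulate positive and negative samples and score detection on each.

    File i uses seed ``config.seed + i`` (positives first).  A positive
    sample counts as detected iff at least one focus is called; a negative
    sample counts as a false positive iff any focus is called.  When
    ``out_dir`` is given, every simulated VCF (and positive truth BED) is
    also written there.
    """
    if n_pos < 1 or n_neg < 1:
        raise SimulationError("n_pos and n_neg must both be >= 1")
    config = config or SimConfig()
    params = params or PcfParams()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        cfg = replace(config, kataegis_mode=positive, seed=config.seed + i)
        res = simulate(cfg)
        called = kata(compute_imd(res.variants), params)
        label = "pos" if positive else "neg"
        name = f"{label}_{(i if positive else i - n_pos) + 1:03d}"
        if out_dir is not None:
            write_vcf(res.variants, out_dir / f"{name}.vcf",
                      chrom_sizes={cfg.chrom_name: res.reference.size})
            if positive:
                res.truth.write_bed(out_dir / f"{name}.truth.bed")
        rows.append(
            {
                "file": name,
                "mode": "kataegis" if positive else "background",
                "seed": cfg.seed,
                "n_variants": len(res.variants),
                "n_planted_foci": len(res.truth.foci),
                "n_called_foci": len(called.foci),
                "detected": len(called.foci) > 0,
            }
        )
    report = pd.DataFrame(rows)
    pos_mask = report["mode"] == "kataegis"
    return BenchmarkResult(
        report=report,
        n_pos=n_pos,
        n_neg=n_neg,
        n_detected=int(report.loc[pos_mask, "detected"].sum()),
        n_false_positive=int(report.loc[~pos_mask, "detected"].sum()),
    )
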