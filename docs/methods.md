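# Methods

## Model and procedure

Kataegis is treated operationally: a genomic interval holding at least
`min_mut` single-base substitutions whose mean inter-mutational distance
(IMD) is at most `max_mean_imd` bp. The defaults (`min_mut=6`,
`max_mean_imd=1000`) encode the common "six mutations within 1000 bp"
definition; `min_mut=5` reproduces the more permissive published variant.
Only single-base substitutions participate: indels, MNVs and symbolic
alleles are dropped on input with a count, because both the definition and
the substitution spectra are SNV-based.

IMDs are defined between neighbouring variants on the same chromosome
after coordinate sorting; the first variant of each chromosome has no IMD
and distances never cross chromosome boundaries. Variants sharing a
position are collapsed (keeping the alphabetically first alternate) so
every defined IMD is ≥ 1 and `log10(IMD)` is finite.

Segmentation minimizes, over all contiguous segmentations of a
chromosome's ordered `log10(IMD)` series,

    sum_seg sum_{i in seg} (v_i - mean_seg)^2  +  gamma * (#breakpoints)

subject to each segment holding at least `kmin` points. The minimizer is
found exactly by an O(n²) dynamic program over prefix objectives with
prefix-sum SSE evaluation; ties (equal objective within 1e-9 relative) are
broken toward fewer segments. Segmentation operates on the log scale
because IMDs span five orders of magnitude; a focus is then a factor-wise,
not additive, anomaly, which is exactly what a least-squares fit on logs
separates. A segment over IMD indices i..j maps back to variants i..j+1,
so consecutive segments share their boundary variant and
`sum(n_mut) = n_variants + n_segments − 1` per chromosome. No denser-side
reattribution of boundary variants is attempted (documented
simplification).

## Parameter calibration

`gamma` (per-breakpoint penalty, in squared log10-IMD units) and `kmin`
are the only free parameters of the segmentation. Carving k points with
mean separation Δ (log10 units) out of a large segment reduces the SSE by
roughly k·Δ², so a run of k clustered mutations is isolated whenever
k·Δ² exceeds the breakpoint cost. Under the defining conditions — a focus
of ≥ 7 mutations within 1 kb (per-focus Δ ≈ 2.3–2.7 against a background
of ~10 mutations/Mb) — the smallest foci provide a gain of roughly 40,
while the internal SSE of a homogeneous run or background series is of
order 1–3. The default `gamma=3` sits in the wide window between those
scales; a grid scan on 150 simulated positive and 150 negative 10-Mb
samples showed per-focus detection degrading for `gamma ≥ 5` (large
penalties merge the smallest foci into flanking segments) and
over-fragmentation below `gamma ≈ 1`. `kmin=1` lets a single bridging
distance — e.g. the long IMD between a focus and a lone flanking variant —
form its own segment; larger `kmin` forces such bridges into the focus
segment and inflates its mean IMD. Both parameters are exposed on the API
and CLI.

False calls on kataegis-free data are structurally impossible whenever all
IMDs exceed `max_mean_imd`: every segment's mean IMD then exceeds the
threshold regardless of the segmentation, so specificity does not depend
on `gamma`.

## Input handling

The crude FILTER rule keeps VCF records whose FILTER is `PASS` or missing
(`.`); treating `.` as a pass is an assumption (unfiltered call sets mark
every record `.`). MAF files have no mandatory quality column, so MAF
filtering is off by default and, when enabled, applies the same rule to a
user-named column (`FILTER` by default). Chromosome names are compared as
exact strings and ordered karyotypically (chr1 < chr2 < chr10 < chrX).
Coordinates are 1-based inclusive end-to-end; only the BED exports convert
to 0-based half-open.

## Simulator

The simulator emulates the *output* of somatic SNV calling on one
chromosome, not sequencing itself: no read errors, no indels, no
signature-aware substitution bias (alternate bases are uniform over the
three non-reference bases), and a uniform-random reference by default (a
real FASTA can be supplied). Background burden is `round(TMB × L / 1e6)`
mutations. In kataegis mode, `n_foci` non-overlapping 1-kb windows are
placed uniformly at random (window starts separated by more than the
window width), each receiving a uniform count in `focus_mut_range`
(default 7–20, matching the "small, < 20 mutations" foci reported in
tumour genomes) at distinct uniform positions; background positions are
drawn from the sequence outside the windows, so focus and background never
collide. In negative mode, consecutive mutations keep a minimum gap of
`focus_window_bp + 1`, a deliberately stronger condition than the minimal
"never > 6 per 1-kb window" requirement — any 1-kb window then holds at
most one mutation. All draws flow from a single seeded generator, making
VCF output byte-identical for identical configurations.

Because the simulated background is uniform and foci are cleanly
separated, a perfect benchmark score shows the detector is correct under
the definition, not that real tumours are this easy: real data have
replication-timing-structured backgrounds, shared positions across
samples, and foci co-located with rearrangements.

The benchmark runs 50 positive and 50 negative samples on a 10-Mb
chromosome at TMB 10/Mb — a scaled-down stand-in chosen so the whole
benchmark completes in seconds while each sample still carries ~100
background mutations, enough for the segmentation to face a realistic
background series. File i uses seed `base_seed + i`, recorded per file in
the report.

## Numerical and degenerate-input choices

- Series shorter than `kmin` return a single segment with a warning;
  chromosomes with one variant contribute no IMD and are skipped by the
  caller with a warning when nothing is segmentable.
- Non-finite segmentation inputs are errors; duplicate positions are
  collapsed before the log transform.
- Sample sets can be pruned with `drop_sparse_samples` (default minimum 2
  variants, the minimum for one distance); removed sample IDs are listed
  in the warning.
- Flank composition uses 1000 bp per side by default (the focus window
  scale); flank intervals are clipped to chromosome bounds, unioned, and
  focus bases removed so no base is counted twice. N bases are excluded
  from composition denominators. An entirely clipped flank yields a
  warning and an omitted profile rather than an error.
- Plots export their underlying table as `<image>.data.tsv`; analyses
  should assert on the tables, not pixels.

## Known limitations

- No trinucleotide (96-class) signatures or signature extraction; spectra
  are 6-class only.
- No co-localization analysis with structural variants, no per-sample
  false-discovery control for focus calls, and no strand-specific IMD.
- The O(n²) dynamic program is exact but not intended for series beyond a
  few tens of thousands of points per chromosome.
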