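"""Call kataegis foci on a small in-memory sample.

Builds a chromosome with sparse background mutations plus one dense
cluster, computes inter-mutational distances, segments them and prints the
called foci.
"""

import numpy as np

from katacall import PcfParams, VariantTable, compute_imd, kata

rng = np.random.default_rng(0)

# ~40 background SNVs spread over 4 Mb, plus 9 SNVs within ~700 bp
background = np.cumsum(rng.integers(50_000, 150_000, size=40))
cluster = 2_000_000 + np.sort(rng.choice(700, size=9, replace=False))
positions = np.sort(np.concatenate([background, cluster]))
table = VariantTable.from_records(
    [("chr1", int(p), "C", "T") for p in positions], sample_id="demo"
)

imd = compute_imd(table)
result = kata(imd, PcfParams())  # gamma=3, kmin=1, min_mut=6, max_mean_imd=1000

print(f"{len(table)} SNVs -> {len(result.segments)} segments, "
      f"{len(result.foci)} kataegis focus/foci")
for f in result.foci:
    print(f"  focus {f.focus_id}: {f.chrom}:{f.start_pos}-{f.end_pos} "
          f"({f.n_mut} mutations, mean IMD {f.mean_imd:.1f} bp)")
# The focus is the planted cluster: >=6 mutations whose mean spacing is
# far below 1000 bp, while background spacing is ~100 kb.
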