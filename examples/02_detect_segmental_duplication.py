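"""Detect an autosome-to-Y segmental duplication from sexed read depth.

Implants 6 hemizygous Y copies of a 50 kb autosomal interval, simulates 20x
male/female reads, places them back on the source assembly and calls the
duplication from the excess male depth.  Each Y copy adds 0.5 to the
normalized male track, so 6 copies push it to about 1 + 6/2 = 4.
"""

import ytraffic as yt
from ytraffic import covdup

spec = yt.GenomeSpec(n_autosomal_scaffolds=1, n_y_scaffolds=0,
                     scaffold_length_bp=300_000, gc=0.45, seed=4)
source, truth = yt.simulate_genome(spec)
src = next(iter(source))
genome, truth = yt.implant_segdup(source, (src, 100_000, 150_000), n_copies=6,
                                  seed=5, truth=truth)

male, _ = yt.simulate_reads(genome, truth, yt.ReadSimConfig(sex="male", depth=20, seed=6))
female, _ = yt.simulate_reads(genome, truth, yt.ReadSimConfig(sex="female", depth=20, seed=7))

pm, _ = covdup.place_reads(male, source)
pf, _ = covdup.place_reads(female, source)
lengths = {src: len(source[src])}
bins = covdup.bin_depth(
    covdup.depth_from_placements(pm, lengths, 100),
    covdup.depth_from_placements(pf, lengths, 100),
)
track = covdup.normalize(bins, *covdup.autosomal_baseline(bins, [src]))
calls = covdup.call_segdups(track)
print(calls.drop(columns=["n_male_specific_snps"]).to_string(index=False))
print("\nThe call should span ~100-150 kb with est_copies ~ 6: male depth in")
print("the window is ~4x the autosomal baseline while female depth stays flat.")
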