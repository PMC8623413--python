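"""Sort functional Y-gene copies from pseudogenes.

A copy is functional only with an intact CDS (no premature stop, no net
frameshift) and more than 10% of its copy group's expression.  The example
disables one copy with a premature stop, one with a 1-bp frameshift, and
silences a third (3% expression share, mirroring a borderline real case).
"""

from ytraffic import genefate
from ytraffic.simdata import pseudogenize, random_cds

reference = random_cds(150, seed=8)

copies = {
    "y_intact": (reference, 0.45),
    "y_stop": (pseudogenize(reference, stop_rate=0.03, seed=9)[0], 0.45),
    "y_frameshift": (pseudogenize(reference, frameshift_rate=0.01, seed=12)[0], 0.45),
    "y_silenced": (reference, 0.03),
}

for name, (cds, share) in copies.items():
    integrity = genefate.check_cds_integrity(cds, reference)
    identity = genefate.nucleotide_identity(cds, reference)
    fate = genefate.classify_fate(name, integrity, share, identity)
    print(f"{name:13s} integrity={integrity.status:14s} share={share:.2f} "
          f"identity={identity:.3f} -> {fate.status}" + (" (recent)" if fate.recent_flag else ""))

print("\nOnly the intact, expressed copy is functional; a disabled CDS or a")
print("<=10% expression share makes the copy a pseudogene either way.")

call = genefate.infer_mechanism("y_intact", ("s2", 0, 450), None, [120], [120])
print(f"\nmechanism for y_intact: {call.call} ({call.reason})")
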