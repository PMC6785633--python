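"""Interval algebra on LAD sets: intersect, jaccard, gain/loss decomposition.

Builds two small LAD samples (think: non-synchronized liver vs the first
circadian time point after clock entrainment) and quantifies how coverage
changed and in what form.
"""

from ladcycle import IntervalSet, classify_gain_loss, gain_loss_totals

ns = IntervalSet.from_tuples(
    [("chr1", 1_000_000, 3_000_000), ("chr1", 8_000_000, 9_000_000)], label="NS"
).normalize()
ct0 = IntervalSet.from_tuples(
    [("chr1", 1_000_000, 4_500_000), ("chr1", 12_000_000, 13_000_000)], label="CT0"
).normalize()

print(f"coverage NS  = {ns.coverage() / 1e6:.1f} Mb")
print(f"coverage CT0 = {ct0.coverage() / 1e6:.1f} Mb")
print(f"jaccard(NS, CT0) = {ns.jaccard(ct0):.3f}")

records = classify_gain_loss(ns, ct0)
print("\nper-region changes (CT0 relative to NS):")
print(records.to_string(index=False))
print("\nbp totals by direction and mode:")
print(gain_loss_totals(records).to_string(index=False))
# A gained region attached to an existing LAD is an "extension"; a gained
# region with no overlap to any NS LAD is a "stand-alone" new LAD, and
# symmetrically for losses.
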