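"""Positivity calling with germline and no-template controls.

Shows the core decision rules: two FAM droplets inside one replicate call a
sample positive, the same two droplets split across replicates do not, and
any signal in a control invalidates the timepoint.
"""

from liquidmrd.calling import call_replicate, call_sample, flag_chip

clean = [call_replicate(0), call_replicate(0)]
dirty = [call_replicate(3), call_replicate(0)]

for fam_counts, controls, label in [
    ([2], clean, "2 FAM droplets in one replicate, clean controls"),
    ([1, 1], clean, "1 + 1 FAM droplets split across replicates"),
    ([0, 4], clean, "first replicate negative, second positive"),
    ([5], dirty, "5 FAM droplets but a positive germline control"),
]:
    s = call_sample(fam_counts, controls)
    extras = []
    if s.low_positive_flag:
        extras.append("low-positive: confirm with 2 extra germline wells")
    if s.combine_wells_for_quant:
        extras.append("quantify on wells from both replicates")
    print(f"{label:55s} -> {s.status.value:12s} ({s.reason.value})"
          + (f"  [{'; '.join(extras)}]" if extras else ""))

print()
print("germline itself positive (3 FAM) -> CHIP flag:",
      flag_chip(call_sample([4], clean), matched_germline_fam_positive=3))
# A CHIP flag means the mutation is detectable in the patient's own blood
# cells, so plasma positivity cannot be attributed to the tumor.
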