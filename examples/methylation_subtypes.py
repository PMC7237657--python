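"""ICR methylation QC and molecular subtype assignment."""

from imprintloop import classify_methylation, infer_subtype

cohort = {  # sample -> (ICR1 %, ICR2 %)
    "CTRL1": (42, 43),
    "BWS-ICR1": (78, 42),
    "BWS-ICR2": (44, 16),
    "BWS-UPD": (60, 27),
    "SRS-ICR1": (28, 50),
}

print("sample     ICR1              ICR2              subtype")
for sample, (l1, l2) in cohort.items():
    s1, s2 = classify_methylation(l1, "ICR1"), classify_methylation(l2, "ICR2")
    print(f"{sample:9s}  {l1:3d}% {s1:14s}  {l2:3d}% {s2:14s}  {infer_subtype(s1, s2)}")
# Normal ranges are ICR1 40-52% and ICR2 39-50% (inclusive); the four defect
# patterns map to the classical imprinting-disorder molecular subtypes.
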