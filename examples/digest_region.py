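"""In-silico BglII digestion of a small region and 3C fragment-axis setup."""

from imprintloop import (
    ENZYMES,
    AnnotatedElement,
    GenomicInterval,
    digest_sequence,
    locate_fragments,
)

# a toy 70 bp region with two BglII sites (AGATCT)
seq = "AATTCCGG" + "AGATCT" + "C" * 20 + "AGATCT" + "G" * 30
fragments = digest_sequence(seq, region_start=2_016_000, enzyme=ENZYMES["BglII"])

print(f"{len(fragments)} BglII fragments:")
for f in fragments:
    iv = f.interval
    print(f"  {f.name}  {iv.chrom}:{iv.start}-{iv.end}  ({len(iv)} bp)")

primers = [
    AnnotatedElement(GenomicInterval("chr11", 2_016_001, 2_016_005, name="ICR1"), "anchor_primer"),
    AnnotatedElement(GenomicInterval("chr11", 2_016_020, 2_016_028, name="t_mid"), "test_primer"),
    AnnotatedElement(GenomicInterval("chr11", 2_016_050, 2_016_060, name="t_far"), "test_primer"),
]
axis = locate_fragments(primers, fragments, anchor_name="ICR1")
print(f"anchor fragment: {axis.anchor.name}; test axis: {axis.test_names}")
# Each test fragment becomes one point of the anchor's looping profile;
# a primer spanning a cut site would have been rejected.
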