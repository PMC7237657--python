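"""Allele specificity of 3C contacts from SNP signals in ligation products."""

from imprintloop import SnpSignal, call_haplotype_qualitative, quantify_allele_fraction

heterozygous = {"rs59121562": ("T", "A"), "rs80047492": ("T", "A")}

# qualitative (Sanger-style): only one allele visible at both SNPs
signals = [
    SnpSignal("rs59121562", "T", "A", 120.0, 4.0),
    SnpSignal("rs80047492", "T", "A", 95.0, 0.0),
]
call = call_haplotype_qualitative("ICR1-EnhA", signals, heterozygous)
print(f"{call.interaction}: {call.classification} (haplotype {call.haplotype})")

# quantitative (mass-spectrometry allele frequencies)
for sa, sb in ((900.0, 100.0), (520.0, 480.0)):
    frac, cls = quantify_allele_fraction(SnpSignal("rs80047492", "T", "A", sa, sb), theta=0.8)
    print(f"signals ({sa:.0f}, {sb:.0f}) -> fraction_T {frac:.2f} -> {cls}")
# A contact confined to one parental allele shows a single haplotype and a
# major-allele fraction >= 0.8; balanced signals indicate a biallelic contact.
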