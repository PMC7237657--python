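"""Allele specificity of 3C contacts and ICR methylation status.

3C-SNP assays sequence ligation products across heterozygous SNPs in the
anchor fragment: a contact occurring on one parental allele shows a single
allele in the product (monoallelic, with an observable haplotype), a contact
on both alleles shows both.  Qualitative calls mirror Sanger traces; the
quantitative path uses allele signal intensities (e.g. MassARRAY peak
areas).  ICR methylation percentages are classified against published
normal ranges (ICR1 40-52%, ICR2 39-50%) to QC the cell lines and assign a
molecular subtype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import ValidationError

MONOALLELIC_THRESHOLD = 0.8  # default major-allele fraction for a monoallelic call
MINOR_PRESENCE_FRACTION = 0.2  # qualitative: minor peak >= 20% of major counts as present


@dataclass(frozen=True)
class SnpSignal:
    """Per-SNP allele signals from one 3C ligation product."""

    snp_id: str
    allele_a: str
    allele_b: str
    signal_a: float
    signal_b: float

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.snp_id}: alleles must differ")
        if self.signal_a < 0 or self.signal_b < 0:
            raise ValidationError(f"{self.snp_id}: signals must be >= 0")


@dataclass(frozen=True)
class AlleleCall:
    """Allele-specificity call for one interaction."""

    interaction: str
    classification: str  # monoallelic | biallelic | uninformative
    haplotype: str = ""
    major_fraction: float = 1.0


def call_haplotype_qualitative(
    interaction: str,
    signals: Sequence[SnpSignal],
    heterozygous: Mapping[str, tuple[str, str]],
    minor_presence: float = MINOR_PRESENCE_FRACTION,
) -> AlleleCall:
    """Qualitative (Sanger-style) allele call over the SNPs of one product.

    ``heterozygous`` maps snp_id -> the sample's heterozygous allele pair;
    a SNP absent from it (sample homozygous) makes the call uninformative.
    If every SNP shows a single allele the call is monoallelic with the
    haplotype string (alleles concatenated in the given genomic order);
    a minor allele above ``minor_presence`` of the major peak at any SNP
    makes the call biallelic.
    """
    if not signals:
        raise ValidationError("no SNP signals supplied")
    if any(s.snp_id not in heterozygous for s in signals):
        return AlleleCall(interaction, "uninformative")

    haplotype = []
    fractions = []
    biallelic = False
    for s in signals:
        total = s.signal_a + s.signal_b
        if total == 0:
            raise ValidationError(f"{s.snp_id}: all signals zero")
        major, minor = max(s.signal_a, s.signal_b), min(s.signal_a, s.signal_b)
        haplotype.append(s.allele_a if s.signal_a >= s.signal_b else s.allele_b)
        fractions.append(major / total)
        if minor >= minor_presence * major:
            biallelic = True
    major_fraction = sum(fractions) / len(fractions)
    if biallelic:
        return AlleleCall(interaction, "biallelic", "", major_fraction)
    return AlleleCall(interaction, "monoallelic", "".join(haplotype), major_fraction)


def quantify_allele_fraction(
    s: SnpSignal, theta: float = MONOALLELIC_THRESHOLD
) -> tuple[float, str]:
    """Allele-A fraction and mono/biallelic classification from signal ratios.

    The call is monoallelic when the major-allele fraction reaches ``theta``
    (default 0.8, tolerating a minor second-allele signal), else biallelic.
    Invariant to common scaling of the two signals.
    """
    total = s.signal_a + s.signal_b
    if total == 0:
        raise ValidationError(f"{s.snp_id}: both signals zero")
    fraction_a = s.signal_a / total
    classification = (
        "monoallelic" if max(fraction_a, 1 - fraction_a) >= theta else "biallelic"
    )
    return fraction_a, classification


@dataclass(frozen=True)
class MethylationRanges:
    """Inclusive normal ranges (percent methylation) per ICR."""

    icr1_normal: tuple[float, float] = (40.0, 52.0)
    icr2_normal: tuple[float, float] = (39.0, 50.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.icr1_normal, self.icr2_normal):
            if not lo < hi:
                raise ValidationError("range lower bound must be below upper bound")

    def for_icr(self, icr: str) -> tuple[float, float]:
        if icr == "ICR1":
            return self.icr1_normal
        if icr == "ICR2":
            return self.icr2_normal
        raise ValidationError(f"unknown ICR {icr!r}")


@dataclass(frozen=True)
class MethylationRecord:
    sample: str
    icr: str
    level: float
    status: str


def classify_methylation(
    level: float, icr: str, ranges: MethylationRanges | None = None
) -> str:
    """hypomethylated / normal / hypermethylated against the ICR's normal range.

    Bounds are inclusive: a level exactly at either end of the range is
    normal.  Levels outside [0, 100] are rejected.
    """
    ranges = ranges or MethylationRanges()
    if not 0 <= level <= 100:
        raise ValidationError(f"methylation level {level} outside [0, 100]%")
    lo, hi = ranges.for_icr(icr)
    if level < lo:
        return "hypomethylated"
    if level > hi:
        return "hypermethylated"
    return "normal"


def classify_sample(
    sample: str, icr: str, level: float, ranges: MethylationRanges | None = None
) -> MethylationRecord:
    return MethylationRecord(sample, icr, level, classify_methylation(level, icr, ranges))


#: molecular subtype by (ICR1 status, ICR2 status)
_SUBTYPES = {
    ("normal", "normal"): "normal",
    ("hypermethylated", "normal"): "BWS-ICR1-like",
    ("normal", "hypomethylated"): "BWS-ICR2-like",
    ("hypermethylated", "hypomethylated"): "BWS-UPD-like",
    ("hypomethylated", "normal"): "SRS-ICR1-like",
}


def infer_subtype(icr1_status: str, icr2_status: str) -> str:
    """Molecular subtype label from the two ICR methylation statuses.

    ICR1 gain-of-methylation alone -> BWS-ICR1-like; ICR2 loss alone ->
    BWS-ICR2-like; both defects -> BWS-UPD-like (paternal UPD pattern);
    ICR1 loss alone -> SRS-ICR1-like; both normal -> normal; any other
    combination -> unclassified.
    """
    valid = {"normal", "hypomethylated", "hypermethylated"}
    if icr1_status not in valid or icr2_status not in valid:
        raise ValidationError("invalid methylation status")
    return _SUBTYPES.get((icr1_status, icr2_status), "unclassified")
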