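"""3C band quantification: normalized interaction frequencies and looping
profiles.

The 3C readout for an anchor-test fragment pair is a PCR band intensity from
the 3C ligation library and one from an equimolar control-template library
(BAC/fosmid digest-ligation providing every junction in equal amounts).  The
association frequency is the ratio 3C / control, which cancels primer-pair
efficiency.  Profiles report mean ± sample SD over independent 3C assays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndetectableControlError, ValidationError

logger = logging.getLogger(__name__)

BAND_COLUMNS = ["sample", "replicate", "anchor", "test", "intensity_3c", "intensity_ctrl"]


@dataclass(frozen=True)
class BandMeasurement:
    """One quantified gel band pair for (sample, replicate, anchor, test)."""

    sample: str
    replicate: int
    anchor: str
    test: str
    intensity_3c: float
    intensity_ctrl: float

    def __post_init__(self) -> None:
        for v in (self.intensity_3c, self.intensity_ctrl):
            if not math.isfinite(v) or v < 0:
                raise ValidationError("band intensities must be finite and >= 0")
        if self.replicate < 1:
            raise ValidationError("replicate numbering starts at 1")


@dataclass(frozen=True)
class InteractionFrequency:
    """Normalized association frequency at one fragment (mean ± SD over reps).

    A gap (fragment with no usable measurement) is represented with
    ``n_reps == 0`` and NaN mean/sd; gaps are never imputed as zeros.
    """

    anchor: str
    test: str
    mean: float
    sd: float
    n_reps: int

    @property
    def is_gap(self) -> bool:
        return self.n_reps == 0


@dataclass
class LoopingProfile:
    """Ordered interaction frequencies along one anchor's fragment axis."""

    label: str
    anchor: str
    points: list[InteractionFrequency] = field(default_factory=list)

    @property
    def axis(self) -> tuple[str, ...]:
        return tuple(p.test for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "anchor": self.anchor,
                "test": [p.test for p in self.points],
                "mean": [p.mean for p in self.points],
                "sd": [p.sd for p in self.points],
                "n_reps": [p.n_reps for p in self.points],
            }
        )


def normalize_band(m: BandMeasurement) -> float:
    """Association frequency = 3C band / control-template band.

    Raises :class:`UndetectableControlError` when the control band is zero;
    such records are flagged and excluded downstream rather than treated as
    zero frequency.
    """
    if m.intensity_ctrl == 0:
        raise UndetectableControlError(
            f"control band undetectable for {m.sample} {m.anchor}-{m.test} "
            f"rep {m.replicate}"
        )
    return m.intensity_3c / m.intensity_ctrl


def aggregate_replicates(freqs: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n over replicate frequencies."""
    if len(freqs) == 0:
        raise ValidationError("cannot aggregate an empty replicate list")
    arr = np.asarray(freqs, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return mean, sd, int(arr.size)


def read_bands(path: str | Path) -> pd.DataFrame:
    """Read the band-intensity TSV and validate schema and uniqueness."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BAND_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"band table missing columns: {sorted(missing)}")
    key = ["sample", "replicate", "anchor", "test"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key, keep=False)].head(4)
        raise ValidationError(f"duplicate (sample, replicate, anchor, test) rows:\n{dup}")
    if (df["intensity_3c"] < 0).any() or (df["intensity_ctrl"] < 0).any():
        raise ValidationError("negative band intensities")
    return df


def _frequencies(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``frequency`` column; rows with zero control are flagged & dropped."""
    flagged = df["intensity_ctrl"] == 0
    if flagged.any():
        for _, r in df[flagged].iterrows():
            logger.warning(
                "dropping %s %s-%s rep %s: control band undetectable",
                r["sample"], r["anchor"], r["test"], r["replicate"],
            )
    out = df[~flagged].copy()
    out["frequency"] = out["intensity_3c"] / out["intensity_ctrl"]
    return out


def build_looping_profile(
    bands: pd.DataFrame,
    sample: str,
    anchor: str,
    axis: Sequence[str],
    label: str | None = None,
) -> LoopingProfile:
    """Aggregate replicate frequencies into a profile along ``axis``.

    Axis fragments without any usable measurement appear as explicit gap
    points (``n_reps == 0``), not as zeros.
    """
    sub = bands[(bands["sample"] == sample) & (bands["anchor"] == anchor)]
    if sub.empty:
        raise ValidationError(f"no bands for sample {sample!r} anchor {anchor!r}")
    freqs = _frequencies(sub)
    profile = LoopingProfile(label or sample, anchor)
    for test in axis:
        vals = freqs.loc[freqs["test"] == test, "frequency"].to_numpy()
        if vals.size == 0:
            logger.warning("gap at %s for %s anchor %s", test, sample, anchor)
            profile.points.append(
                InteractionFrequency(anchor, test, float("nan"), float("nan"), 0)
            )
        else:
            mean, sd, n = aggregate_replicates(vals)
            profile.points.append(InteractionFrequency(anchor, test, mean, sd, n))
    return profile


def pool_control_profiles(profiles: Sequence[LoopingProfile]) -> LoopingProfile:
    """Pool control lines into a "controls mean" profile.

    Per fragment, the pooled mean and sample SD are taken over *all*
    constituent assay values (replicates pooled, not line means), recovered
    exactly from each profile's sufficient statistics (mean, sd, n).
    """
    if not profiles:
        raise ValidationError("no profiles to pool")
    anchor = profiles[0].anchor
    axis = profiles[0].axis
    for p in profiles[1:]:
        if p.anchor != anchor or p.axis != axis:
            raise ValidationError("profiles to pool must share anchor and axis")
    if len(profiles) == 1:
        logger.warning("pooling a single control line; mean is over its replicates only")

    pooled = LoopingProfile("controls mean", anchor)
    for i, test in enumerate(axis):
        pts = [p.points[i] for p in profiles if not p.points[i].is_gap]
        if not pts:
            pooled.points.append(
                InteractionFrequency(anchor, test, float("nan"), float("nan"), 0)
            )
            continue
        n_tot = sum(pt.n_reps for pt in pts)
        mean = sum(pt.n_reps * pt.mean for pt in pts) / n_tot
        # pooled sum of squared deviations from within-line sd and mean shift
        ss = sum(
            (pt.n_reps - 1) * pt.sd**2 + pt.n_reps * (pt.mean - mean) ** 2
            for pt in pts
        )
        sd = math.sqrt(ss / (n_tot - 1)) if n_tot > 1 else 0.0
        pooled.points.append(InteractionFrequency(anchor, test, mean, sd, n_tot))
    return pooled


@dataclass(frozen=True)
class ControlTemplateReport:
    """Uniformity check of the equimolar control template."""

    cv: float
    threshold: float
    passed: bool
    n: int


def validate_control_template(
    ctrl_bands: Sequence[float], threshold: float = 0.5
) -> ControlTemplateReport:
    """Coefficient of variation of control-template bands across primer pairs.

    The control template should yield comparable band intensities for every
    junction; a CV above ``threshold`` fails the check.
    """
    arr = np.asarray(ctrl_bands, dtype=float)
    if arr.size < 2:
        raise ValidationError("need at least 2 control intensities")
    if (arr == 0).all():
        raise ValidationError("all control intensities are zero")
    cv = float(arr.std(ddof=1) / arr.mean())
    return ControlTemplateReport(cv=cv, threshold=threshold, passed=cv <= threshold, n=arr.size)


def profile_to_tsv(
    profile: LoopingProfile,
    path: str | Path,
    fragments: Iterable | None = None,
) -> None:
    """Write a profile TSV; fragment coordinates are added when a map is given."""
    df = profile.to_frame()
    if fragments is not None:
        coords = {f.name: f.interval for f in fragments}
        df["chrom"] = [coords[t].chrom if t in coords else "" for t in df["test"]]
        df["start"] = [coords[t].start if t in coords else -1 for t in df["test"]]
        df["end"] = [coords[t].end if t in coords else -1 for t in df["test"]]
    df.to_csv(path, sep="\t", index=False)
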