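"""Differential interactome calling between control and patient looping
profiles.

Per-anchor profiles are compared with a two-way fixed-effects ANOVA
(group x fragment) on individual assay values, followed by per-fragment
Bonferroni-corrected group contrasts using the pooled residual error — the
standard "two-way ANOVA + Bonferroni post-test" procedure.  Each fragment is
then categorized as unchanged / increased / decreased / novel / lost, where
novel and lost additionally require the absent side to fall below a relative
presence floor (a fraction of the profile maximum, mimicking gel-band
detectability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .errors import ValidationError
from .region import AnnotatedElement, RestrictionFragment

logger = logging.getLogger(__name__)

CATEGORIES = ("unchanged", "increased", "decreased", "novel", "lost")


@dataclass(frozen=True)
class StatConfig:
    """Significance thresholds and the presence floor for novel/lost calls.

    ``alpha_levels`` map to star codes * through **** in order;
    ``presence_epsilon_fraction`` is the fraction of the profile maximum
    below which a mean counts as absent.
    """

    alpha_levels: tuple[float, ...] = (0.05, 0.01, 0.001, 0.0001)
    presence_epsilon_fraction: float = 0.05

    def __post_init__(self) -> None:
        if list(self.alpha_levels) != sorted(self.alpha_levels, reverse=True):
            raise ValidationError("alpha_levels must be strictly decreasing")
        if not 0 < self.presence_epsilon_fraction < 1:
            raise ValidationError("presence_epsilon_fraction must be in (0, 1)")

    def stars(self, p: float) -> str:
        code = "ns"
        for i, alpha in enumerate(self.alpha_levels):
            if p <= alpha:
                code = "*" * (i + 1)
        return code


@dataclass(frozen=True)
class ROIRecord:
    """Differential call for one anchor-test fragment pair."""

    anchor: str
    test: str
    control_mean: float
    control_sd: float
    case_mean: float
    case_sd: float
    p_adjusted: float
    category: str
    star_code: str


@dataclass
class AnovaResult:
    """Two-way ANOVA table plus per-fragment Bonferroni post-tests."""

    table: pd.DataFrame
    posttests: pd.DataFrame  # fragment, control_mean, case_mean, diff, t, p_raw, p_adj
    zero_variance: bool = False

    def p_adjusted(self) -> dict[str, float]:
        return dict(zip(self.posttests["fragment"], self.posttests["p_adj"]))


def _as_long(
    control: Mapping[str, Sequence[float]],
    case: Mapping[str, Sequence[float]],
    units: str,
) -> pd.DataFrame:
    if set(control) != set(case):
        raise ValidationError("control and case must share the fragment axis")
    rows = []
    for group, assays in (("control", control), ("case", case)):
        for frag, vals in assays.items():
            vals = list(np.asarray(vals, dtype=float))
            if units == "lines":
                # collapse replicate pairs (1,2), (3,4), ... to line means
                vals = [float(np.mean(vals[i : i + 2])) for i in range(0, len(vals), 2)]
            if len(vals) < 2:
                raise ValidationError(
                    f"{group} group has a singleton at fragment {frag!r}; "
                    "need >= 2 assays per group"
                )
            rows.extend(
                {"group": group, "fragment": frag, "value": v} for v in vals
            )
    return pd.DataFrame(rows)


def anova_profiles(
    control_assays: Mapping[str, Sequence[float]],
    case_assays: Mapping[str, Sequence[float]],
    units: str = "assays",
) -> AnovaResult:
    """Two-way ANOVA (group x fragment) with per-fragment Bonferroni contrasts.

    Parameters
    ----------
    control_assays, case_assays
        Mapping fragment label -> individual assay frequencies, on a shared
        fragment axis (insertion order of ``control_assays`` is kept).
    units
        ``"assays"`` treats each 3C assay as an observation (default);
        ``"lines"`` first averages consecutive replicate pairs per line.

    The post-test per fragment is the group contrast t-statistic with the
    pooled residual mean square of the full model; raw two-sided p-values
    are Bonferroni-multiplied by the number of fragments and clipped at 1.
    A design with zero residual variance everywhere is reported with the
    ``zero_variance`` flag rather than NaNs.
    """
    fragments = list(control_assays)
    long = _as_long(control_assays, case_assays, units)

    model = ols("value ~ C(group) * C(fragment)", data=long).fit()
    table = anova_lm(model, typ=2)
    mse = float(model.mse_resid)
    df_resid = float(model.df_resid)

    scale = float(np.abs(long["value"]).max()) or 1.0
    zero_var = mse <= (1e-12 * scale**2) or df_resid <= 0

    rows = []
    k = len(fragments)
    for frag in fragments:
        ctrl = long[(long["group"] == "control") & (long["fragment"] == frag)]["value"]
        case = long[(long["group"] == "case") & (long["fragment"] == frag)]["value"]
        diff = float(case.mean() - ctrl.mean())
        if zero_var:
            t = np.inf if diff != 0 else 0.0
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(mse * (1 / len(ctrl) + 1 / len(case)))
            t = diff / se
            p_raw = 2 * stats.t.sf(abs(t), df_resid)
        rows.append(
            {
                "fragment": frag,
                "control_mean": float(ctrl.mean()),
                "case_mean": float(case.mean()),
                "diff": diff,
                "t": float(t),
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, p_raw * k)),
            }
        )
    if zero_var:
        logger.warning("zero residual variance; post-test p-values are 0/1 flags")
    return AnovaResult(table=table, posttests=pd.DataFrame(rows), zero_variance=zero_var)


def classify_roi(
    control_stats: tuple[float, float],
    case_stats: tuple[float, float],
    p_adjusted: float,
    cfg: StatConfig,
    profile_max: float,
    anchor: str = "",
    test: str = "",
) -> ROIRecord:
    """Categorize one fragment's differential call.

    unchanged if adjusted p > 0.05; otherwise novel (control absent, case
    present), lost (case absent, control present) or increased/decreased by
    the sign of case - control.  "Absent" means mean < epsilon * profile_max,
    boundary inclusive on the present side.
    """
    control_mean, control_sd = control_stats
    case_mean, case_sd = case_stats
    if control_mean < 0 or case_mean < 0:
        raise ValidationError("interaction frequency means must be >= 0")
    if profile_max <= 0:
        raise ValidationError("profile_max must be positive")

    eps = cfg.presence_epsilon_fraction * profile_max
    if p_adjusted > cfg.alpha_levels[0]:
        category = "unchanged"
    elif control_mean < eps <= case_mean:
        category = "novel"
    elif case_mean < eps <= control_mean:
        category = "lost"
    elif case_mean > control_mean:
        category = "increased"
    elif case_mean < control_mean:
        category = "decreased"
    else:
        category = "unchanged"
    return ROIRecord(
        anchor=anchor,
        test=test,
        control_mean=control_mean,
        control_sd=control_sd,
        case_mean=case_mean,
        case_sd=case_sd,
        p_adjusted=p_adjusted,
        category=category,
        star_code=cfg.stars(p_adjusted) if category != "unchanged" else cfg.stars(p_adjusted),
    )


def _nearest_element(
    midpoint: float, elements: Sequence[AnnotatedElement]
) -> str:
    """Enclosing element name, else nearest by midpoint (tie -> upstream)."""
    if not elements:
        return "unannotated"
    span_lo = min(e.interval.start for e in elements)
    span_hi = max(e.interval.end for e in elements)
    for e in elements:
        if e.interval.start <= midpoint < e.interval.end:
            return e.name
    if not (span_lo <= midpoint < span_hi):
        return "unannotated"
    best = min(
        elements,
        key=lambda e: (abs(e.interval.midpoint - midpoint), e.interval.start),
    )
    return best.name


def build_interactome_table(
    rois: Sequence[ROIRecord],
    elements: Sequence[AnnotatedElement],
    fragments: Sequence[RestrictionFragment],
) -> pd.DataFrame:
    """Summarize ROI calls as (anchor element, test element) rows.

    Each fragment is mapped to its enclosing annotated element, falling back
    to the nearest element by midpoint distance (ties break upstream);
    fragments outside the annotation span are labeled ``unannotated`` rather
    than dropped.  Rows are ordered by genomic coordinate.
    """
    annotation = [e for e in elements if e.kind not in {"anchor_primer", "test_primer"}]
    frag_by_name = {f.name: f for f in fragments}
    rows = []
    for roi in rois:
        rec = {
            "anchor": roi.anchor,
            "test": roi.test,
            "control_mean": roi.control_mean,
            "control_sd": roi.control_sd,
            "case_mean": roi.case_mean,
            "case_sd": roi.case_sd,
            "p_adj": roi.p_adjusted,
            "stars": roi.star_code,
            "category": roi.category,
        }
        for side, key in (("anchor", "anchor_element"), ("test", "test_element")):
            frag = frag_by_name.get(rec[side])
            rec[key] = (
                _nearest_element(frag.interval.midpoint, annotation)
                if frag is not None
                else "unannotated"
            )
            rec[f"_{side}_pos"] = frag.interval.midpoint if frag is not None else np.inf
        rows.append(rec)
    if not rows:
        return pd.DataFrame(
            columns=[
                "anchor", "test", "control_mean", "control_sd", "case_mean",
                "case_sd", "p_adj", "stars", "category", "anchor_element",
                "test_element",
            ]
        )
    df = pd.DataFrame(rows).sort_values(["_anchor_pos", "_test_pos"], kind="stable")
    return df.drop(columns=["_anchor_pos", "_test_pos"]).reset_index(drop=True)
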