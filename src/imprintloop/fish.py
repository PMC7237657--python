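"""3D DNA FISH colocalization analysis.

Each nucleus carries two alleles of the locus, each marked by a green
(ICR1-domain probe) + red (ICR2-domain probe) signal doublet.  From
per-nucleus spot centroids (µm) the pipeline pairs green and red spots into
two allele doublets, measures the intra-allele (cis) green-red distance and
the inter-allele (trans) doublet distance, classifies alleles as colocalized
(cis distance <= 0.35 µm, boundary inclusive), nuclei as +/+, +/- or -/-,
and flags trans association when the doublet-to-doublet distance is
<= 1 µm.  Cohorts are summarized as category percentages, the per-allele
colocalization rate (2 N++ + N+-) / 2n, and the trans rate, with unpaired
t-tests on cis distances and Fisher's exact tests on category counts
between lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import QCFailure, ValidationError

logger = logging.getLogger(__name__)

GREEN = "green_ICR1"
RED = "red_ICR2"
CHANNELS = (GREEN, RED)
CATEGORIES = ("plus_plus", "plus_minus", "minus_minus")

SPOT_COLUMNS = ["nucleus_id", "channel", "x_um", "y_um", "z_um"]


@dataclass(frozen=True)
class FishConfig:
    """Distance cutoffs (µm) and spot-count expectations."""

    cis_cutoff: float = 0.35
    trans_cutoff: float = 1.0
    spots_per_channel: int = 2
    doublet_reference: Literal["midpoint", "green_spot", "red_spot"] = "midpoint"

    def __post_init__(self) -> None:
        if not 0 < self.cis_cutoff < self.trans_cutoff:
            raise ValidationError("require 0 < cis_cutoff < trans_cutoff")


@dataclass
class NucleusSpots:
    """Spot centroids of one nucleus, split by channel; coordinates in µm."""

    nucleus_id: str
    green: np.ndarray  # (n, 3)
    red: np.ndarray  # (m, 3)

    def __post_init__(self) -> None:
        self.green = np.atleast_2d(np.asarray(self.green, dtype=float))
        self.red = np.atleast_2d(np.asarray(self.red, dtype=float))
        for arr in (self.green, self.red):
            if arr.shape[-1] != 3 or not np.isfinite(arr).all():
                raise ValidationError(
                    f"nucleus {self.nucleus_id}: spots must be finite (x, y, z) triples"
                )


@dataclass(frozen=True)
class AlleleDoublet:
    """One allele's paired green-red signal."""

    green: tuple[float, float, float]
    red: tuple[float, float, float]
    cis_distance: float
    colocalized: bool
    midpoint: tuple[float, float, float]


@dataclass(frozen=True)
class NucleusCall:
    nucleus_id: str
    category: str  # plus_plus | plus_minus | minus_minus
    trans_associated: bool
    inter_doublet_distance: float
    cis_distances: tuple[float, float]


@dataclass(frozen=True)
class QCResult:
    nucleus_id: str
    passed: bool
    reason: str = ""


def read_spots(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValidationError(f"unknown channels {sorted(bad)}; expected {CHANNELS}")
    return df


def iter_nuclei(spots: pd.DataFrame) -> Iterable[NucleusSpots]:
    for nucleus_id, grp in spots.groupby("nucleus_id", sort=False):
        coords = {
            ch: grp.loc[grp["channel"] == ch, ["x_um", "y_um", "z_um"]].to_numpy()
            for ch in CHANNELS
        }
        yield NucleusSpots(str(nucleus_id), coords[GREEN], coords[RED])


def qc_nucleus(n: NucleusSpots, cfg: FishConfig = FishConfig()) -> QCResult:
    """Pass iff the nucleus has exactly the expected spots per channel.

    Nuclei failing QC are excluded from pairing and counted in the QC
    report; no salvage heuristics are applied.  Never raises.
    """
    k = cfg.spots_per_channel
    ng, nr = len(n.green), len(n.red)
    if ng == k and nr == k:
        return QCResult(n.nucleus_id, True)
    return QCResult(
        n.nucleus_id, False, f"expected {k}+{k} spots, found {ng} green + {nr} red"
    )


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)))


def pair_doublets(
    n: NucleusSpots, cfg: FishConfig = FishConfig()
) -> tuple[AlleleDoublet, AlleleDoublet]:
    """Pair the 2 green with the 2 red spots into two allele doublets.

    Of the two perfect matchings, the one minimizing the summed green-red
    distance is chosen; an exact tie keeps index order (green i with red i).
    """
    qc = qc_nucleus(n, cfg)
    if not qc.passed:
        raise QCFailure(f"nucleus {n.nucleus_id}: {qc.reason}")
    g, r = n.green, n.red
    straight = _dist(g[0], r[0]) + _dist(g[1], r[1])
    crossed = _dist(g[0], r[1]) + _dist(g[1], r[0])
    pairs = ((0, 0), (1, 1)) if straight <= crossed else ((0, 1), (1, 0))
    doublets = []
    for gi, ri in pairs:
        d = _dist(g[gi], r[ri])
        mid = (g[gi] + r[ri]) / 2.0
        doublets.append(
            AlleleDoublet(
                green=tuple(g[gi]),
                red=tuple(r[ri]),
                cis_distance=d,
                colocalized=classify_allele(d, cfg),
                midpoint=tuple(mid),
            )
        )
    return doublets[0], doublets[1]


def classify_allele(d: float, cfg: FishConfig = FishConfig()) -> bool:
    """Colocalized iff the cis green-red distance is <= the cutoff (inclusive)."""
    if d < 0:
        raise ValidationError("distances cannot be negative")
    return d <= cfg.cis_cutoff


def _reference_point(d: AlleleDoublet, cfg: FishConfig) -> np.ndarray:
    if cfg.doublet_reference == "green_spot":
        return np.asarray(d.green)
    if cfg.doublet_reference == "red_spot":
        return np.asarray(d.red)
    return np.asarray(d.midpoint)


def classify_trans(
    d1: AlleleDoublet, d2: AlleleDoublet, cfg: FishConfig = FishConfig()
) -> tuple[float, bool]:
    """Inter-doublet distance and trans flag (<= trans cutoff, inclusive).

    The doublet reference point defaults to the midpoint of its two spots.
    """
    dist = _dist(_reference_point(d1, cfg), _reference_point(d2, cfg))
    return dist, dist <= cfg.trans_cutoff


def classify_nucleus(a1: bool, a2: bool) -> str:
    if a1 and a2:
        return "plus_plus"
    if a1 or a2:
        return "plus_minus"
    return "minus_minus"


@dataclass
class LineResult:
    """Full per-nucleus results of one cell line."""

    label: str
    calls: list[NucleusCall]
    qc_failures: list[QCResult] = field(default_factory=list)

    @property
    def cis_distances(self) -> np.ndarray:
        return np.array([d for c in self.calls for d in c.cis_distances])

    def allele_table(self) -> pd.DataFrame:
        rows = [
            {
                "nucleus_id": c.nucleus_id,
                "allele_index": i,
                "cis_distance": d,
                "colocalized": d <= FishConfig().cis_cutoff,
            }
            for c in self.calls
            for i, d in enumerate(c.cis_distances)
        ]
        return pd.DataFrame(rows)

    def nucleus_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus_id": [c.nucleus_id for c in self.calls],
                "category": [c.category for c in self.calls],
                "inter_doublet_distance": [c.inter_doublet_distance for c in self.calls],
                "trans": [c.trans_associated for c in self.calls],
            }
        )


def process_line(
    spots: pd.DataFrame, label: str, cfg: FishConfig = FishConfig()
) -> LineResult:
    """QC, pair and classify every nucleus of one line's spot table."""
    calls: list[NucleusCall] = []
    failures: list[QCResult] = []
    for nucleus in iter_nuclei(spots):
        qc = qc_nucleus(nucleus, cfg)
        if not qc.passed:
            logger.warning("QC-EXCLUDED\t%s\t%s", qc.nucleus_id, qc.reason)
            failures.append(qc)
            continue
        d1, d2 = pair_doublets(nucleus, cfg)
        inter, trans = classify_trans(d1, d2, cfg)
        calls.append(
            NucleusCall(
                nucleus_id=nucleus.nucleus_id,
                category=classify_nucleus(d1.colocalized, d2.colocalized),
                trans_associated=trans,
                inter_doublet_distance=inter,
                cis_distances=(d1.cis_distance, d2.cis_distance),
            )
        )
    return LineResult(label, calls, failures)


@dataclass(frozen=True)
class CohortSummary:
    """Counts and percentages of nucleus categories for one line or pool."""

    label: str
    n_nuclei: int
    counts: Mapping[str, int]  # keys = CATEGORIES
    n_trans: int
    mode: str = "single_line"
    # percentage fields are derived unless a mean-of-lines pool overrides them
    percentages: Mapping[str, float] = field(default_factory=dict)
    allele_rate_pct: float = float("nan")
    trans_rate_pct: float = float("nan")

    @staticmethod
    def from_counts(
        label: str,
        counts: Mapping[str, int],
        n_trans: int = 0,
        mode: str = "single_line",
    ) -> "CohortSummary":
        n = sum(counts[c] for c in CATEGORIES)
        if n == 0:
            raise ValidationError("empty cohort")
        pct = {c: 100.0 * counts[c] / n for c in CATEGORIES}
        allele = 100.0 * (2 * counts["plus_plus"] + counts["plus_minus"]) / (2 * n)
        return CohortSummary(
            label=label,
            n_nuclei=n,
            counts=dict(counts),
            n_trans=n_trans,
            mode=mode,
            percentages=pct,
            allele_rate_pct=allele,
            trans_rate_pct=100.0 * n_trans / n,
        )

    def to_frame(self) -> pd.DataFrame:
        row = {"label": self.label, "n_nuclei": self.n_nuclei, "mode": self.mode}
        for c in CATEGORIES:
            row[f"n_{c}"] = self.counts[c]
            row[f"pct_{c}"] = self.percentages[c]
        row["allele_colocalization_pct"] = self.allele_rate_pct
        row["trans_rate_pct"] = self.trans_rate_pct
        return pd.DataFrame([row])


def summarize_line(calls: Sequence[NucleusCall], label: str = "") -> CohortSummary:
    """Cohort summary of one line's nucleus calls.

    The allele colocalization rate is (2 N++ + N+-) / 2n — each +/+ nucleus
    contributes two colocalized alleles, each +/- one.
    """
    if not calls:
        raise ValidationError("cannot summarize an empty line")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n_trans = sum(c.trans_associated for c in calls)
    return CohortSummary.from_counts(label, counts, n_trans)


def pool_lines(
    summaries: Sequence[CohortSummary],
    mode: Literal["pooled_counts", "mean_of_lines"] = "pooled_counts",
) -> CohortSummary:
    """Pool several lines into one summary.

    ``pooled_counts`` sums integer nucleus counts and recomputes every
    percentage from the pooled counts; ``mean_of_lines`` averages the
    per-line percentages unweighted (the convention behind a "mean of the
    controls" rate).  The mode is recorded in the output.
    """
    if not summaries:
        raise ValidationError("no summaries to pool")
    label = "+".join(s.label for s in summaries)
    counts = {c: sum(s.counts[c] for s in summaries) for c in CATEGORIES}
    n_trans = sum(s.n_trans for s in summaries)
    if mode == "pooled_counts":
        return CohortSummary.from_counts(label, counts, n_trans, mode=mode)
    if mode != "mean_of_lines":
        raise ValidationError(f"unknown pooling mode {mode!r}")
    k = len(summaries)
    pct = {c: sum(s.percentages[c] for s in summaries) / k for c in CATEGORIES}
    return CohortSummary(
        label=label,
        n_nuclei=sum(s.n_nuclei for s in summaries),
        counts=counts,
        n_trans=n_trans,
        mode=mode,
        percentages=pct,
        allele_rate_pct=sum(s.allele_rate_pct for s in summaries) / k,
        trans_rate_pct=sum(s.trans_rate_pct for s in summaries) / k,
    )


def ecdf_table(
    distances: Sequence[float], step: float = 0.05, min_extent: float = 0.35
) -> pd.DataFrame:
    """Cumulative percentage of distances <= each grid point.

    The grid runs from 0 to the smallest multiple of ``step`` covering both
    the maximum distance and ``min_extent`` (default: the cis cutoff, so the
    colocalization rate is always readable off the table); the curve is
    non-decreasing and reaches 100% at the maximum distance.
    """
    arr = np.asarray(distances, dtype=float)
    if arr.size == 0:
        raise ValidationError("no distances")
    if (arr < 0).any():
        raise ValidationError("distances cannot be negative")
    extent = max(float(arr.max()), min_extent)
    n_steps = int(np.ceil(extent / step)) if extent > 0 else 1
    grid = np.arange(0, n_steps + 1) * step
    pct = [100.0 * np.mean(arr <= g) for g in grid]
    return pd.DataFrame({"distance_um": grid, "cumulative_pct": pct})


def _fisher_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p; degenerate zero-margin tables give p = 1."""
    table = np.asarray(table, dtype=int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table with a zero margin; p set to 1")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def compare_lines(
    ctrl_distances: Sequence[float],
    case_distances: Sequence[float],
    ctrl_summary: CohortSummary,
    case_summary: CohortSummary,
    alpha_levels: Sequence[float] = (0.05, 0.01, 0.001, 0.0001),
) -> pd.DataFrame:
    """Between-line statistics report.

    Rows: unpaired two-sided t-test on per-allele cis distances; Fisher's
    exact test per nucleus category on [in-category vs not] x [control vs
    case]; Fisher's exact test on trans counts.  Star codes follow the
    alpha ladder.
    """
    ctrl = np.asarray(ctrl_distances, dtype=float)
    case = np.asarray(case_distances, dtype=float)
    if ctrl.size == 0 or case.size == 0:
        raise ValidationError("both groups must be non-empty")

    def _stars(p: float) -> str:
        code = "ns"
        for i, a in enumerate(sorted(alpha_levels, reverse=True)):
            if p <= a:
                code = "*" * (i + 1)
        return code

    rows = []
    t, p = stats.ttest_ind(ctrl, case, equal_var=True)
    rows.append({"test": "t_cis_distance", "statistic": float(t), "p": float(p)})
    for c in CATEGORIES:
        tab = [
            [ctrl_summary.counts[c], ctrl_summary.n_nuclei - ctrl_summary.counts[c]],
            [case_summary.counts[c], case_summary.n_nuclei - case_summary.counts[c]],
        ]
        rows.append(
            {"test": f"fisher_{c}", "statistic": float("nan"), "p": _fisher_2x2(np.array(tab))}
        )
    tab = [
        [ctrl_summary.n_trans, ctrl_summary.n_nuclei - ctrl_summary.n_trans],
        [case_summary.n_trans, case_summary.n_nuclei - case_summary.n_trans],
    ]
    rows.append(
        {"test": "fisher_trans", "statistic": float("nan"), "p": _fisher_2x2(np.array(tab))}
    )
    df = pd.DataFrame(rows)
    df["stars"] = [_stars(p) for p in df["p"]]
    return df
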