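"""Two-way ANOVA + Bonferroni post-tests and ROI categorization."""

import numpy as np
import pytest

from imprintloop import (
    GenomicInterval,
    AnnotatedElement,
    RestrictionFragment,
    StatConfig,
    ValidationError,
    anova_profiles,
    build_interactome_table,
    classify_roi,
)


def anova_ss_oracle(control, case):
    """Explicit sums-of-squares two-way ANOVA for balanced designs.

    Returns (F_group, F_fragment, F_interaction) computed from first
    principles: cell means, marginal means, and the residual within-cell
    variation.
    """
    groups = ("control", "case")
    frags = list(control)
    data = {("control", f): np.asarray(control[f], float) for f in frags}
    data.update({("case", f): np.asarray(case[f], float) for f in frags})
    r = len(next(iter(data.values())))
    a, b = len(groups), len(frags)
    grand = np.mean([v for vals in data.values() for v in vals])
    mean_g = {g: np.mean([v for f in frags for v in data[(g, f)]]) for g in groups}
    mean_f = {f: np.mean([v for g in groups for v in data[(g, f)]]) for f in frags}
    cell = {k: v.mean() for k, v in data.items()}

    ss_a = r * b * sum((mean_g[g] - grand) ** 2 for g in groups)
    ss_b = r * a * sum((mean_f[f] - grand) ** 2 for f in frags)
    ss_ab = r * sum(
        (cell[(g, f)] - mean_g[g] - mean_f[f] + grand) ** 2
        for g in groups for f in frags
    )
    ss_e = sum(((data[k] - cell[k]) ** 2).sum() for k in data)
    df_e = a * b * (r - 1)
    ms_e = ss_e / df_e
    return (
        (ss_a / (a - 1)) / ms_e,
        (ss_b / (b - 1)) / ms_e,
        (ss_ab / ((a - 1) * (b - 1))) / ms_e,
    )


class TestAnova:
    def test_f_statistics_match_sums_of_squares_oracle(self, rng):
        for _ in range(5):
            frags = [f"t{i}" for i in range(rng.integers(2, 6))]
            r = int(rng.integers(2, 5))
            control = {f: rng.lognormal(size=r) for f in frags}
            case = {f: rng.lognormal(size=r) for f in frags}
            res = anova_profiles(control, case)
            f_a, f_b, f_ab = anova_ss_oracle(control, case)
            tab = res.table
            assert tab.loc["C(group)", "F"] == pytest.approx(f_a, rel=1e-8)
            assert tab.loc["C(fragment)", "F"] == pytest.approx(f_b, rel=1e-8)
            assert tab.loc["C(group):C(fragment)", "F"] == pytest.approx(f_ab, rel=1e-8)

    def test_identical_groups_all_ns(self):
        vals = {"t0": [1.0, 1.0], "t1": [1.0, 1.0], "t2": [1.0, 1.0]}
        res = anova_profiles(vals, {k: list(v) for k, v in vals.items()})
        assert res.zero_variance
        assert all(p == 1.0 for p in res.posttests["p_adj"])

    def test_single_shifted_fragment_is_the_only_significant_one(self, rng):
        # balanced 2 x 3 design; fragment t1 shifted by 10 within-cell SDs
        sd = 0.05
        control = {f: list(1.0 + sd * rng.standard_normal(3)) for f in ("t0", "t1", "t2")}
        case = {f: list(1.0 + sd * rng.standard_normal(3)) for f in ("t0", "t1", "t2")}
        case["t1"] = [v + 10 * sd for v in case["t1"]]
        res = anova_profiles(control, case)
        padj = res.p_adjusted()
        assert padj["t1"] <= 0.05
        assert padj["t0"] > 0.05 and padj["t2"] > 0.05

    def test_bonferroni_multiplies_by_axis_size_and_clips(self, rng):
        control = {f: list(rng.lognormal(size=2)) for f in ("t0", "t1", "t2", "t3")}
        case = {f: list(rng.lognormal(size=2)) for f in ("t0", "t1", "t2", "t3")}
        res = anova_profiles(control, case)
        for _, r in res.posttests.iterrows():
            assert r["p_adj"] == pytest.approx(min(1.0, r["p_raw"] * 4))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="singleton"):
            anova_profiles({"t0": [1.0]}, {"t0": [1.0, 2.0]})

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValidationError):
            anova_profiles({"t0": [1, 2]}, {"t1": [1, 2]})


CFG = StatConfig()


class TestClassifyRoi:
    @pytest.mark.parametrize(
        "ctrl,case,p,expected,stars",
        [
            ((1.0, 0.1), (1.8, 0.1), 0.001, "increased", "***"),
            ((0.02, 0.01), (0.9, 0.1), 1e-5, "novel", "****"),
            ((0.9, 0.1), (0.9, 0.1), 0.6, "unchanged", "ns"),
            ((0.9, 0.1), (0.02, 0.01), 1e-5, "lost", "****"),
            ((1.8, 0.1), (1.0, 0.1), 0.04, "decreased", "*"),
        ],
    )
    def test_categories_and_stars(self, ctrl, case, p, expected, stars):
        roi = classify_roi(ctrl, case, p, CFG, profile_max=1.0)
        assert roi.category == expected
        assert roi.star_code == stars

    def test_epsilon_boundary_present_side_inclusive(self):
        # case mean exactly at epsilon counts as present -> novel
        roi = classify_roi((0.01, 0.0), (0.05, 0.0), 1e-4, CFG, profile_max=1.0)
        assert roi.category == "novel"

    def test_symmetry_under_group_swap(self, rng):
        swap = {"increased": "decreased", "decreased": "increased",
                "novel": "lost", "lost": "novel", "unchanged": "unchanged"}
        for _ in range(50):
            c, k = rng.uniform(0, 2), rng.uniform(0, 2)
            p = rng.uniform(0, 0.2)
            fwd = classify_roi((c, 0.1), (k, 0.1), p, CFG, profile_max=2.0)
            rev = classify_roi((k, 0.1), (c, 0.1), p, CFG, profile_max=2.0)
            assert rev.category == swap[fwd.category]

    def test_lower_epsilon_only_moves_novel_lost_to_inc_dec(self, rng):
        loose = StatConfig(presence_epsilon_fraction=0.10)
        tight = StatConfig(presence_epsilon_fraction=0.02)
        moves = {("novel", "increased"), ("lost", "decreased")}
        for _ in range(100):
            c, k = rng.uniform(0, 1), rng.uniform(0, 1)
            a = classify_roi((c, 0), (k, 0), 0.001, loose, 1.0).category
            b = classify_roi((c, 0), (k, 0), 0.001, tight, 1.0).category
            assert a == b or (a, b) in moves

    def test_negative_means_rejected(self):
        with pytest.raises(ValidationError):
            classify_roi((-0.1, 0.0), (1.0, 0.0), 0.01, CFG, 1.0)


class TestInteractomeTable:
    def _frag(self, name, start, end, idx):
        return RestrictionFragment(idx, GenomicInterval("chr11", start, end, name=name), "BglII")

    def _element(self, name, start, end, kind="ICR"):
        return AnnotatedElement(GenomicInterval("chr11", start, end, name=name), kind)

    def test_rows_annotated_and_ordered(self):
        frags = [self._frag("f0", 0, 100, 0), self._frag("f1", 100, 200, 1),
                 self._frag("anchor", 900, 1000, 9)]
        elements = [self._element("E1", 0, 100, "enhancer"),
                    self._element("E2", 100, 220, "gene"),
                    self._element("A", 880, 1000, "ICR")]
        rois = [
            classify_roi((1, 0), (2, 0), 0.01, CFG, 2.0, anchor="anchor", test="f1"),
            classify_roi((1, 0), (2, 0), 0.01, CFG, 2.0, anchor="anchor", test="f0"),
        ]
        table = build_interactome_table(rois, elements, frags)
        assert list(table["test"]) == ["f0", "f1"]  # coordinate order
        assert list(table["test_element"]) == ["E1", "E2"]
        assert set(table["anchor_element"]) == {"A"}

    def test_fragment_between_elements_maps_to_nearest_tie_upstream(self):
        frags = [self._frag("f0", 140, 160, 0)]  # midpoint 150
        elements = [self._element("up", 0, 100), self._element("dn", 200, 300)]
        # midpoints 50 and 250, equidistant from 150 -> upstream wins
        rois = [classify_roi((1, 0), (2, 0), 0.01, CFG, 2.0, anchor="f0", test="f0")]
        table = build_interactome_table(rois, elements, frags)
        assert table.loc[0, "test_element"] == "up"

    def test_fragment_outside_span_is_unannotated(self):
        frags = [self._frag("f0", 5000, 5100, 0)]
        elements = [self._element("E", 0, 100)]
        rois = [classify_roi((1, 0), (2, 0), 0.01, CFG, 2.0, anchor="f0", test="f0")]
        table = build_interactome_table(rois, elements, frags)
        assert table.loc[0, "test_element"] == "unannotated"

    def test_empty_roi_list_gives_empty_table(self):
        assert build_interactome_table([], [], []).empty
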