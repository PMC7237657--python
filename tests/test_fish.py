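"""FISH doublet pairing, nucleus classification and cohort statistics."""

import math

import numpy as np
import pytest
from scipy.special import comb

from imprintloop import (
    CohortSummary,
    FishConfig,
    NucleusSpots,
    QCFailure,
    ValidationError,
    classify_allele,
    classify_nucleus,
    classify_trans,
    compare_lines,
    ecdf_table,
    pair_doublets,
    pool_lines,
    qc_nucleus,
    summarize_line,
)
from imprintloop.fish import NucleusCall

CFG = FishConfig()


def nucleus(green, red, nid="n0"):
    return NucleusSpots(nid, np.asarray(green, float), np.asarray(red, float))


class TestQC:
    @pytest.mark.parametrize(
        "ng,nr,ok", [(2, 2, True), (1, 2, False), (3, 2, False), (2, 4, False)]
    )
    def test_requires_exactly_two_spots_per_channel(self, ng, nr, ok):
        n = nucleus([[i, 0, 0] for i in range(ng)], [[i, 1, 0] for i in range(nr)])
        assert qc_nucleus(n, CFG).passed is ok


class TestPairing:
    def test_obvious_pairing(self):
        n = nucleus([[0, 0, 0], [5, 0, 0]], [[0.1, 0, 0], [5.2, 0, 0]])
        d1, d2 = pair_doublets(n, CFG)
        assert d1.cis_distance == pytest.approx(0.1)
        assert d2.cis_distance == pytest.approx(0.2)

    def test_crossed_assignment_chosen_when_cheaper(self):
        n = nucleus([[0, 0, 0], [5, 0, 0]], [[5.1, 0, 0], [0.1, 0, 0]])
        d1, d2 = pair_doublets(n, CFG)
        assert d1.cis_distance == pytest.approx(0.1)
        assert d2.cis_distance == pytest.approx(0.1)

    def test_matches_brute_force_oracle_on_random_nuclei(self, rng):
        for _ in range(300):
            g = rng.uniform(-3, 3, size=(2, 3))
            r = rng.uniform(-3, 3, size=(2, 3))
            d1, d2 = pair_doublets(nucleus(g, r), CFG)
            best = min(
                np.linalg.norm(g[0] - r[0]) + np.linalg.norm(g[1] - r[1]),
                np.linalg.norm(g[0] - r[1]) + np.linalg.norm(g[1] - r[0]),
            )
            assert d1.cis_distance + d2.cis_distance == pytest.approx(best)

    def test_tie_breaks_by_index_order(self):
        # perfect square: both matchings cost the same
        n = nucleus([[0, 0, 0], [1, 1, 0]], [[1, 0, 0], [0, 1, 0]])
        d1, d2 = pair_doublets(n, CFG)
        assert d1.green == (0, 0, 0) and d1.red == (1, 0, 0)

    def test_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        g = rng.uniform(-2, 2, size=(2, 3))
        r = rng.uniform(-2, 2, size=(2, 3))
        base = pair_doublets(nucleus(g, r), CFG)
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.uniform(-5, 5, size=3)
            moved = pair_doublets(nucleus(g @ rot.T + shift, r @ rot.T + shift), CFG)
            for a, b in zip(base, moved):
                assert a.cis_distance == pytest.approx(b.cis_distance)

    def test_qc_failed_nucleus_raises(self):
        with pytest.raises(QCFailure):
            pair_doublets(nucleus([[0, 0, 0]], [[0, 0, 0], [1, 0, 0]]), CFG)


class TestClassification:
    @pytest.mark.parametrize("d,flag", [(0.35, True), (0.3501, False), (0.0, True)])
    def test_cis_cutoff_inclusive(self, d, flag):
        assert classify_allele(d, CFG) is flag

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            classify_allele(-0.1, CFG)

    @pytest.mark.parametrize("sep,flag", [(0.9, True), (1.0, True), (2.5, False)])
    def test_trans_cutoff_inclusive_on_midpoints(self, sep, flag):
        n1 = nucleus([[0, 0, 0], [sep, 0, 0]], [[0, 0, 0], [sep, 0, 0]])
        d1, d2 = pair_doublets(n1, CFG)
        dist, trans = classify_trans(d1, d2, CFG)
        assert dist == pytest.approx(sep)
        assert trans is flag

    @pytest.mark.parametrize(
        "a1,a2,cat",
        [(True, True, "plus_plus"), (True, False, "plus_minus"),
         (False, True, "plus_minus"), (False, False, "minus_minus")],
    )
    def test_nucleus_categories(self, a1, a2, cat):
        assert classify_nucleus(a1, a2) == cat


def calls_from_counts(counts, n_trans=0):
    calls, i = [], 0
    for cat, k in counts.items():
        for _ in range(k):
            d = {"plus_plus": (0.1, 0.1), "plus_minus": (0.1, 0.8),
                 "minus_minus": (0.8, 0.8)}[cat]
            calls.append(NucleusCall(f"n{i}", cat, i < n_trans, 0.5, d))
            i += 1
    return calls


class TestSummaries:
    def test_control_line_allele_rate_from_reconstructed_counts(self):
        # 302-nucleus line with 77 / 121 / 104 category counts
        s = CohortSummary.from_counts(
            "CTRL1", {"plus_plus": 77, "plus_minus": 121, "minus_minus": 104}
        )
        assert s.n_nuclei == 302
        assert s.allele_rate_pct == pytest.approx(100 * 275 / 604, abs=1e-6)
        assert round(s.allele_rate_pct, 2) == 45.53

    def test_all_plus_plus_rate_100(self):
        calls = calls_from_counts({"plus_plus": 5, "plus_minus": 0, "minus_minus": 0})
        assert summarize_line(calls, "x").allele_rate_pct == 100.0

    def test_counts_conserved_and_consistent_with_allele_flags(self, rng):
        counts = {"plus_plus": 7, "plus_minus": 13, "minus_minus": 9}
        calls = calls_from_counts(counts, n_trans=4)
        s = summarize_line(calls, "x")
        assert sum(s.counts.values()) == s.n_nuclei == 29
        coloc_alleles = sum(d <= CFG.cis_cutoff for c in calls for d in c.cis_distances)
        assert coloc_alleles == 2 * s.counts["plus_plus"] + s.counts["plus_minus"]
        assert s.trans_rate_pct == pytest.approx(100 * 4 / 29)

    def test_empty_line_rejected(self):
        with pytest.raises(ValidationError):
            summarize_line([], "x")

    def test_mean_of_lines_matches_mean_of_control_rates(self):
        c1 = CohortSummary.from_counts(
            "CTRL1", {"plus_plus": 77, "plus_minus": 121, "minus_minus": 104}
        )
        c2 = CohortSummary.from_counts(
            "CTRL2", {"plus_plus": 59, "plus_minus": 129, "minus_minus": 102}
        )
        pooled = pool_lines([c1, c2], mode="mean_of_lines")
        assert round(pooled.allele_rate_pct, 2) == 44.06

    def test_pooled_counts_percentages(self):
        c1 = CohortSummary.from_counts(
            "CTRL1", {"plus_plus": 77, "plus_minus": 121, "minus_minus": 104}
        )
        c2 = CohortSummary.from_counts(
            "CTRL2", {"plus_plus": 59, "plus_minus": 129, "minus_minus": 102}
        )
        pooled = pool_lines([c1, c2], mode="pooled_counts")
        assert pooled.n_nuclei == 592
        assert pooled.percentages["plus_minus"] == pytest.approx(100 * 250 / 592)
        assert round(pooled.percentages["plus_minus"], 2) == 42.23
        assert round(pooled.percentages["minus_minus"], 2) == 34.80

    def test_single_line_pool_identity_either_mode(self):
        s = CohortSummary.from_counts(
            "x", {"plus_plus": 3, "plus_minus": 4, "minus_minus": 5}, n_trans=1
        )
        for mode in ("pooled_counts", "mean_of_lines"):
            p = pool_lines([s], mode=mode)
            assert p.counts == s.counts
            assert p.allele_rate_pct == pytest.approx(s.allele_rate_pct)


class TestEcdf:
    def test_full_coverage_below_cutoff(self):
        t = ecdf_table([0.1, 0.2, 0.3])
        at_035 = t.loc[np.isclose(t["distance_um"], 0.35), "cumulative_pct"]
        assert float(at_035.iloc[0]) == 100.0

    def test_half_coverage(self):
        t = ecdf_table([0.1, 0.5])
        at_035 = float(t.loc[np.isclose(t["distance_um"], 0.35), "cumulative_pct"].iloc[0])
        assert at_035 == 50.0

    def test_monotone_and_reaches_100(self, rng):
        d = rng.exponential(0.5, size=200)
        t = ecdf_table(d)
        assert (np.diff(t["cumulative_pct"]) >= 0).all()
        assert t["cumulative_pct"].iloc[-1] == 100.0

    def test_ecdf_at_cutoff_equals_allele_rate(self, rng):
        d = rng.exponential(0.4, size=500)
        t = ecdf_table(d)
        at_cut = float(t.loc[np.isclose(t["distance_um"], 0.35), "cumulative_pct"].iloc[0])
        assert at_cut == pytest.approx(100 * np.mean(d <= 0.35))

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ecdf_table([])


class TestCompareLines:
    @staticmethod
    def _summary(label, pp, pm, mm, n_trans=0):
        return CohortSummary.from_counts(
            label, {"plus_plus": pp, "plus_minus": pm, "minus_minus": mm}, n_trans
        )

    def test_fisher_matches_hypergeometric_enumeration(self):
        # perfectly separated 10 vs 10: two-sided p = 2 / C(20, 10)
        s1 = self._summary("a", 10, 0, 0)
        s2 = self._summary("b", 0, 0, 10)
        rep = compare_lines([0.1] * 20, [0.8] * 20, s1, s2)
        p = rep.loc[rep["test"] == "fisher_plus_plus", "p"].iloc[0]
        assert p == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-9)

    def test_identical_proportions_p_one(self):
        s = self._summary("a", 5, 5, 5)
        rep = compare_lines([0.3] * 10, [0.3] * 10, s, s)
        for cat in ("plus_plus", "plus_minus", "minus_minus"):
            assert rep.loc[rep["test"] == f"fisher_{cat}", "p"].iloc[0] == 1.0

    def test_reconstructed_study_contrast_is_highly_significant(self):
        # pooled controls vs the ICR2-hypomethylation line, +/+ category
        ctrl = self._summary("CTRL", 136, 250, 206)
        case = self._summary("BWS-ICR2", 23, 131, 154)
        rep = compare_lines([0.2] * 10, [0.6] * 10, ctrl, case)
        p_pp = rep.loc[rep["test"] == "fisher_plus_plus", "p"].iloc[0]
        p_mm = rep.loc[rep["test"] == "fisher_minus_minus", "p"].iloc[0]
        assert p_pp <= 0.0001
        assert p_mm <= 0.001

    def test_degenerate_margin_gives_p_one_with_warning(self):
        s1 = self._summary("a", 0, 5, 5)
        s2 = self._summary("b", 0, 6, 4)
        with pytest.warns(UserWarning, match="zero margin"):
            rep = compare_lines([0.5] * 10, [0.5] * 10, s1, s2)
        assert rep.loc[rep["test"] == "fisher_plus_plus", "p"].iloc[0] == 1.0

    def test_empty_group_rejected(self):
        s = self._summary("a", 1, 1, 1)
        with pytest.raises(ValidationError):
            compare_lines([], [0.1], s, s)
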