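"""Fisher exact test, Woolf odds-ratio CIs, and the association panel.

Two independent oracles guard the statistics: an exhaustive exact-
rational enumeration of every same-margins table (Fisher), and a
from-scratch reimplementation of the logit formulas plus
``scipy.stats.fisher_exact`` (cross-checks).
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from kirhla.assoc_stats import (
    ContingencyTable,
    carrier_frequency,
    contingency_from_subjects,
    fisher_exact_two_sided,
    odds_ratio_ci,
    run_association_panel,
)
from kirhla.cohort_io import Subject
from kirhla.hla_ligands import LigandProfile
from kirhla.kir_classify import KIR_LOCI, A_GENOTYPE_LOCI, KIRProfile
from kirhla.markers import Marker, build_markers

cells = st.integers(min_value=0, max_value=40)
pos_cells = st.integers(min_value=1, max_value=40)


def fisher_oracle(a, b, c, d):
    """Point-probability two-sided Fisher p in exact rational arithmetic."""
    M, K, N = a + b + c + d, a + c, a + b

    def pmf(k):
        return Fraction(
            math.comb(K, k) * math.comb(M - K, N - k), math.comb(M, N)
        )

    obs = pmf(a)
    total = sum(
        (p for k in range(max(0, N - (M - K)), min(N, K) + 1)
         if (p := pmf(k)) <= obs),
        Fraction(0),
    )
    return float(total)


class TestFisher:
    def test_symmetric_table_p_is_one(self):
        assert fisher_exact_two_sided(ContingencyTable(5, 5, 5, 5)) == 1.0

    def test_exhaustive_enumeration_oracle_all_margins_le_12(self):
        for n1 in range(13):
            for n0 in range(13):
                if n1 + n0 == 0:
                    continue
                for a in range(n1 + 1):
                    for c in range(n0 + 1):
                        t = ContingencyTable(a, n1 - a, c, n0 - c)
                        expected = fisher_oracle(a, n1 - a, c, n0 - c)
                        got = fisher_exact_two_sided(t)
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(cells, cells, cells, cells)
    @settings(max_examples=150, derandomize=True)
    def test_matches_scipy_cross_check(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        theirs = scipy_fisher([[a, b], [c, d]])[1]
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    @given(cells, cells, cells, cells)
    @settings(max_examples=100, derandomize=True)
    def test_arm_swap_and_transpose_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert fisher_exact_two_sided(ContingencyTable(c, d, a, b)) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_two_sided(ContingencyTable(a, c, b, d)) == pytest.approx(p, rel=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestOddsRatio:
    def test_equal_odds_gives_unit_or(self):
        r = odds_ratio_ci(ContingencyTable(10, 20, 30, 60))
        assert r["or_point"] == pytest.approx(1.0)
        assert r["ci_low"] < 1.0 < r["ci_high"]
        assert not r["zero_cell_corrected"]

    def test_haldane_correction_on_zero_cell(self):
        r = odds_ratio_ci(ContingencyTable(0, 44, 34, 244))
        assert r["zero_cell_corrected"]
        assert r["or_point"] == pytest.approx(0.0796, abs=5e-4)
        assert r["ci_low"] == pytest.approx(0.0048, abs=5e-4)
        assert r["ci_high"] == pytest.approx(1.32, abs=5e-3)

    def test_diagonal_zeros_undefined(self):
        with pytest.raises(ValueError, match="diagonal"):
            odds_ratio_ci(ContingencyTable(0, 5, 5, 0))
        with pytest.raises(ValueError, match="diagonal"):
            odds_ratio_ci(ContingencyTable(5, 0, 0, 5))

    def test_independent_reimplementation_on_random_tables(self):
        rng = np.random.default_rng(2021)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 400, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            r = odds_ratio_ci(t, z=None)  # exact normal quantile
            # independent formula path (numpy, log10 domain)
            lor = np.log10(a) + np.log10(d) - np.log10(b) - np.log10(c)
            se10 = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d) / np.log(10)
            z = 1.9599639845400545
            assert r["or_point"] == pytest.approx(10 ** lor, rel=1e-10)
            assert r["ci_low"] == pytest.approx(10 ** (lor - z * se10), rel=1e-9)
            assert r["ci_high"] == pytest.approx(10 ** (lor + z * se10), rel=1e-9)

    @given(pos_cells, pos_cells, pos_cells, pos_cells)
    @settings(max_examples=100, derandomize=True)
    def test_reciprocity_under_arm_swap(self, a, b, c, d):
        r = odds_ratio_ci(ContingencyTable(a, b, c, d))
        s = odds_ratio_ci(ContingencyTable(c, d, a, b))
        assert s["or_point"] == pytest.approx(1 / r["or_point"], rel=1e-12)
        assert s["ci_low"] == pytest.approx(1 / r["ci_high"], rel=1e-12)
        assert s["ci_high"] == pytest.approx(1 / r["ci_low"], rel=1e-12)

    def test_or_strictly_increases_in_a(self):
        ors = [
            odds_ratio_ci(ContingencyTable(a, 10, 20, 30))["or_point"]
            for a in range(1, 20)
        ]
        assert all(x < y for x, y in zip(ors, ors[1:]))

    def test_ci_brackets_point_estimate(self):
        r = odds_ratio_ci(ContingencyTable(135, 27, 200, 78))
        assert r["ci_low"] <= r["or_point"] <= r["ci_high"]


def _subject(i, stratum, bx=False, c2=None):
    kir = KIRProfile(frozenset(KIR_LOCI)) if bx else KIRProfile(A_GENOTYPE_LOCI)
    lig = None
    if c2 is not None:
        lig = LigandProfile(c2_pos=c2, c_typed=True, b_typed=True, a_typed=True)
    return Subject(f"s{i}", stratum, kir, ligands=lig)


class TestCarrierFrequency:
    def test_always_true_predicate_is_100_percent(self):
        subjects = [_subject(i, "control") for i in range(10)]
        out = carrier_frequency(subjects, lambda s: True, "control")
        assert out == {"pct": 100.0, "n_pos": 10, "n": 10}

    def test_not_evaluable_subjects_shrink_denominator(self):
        subjects = [_subject(i, "control", c2=True) for i in range(8)]
        subjects += [_subject(i + 8, "control") for i in range(2)]  # untyped
        pred = lambda s: s.ligands.c2_pos if s.ligands else None
        out = carrier_frequency(subjects, pred, "control")
        assert out["n"] == 8 and out["n_pos"] == 8

    def test_empty_denominator_is_error(self):
        subjects = [_subject(0, "control")]
        with pytest.raises(ValueError, match="empty denominator"):
            carrier_frequency(subjects, lambda s: True, "advanced")

    def test_all_cases_pools_every_case_stratum(self):
        subjects = [
            _subject(0, "control"), _subject(1, "early"),
            _subject(2, "advanced"), _subject(3, "case"),
        ]
        assert carrier_frequency(subjects, lambda s: True, "all")["n"] == 3


class TestPanel:
    def _cohort(self):
        subjects = [_subject(i, "control", bx=i < 20) for i in range(40)]
        subjects += [_subject(100 + i, "early", bx=i < 15) for i in range(20)]
        subjects += [_subject(200 + i, "advanced", bx=i < 15) for i in range(20)]
        return subjects

    def test_identical_carriage_gives_unit_or(self):
        subjects = [_subject(i, "control", bx=i % 2 == 0) for i in range(20)]
        subjects += [_subject(50 + i, "early", bx=i % 2 == 0) for i in range(20)]
        (res,) = run_association_panel(
            subjects, build_markers(["haplogroups"])[1:], contrasts=["all"]
        )
        assert res.or_point == pytest.approx(1.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_panel_is_deterministic(self):
        subjects = self._cohort()
        markers = build_markers(["genes", "haplogroups", "linkage"])
        r1 = run_association_panel(subjects, markers)
        r2 = run_association_panel(subjects, markers)
        assert [(r.marker, r.stratum, r.p_two_sided, r.or_point) for r in r1] == [
            (r.marker, r.stratum, r.p_two_sided, r.or_point) for r in r2
        ]

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            run_association_panel(self._cohort(), build_markers(["haplogroups"]),
                                  contrasts=["metastatic"])

    def test_bonferroni_annotation(self):
        res = run_association_panel(
            self._cohort(), build_markers(["haplogroups"]),
            contrasts=["all"], bonferroni=True,
        )
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_two_sided * len(res)))

    def test_contingency_matches_manual_count(self):
        subjects = self._cohort()
        bx = build_markers(["haplogroups"])[1]
        t = contingency_from_subjects(subjects, bx.fn, "all")
        assert (t.a, t.b, t.c, t.d) == (30, 10, 20, 20)
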