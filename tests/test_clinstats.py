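"""Welch tests, chi-square, CKD-EPI/KDIGO, and survival analysis."""

import numpy as np
import pytest

from foundertrace.clinstats import (
    CkdEpiInput,
    GroupSummary,
    SurvivalError,
    SurvivalRecord,
    ZeroVarianceError,
    chi_square_2x2,
    ckd_epi_2009,
    ckd_stage,
    clinical_comparison,
    km_curve,
    logrank,
    welch_t_from_summary,
)
from foundertrace.rare_tagging import ContingencyTable
from foundertrace.simulate import simulate_clinical


class TestWelch:
    # Carrier-vs-population comparisons from published mean+/-SD summaries:
    # n=9 carriers against a ~451k background.
    @pytest.mark.parametrize(
        "g1,g2,expected_p",
        [
            ((163.6, 20.8, 9), (144.2, 24.1, 450984), 0.023),  # systolic BP
            ((99.3, 13.0, 9), (86.4, 13.5, 450984), 0.017),  # diastolic BP
            ((58.5, 8.7, 9), (57.3, 8.0, 450984), 0.69),  # age
            ((309.7, 55.1, 9), (309.1, 80.4, 450984), 0.98),  # serum urate
        ],
    )
    def test_published_summaries(self, g1, g2, expected_p):
        res = welch_t_from_summary(GroupSummary(*g1), GroupSummary(*g2))
        assert res.p_two_sided == pytest.approx(expected_p, rel=0.05)

    def test_identical_groups(self):
        g = GroupSummary(10.0, 2.0, 5)
        res = welch_t_from_summary(g, g)
        assert (res.t, res.p_two_sided) == (0.0, 1.0)

    def test_antisymmetric(self):
        g1, g2 = GroupSummary(5.0, 1.0, 8), GroupSummary(4.0, 2.0, 20)
        a, b = welch_t_from_summary(g1, g2), welch_t_from_summary(g2, g1)
        assert a.t == pytest.approx(-b.t)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_zero_variance_unequal_means(self):
        with pytest.raises(ZeroVarianceError):
            welch_t_from_summary(GroupSummary(1, 0, 3), GroupSummary(2, 0, 3))

    def test_huge_background_df_collapses_to_small_group(self):
        # As background n grows with sd fixed, df -> n1 - 1 and p depends
        # only on the small group's summary.
        g1 = GroupSummary(10.0, 3.0, 9)
        res = welch_t_from_summary(g1, GroupSummary(8.0, 5.0, 10**7))
        assert res.df == pytest.approx(8, abs=0.01)


class TestChiSquare:
    def test_independent_table(self):
        stat, p = chi_square_2x2(ContingencyTable(10, 10, 10, 10))
        assert (stat, p) == (0.0, 1.0)

    def test_closed_form(self):
        stat, p = chi_square_2x2(ContingencyTable(20, 10, 10, 20))
        assert stat == pytest.approx(60 * 300**2 / 30**4)
        assert stat == pytest.approx(6.667, abs=1e-3)
        assert p == pytest.approx(0.0098, abs=2e-4)

    def test_continuity_correction_shrinks_statistic(self):
        t = ContingencyTable(20, 10, 10, 20)
        assert chi_square_2x2(t, continuity_correction=True)[0] < chi_square_2x2(t)[0]

    def test_moving_toward_independence_decreases_statistic(self):
        s1, _ = chi_square_2x2(ContingencyTable(20, 10, 10, 20))
        s2, _ = chi_square_2x2(ContingencyTable(18, 12, 12, 18))
        assert s2 < s1

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable(0, 0, 10, 20))


class TestCkdEpi:
    def test_female_at_kappa(self):
        egfr = ckd_epi_2009(CkdEpiInput(0.7, 50, "female"))
        assert egfr == pytest.approx(141 * 0.993**50 * 1.018, rel=1e-9)
        assert egfr == pytest.approx(101.0, abs=0.2)

    def test_male_high_creatinine(self):
        egfr = ckd_epi_2009(CkdEpiInput(1.8, 60, "male"))
        assert egfr == pytest.approx(40.0, abs=0.2)

    def test_piecewise_factors_cancel_at_kappa(self):
        male = ckd_epi_2009(CkdEpiInput(0.9, 40, "male"))
        assert male == pytest.approx(141 * 0.993**40, rel=1e-9)

    def test_ethnicity_coefficient(self):
        base = ckd_epi_2009(CkdEpiInput(1.0, 50, "male"))
        assert ckd_epi_2009(CkdEpiInput(1.0, 50, "male", black=True)) == pytest.approx(
            base * 1.159, rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ckd_epi_2009(CkdEpiInput(0.0, 50, "male"))
        with pytest.raises(ValueError):
            ckd_epi_2009(CkdEpiInput(1.0, 50, "other"))


class TestCkdStage:
    @pytest.mark.parametrize(
        "egfr,acr,g,a,ckd",
        [
            (69, 1.6, "G2", "A1", False),
            (90, 1.0, "G1", "A1", False),
            (59.9, None, "G3a", None, True),
            (95, 40, "G1", "A3", True),
            (10, 31, "G5", "A3", True),
            (45, 3.0, "G3a", "A2", True),
        ],
    )
    def test_stages(self, egfr, acr, g, a, ckd):
        assert ckd_stage(egfr, acr) == (g, a, ckd)


class TestKaplanMeier:
    def test_no_censoring_product_limit(self):
        records = [SurvivalRecord(f"s{t}", t, True) for t in range(1, 6)]
        km = km_curve(records)
        assert km.survival[km.times > 0].tolist() == pytest.approx(
            [0.8, 0.6, 0.4, 0.2, 0.0]
        )
        assert km.median == 3

    def test_all_censored(self):
        records = [SurvivalRecord(f"s{t}", t, False) for t in (2, 4, 6)]
        km = km_curve(records)
        assert np.all(km.survival == 1.0)
        assert km.median is None

    def test_single_event(self):
        km = km_curve([SurvivalRecord("s", 7, True)])
        assert km.median == 7

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(10, size=60)
        records = [SurvivalRecord(f"s{i}", t, True) for i, t in enumerate(times)]
        km = km_curve(records)
        grid = np.linspace(0, times.max() + 1, 80)
        empirical = [(times > t).mean() for t in grid]
        estimated = [km.at(t) for t in grid]
        assert estimated == pytest.approx(empirical)


class TestLogrank:
    def make(self, times_a, times_b, events=None):
        ev = events or [True] * len(times_a)
        recs = [
            SurvivalRecord(f"a{i}", t, e, "A")
            for i, (t, e) in enumerate(zip(times_a, ev))
        ]
        recs += [
            SurvivalRecord(f"b{i}", t, e, "B")
            for i, (t, e) in enumerate(zip(times_b, ev))
        ]
        return recs

    def test_identical_groups(self):
        stat, p = logrank(self.make([1, 2, 3, 4], [1, 2, 3, 4]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        stat, p = logrank(self.make([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]))
        assert stat > 0
        assert p < 1

    def test_errors(self):
        with pytest.raises(SurvivalError):
            logrank(
                [
                    SurvivalRecord("a", 1, False, "A"),
                    SurvivalRecord("b", 2, False, "B"),
                ]
            )
        with pytest.raises(SurvivalError):
            logrank([SurvivalRecord("a", 1, True, "A")])


def test_clinical_comparison_on_simulated_cohort():
    pheno = simulate_clinical(n=500, n_carriers=30, seed=2)
    carriers = pheno.loc[pheno["carrier"] == 1, "sample"].tolist()
    table = clinical_comparison(pheno, carriers)
    rows = table.set_index("variable")
    # Carrier blood-pressure shift is detectable; urate is a true null.
    assert rows.loc["sbp", "p"] < 0.01
    assert rows.loc["urate", "p"] > 0.01
    assert set(rows.index) >= {"age", "sbp", "dbp", "creatinine_mg_dl"}
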