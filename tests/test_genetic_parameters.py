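"""Variance-component formulas, genetic indices and their published
worked examples; analytic estimator expectations vs a symbolic oracle."""

import numpy as np
import pandas as pd
import pytest
import sympy

from metscreen import synthetic_data as sd
from metscreen.anova import AnovaTable, ModelSpec, anova_balanced
from metscreen.genetic_parameters import (
    VarianceComponents,
    cv_percent,
    formula_expectations,
    genetic_summary,
    heritability_percent,
    variance_components,
)


def table_from_ms(ms: dict) -> AnovaTable:
    rows = [
        (name, 1, ms[name], ms[name], np.nan, np.nan, "")
        for name in ("year", "block(year)", "genotype", "genotype:year", "residual")
        if name in ms
    ]
    frame = pd.DataFrame(
        rows, columns=["source", "df", "ss", "ms", "F", "p", "denominator"]
    )
    return AnovaTable(table=frame, response="X", n_obs=0)


class TestComponentFormulas:
    def test_direct_arithmetic(self):
        tab = table_from_ms(
            {"year": 1, "block(year)": 1, "genotype": 10, "genotype:year": 1,
             "residual": 1}
        )
        vc = variance_components(tab, blk=3, yr=6, gn=30)
        assert vc.genotype == pytest.approx(9 / 18)

    def test_equal_ms_gives_zero_component(self):
        tab = table_from_ms(
            {"year": 1, "block(year)": 1, "genotype": 2, "genotype:year": 1,
             "residual": 2}
        )
        vc = variance_components(tab, blk=3, yr=6, gn=30)
        assert vc.genotype == 0.0

    def test_formula_inversion_roundtrip(self):
        """MS set to the formula-implied values for chosen components
        recover those components exactly."""
        blk, yr, gn = 3, 6, 30
        target = {"residual": 1.7, "block_in_year": 0.4, "gxy": 2.2, "genotype": 5.5}
        ms = {
            "residual": target["residual"],
            "genotype:year": target["gxy"] * blk + target["residual"],
            "genotype": target["genotype"] * blk * yr + target["residual"],
            "block(year)": target["block_in_year"] * yr * gn + target["residual"],
            "year": 0.0,
        }
        vc = variance_components(table_from_ms(ms), blk, yr, gn)
        assert vc.residual == pytest.approx(target["residual"])
        assert vc.block_in_year == pytest.approx(target["block_in_year"])
        assert vc.gxy == pytest.approx(target["gxy"])
        assert vc.genotype == pytest.approx(target["genotype"])
        assert vc.phenotypic == pytest.approx(
            vc.genotype + vc.year / (blk * yr) + vc.gxy / yr
        )

    def test_missing_ms_row_named(self):
        tab = table_from_ms({"residual": 1, "genotype": 2, "year": 1,
                             "genotype:year": 1})
        with pytest.raises(KeyError, match="block"):
            variance_components(tab, 3, 6, 30)

    def test_degenerate_counts_rejected(self):
        tab = table_from_ms(
            {"year": 1, "block(year)": 1, "genotype": 2, "genotype:year": 1,
             "residual": 1}
        )
        with pytest.raises(ValueError):
            variance_components(tab, blk=1, yr=6, gn=30)

    def test_textbook_genotype_formula(self):
        tab = table_from_ms(
            {"year": 1, "block(year)": 1, "genotype": 10, "genotype:year": 4,
             "residual": 1}
        )
        vc = variance_components(tab, 3, 6, 30, genotype_formula="textbook")
        assert vc.genotype == pytest.approx((10 - 4) / 18)


class TestPublishedWorkedExamples:
    """Index values recomputed from the printed component table."""

    def test_heritability_drought_sod(self):
        vc = VarianceComponents(
            residual=0, block_in_year=0, gxy=0, genotype=20.06, year=0,
            phenotypic=32.91, blk=3, yr=6, gn=30,
        )
        assert heritability_percent(vc, truncate=False) == pytest.approx(60.95, abs=0.01)
        assert round(heritability_percent(vc)) == 61

    def test_heritability_normal_carotenoid(self):
        vc = VarianceComponents(
            residual=0, block_in_year=0, gxy=0, genotype=0.83, year=0,
            phenotypic=1.34, blk=3, yr=6, gn=30,
        )
        assert heritability_percent(vc) == pytest.approx(61.9, abs=0.05)
        assert round(heritability_percent(vc)) == 62

    def test_heritability_drought_yield(self):
        vc = VarianceComponents(
            residual=0, block_in_year=0, gxy=0, genotype=47.06, year=0,
            phenotypic=121.9, blk=3, yr=6, gn=30,
        )
        assert heritability_percent(vc) == pytest.approx(38.61, abs=0.01)

    def test_pcv_gcv_table_ratio(self):
        assert cv_percent(32.91, 43.21) == pytest.approx(76.16, abs=0.01)
        assert cv_percent(6.85, 19.18) == pytest.approx(35.71, abs=0.01)

    def test_methods_sqrt_convention(self):
        assert cv_percent(4.0, 10.0, convention="methods_sqrt") == pytest.approx(20.0)

    def test_phenotypic_additivity(self):
        for gn, env, pheno in ((20.06, 12.85, 32.91), (41.16, 173.9, 215.1)):
            vc = VarianceComponents(
                residual=0, block_in_year=0, gxy=0, genotype=gn, year=0,
                phenotypic=gn + env, blk=3, yr=6, gn=30,
            )
            assert vc.environment_effective == pytest.approx(env)
            assert gn + env == pytest.approx(pheno, abs=0.05)

    def test_identical_components_full_heritability(self):
        vc = VarianceComponents(
            residual=0, block_in_year=0, gxy=0, genotype=5.0, year=0,
            phenotypic=5.0, blk=3, yr=6, gn=30,
        )
        assert heritability_percent(vc) == pytest.approx(100.0)


class TestEstimatorExpectations:
    def test_against_sympy_derivation(self):
        """Re-derive the estimator expectations symbolically from the
        balanced expected mean squares and compare."""
        s_res, s_blk, s_gxy, s_gn, s_yr = sympy.symbols(
            "s_res s_blk s_gxy s_gn s_yr", nonnegative=True
        )
        blk, yr, gn = sympy.symbols("blk yr gn", positive=True)
        ems = {
            "residual": s_res,
            "gxy": s_res + blk * s_gxy,
            "genotype": s_res + blk * s_gxy + blk * yr * s_gn,
            "block(year)": s_res + gn * s_blk,
        }
        published = {
            "residual": ems["residual"],
            "block_in_year": (ems["block(year)"] - ems["residual"]) / (yr * gn),
            "gxy": (ems["gxy"] - ems["residual"]) / blk,
            "genotype": (ems["genotype"] - ems["residual"]) / (blk * yr),
            "year": (ems["block(year)"] - ems["gxy"] + ems["residual"]) / (blk * gn),
        }
        published["phenotypic"] = (
            published["genotype"]
            + published["year"] / (blk * yr)
            + published["gxy"] / yr
        )
        numbers = {s_res: 12, s_blk: 4, s_gxy: 5, s_gn: 20, s_yr: 8,
                   blk: 3, yr: 6, gn: 30}
        got = formula_expectations(
            {"residual": 12, "block_in_year": 4, "gxy": 5, "genotype": 20, "year": 8},
            blk=3, yr=6, gn=30,
        )
        for name, attr in [
            ("residual", got.residual), ("block_in_year", got.block_in_year),
            ("gxy", got.gxy), ("genotype", got.genotype), ("year", got.year),
            ("phenotypic", got.phenotypic),
        ]:
            assert attr == pytest.approx(float(published[name].subs(numbers)))

    def test_published_genotype_estimator_biased_by_gxy(self):
        got = formula_expectations(
            {"residual": 1, "block_in_year": 0, "gxy": 6, "genotype": 10, "year": 0},
            blk=3, yr=6, gn=30,
        )
        assert got.genotype == pytest.approx(10 + 1.0)
        textbook = formula_expectations(
            {"residual": 1, "block_in_year": 0, "gxy": 6, "genotype": 10, "year": 0},
            blk=3, yr=6, gn=30, genotype_formula="textbook",
        )
        assert textbook.genotype == pytest.approx(10.0)


class TestIndices:
    def test_heritability_scale_invariance(self, small_trial):
        model = ModelSpec.per_condition()
        vc1 = variance_components(anova_balanced(small_trial, "X", model), 2, 2, 3)
        scaled = small_trial.assign(X=small_trial["X"] * 7.3)
        vc2 = variance_components(anova_balanced(scaled, "X", model), 2, 2, 3)
        assert heritability_percent(vc1) == pytest.approx(
            heritability_percent(vc2), rel=1e-9
        )

    def test_truncation_keeps_h2_in_range(self):
        tab = table_from_ms(
            {"year": 1, "block(year)": 1, "genotype": 0.5, "genotype:year": 5,
             "residual": 2}
        )
        vc = variance_components(tab, 3, 6, 30)
        assert vc.genotype < 0  # raw estimate reported as-is
        h2 = heritability_percent(vc)
        assert 0.0 <= h2 <= 100.0

    def test_zero_phenotypic_flagged(self):
        vc = VarianceComponents(
            residual=0, block_in_year=0, gxy=0, genotype=0, year=0,
            phenotypic=0, blk=3, yr=6, gn=30,
        )
        with pytest.warns(RuntimeWarning):
            assert np.isnan(heritability_percent(vc))

    def test_zero_mean_cv_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(cv_percent(1.0, 0.0))

    def test_summary_shape_and_pcv_ge_gcv(self, small_trial):
        summary = genetic_summary(small_trial, ["X"], blk=2, yr=2, gn=3)
        assert set(summary.index) == {
            "genotypic_variance", "environmental_variance", "phenotypic_variance",
            "heritability", "PCV", "GCV", "mean",
        }
        assert summary.loc["PCV", "X"] >= summary.loc["GCV", "X"]
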