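"""Mixed models, AIC selection, BY-FDR and the land-use pipeline."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from comindic import (
    LandUseTable,
    ScenarioConfig,
    SiteContext,
    aic_select,
    build_design,
    by_fdr,
    classification_robustness,
    community_index,
    fit_mixed,
    gen_landuse,
    gen_survey,
    landuse_sensitivity,
    watershed_consistency,
)
from comindic.sensitivity import DesignError
from comindic.synthetic import coarsen_landuse

BASE_ONLY = (("year", "x", "y"),)


def make_series(n_sites=40, n_years=4, sigma_site=0.01, sigma_eps=0.02,
                beta_x=0.0, seed=0):
    """Index series simulated directly from the mixed-model data law."""
    rng = np.random.default_rng(seed)
    sites = [f"s{i:03d}" for i in range(n_sites)]
    x = rng.random(n_sites)
    y = rng.random(n_sites)
    b = rng.normal(0, sigma_site, n_sites)
    rows = []
    for i, site in enumerate(sites):
        for yr in range(2000, 2000 + n_years):
            rows.append(
                (site, yr, 0.3 + beta_x * x[i] + b[i] + rng.normal(0, sigma_eps),
                 1.0, False)
            )
    series = pd.DataFrame(
        rows, columns=["site_id", "year", "index", "coverage", "flagged"]
    )
    ctx = SiteContext(
        pd.DataFrame(
            {
                "site_id": sites,
                "x": x,
                "y": y,
                "watershed": ["W1" if xi < 0.5 else "W2" for xi in x],
            }
        )
    )
    return series, ctx


class TestBuildDesign:
    def test_year_and_coordinate_interactions_column_count(self):
        series, ctx = make_series()
        design = build_design(
            series, ctx, spec=("year", "x", "y", "year:x", "year:y")
        )
        X = design.fixed_effect_matrix()
        assert X.shape[1] == 6  # intercept + year + x + y + year:x + year:y
        assert "Intercept" in X.columns

    def test_landuse_reference_coding_drops_forest(self):
        series, ctx = make_series()
        lu = gen_landuse(ctx.table["site_id"], "CLC5", seed=0)
        design = build_design(series, ctx, lu=lu, spec=("year", "landuse"))
        X = design.fixed_effect_matrix()
        lu_cols = [c for c in X.columns if "landuse" in c]
        assert len(lu_cols) == 4  # k-1 coding
        assert not any(c.endswith("[T.Forest]") for c in lu_cols)

    def test_duplicate_term_rejected(self):
        series, ctx = make_series()
        with pytest.raises(DesignError, match="duplicate"):
            build_design(series, ctx, spec=("year", "x", "year"))

    def test_unknown_site_rejected(self):
        series, ctx = make_series()
        bad = series.copy()
        bad.loc[0, "site_id"] = "nowhere"
        with pytest.raises(DesignError, match="missing from context"):
            build_design(bad, ctx, spec=("year",))

    def test_year_is_centered(self):
        series, ctx = make_series()
        design = build_design(series, ctx, spec=("year",))
        assert design.data["year_c"].mean() == pytest.approx(0.0, abs=1e-9)


class TestFitMixed:
    def test_null_site_variance_matches_ols(self):
        series, ctx = make_series(sigma_site=0.0, beta_x=0.01, seed=1)
        design = build_design(series, ctx, spec=("year", "x", "y"))
        fit = fit_mixed(design)
        ols = smf.ols(design.formula, design.data).fit()
        np.testing.assert_allclose(
            fit.params.loc[ols.params.index], ols.params, atol=1e-6
        )

    def test_recovers_known_slope(self):
        hits = 0
        for seed in range(10):
            series, ctx = make_series(
                n_sites=120, n_years=5, beta_x=0.05, seed=seed
            )
            design = build_design(series, ctx, spec=("year", "x"))
            fit = fit_mixed(design)
            se = fit.params["x"] / fit.tvalues["x"]
            if abs(fit.params["x"] - 0.05) < 3 * se:
                hits += 1
        assert hits >= 9

    def test_positive_site_variance_detected(self):
        series, ctx = make_series(
            n_sites=150, n_years=5, sigma_site=0.05, sigma_eps=0.01, seed=3
        )
        design = build_design(series, ctx, spec=("year",))
        fit = fit_mixed(design)
        assert not fit.used_ols
        assert fit.group_var == pytest.approx(0.05**2, rel=0.5)

    def test_single_site_rejected(self):
        series, ctx = make_series(n_sites=1)
        design = build_design(series, ctx, spec=("year",))
        with pytest.raises(DesignError, match="at least 2 sites"):
            fit_mixed(design)

    def test_rank_deficient_design_lists_aliased_columns(self):
        series, ctx = make_series()
        series = series.merge(ctx.table[["site_id", "x"]], on="site_id")
        ctx.table["y"] = ctx.table["x"]  # y aliases x
        with pytest.raises(DesignError, match="aliased"):
            fit_mixed(build_design(series.drop(columns="x"), ctx, spec=("x", "y")))


class TestAicSelect:
    def _fit(self, spec, series, ctx):
        return fit_mixed(build_design(series, ctx, spec=spec))

    def test_single_candidate_returned(self):
        series, ctx = make_series(seed=2)
        fit = self._fit(("year",), series, ctx)
        assert aic_select([fit]) is fit

    def test_tie_broken_toward_fewer_parameters(self):
        series, ctx = make_series(seed=2)
        fit = self._fit(("year",), series, ctx)
        clone = fit.__class__(**{**fit.__dict__})
        clone.n_params = fit.n_params + 5
        assert aic_select([clone, fit]) is fit

    def test_differing_rows_rejected(self):
        s1, ctx = make_series(seed=2)
        f1 = self._fit(("year",), s1, ctx)
        f2 = self._fit(("year",), s1.iloc[: len(s1) - 4], ctx)
        with pytest.raises(DesignError, match="differing row"):
            aic_select([f1, f2])

    def test_reml_fits_rejected(self):
        series, ctx = make_series(seed=2)
        fit = fit_mixed(build_design(series, ctx, spec=("year",)), reml=True)
        with pytest.raises(DesignError, match="ML"):
            aic_select([fit])

    def test_generating_watershed_effect_selected(self):
        """Watershed-structured data should AIC-prefer the watershed model."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            series, ctx = make_series(n_sites=100, n_years=4, seed=seed)
            shift = {"W1": -0.04, "W2": 0.04}
            series["index"] += series["site_id"].map(
                dict(zip(ctx.table["site_id"], ctx.table["watershed"].map(shift)))
            )
            fits = [
                self._fit(("year", "x", "y"), series, ctx),
                self._fit(("year", "watershed"), series, ctx),
            ]
            if aic_select(fits).design.terms == ("year", "watershed"):
                wins += 1
        assert wins >= 9


class TestByFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(by_fdr([0.04]), [0.04])

    def test_hand_worked_triple(self):
        np.testing.assert_allclose(
            by_fdr([0.01, 0.02, 0.03]), [0.055, 0.055, 0.055], atol=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            by_fdr([0.5, 1.2])

    def test_matches_statsmodels_by_and_dominates_bh(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 12)))
            ours = by_fdr(p)
            theirs = multipletests(p, method="fdr_by")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)
            bh = multipletests(p, method="fdr_bh")[1]
            assert (ours >= bh - 1e-12).all()

    def test_monotone_in_sorted_order(self):
        p = np.array([0.3, 0.01, 0.2, 0.005, 0.9])
        adj = by_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _scenario(seed, effects=None, n_sites=80, n_years=3, variant="CLC5"):
    cfg = ScenarioConfig(
        n_sites=n_sites,
        n_years=n_years,
        landuse_variant=variant,
        class_effects=effects or {},
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    from comindic import SpeciesScoreVector

    vals = np.sort(rng.uniform(0.05, 0.6, cfg.n_species))
    scores = SpeciesScoreVector(cfg.species_ids(), vals)
    sites = [f"s{i:04d}" for i in range(n_sites)]
    lu = gen_landuse(sites, variant, seed=seed + 1)
    survey, ctx = gen_survey(cfg, scores, lu, seed=seed + 2)
    series = community_index(survey, scores)
    return series, ctx, lu


class TestLanduseSensitivity:
    def test_reference_coefficient_structurally_zero(self):
        series, ctx, lu = _scenario(0)
        res = landuse_sensitivity(series, ctx, lu, candidate_specs=BASE_ONLY)
        assert res.table.loc["Forest", "coef"] == 0.0
        assert np.isnan(res.table.loc["Forest", "p_by"])

    def test_adjusted_p_dominates_raw(self):
        series, ctx, lu = _scenario(1)
        res = landuse_sensitivity(series, ctx, lu, candidate_specs=BASE_ONLY)
        tab = res.table.drop(index="Forest")
        assert (tab["p_by"] >= tab["p_raw"] - 1e-12).all()
        assert (tab["p_by"] <= 1.0 + 1e-12).all()

    def test_injected_negative_gradient_recovered(self):
        effects = {"Meadow": -0.01, "Farming": -0.02, "Mix": -0.03, "Urban": -0.04}
        series, ctx, lu = _scenario(5, effects=effects, n_sites=150, n_years=4)
        res = landuse_sensitivity(series, ctx, lu, candidate_specs=BASE_ONLY)
        tab = res.table.drop(index="Forest")
        assert (tab["coef"] < 0).all()
        ordered = tab.loc[["Meadow", "Farming", "Mix", "Urban"], "coef"]
        assert (np.diff(ordered) < 0).all()

    def test_exclude_region_equals_fit_on_complement(self):
        series, ctx, lu = _scenario(3, n_sites=100)
        region = ctx.table["region"].iloc[0]
        res_excl = landuse_sensitivity(
            series, ctx, lu, exclude_region=region, candidate_specs=BASE_ONLY
        )
        keep = set(ctx.table.loc[ctx.table["region"] != region, "site_id"])
        sub_series = series[series["site_id"].isin(keep)].reset_index(drop=True)
        sub_ctx = SiteContext(
            ctx.table[ctx.table["region"] != region].reset_index(drop=True)
        )
        res_manual = landuse_sensitivity(
            sub_series, sub_ctx, lu, candidate_specs=BASE_ONLY
        )
        pd.testing.assert_frame_equal(res_excl.table, res_manual.table)

    def test_r2_proxy_matches_random_effect_free_refit(self):
        series, ctx, lu = _scenario(4)
        res = landuse_sensitivity(series, ctx, lu, candidate_specs=BASE_ONLY)
        assert -1 <= res.r2_proxy <= 1


class TestRobustnessAndWatersheds:
    def test_uniform_negative_gradient_flagged_robust(self):
        effects = {
            "Meadow": -0.01,
            "Farming": -0.02,
            "Intensive Farming": -0.025,
            "Mix": -0.02,
            "Urban": -0.03,
            "Intensive Urban": -0.035,
        }
        series, ctx, lu7 = _scenario(
            7, effects=effects, n_sites=150, n_years=4, variant="ONEMA7"
        )
        variants = [
            coarsen_landuse(lu7, "CLC5"),
            coarsen_landuse(lu7, "EUROWATER6"),
            lu7,
        ]
        report = classification_robustness(
            series, ctx, variants, candidate_specs=BASE_ONLY
        )
        assert report.robust is True
        assert set(report.signs.columns) == {"CLC5", "EUROWATER6", "ONEMA7"}

    def test_opposing_signs_flagged_non_robust(self):
        effects = {
            "Farming": -0.04,
            "Intensive Farming": -0.04,
            "Urban": 0.04,
            "Intensive Urban": 0.04,
        }
        series, ctx, lu7 = _scenario(
            8, effects=effects, n_sites=150, n_years=4, variant="ONEMA7"
        )
        variants = [coarsen_landuse(lu7, "CLC5"), lu7]
        report = classification_robustness(
            series, ctx, variants, candidate_specs=BASE_ONLY
        )
        assert report.robust is False

    def test_single_variant_robustness_undefined(self):
        series, ctx, lu = _scenario(9)
        report = classification_robustness(
            series, ctx, [lu], candidate_specs=BASE_ONLY
        )
        assert report.robust is None

    def test_mismatched_variant_sites_rejected(self):
        series, ctx, lu = _scenario(10)
        other = LandUseTable(lu.assignment.iloc[:-1], variant=lu.variant)
        with pytest.raises(DesignError, match="same sites"):
            classification_robustness(series, ctx, [lu, other])

    def test_homogeneous_effect_agrees_across_watersheds(self):
        effects = {"Urban": -0.05, "Farming": -0.04}
        series, ctx, lu = _scenario(11, effects=effects, n_sites=240, n_years=4)
        report = watershed_consistency(series, ctx, lu, min_sites=30)
        sig = report.agreement.dropna()
        assert len(report.results) >= 2
        assert (sig >= 0.75).all()

    def test_small_watershed_skipped_with_warning(self, caplog):
        series, ctx, lu = _scenario(12, n_sites=60)
        tiny = ctx.table["watershed"].iloc[0]
        # shrink one watershed below the threshold by relabeling most of it
        mask = ctx.table["watershed"] == tiny
        keep_small = ctx.table.loc[mask, "site_id"].iloc[:3]
        ctx.table.loc[
            mask & ~ctx.table["site_id"].isin(keep_small), "watershed"
        ] = "BIG"
        with caplog.at_level("WARNING"):
            report = watershed_consistency(series, ctx, lu, min_sites=5)
        assert tiny in report.skipped
        assert tiny not in report.results
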