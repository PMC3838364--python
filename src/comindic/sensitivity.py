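"""Indicator evaluation: land-use sensitivity of community indices.

An index is a useful pressure indicator when it responds to a landscape
artificialization gradient.  The pipeline mirrors standard monitoring
practice:

1. choose a spatio-temporal base model by AIC among mixed-effects linear
   models (site random intercept; fixed effects among year, coordinates,
   watershed and year interactions);
2. add land-use classes coded relative to the natural reference class
   (Forest), so each coefficient is a departure from forested sites;
3. correct the family of class tests with the Benjamini-Yekutieli false
   discovery rate (valid under arbitrary dependence);
4. report an R-squared proxy from the identical fixed-effects model
   refit without the random intercept;
5. check robustness across alternative land-use classifications and
   across watersheds, and optionally rerun with an outlier region (e.g.
   an island hotspot) excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

#: Land-use classification variants, classes listed along the
#: artificialization gradient (natural -> urban).
VARIANTS = {
    "CLC5": ["Forest", "Meadow", "Farming", "Mix", "Urban"],
    "EUROWATER6": ["Forest", "Meadow", "Farming", "Mix", "Urban", "Intensive Urban"],
    "ONEMA7": [
        "Forest",
        "Meadow",
        "Farming",
        "Intensive Farming",
        "Mix",
        "Urban",
        "Intensive Urban",
    ],
}

REFERENCE_CLASS = "Forest"

TERM_VOCABULARY = (
    "year",
    "x",
    "y",
    "watershed",
    "landuse",
    "year:x",
    "year:y",
    "year:watershed",
)


class DesignError(ValueError):
    pass


@dataclass
class SiteContext:
    """Per-site spatial context: planar coordinates, watershed, region flag."""

    table: pd.DataFrame  # columns: site_id, x, y, watershed[, region]

    def __post_init__(self) -> None:
        needed = ["site_id", "x", "y", "watershed"]
        missing = [c for c in needed if c not in self.table.columns]
        if missing:
            raise DesignError(f"site context missing column(s): {missing}")
        if self.table["site_id"].duplicated().any():
            raise DesignError("duplicate site ids in site context")
        if not np.isfinite(self.table[["x", "y"]].to_numpy(dtype=float)).all():
            raise DesignError("non-finite coordinates in site context")
        if "region" not in self.table.columns:
            self.table = self.table.assign(region="")

    @classmethod
    def from_csv(cls, path) -> "SiteContext":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class LandUseTable:
    """site_id -> land-use class under a declared classification variant."""

    assignment: pd.Series  # index site_id, values class labels
    variant: str
    reference: str = REFERENCE_CLASS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise DesignError(
                f"unknown land-use variant {self.variant!r}; "
                f"expected one of {sorted(VARIANTS)}"
            )
        classes = set(VARIANTS[self.variant])
        bad = set(self.assignment.unique()) - classes
        if bad:
            raise DesignError(
                f"class label(s) {sorted(bad)} not in variant {self.variant}"
            )
        if self.reference not in classes:
            raise DesignError(
                f"reference class {self.reference!r} not in variant {self.variant}"
            )
        if self.assignment.index.has_duplicates:
            raise DesignError("duplicate site ids in land-use table")

    @property
    def classes(self) -> list:
        return list(VARIANTS[self.variant])

    @classmethod
    def from_csv(cls, path, variant: str) -> "LandUseTable":
        df = pd.read_csv(path)
        return cls(df.set_index("site_id")["landuse"], variant=variant)

    def to_csv(self, path) -> None:
        self.assignment.rename("landuse").rename_axis("site_id").to_csv(path)


@dataclass
class ModelDesign:
    """A merged data frame plus the fixed-effects formula to fit on it."""

    data: pd.DataFrame
    formula: str
    terms: tuple
    landuse_classes: tuple = ()
    reference: str = REFERENCE_CLASS

    @property
    def description(self) -> str:
        return "+".join(self.terms)

    def fixed_effect_matrix(self) -> pd.DataFrame:
        """Fixed-effects design matrix (including intercept)."""
        import patsy

        return patsy.dmatrix(
            self.formula.split("~", 1)[1], self.data, return_type="dataframe"
        )


def _formula_term(term: str, reference: str) -> str:
    mapping = {
        "year": "year_c",
        "x": "x",
        "y": "y",
        "watershed": "C(watershed)",
        "landuse": f'C(landuse, Treatment("{reference}"))',
        "year:x": "year_c:x",
        "year:y": "year_c:y",
        "year:watershed": "year_c:C(watershed)",
    }
    return mapping[term]


def build_design(
    series: pd.DataFrame,
    ctx: SiteContext,
    lu: LandUseTable | None = None,
    spec: tuple = ("year", "x", "y"),
) -> ModelDesign:
    """Merge index series with site context (and land use) into a design.

    ``spec`` draws terms from year, x, y, watershed, landuse and the year
    interactions with spatial terms; year is centered.  The response is
    the index value; occasions with an undefined index are dropped.
    """
    spec = tuple(spec)
    if len(set(spec)) != len(spec):
        dup = [t for t in spec if spec.count(t) > 1]
        raise DesignError(f"duplicate fixed effect(s) in spec: {sorted(set(dup))}")
    bad = [t for t in spec if t not in TERM_VOCABULARY]
    if bad:
        raise DesignError(f"unknown term(s) {bad}; vocabulary: {TERM_VOCABULARY}")
    if "landuse" in spec and lu is None:
        raise DesignError("spec includes 'landuse' but no land-use table given")

    df = series.copy()
    unknown = set(df["site_id"]) - set(ctx.table["site_id"])
    if unknown:
        raise DesignError(f"site(s) missing from context: {sorted(unknown)[:5]}")
    df = df.merge(ctx.table, on="site_id", how="left")
    if lu is not None:
        unknown = set(df["site_id"]) - set(lu.assignment.index)
        if unknown:
            raise DesignError(
                f"site(s) missing from land-use table: {sorted(unknown)[:5]}"
            )
        df["landuse"] = lu.assignment.loc[df["site_id"]].to_numpy()
    df = df[df["index"].notna()].reset_index(drop=True)
    df["year_c"] = df["year"] - df["year"].mean()

    reference = lu.reference if lu is not None else REFERENCE_CLASS
    rhs = " + ".join(_formula_term(t, reference) for t in spec) or "1"
    formula = f"index ~ {rhs}"
    landuse_classes = tuple(lu.classes) if (lu is not None and "landuse" in spec) else ()
    return ModelDesign(
        data=df,
        formula=formula,
        terms=spec,
        landuse_classes=landuse_classes,
        reference=reference,
    )


@dataclass
class MixedFit:
    """Fitted model summary shared by the mixed and OLS fallback paths."""

    design: ModelDesign
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float
    n_params: int
    reml: bool
    used_ols: bool
    group_var: float
    nobs: int
    row_key: tuple = field(repr=False, default=())


def _check_rank(design: ModelDesign) -> None:
    X = design.fixed_effect_matrix()
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, _, piv = scipy.linalg.qr(arr, pivoting=True, mode="economic")
        aliased = [X.columns[j] for j in piv[rank:]]
        raise DesignError(f"rank-deficient design; aliased column(s): {aliased}")


def fit_mixed(design: ModelDesign, reml: bool = False) -> MixedFit:
    """Fit the design with a site random intercept.

    ML (``reml=False``) for AIC comparison, REML for final coefficients.
    When the random-intercept variance collapses to the boundary (or the
    fit fails), falls back to ordinary least squares with a warning.
    """
    data = design.data
    sites = data["site_id"]
    n_sites = sites.nunique()
    if n_sites < 2:
        raise DesignError("need at least 2 sites to fit a site random intercept")
    occ_per_site = data.groupby("site_id").size()
    if (occ_per_site >= 2).sum() < 2:
        raise DesignError("need at least 2 sites with at least 2 occasions")
    _check_rank(design)

    used_ols = False
    group_var = np.nan
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(design.formula, data, groups=sites)
            result = model.fit(reml=reml)
        group_var = float(result.cov_re.iloc[0, 0])
        scale = float(result.scale)
        if not result.converged:
            logger.info("mixed-model optimizer reported non-convergence")
        if group_var < 1e-8 * max(scale, 1e-300):
            used_ols = True
    except (np.linalg.LinAlgError, ValueError):
        used_ols = True

    if used_ols:
        logger.warning(
            "random-intercept variance at the boundary; falling back to OLS"
        )
        ols = smf.ols(design.formula, data).fit()
        k = len(ols.params) + 1  # + residual variance
        return MixedFit(
            design=design,
            params=ols.params,
            tvalues=ols.tvalues,
            pvalues=ols.pvalues,
            llf=float(ols.llf),
            aic=float(2 * k - 2 * ols.llf),
            n_params=k,
            reml=reml,
            used_ols=True,
            group_var=0.0,
            nobs=int(ols.nobs),
            row_key=_row_key(data),
        )

    fe = result.fe_params.index
    k = len(fe) + 2  # fixed effects + group variance + residual variance
    return MixedFit(
        design=design,
        params=result.fe_params,
        tvalues=result.tvalues.loc[fe],
        pvalues=result.pvalues.loc[fe],
        llf=float(result.llf),
        aic=float(2 * k - 2 * result.llf),
        n_params=k,
        reml=reml,
        used_ols=False,
        group_var=group_var,
        nobs=int(result.nobs),
        row_key=_row_key(data),
    )


def _row_key(data: pd.DataFrame) -> tuple:
    return tuple(map(tuple, data[["site_id", "year"]].itertuples(index=False)))


def aic_select(fits: list) -> MixedFit:
    """Minimum-AIC candidate; ties broken toward fewer parameters."""
    if not fits:
        raise DesignError("no candidate models")
    if any(f.reml for f in fits):
        raise DesignError("AIC comparison requires ML (reml=False) fits")
    keys = {f.row_key for f in fits}
    if len(keys) > 1:
        raise DesignError("candidates were fitted on differing row sets")
    return min(fits, key=lambda f: (f.aic, f.n_params))


def by_fdr(pvals) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (arbitrary dependence).

    adjusted_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j) with
    c(m) = sum_{j=1..m} 1/j, returned in the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    cm = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * cm / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


#: AIC candidate vocabulary: year always; spatial structure one of
#: coordinates, watershed, or both; optionally year interactions with the
#: chosen spatial terms.
DEFAULT_CANDIDATES: tuple = tuple(
    ("year",) + spatial + (tuple(f"year:{s}" for s in spatial) if inter else ())
    for spatial in (("x", "y"), ("watershed",), ("x", "y", "watershed"))
    for inter in (False, True)
)


@dataclass
class SensitivityResult:
    """Land-use class effects relative to the natural reference class."""

    table: pd.DataFrame  # index: class; coef, t, p_raw, p_by (ref row = 0/NaN)
    model_terms: tuple
    r2_proxy: float
    variant: str
    reference: str
    n_obs: int
    n_sites: int
    used_ols: bool

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        tab = self.table.drop(index=self.reference)
        return tab[tab["p_by"] < alpha]


def landuse_sensitivity(
    series: pd.DataFrame,
    ctx: SiteContext,
    lu: LandUseTable,
    exclude_region: str | None = None,
    candidate_specs: tuple | None = None,
    reml_final: bool = True,
) -> SensitivityResult:
    """AIC-select the spatio-temporal base model, add land-use, test classes.

    Class coefficients are relative to the reference class; their raw
    Wald p-values are BY-adjusted as a family.  ``exclude_region`` drops
    sites whose context ``region`` matches before any fitting.
    """
    if exclude_region is not None:
        keep = ctx.table.loc[ctx.table["region"] != exclude_region, "site_id"]
        series = series[series["site_id"].isin(set(keep))].reset_index(drop=True)
        ctx = SiteContext(ctx.table[ctx.table["region"] != exclude_region].copy())
        if series.empty:
            raise DesignError(f"excluding region {exclude_region!r} removed all data")

    if candidate_specs is None:
        candidate_specs = DEFAULT_CANDIDATES
    candidates = []
    for spec in candidate_specs:
        design = build_design(series, ctx, lu=None, spec=tuple(spec))
        candidates.append(fit_mixed(design, reml=False))
    base = aic_select(candidates)

    full_spec = base.design.terms + ("landuse",)
    full_design = build_design(series, ctx, lu=lu, spec=full_spec)
    fit = fit_mixed(full_design, reml=reml_final)

    prefix = f'C(landuse, Treatment("{lu.reference}"))'
    rows = []
    present = set(full_design.data["landuse"].unique())
    for cls in lu.classes:
        if cls == lu.reference:
            rows.append((cls, 0.0, np.nan, np.nan))
            continue
        name = f"{prefix}[T.{cls}]"
        if name in fit.params.index:
            rows.append(
                (cls, fit.params[name], fit.tvalues[name], fit.pvalues[name])
            )
        elif cls not in present:
            logger.warning("class %s absent from the data; no coefficient", cls)
            rows.append((cls, np.nan, np.nan, np.nan))
        else:
            raise DesignError(f"coefficient for class {cls!r} not found")
    tab = pd.DataFrame(
        rows, columns=["class", "coef", "t", "p_raw"]
    ).set_index("class")
    tested = tab["p_raw"].notna()
    tab["p_by"] = np.nan
    if tested.any():
        tab.loc[tested, "p_by"] = by_fdr(tab.loc[tested, "p_raw"].to_numpy())

    ols = smf.ols(full_design.formula, full_design.data).fit()
    return SensitivityResult(
        table=tab,
        model_terms=full_spec,
        r2_proxy=float(ols.rsquared_adj),
        variant=lu.variant,
        reference=lu.reference,
        n_obs=fit.nobs,
        n_sites=int(full_design.data["site_id"].nunique()),
        used_ols=fit.used_ols,
    )


@dataclass
class RobustnessReport:
    """Sign agreement of significant land-use effects across classifications."""

    results: dict  # variant -> SensitivityResult
    signs: pd.DataFrame  # class x variant: +1/-1 significant sign, 0 = NS
    robust: bool | None  # None when undeterminable (single variant / no signal)
    alpha: float


def classification_robustness(
    series: pd.DataFrame,
    ctx: SiteContext,
    variants: list,
    alpha: float = 0.05,
    **kwargs,
) -> RobustnessReport:
    """Run the sensitivity pipeline per classification variant.

    Flags the index "robust" iff every significant (BY-adjusted) class
    effect, across all variants, carries the same sign; with a single
    variant or no significant effect robustness is undetermined (None).
    """
    sites = None
    for lu in variants:
        cur = set(lu.assignment.index)
        if sites is None:
            sites = cur
        elif cur != sites:
            raise DesignError("land-use variants do not cover the same sites")
    results = {}
    sign_cols = {}
    for lu in variants:
        res = landuse_sensitivity(series, ctx, lu, **kwargs)
        results[lu.variant] = res
        signs = pd.Series(0, index=res.table.index, dtype=int)
        sig = res.significant(alpha)
        signs.loc[sig.index] = np.sign(sig["coef"]).astype(int)
        sign_cols[lu.variant] = signs
    signs = pd.DataFrame(sign_cols).fillna(0).astype(int)
    observed = set(signs.to_numpy().ravel()) - {0}
    if len(variants) < 2 or not observed:
        robust: bool | None = None
    else:
        robust = len(observed) == 1
    return RobustnessReport(results=results, signs=signs, robust=robust, alpha=alpha)


@dataclass
class WatershedReport:
    """Per-watershed land-use effects and their sign consistency."""

    results: dict  # watershed -> SensitivityResult
    signs: pd.DataFrame  # class x watershed significant signs
    agreement: pd.Series  # per class: fraction of significant watersheds agreeing
    skipped: list


def watershed_consistency(
    series: pd.DataFrame,
    ctx: SiteContext,
    lu: LandUseTable,
    min_sites: int = 20,
    alpha: float = 0.05,
    candidate_specs: tuple | None = None,
) -> WatershedReport:
    """Refit the land-use model within each watershed and compare signs.

    Watersheds with fewer than ``min_sites`` sites carrying data are
    skipped with a warning.  Fixed effects are reduced to year and
    coordinates (the watershed term is meaningless within one watershed).
    """
    if candidate_specs is None:
        candidate_specs = (("year", "x", "y"), ("year", "x", "y", "year:x", "year:y"))
    watersheds = sorted(ctx.table["watershed"].unique())
    if len(watersheds) < 2:
        raise DesignError("need at least 2 watersheds")
    results, sign_cols, skipped = {}, {}, []
    for w in watersheds:
        w_sites = set(ctx.table.loc[ctx.table["watershed"] == w, "site_id"])
        sub = series[series["site_id"].isin(w_sites)]
        if sub["site_id"].nunique() < min_sites:
            logger.warning(
                "watershed %s has %d sites (< %d); skipped",
                w,
                sub["site_id"].nunique(),
                min_sites,
            )
            skipped.append(w)
            continue
        sub_ctx = SiteContext(ctx.table[ctx.table["watershed"] == w].copy())
        res = landuse_sensitivity(
            sub.reset_index(drop=True),
            sub_ctx,
            lu,
            candidate_specs=candidate_specs,
        )
        results[w] = res
        signs = pd.Series(0, index=res.table.index, dtype=int)
        sig = res.significant(alpha)
        signs.loc[sig.index] = np.sign(sig["coef"]).astype(int)
        sign_cols[w] = signs
    if not results:
        raise DesignError("no watershed reached the minimum site count")
    signs = pd.DataFrame(sign_cols)
    agreement = {}
    for cls, row in signs.iterrows():
        sig = row[row != 0]
        if len(sig) == 0:
            agreement[cls] = np.nan
        else:
            counts = sig.value_counts()
            agreement[cls] = counts.max() / len(sig)
    return WatershedReport(
        results=results,
        signs=signs,
        agreement=pd.Series(agreement),
        skipped=skipped,
    )


def write_sensitivity_csv(res: SensitivityResult, path) -> None:
    """Class x {coef, t, p} table mirroring a monitoring-report layout."""
    out = res.table.copy()
    out.insert(0, "variant", res.variant)
    with open(path, "w") as fh:
        fh.write(f"# model={'+'.join(res.model_terms)}\n")
        fh.write(f"# r2_proxy={res.r2_proxy:.6g}\n")
        fh.write(f"# n_obs={res.n_obs}\n# n_sites={res.n_sites}\n")
        out.to_csv(fh)
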