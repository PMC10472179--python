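"""Sex-stratified Cox proportional-hazards analysis stage.

Implements the three nested covariate adjustment levels, quintile and
continuous exposure fits, quintile trend tests, restricted-cubic-spline
dose-response with overall/nonlinearity tests, binary-subgroup analyses with
multiplicative interaction tests, disease-exclusion sensitivity analyses,
per-component analyses, and proportional-hazards diagnostics.

The analysis-ready cohort table is one row per retained subject with at
least: ``person_time``, ``event``, ``dii``, ``dii_quintile``, and the
covariate columns named in :data:`COVARIATE_LEVELS`.

Partial likelihoods are maximised with lifelines (Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy.stats import chi2

from .cohort import assign_quintiles
from .errors import FitError, SchemaError, UsageError
from .spline import default_knots, rcs_basis
from .vocabulary import COMPONENT_ANALYSIS_NUTRIENTS

# conventional two-sided 95% multiplier; CI bounds are exp(beta +/- 1.96 se)
Z95 = 1.96

#: Nested adjustment sets. Level 1: demographics; level 2: + lifestyle and
#: physical measures; level 3: + disease information and osteoporosis risk.
COVARIATE_LEVELS: dict[int, tuple[str, ...]] = {
    1: ("age", "sex", "residence", "education", "income", "marital"),
    2: ("age", "sex", "residence", "education", "income", "marital",
        "smoking", "drinking", "pal", "bmi", "mamc", "whr"),
    3: ("age", "sex", "residence", "education", "income", "marital",
        "smoking", "drinking", "pal", "bmi", "mamc", "whr",
        "hypertension", "diabetes", "osta_class"),
}

N_QUINTILES = 5


@dataclass
class ModelSpec:
    """One fitted specification.

    exposure: 'quintile', 'continuous' or 'rcs'; covariate_level 1..3 selects
    the nested adjustment set; trend_coding chooses the ordered score used by
    the trend test ('median' = within-stratum quintile median DII, 'integer'
    = 1..5).
    """

    exposure: str = "quintile"
    covariate_level: int = 3
    exposure_col: str = "dii"
    quintile_col: str = "dii_quintile"
    trend_coding: str = "median"

    def covariates(self) -> tuple[str, ...]:
        if self.covariate_level not in COVARIATE_LEVELS:
            raise UsageError("covariate_level must be 1, 2 or 3")
        return COVARIATE_LEVELS[self.covariate_level]


@dataclass
class ModelResult:
    """Hazard ratios and inference for one fitted Cox specification.

    ``table`` has one row per model term (betas on the log scale, HR with
    95% CI); for quintile exposures a reference row (HR exactly 1, no CI) is
    included. ``exposure_terms`` names the non-reference exposure rows.
    """

    table: pd.DataFrame
    exposure_terms: tuple
    n: int
    n_events: int
    log_likelihood: float
    covariance: pd.DataFrame
    reference_label: str | None = None
    _fitter: object = field(default=None, repr=False)
    _design: pd.DataFrame = field(default=None, repr=False)

    def hr(self, term: str) -> float:
        return float(self.table.loc[term, "hr"])


@dataclass
class TrendResult:
    p: float
    coef: float
    se: float
    coding: str


@dataclass
class RCSCurve:
    """Restricted-cubic-spline dose-response curve, HR(reference) = 1."""

    knots: np.ndarray
    grid: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference: float
    overall_p: float
    nonlinearity_p: float
    model: ModelResult

    def hr_at(self, x) -> float | np.ndarray:
        """HR relative to the median reference at arbitrary exposure values."""
        from .spline import rcs_basis

        names = list(self.model.exposure_terms)
        beta = self.model.table.loc[names, "beta"].to_numpy()
        delta = (rcs_basis(np.atleast_1d(x), self.knots)
                 - rcs_basis(np.array([self.reference]), self.knots))
        out = np.exp(delta @ beta)
        return float(out[0]) if np.isscalar(x) else out


@dataclass
class SubgroupStratum:
    label: object
    model: ModelResult | None
    trend: TrendResult | None
    continuous: ModelResult | None
    note: str | None = None


@dataclass
class SubgroupResult:
    stratifier: str
    strata: dict
    interaction_p: float


@dataclass
class SensitivityResult:
    name: str
    quintile_model: ModelResult
    trend: TrendResult
    continuous_model: ModelResult


@dataclass
class PHDiagnostics:
    """Proportional-hazards diagnostics for a fitted model.

    ``lrt_p`` is the likelihood-ratio test of exposure x log(t) interaction
    terms; ``per_covariate`` holds scaled-Schoenfeld-residual tests.
    ``passed`` is the global verdict at ``alpha``.
    """

    lrt_stat: float
    lrt_df: int
    lrt_p: float
    per_covariate: pd.DataFrame
    alpha: float
    passed: bool


# --------------------------------------------------------------------------
# design-matrix construction
# --------------------------------------------------------------------------

def _encode(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Encode covariates: numerics as floats, categoricals as 0/1 dummies
    (first level dropped), booleans as 0/1. Constant columns are removed."""
    pieces = []
    for col in columns:
        if col not in cohort.columns:
            raise SchemaError(f"cohort table lacks covariate column {col!r}")
        s = cohort[col]
        if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float).rename(col))
        else:
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            pieces.extend(d[c] for c in d.columns)
    out = pd.DataFrame(pieces).T if pieces else pd.DataFrame(index=cohort.index)
    keep = [c for c in out.columns if out[c].nunique() > 1]
    return out[keep]


def _quintile_dummies(cohort: pd.DataFrame, quintile_col: str) -> pd.DataFrame:
    q = cohort[quintile_col].astype(int)
    cols = {}
    for level in range(2, N_QUINTILES + 1):
        cols[f"{quintile_col}_q{level}"] = (q == level).astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def _fit(design: pd.DataFrame) -> CoxPHFitter:
    if design["event"].sum() == 0:
        raise FitError("no events in the fitted stratum")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="person_time", event_col="event")
    except ConvergenceError as err:  # separation or flat likelihood
        raise FitError(f"Cox model failed to converge: {err}") from err
    return cph


def _result_from_fit(cph: CoxPHFitter, design: pd.DataFrame,
                     exposure_terms: Sequence[str],
                     reference_label: str | None = None) -> ModelResult:
    summ = cph.summary
    with np.errstate(over="ignore"):
        table = pd.DataFrame({
            "beta": summ["coef"],
            "se": summ["se(coef)"],
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef"] - Z95 * summ["se(coef)"]),
            "ci_upper": np.exp(summ["coef"] + Z95 * summ["se(coef)"]),
            "p": summ["p"],
        })
    if reference_label is not None:
        ref = pd.DataFrame(
            {"beta": 0.0, "se": np.nan, "hr": 1.0,
             "ci_lower": np.nan, "ci_upper": np.nan, "p": np.nan},
            index=[reference_label],
        )
        table = pd.concat([ref, table])
    return ModelResult(
        table=table,
        exposure_terms=tuple(exposure_terms),
        n=len(design),
        n_events=int(design["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
        covariance=cph.variance_matrix_,
        reference_label=reference_label,
        _fitter=cph,
        _design=design,
    )


def _wald_joint(result: ModelResult, terms: Sequence[str]) -> tuple[float, int, float]:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    terms = [t for t in terms]
    b = result.table.loc[terms, "beta"].to_numpy()
    V = result.covariance.loc[terms, terms].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    df = len(terms)
    return stat, df, float(chi2.sf(stat, df))


# --------------------------------------------------------------------------
# core fits
# --------------------------------------------------------------------------

def fit_cox(cohort: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one Cox specification on an analysis-ready cohort.

    Quintile exposure enters as indicator contrasts against the lowest
    quintile (reference HR exactly 1); continuous exposure as a single
    per-unit term.
    """
    cov = _encode(cohort, spec.covariates())
    if spec.exposure == "quintile":
        expo = _quintile_dummies(cohort, spec.quintile_col)
        reference = f"{spec.quintile_col}_q1"
    elif spec.exposure == "continuous":
        expo = cohort[[spec.exposure_col]].astype(float)
        reference = None
    else:
        raise UsageError("fit_cox handles 'quintile' and 'continuous'; use fit_rcs for splines")
    expo = expo[[c for c in expo.columns if expo[c].nunique() > 1]]
    if expo.shape[1] == 0:
        raise FitError("exposure is constant in this stratum")
    design = pd.concat(
        [cohort[["person_time", "event"]].astype(float), expo, cov], axis=1
    )
    cph = _fit(design)
    return _result_from_fit(cph, design, tuple(expo.columns), reference)


def trend_test(cohort: pd.DataFrame, spec: ModelSpec) -> TrendResult:
    """Quintile trend test: refit with a single ordered numeric exposure.

    The ordered score is the within-stratum (per sex, when both sexes are
    present) median DII of each quintile (``spec.trend_coding='median'``), or
    the integer quintile index 1..5 (``'integer'``). The p-value is the Wald
    p for that coefficient.
    """
    q = cohort[spec.quintile_col].astype(int)
    if q.nunique() < 2:
        warnings.warn("quintile exposure is constant; trend test undefined")
        return TrendResult(p=np.nan, coef=np.nan, se=np.nan, coding=spec.trend_coding)
    if spec.trend_coding == "integer":
        score = q.astype(float)
    elif spec.trend_coding == "median":
        if "sex" in cohort.columns and cohort["sex"].nunique() > 1:
            med = cohort.groupby(["sex", q])[spec.exposure_col].transform("median")
        else:
            med = cohort.groupby(q)[spec.exposure_col].transform("median")
        score = med.astype(float)
    else:
        raise UsageError("trend_coding must be 'median' or 'integer'")
    cov = _encode(cohort, spec.covariates())
    design = pd.concat(
        [cohort[["person_time", "event"]].astype(float), score.rename("trend"), cov],
        axis=1,
    )
    cph = _fit(design)
    row = cph.summary.loc["trend"]
    return TrendResult(p=float(row["p"]), coef=float(row["coef"]),
                       se=float(row["se(coef)"]), coding=spec.trend_coding)


def fit_rcs(cohort: pd.DataFrame, spec: ModelSpec, n_knots: int = 4,
            *, knots=None, grid_size: int = 150) -> RCSCurve:
    """Restricted-cubic-spline dose-response in the Cox model.

    The spline basis (natural cubic, linear beyond the boundary knots) of
    the continuous exposure enters the adjusted model; the curve is
    re-centred so HR equals 1 exactly at the cohort median exposure.
    ``overall_p`` is the joint Wald test of all spline terms and
    ``nonlinearity_p`` the Wald test of the nonlinear terms only.
    """
    x = cohort[spec.exposure_col].to_numpy(dtype=float)
    if knots is None:
        knots = default_knots(x, n_knots)
    knots = np.asarray(knots, dtype=float)
    if len(knots) < 3:
        raise UsageError("restricted cubic splines need at least 3 knots")
    if knots.min() < x.min() or knots.max() > x.max():
        raise UsageError("knots must lie inside the observed exposure range")
    basis = rcs_basis(x, knots)
    names = [f"rcs_{j}" for j in range(basis.shape[1])]
    expo = pd.DataFrame(basis, columns=names, index=cohort.index)
    cov = _encode(cohort, spec.covariates())
    design = pd.concat(
        [cohort[["person_time", "event"]].astype(float), expo, cov], axis=1
    )
    cph = _fit(design)
    result = _result_from_fit(cph, design, tuple(names))
    _, _, overall_p = _wald_joint(result, names)
    _, _, nonlin_p = _wald_joint(result, names[1:])

    reference = float(np.median(x))
    grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), grid_size)
    bg = rcs_basis(grid, knots)
    bref = rcs_basis(np.array([reference]), knots)
    delta = bg - bref  # contrast vs the median reference
    beta = result.table.loc[names, "beta"].to_numpy()
    V = result.covariance.loc[names, names].to_numpy()
    log_hr = delta @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", delta, V, delta))
    return RCSCurve(
        knots=knots, grid=grid,
        hr=np.exp(log_hr),
        ci_lower=np.exp(log_hr - Z95 * se),
        ci_upper=np.exp(log_hr + Z95 * se),
        reference=reference,
        overall_p=overall_p,
        nonlinearity_p=nonlin_p,
        model=result,
    )


# --------------------------------------------------------------------------
# subgroup, sensitivity, per-component analyses
# --------------------------------------------------------------------------

def make_stratifiers(cohort: pd.DataFrame, *, mamc_split: float | None = None) -> pd.DataFrame:
    """Standard binary stratifiers for subgroup analyses.

    mamc_split defaults to the within-sex median MAMC of the cohort passed
    in; pass a fixed value to override.
    """
    s = pd.DataFrame(index=cohort.index)
    s["age_ge_50"] = cohort["age"] >= 50
    s["bmi_ge_24"] = cohort["bmi"] >= 24
    s["smoker"] = _as_bool(cohort["smoking"])
    s["drinker"] = _as_bool(cohort["drinking"])
    s["abdominal_obesity"] = cohort["abdominal_obesity"].astype(bool)
    s["osta_le_minus1"] = cohort["osta"] <= -1
    if mamc_split is None:
        split = cohort.groupby("sex")["mamc"].transform("median")
    else:
        split = mamc_split
    s["mamc_ge_split"] = cohort["mamc"] >= split
    return s


def _as_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool or pd.api.types.is_numeric_dtype(s):
        return s.astype(bool)
    return s.isin(["former_or_current", "yes", "current", "former"])


def subgroup_analysis(cohort: pd.DataFrame, stratifier: pd.Series,
                      spec: ModelSpec | None = None,
                      *, name: str | None = None,
                      fit_strata: bool = True) -> SubgroupResult:
    """Per-stratum quintile fits plus a multiplicative interaction test.

    ``stratifier`` is a boolean/binary series aligned with the cohort. The
    interaction p-value comes from a pooled model adding quintile x
    stratifier product terms, tested jointly (Wald). ``fit_strata=False``
    skips the per-stratum fits when only the interaction test is wanted.
    """
    spec = spec or ModelSpec()
    name = name or (stratifier.name or "stratum")
    s = stratifier.reindex(cohort.index)
    if s.nunique() < 2:
        raise FitError(f"stratifier {name!r} is constant")
    s = _as_bool(s).astype(float)

    strata: dict = {}
    for label, mask in ((False, s == 0), (True, s == 1)) if fit_strata else ():
        sub = cohort[mask]
        try:
            model = fit_cox(sub, spec)
            trend = trend_test(sub, spec)
            continuous = fit_cox(sub, ModelSpec(
                exposure="continuous", covariate_level=spec.covariate_level,
                exposure_col=spec.exposure_col, quintile_col=spec.quintile_col))
            strata[label] = SubgroupStratum(label, model, trend, continuous)
        except FitError as err:
            strata[label] = SubgroupStratum(label, None, None, None, note=str(err))

    # pooled model with product terms
    expo = _quintile_dummies(cohort, spec.quintile_col)
    cov_cols = [c for c in spec.covariates() if c != name]
    cov = _encode(cohort, cov_cols)
    pieces = [cohort[["person_time", "event"]].astype(float), expo,
              s.rename(f"{name}_ind"), cov]
    products = expo.mul(s, axis=0)
    products.columns = [f"{c}_x_{name}" for c in expo.columns]
    pieces.append(products)
    design = pd.concat(pieces, axis=1)
    design = design.loc[:, ~design.columns.duplicated()]
    keep = [c for c in design.columns
            if c in ("person_time", "event") or design[c].nunique() > 1]
    design = design[keep]
    try:
        cph = _fit(design)
        prod_terms = [c for c in products.columns if c in design.columns]
        pooled = _result_from_fit(cph, design, tuple(prod_terms))
        _, _, interaction_p = _wald_joint(pooled, prod_terms)
    except FitError:
        interaction_p = np.nan
    return SubgroupResult(stratifier=name, strata=strata, interaction_p=interaction_p)


SENSITIVITY_GROUPS = (
    "non_hypertension",
    "non_diabetes",
    "non_hypertension_and_non_diabetes",
    "non_hypertension_or_non_diabetes",
)


def sensitivity_subsets(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The four disease-exclusion subsets (kept as data, order fixed)."""
    htn = cohort["hypertension"].astype(bool)
    dm = cohort["diabetes"].astype(bool)
    return {
        "non_hypertension": cohort[~htn],
        "non_diabetes": cohort[~dm],
        "non_hypertension_and_non_diabetes": cohort[~htn & ~dm],
        "non_hypertension_or_non_diabetes": cohort[~htn | ~dm],
    }


def sensitivity_analysis(cohort: pd.DataFrame,
                         spec: ModelSpec | None = None) -> dict[str, SensitivityResult]:
    """Re-run the adjusted quintile and continuous fits on each subset."""
    spec = spec or ModelSpec()
    cont_spec = ModelSpec(exposure="continuous", covariate_level=spec.covariate_level,
                          exposure_col=spec.exposure_col, quintile_col=spec.quintile_col)
    out = {}
    for gname, sub in sensitivity_subsets(cohort).items():
        out[gname] = SensitivityResult(
            name=gname,
            quintile_model=fit_cox(sub, spec),
            trend=trend_test(sub, spec),
            continuous_model=fit_cox(sub, cont_spec),
        )
    return out


def component_dii_analysis(cohort: pd.DataFrame, nutrient: str,
                           spec: ModelSpec | None = None
                           ) -> tuple[ModelResult, TrendResult]:
    """Quintile the single component's score within sex and fit the adjusted
    model plus trend test.

    The component scores come from the energy-adjusted scoring stage
    (``component_<name>`` columns on the cohort table).
    """
    if nutrient not in COMPONENT_ANALYSIS_NUTRIENTS:
        raise UsageError(
            f"unknown component {nutrient!r}; supported: "
            f"{', '.join(COMPONENT_ANALYSIS_NUTRIENTS)}"
        )
    col = f"component_{nutrient}"
    if col not in cohort.columns:
        raise SchemaError(f"cohort table lacks the component column {col!r}")
    spec = spec or ModelSpec()
    work = cohort.copy()
    qcol = f"{col}_quintile"
    work[qcol] = assign_quintiles(work[col], work["sex"])
    comp_spec = ModelSpec(exposure="quintile", covariate_level=spec.covariate_level,
                          exposure_col=col, quintile_col=qcol,
                          trend_coding=spec.trend_coding)
    model = fit_cox(work, comp_spec)
    trend = trend_test(work, comp_spec)
    return model, trend


# --------------------------------------------------------------------------
# proportional-hazards diagnostics
# --------------------------------------------------------------------------

def _episodic_split(design: pd.DataFrame) -> pd.DataFrame:
    """Risk-set split of a (person_time, event) design at distinct event times,
    producing (start, stop, event) long format."""
    t = design["person_time"].to_numpy(dtype=float)
    e = design["event"].to_numpy(dtype=bool)
    cuts = np.unique(t[e])
    covs = design.drop(columns=["person_time", "event"])
    rows, starts, stops, events = [], [], [], []
    for i in range(len(design)):
        edges = cuts[cuts < t[i]]
        bounds = np.concatenate([[0.0], edges, [t[i]]])
        bounds = np.unique(bounds)
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(i)
            starts.append(a)
            stops.append(b)
            events.append(bool(e[i]) and b == t[i])
    long = covs.iloc[rows].reset_index(drop=True)
    long["start"] = starts
    long["stop"] = stops
    long["event"] = np.asarray(events, dtype=int)
    long["id"] = rows
    return long


def check_proportional_hazards(result: ModelResult, *, alpha: float = 0.05,
                               time_transform: str = "rank") -> PHDiagnostics:
    """Test the proportional-hazards assumption for a fitted model.

    (a) Likelihood-ratio test of exposure x log(t) interaction terms, fitted
    on risk-set-split data with a time-varying Cox model; (b) per-covariate
    scaled-Schoenfeld-residual tests. The LRT gives the global verdict at
    ``alpha``; the per-covariate tests are reported for inspection.
    """
    if result._fitter is None or result._design is None:
        raise UsageError("model was not fitted by this package's fit functions")
    design = result._design
    long = _episodic_split(design)
    terms = [t for t in result.exposure_terms]
    covs = [c for c in design.columns if c not in ("person_time", "event")]
    with np.errstate(divide="ignore"):
        logt = np.log(np.maximum(long["stop"].to_numpy(), 1e-12))
    for t_ in terms:
        long[f"{t_}_x_logt"] = long[t_] * logt
    inter_cols = [f"{t_}_x_logt" for t_ in terms]

    def _fit_tv(columns):
        ctv = CoxTimeVaryingFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctv.fit(long[["id", "start", "stop", "event"] + columns],
                    id_col="id", start_col="start", stop_col="stop", event_col="event")
        return ctv

    try:
        reduced = _fit_tv(covs)
        full = _fit_tv(covs + inter_cols)
        lrt_stat = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
        lrt_stat = max(lrt_stat, 0.0)
        lrt_df = len(inter_cols)
        lrt_p = float(chi2.sf(lrt_stat, lrt_df))
    except ConvergenceError:
        lrt_stat, lrt_df, lrt_p = np.nan, len(inter_cols), np.nan

    ph = proportional_hazard_test(result._fitter, design, time_transform=time_transform)
    per_cov = ph.summary.copy()
    per_cov.index = [ix[0] if isinstance(ix, tuple) else ix for ix in per_cov.index]
    # the LRT is the global verdict; per-covariate residual tests are
    # corroborative (testing each at raw alpha would reject under PH with
    # probability far above alpha once there are many covariates)
    passed = bool(np.isnan(lrt_p) or lrt_p > alpha)
    return PHDiagnostics(lrt_stat=lrt_stat, lrt_df=lrt_df, lrt_p=lrt_p,
                         per_covariate=per_cov, alpha=alpha, passed=passed)


# --------------------------------------------------------------------------
# convenience: the three nested models
# --------------------------------------------------------------------------

def run_model_levels(cohort: pd.DataFrame, *, exposure: str = "quintile",
                     levels: Sequence[int] = (1, 2, 3)) -> dict:
    """Fit the nested adjustment levels for one exposure; returns
    {level: (ModelResult, TrendResult | None)}."""
    out = {}
    for level in levels:
        spec = ModelSpec(exposure=exposure, covariate_level=level)
        model = fit_cox(cohort, spec)
        trend = trend_test(cohort, spec) if exposure == "quintile" else None
        out[level] = (model, trend)
    return out
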