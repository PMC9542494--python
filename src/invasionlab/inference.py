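"""OLS model battery for the invasion experiment.

Fits Gaussian linear models of invasion success, resident diversity and
resident density on disturbance frequency (continuous, optionally quadratic),
resource abundance (categorical) and invader type, with interactions.
Provides type II/III ANOVA, backward model selection by likelihood-ratio
tests, per-resource marginal slopes with t-based 95% confidence intervals,
and Bonferroni-adjusted pairwise comparisons of marginal (estimated) means.

Disturbance frequency enters the models as a numeric regressor; the default
coding is the number of disturbance events in the 16-day experiment
(interval d days -> 16/d events), selectable via ``disturbance_coding``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from invasionlab.community import community_table
from invasionlab.data_io import CountTable
from invasionlab.fitness import (
    InvasionSchedule,
    MortalityModel,
    compute_fitness_table,
    fitness_dataframe,
)

logger = logging.getLogger(__name__)

#: Numeric codings of the disturbance treatment.
DISTURBANCE_CODINGS = {
    "events_per_16d": lambda interval: 16.0 / interval,
    "interval_days": lambda interval: float(interval),
    "log2_events": lambda interval: math.log2(16.0 / interval),
}

#: Reference levels for treatment-coded categorical factors.
_REFERENCE = {"resource": "low", "invader_type": "SM"}

_CATEGORICAL = ("resource", "invader_type")


def code_disturbance(interval, coding: str = "events_per_16d"):
    """Map disturbance intervals (days) to the numeric model regressor."""
    try:
        fn = DISTURBANCE_CODINGS[coding]
    except KeyError:
        raise ValueError(
            f"unknown disturbance coding {coding!r}; "
            f"choose from {sorted(DISTURBANCE_CODINGS)}"
        ) from None
    return np.asarray([fn(i) for i in np.atleast_1d(interval)]) if np.ndim(interval) else fn(interval)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one linear model.

    ``disturbance_degree`` 0 omits disturbance, 1 fits a linear term, 2 adds
    a quadratic.  ``factors`` are categorical predictors, ``covariates``
    continuous ones.  ``interactions`` is either an explicit tuple of
    variable-name tuples (e.g. ``(("dist", "resource"),)``) or ``"all"`` for
    the full factorial among the base variables (linear disturbance, factors
    and covariates).  ``data_filter`` restricts rows by equality, e.g.
    ``{"invader_type": "SM"}``.
    """

    response: str
    disturbance_degree: int = 1
    disturbance_coding: str = "events_per_16d"
    factors: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()
    interactions: tuple[tuple[str, ...], ...] | str = ()
    data_filter: Mapping[str, object] | None = None

    def __post_init__(self):
        if self.disturbance_degree not in (0, 1, 2):
            raise ValueError("disturbance_degree must be 0, 1 or 2")
        if self.disturbance_coding not in DISTURBANCE_CODINGS:
            raise ValueError(f"unknown disturbance coding {self.disturbance_coding!r}")

    @property
    def base_variables(self) -> tuple[str, ...]:
        base = ()
        if self.disturbance_degree >= 1:
            base += ("dist",)
        return base + tuple(self.factors) + tuple(self.covariates)

    def terms(self) -> list[tuple[str, ...]]:
        """The model's terms, each a tuple of variable names."""
        main: list[tuple[str, ...]] = [(v,) for v in self.base_variables]
        if self.disturbance_degree == 2:
            main.insert(1, ("dist2",))
        if self.interactions == "all":
            inter = [
                tuple(c)
                for k in range(2, len(self.base_variables) + 1)
                for c in combinations(self.base_variables, k)
            ]
        else:
            inter = [tuple(t) for t in self.interactions]
        return main + inter


def term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


def _multiset(term: tuple[str, ...]) -> tuple[str, ...]:
    """Expand for marginality checks: the quadratic counts as dist twice."""
    out: list[str] = []
    for v in term:
        out.extend(("dist", "dist") if v == "dist2" else (v,))
    return tuple(sorted(out))


def _contains(big: tuple[str, ...], small: tuple[str, ...]) -> bool:
    """Multiset inclusion of model terms (marginality relation)."""
    b, s = list(_multiset(big)), _multiset(small)
    if b == list(s):
        return False
    try:
        for v in s:
            b.remove(v)
    except ValueError:
        return False
    return True


def _var_expr(var: str, contrast: str) -> str:
    if var == "dist":
        return "dist"
    if var == "dist2":
        return "I(dist ** 2)"
    if var in _CATEGORICAL:
        if contrast == "sum":
            return f"C({var}, Sum)"
        return f"C({var}, Treatment(reference='{_REFERENCE[var]}'))"
    return var


def _build_formula(
    response: str, terms: Sequence[tuple[str, ...]], contrast: str
) -> tuple[str, dict[str, str]]:
    """Formula string plus a map from patsy term names to friendly labels."""
    parts, name_map = [], {}
    for term in terms:
        expr = ":".join(_var_expr(v, contrast) for v in term)
        parts.append(expr)
        name_map[expr] = term_label(term)
    rhs = " + ".join(parts) if parts else "1"
    return f"{response} ~ {rhs}", name_map


# ---------------------------------------------------------------------------
# fitting


@dataclass
class ModelFit:
    """A fitted OLS model plus everything needed for downstream summaries."""

    spec: ModelSpec
    terms: list[tuple[str, ...]]
    formula: str
    name_map: dict[str, str]
    data: pd.DataFrame
    result: object  # statsmodels RegressionResults
    n_dropped: int = 0

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def cov_params(self) -> pd.DataFrame:
        return self.result.cov_params()

    @property
    def df_resid(self) -> float:
        return self.result.df_resid

    @property
    def llf(self) -> float:
        return self.result.llf

    @property
    def rss(self) -> float:
        return float(self.result.ssr)

    @property
    def nobs(self) -> int:
        return int(self.result.nobs)

    @property
    def fitted(self) -> np.ndarray:
        return np.asarray(self.result.fittedvalues)

    @property
    def residuals(self) -> np.ndarray:
        return np.asarray(self.result.resid)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.result.params, "se": self.result.bse,
             "t": self.result.tvalues, "p": self.result.pvalues}
        )


def _check_full_rank(result, formula: str) -> None:
    exog = result.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(exog.shape) * np.finfo(float).eps
        names = result.model.exog_names
        aliased = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [names[p] for p in piv[len(diag):]]
        raise ValueError(
            f"rank-deficient design for {formula!r}; aliased columns: {aliased}"
        )


def _prepare_data(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    df = data.copy()
    if spec.data_filter:
        for col, val in spec.data_filter.items():
            df = df[df[col] == val]
    needs_dist = spec.disturbance_degree >= 1
    if needs_dist:
        if "dist" not in df.columns:
            if "disturbance_interval" not in df.columns:
                raise ValueError("data lack a disturbance_interval column")
            df["dist"] = [
                DISTURBANCE_CODINGS[spec.disturbance_coding](i)
                for i in df["disturbance_interval"]
            ]
    used = [spec.response, *spec.factors, *spec.covariates]
    if needs_dist:
        used.append("dist")
    n0 = len(df)
    df = df.dropna(subset=[c for c in used if c in df.columns])
    return df.reset_index(drop=True), n0 - len(df)


def _fit_terms(
    spec: ModelSpec,
    data: pd.DataFrame,
    terms: Sequence[tuple[str, ...]],
    contrast: str = "treatment",
    n_dropped: int = 0,
) -> ModelFit:
    formula, name_map = _build_formula(spec.response, terms, contrast)
    if spec.disturbance_degree >= 1 and data["dist"].nunique() < 2:
        raise ValueError("need at least 2 distinct disturbance values")
    result = smf.ols(formula, data=data).fit()
    _check_full_rank(result, formula)
    return ModelFit(spec, list(terms), formula, name_map, data, result, n_dropped)


def fit_linear_model(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit the OLS model described by ``spec`` on an analysis table.

    The design matrix uses treatment contrasts with documented reference
    levels (resource: low, invader type: SM); rows with missing response or
    predictors are dropped listwise with the count recorded on the fit.
    """
    df, n_dropped = _prepare_data(spec, data)
    if n_dropped:
        logger.warning("fit_linear_model: dropped %d incomplete row(s)", n_dropped)
    return _fit_terms(spec, df, spec.terms(), n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# ANOVA


def anova_table(fit: ModelFit, ss_type: str = "II") -> pd.DataFrame:
    """Term-wise F tests with type II or type III sums of squares.

    Type III is computed on an internal refit with sum-to-zero contrasts (the
    convention under which type III main-effect tests are meaningful);
    reported term labels are unchanged.
    """
    if ss_type not in ("II", "III"):
        raise ValueError(f"ss_type must be 'II' or 'III', got {ss_type!r}")
    if ss_type == "II":
        res, name_map = fit.result, fit.name_map
        table = sm.stats.anova_lm(res, typ=2)
    else:
        refit = _fit_terms(fit.spec, fit.data, fit.terms, contrast="sum")
        name_map = refit.name_map
        table = sm.stats.anova_lm(refit.result, typ=3)
        table = table.drop(index="Intercept", errors="ignore")
    table = table.rename(index={**name_map, "Residual": "Residual"})
    table = table.rename(columns={"PR(>F)": "p"})
    table.index.name = "term"
    return table


def anova_records(table: pd.DataFrame) -> list[dict]:
    out = []
    for term, row in table.iterrows():
        rec = {"term": term, "sum_sq": float(row["sum_sq"]), "df": float(row["df"])}
        if not np.isnan(row.get("F", np.nan)):
            rec["F"] = float(row["F"])
            rec["p"] = float(row["p"])
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# likelihood-ratio model selection


@dataclass
class LRTResult:
    term: str
    statistic: float
    df: float
    p: float
    action: str  # "dropped" | "kept"


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> tuple[float, float, float]:
    """Gaussian-OLS LRT of nested fits: statistic n*ln(RSS0/RSS1), chi2 p.

    ``full`` and ``reduced`` must be fit on the same rows with the reduced
    terms a subset of the full terms.
    """
    full_ms = {_multiset(t) for t in full.terms}
    red_ms = {_multiset(t) for t in reduced.terms}
    if not red_ms <= full_ms:
        raise ValueError("models are not nested: reduced terms not a subset of full")
    if full.nobs != reduced.nobs:
        raise ValueError("models fit on different numbers of observations")
    n = full.nobs
    stat = n * math.log(reduced.rss / full.rss) if reduced.rss > full.rss else 0.0
    df = reduced.df_resid - full.df_resid
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def likelihood_ratio_select(
    full: ModelSpec | ModelFit, data: pd.DataFrame | None = None, alpha: float = 0.05
) -> tuple[ModelFit, list[LRTResult]]:
    """Backward elimination by LRT, respecting marginality.

    At each step, every droppable term (one not contained in any remaining
    higher-order term) is tested by a likelihood-ratio test of the reduced
    against the current model; the least significant droppable term with
    p > alpha is removed.  Every test is recorded in the returned trace.
    """
    if isinstance(full, ModelSpec):
        if data is None:
            raise ValueError("data required when passing a ModelSpec")
        fit = fit_linear_model(full, data)
    else:
        fit = full
    trace: list[LRTResult] = []
    while True:
        terms = fit.terms
        droppable = [
            t for t in terms if not any(_contains(u, t) for u in terms if u != t)
        ]
        if not droppable:
            break
        tested = []
        for t in droppable:
            reduced = _fit_terms(fit.spec, fit.data, [u for u in terms if u != t])
            stat, df, p = likelihood_ratio_test(fit, reduced)
            tested.append((p, t, reduced, stat, df))
        tested.sort(key=lambda x: -x[0])
        p, t, reduced, stat, df = tested[0]
        if p > alpha:
            trace.append(LRTResult(term_label(t), stat, df, p, "dropped"))
            fit = reduced
        else:
            for p_i, t_i, _, stat_i, df_i in tested:
                trace.append(LRTResult(term_label(t_i), stat_i, df_i, p_i, "kept"))
            break
    return fit, trace


# ---------------------------------------------------------------------------
# marginal slopes and means


@dataclass
class SlopeEstimate:
    resource_level: str
    slope: float
    se: float
    ci95: tuple[float, float]
    significant: bool


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    estimate: float
    se: float
    p_raw: float
    p_adjusted: float
    method: str = "bonferroni"


def _design_rows(fit: ModelFit, data: pd.DataFrame) -> np.ndarray:
    design_info = fit.result.model.data.design_info
    (mat,) = patsy.build_design_matrices([design_info], data)
    return np.asarray(mat)


def _linear_combination(fit: ModelFit, L: np.ndarray) -> tuple[float, float]:
    beta = np.asarray(fit.params)
    cov = np.asarray(fit.cov_params)
    est = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    return est, se


def resource_specific_slopes(
    fit: ModelFit, factor: str = "resource", delta: float = 1.0
) -> list[SlopeEstimate]:
    """Marginal slope of the response in the disturbance regressor per level.

    For each level of ``factor``, the model's prediction surface is averaged
    over the observed values of all other predictors and differentiated in
    the coded disturbance regressor (finite difference of ``delta``, exact
    for degree-1 models).  Confidence intervals are t-based Wald intervals on
    the implied coefficient combination; a slope is significant when its 95%
    CI excludes zero.  With no disturbance-by-factor interaction, all levels
    return the common slope.
    """
    if fit.spec.disturbance_degree == 2:
        raise ValueError(
            "per-resource slopes are only reported for degree-1 models; "
            "summarize quadratic fits by their curvature instead"
        )
    if not any("dist" in t for t in fit.terms):
        raise ValueError("model contains no disturbance term")
    if factor not in fit.data.columns:
        raise ValueError(f"factor {factor!r} not in model data")
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    out = []
    for level in sorted(fit.data[factor].unique()):
        lo_df = fit.data.copy()
        lo_df[factor] = level
        hi_df = lo_df.copy()
        hi_df["dist"] = hi_df["dist"] + delta
        L = (_design_rows(fit, hi_df) - _design_rows(fit, lo_df)).mean(axis=0) / delta
        slope, se = _linear_combination(fit, L)
        ci = (slope - tcrit * se, slope + tcrit * se)
        out.append(SlopeEstimate(level, slope, se, ci, not ci[0] <= 0 <= ci[1]))
    return out


def marginal_pairwise(
    fit: ModelFit, factor: str, adjustment: str = "bonferroni"
) -> list[PairwiseComparison]:
    """Pairwise comparisons of marginal (estimated) means of a factor.

    Marginal means are model predictions averaged over the observed values of
    every other predictor; differences are tested with t statistics and
    Bonferroni-adjusted p values (p_adj = min(1, m * p)).
    """
    if adjustment != "bonferroni":
        raise ValueError(f"unsupported adjustment {adjustment!r}")
    if not any(factor in t for t in fit.terms):
        raise ValueError(f"factor {factor!r} is not in the model")
    levels = sorted(fit.data[factor].unique())
    L_by_level = {}
    for level in levels:
        df = fit.data.copy()
        df[factor] = level
        L_by_level[level] = _design_rows(fit, df).mean(axis=0)
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        L = L_by_level[a] - L_by_level[b]
        est, se = _linear_combination(fit, L)
        if se == 0:
            p_raw = 1.0 if est == 0 else 0.0
        else:
            p_raw = 2 * float(stats.t.sf(abs(est / se), fit.df_resid))
        out.append(
            PairwiseComparison(a, b, est, se, p_raw, min(1.0, m * p_raw))
        )
    return out


# ---------------------------------------------------------------------------
# the full analysis sequence


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05
    disturbance_coding: str = "events_per_16d"
    offset_mode: str = "density"
    final_day: int = 16
    mortality: MortalityModel = MortalityModel()
    schedules: dict[str, InvasionSchedule] | None = None


@dataclass
class AnalysisReport:
    """Structured, JSON-serializable record of the whole model battery."""

    sections: dict

    def to_dict(self) -> dict:
        return self.sections

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.sections, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(json.loads(text))


def assemble_analysis_table(
    counts: CountTable,
    day4_reference: CountTable,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """Per-microcosm analysis table: success score, diversity, density, treatments."""
    fitness = fitness_dataframe(
        compute_fitness_table(
            counts,
            schedule=config.schedules,
            day4_reference=day4_reference,
            mortality=config.mortality,
            offset_mode=config.offset_mode,
            final_day=config.final_day,
        )
    )
    fitness = fitness.rename(columns={"log_v_plus_1": "success_score"})
    comm = community_table(counts, final_day=config.final_day)
    comm = comm[comm["invader_type"].notna()]
    merged = fitness.merge(
        comm[["microcosm_id", "simpson_D", "n_morphs", "total_cfu_per_ml",
              "log10_density"]],
        on="microcosm_id",
        how="left",
    )
    merged["dist"] = [
        DISTURBANCE_CODINGS[config.disturbance_coding](i)
        for i in merged["disturbance_interval"]
    ]
    return merged


def _interaction_significant(table: pd.DataFrame, alpha: float) -> bool:
    for term, row in table.iterrows():
        if ":" in str(term) and not np.isnan(row.get("p", np.nan)) and row["p"] < alpha:
            return True
    return False


def _anova_with_fallback(fit: ModelFit, alpha: float) -> tuple[pd.DataFrame, str]:
    """Type III ANOVA, falling back to type II when no interaction is significant."""
    t3 = anova_table(fit, "III")
    if _interaction_significant(t3, alpha) or not any(len(t) > 1 for t in fit.terms):
        return t3, "III"
    return anova_table(fit, "II"), "II"


def _term_record(table: pd.DataFrame, term: str) -> dict | None:
    if term not in table.index:
        return None
    row = table.loc[term]
    return {
        "term": term,
        "F": float(row["F"]),
        "df_num": float(row["df"]),
        "df_den": float(table.loc["Residual", "df"]),
        "p": float(row["p"]),
    }


def _slope_records(slopes: list[SlopeEstimate]) -> list[dict]:
    return [
        {"resource": s.resource_level, "slope": s.slope, "se": s.se,
         "ci95": list(s.ci95), "significant": s.significant}
        for s in slopes
    ]


def _pairwise_records(pairs: list[PairwiseComparison]) -> list[dict]:
    return [
        {"level_a": p.level_a, "level_b": p.level_b, "estimate": p.estimate,
         "se": p.se, "p_raw": p.p_raw, "p_adjusted": p.p_adjusted,
         "method": p.method}
        for p in pairs
    ]


def run_full_analysis(
    counts: CountTable,
    day4_reference: CountTable,
    config: AnalysisConfig = AnalysisConfig(),
) -> AnalysisReport:
    """Execute the full inference sequence on a validated count table.

    Stages: (1) fitness/diversity/density table assembly; (2) three-way
    success model (linear disturbance x resource x invader type) with
    type III -> II ANOVA; (3) when the three-way interaction is significant,
    per-invader-type success models with the disturbance x resource
    interaction, per-resource slopes and resource post-hocs; (4) diversity
    (quadratic disturbance + resource) and density models per invader type
    with LRT model selection; (5) resident-effect models: success against
    diversity x density alone, then treatments plus resident effects.
    """
    alpha = config.alpha
    table = assemble_analysis_table(counts, day4_reference, config)
    n_undefined = int(table["success_score"].isna().sum())

    sections: dict = {
        "n_microcosms": int(len(table)),
        "n_excluded_undefined_v": n_undefined,
        "disturbance_coding": config.disturbance_coding,
        "alpha": alpha,
    }

    # stage 2: three-way success model
    spec3 = ModelSpec(
        response="success_score",
        disturbance_degree=1,
        disturbance_coding=config.disturbance_coding,
        factors=("resource", "invader_type"),
        interactions="all",
    )
    fit3 = fit_linear_model(spec3, table)
    t3_table, t3_type = _anova_with_fallback(fit3, alpha)
    three_way = _term_record(t3_table, "dist:resource:invader_type")
    sections["success_three_way"] = {
        "anova_type": t3_type,
        "anova": anova_records(t3_table),
        "three_way": three_way,
        "n": fit3.nobs,
    }

    # stage 3: per-invader-type success models
    per_morph: dict[str, dict] = {}
    branch = three_way is not None and three_way["p"] < alpha
    sections["three_way_significant"] = bool(branch)
    for morph in sorted(table["invader_type"].dropna().unique()):
        spec_m = ModelSpec(
            response="success_score",
            disturbance_degree=1,
            disturbance_coding=config.disturbance_coding,
            factors=("resource",),
            interactions="all",
            data_filter={"invader_type": morph},
        )
        fit_m = fit_linear_model(spec_m, table)
        tab_m, type_m = _anova_with_fallback(fit_m, alpha)
        entry = {
            "anova_type": type_m,
            "anova": anova_records(tab_m),
            "interaction": _term_record(tab_m, "dist:resource"),
            "slopes": _slope_records(resource_specific_slopes(fit_m)),
            "resource_posthoc": _pairwise_records(
                marginal_pairwise(fit_m, "resource")
            ),
            "n": fit_m.nobs,
        }
        per_morph[morph] = entry
    sections["per_morph_success"] = per_morph

    # stage 4: diversity and density models per invader type
    diversity: dict[str, dict] = {}
    density: dict[str, dict] = {}
    for morph in sorted(table["invader_type"].dropna().unique()):
        spec_div = ModelSpec(
            response="simpson_D",
            disturbance_degree=2,
            disturbance_coding=config.disturbance_coding,
            factors=("resource",),
            interactions=(("dist", "resource"), ("dist2", "resource")),
            data_filter={"invader_type": morph},
        )
        fit_div, trace_div = likelihood_ratio_select(spec_div, table, alpha)
        tab_div = anova_table(fit_div, "II")
        diversity[morph] = {
            "selected_terms": [term_label(t) for t in fit_div.terms],
            "anova": anova_records(tab_div),
            "quadratic": _term_record(tab_div, "dist2"),
            "resource": _term_record(tab_div, "resource"),
            "resource_posthoc": _pairwise_records(
                marginal_pairwise(fit_div, "resource")
            )
            if any("resource" in t for t in fit_div.terms)
            else [],
            "selection_trace": [vars(t) for t in trace_div],
            "n": fit_div.nobs,
        }
        spec_den = ModelSpec(
            response="log10_density",
            disturbance_degree=2,
            disturbance_coding=config.disturbance_coding,
            factors=("resource",),
            interactions=(("dist", "resource"), ("dist2", "resource")),
            data_filter={"invader_type": morph},
        )
        fit_den, trace_den = likelihood_ratio_select(spec_den, table, alpha)
        tab_den = anova_table(fit_den, "II")
        density[morph] = {
            "selected_terms": [term_label(t) for t in fit_den.terms],
            "anova": anova_records(tab_den),
            "interaction": _term_record(tab_den, "dist:resource"),
            "selection_trace": [vars(t) for t in trace_den],
            "n": fit_den.nobs,
        }
    sections["diversity"] = diversity
    sections["density"] = density

    # stage 5: resident effects on success
    resident: dict[str, dict] = {}
    for morph in sorted(table["invader_type"].dropna().unique()):
        spec_res = ModelSpec(
            response="success_score",
            disturbance_degree=0,
            covariates=("simpson_D", "log10_density"),
            interactions=(("simpson_D", "log10_density"),),
            data_filter={"invader_type": morph},
        )
        fit_res = fit_linear_model(spec_res, table)
        tab_res, type_res = _anova_with_fallback(fit_res, alpha)
        spec_both = ModelSpec(
            response="success_score",
            disturbance_degree=1,
            disturbance_coding=config.disturbance_coding,
            factors=("resource",),
            covariates=("simpson_D", "log10_density"),
            interactions=(("dist", "resource"),),
            data_filter={"invader_type": morph},
        )
        fit_both = fit_linear_model(spec_both, table)
        tab_both, type_both = _anova_with_fallback(fit_both, alpha)
        resident[morph] = {
            "residents_only": {
                "anova_type": type_res,
                "anova": anova_records(tab_res),
                "n": fit_res.nobs,
            },
            "with_treatments": {
                "anova_type": type_both,
                "anova": anova_records(tab_both),
                "interaction": _term_record(tab_both, "dist:resource"),
                "n": fit_both.nobs,
            },
        }
    sections["resident_effects"] = resident

    return AnalysisReport(sections)
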