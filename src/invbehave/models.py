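"""Nested mixed-model ladders with likelihood-ratio tests and gated
post-hoc pairwise t-tests.

For each trait a ladder of four nested linear mixed models is fitted by
maximum likelihood, all with a random intercept per experiment block:

    null:         trait ~ 1                                + (1 | block)
    inversion:    trait ~ genotype                         + (1 | block)
    covariate:    trait ~ genotype + covariate             + (1 | block)
    interaction:  trait ~ genotype * covariate             + (1 | block)

where genotype is a 3-level factor (treatment coding, STD reference) and
the covariate is either sex (2-level factor) or temperature (numeric, deg C).
Successive pairs are compared by likelihood-ratio chi-square tests; the
structural parameter counts are (3, 5, 6, 8) — fixed effects plus the
random-intercept variance and the residual variance — giving LRT df
(2, 1, 2).  ML (not REML) estimation is used throughout because the models
differ in their fixed effects.

If the genotype or interaction LRT is significant at ``alpha``, Welch
two-sample t-tests compare every genotype pair within each covariate
stratum; p-values are unadjusted by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PROPORTION_TRAITS, TRAIT_LABELS, TRAITS, ValidationError
from .phenotype import arcsin_sqrt

GENOTYPE_TERM = "C(genotype, Treatment(reference='STD'))"
LADDER_NAMES = ("null", "inversion", "covariate", "interaction")

#: Tolerance below which a (numerically) negative LRT statistic is clamped
#: to zero; anything more negative signals a convergence failure.
LRT_CLAMP = 1e-6


class ConvergenceError(RuntimeError):
    """A model fit or model comparison is numerically untrustworthy."""


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the ladder."""

    trait: str
    name: str  # one of LADDER_NAMES
    covariate: str  # "sex" or "temperature"
    formula: str
    npar: int  # structural: fixed effects + block variance + residual variance
    transform: bool  # arcsin-sqrt applied to the trait before fitting

    @property
    def label(self) -> str:
        cov = "Sex" if self.covariate == "sex" else "Temp"
        return {
            "null": "Null Model",
            "inversion": "Inversion Model",
            "covariate": f"{cov} Model",
            "interaction": "Interaction Model",
        }[self.name]


def build_ladder(trait: str, covariate: str) -> list[ModelSpec]:
    """The four nested model specifications for one trait.

    Sex enters as a 2-level factor, temperature as a numeric regressor in
    deg C (one parameter), so both ladders have structural npar (3, 5, 6, 8).
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if covariate == "sex":
        cov_term = "C(sex)"
    elif covariate == "temperature":
        cov_term = "temperature_c"
    else:
        raise ValidationError(f"covariate must be 'sex' or 'temperature'")
    transform = trait in PROPORTION_TRAITS
    g = GENOTYPE_TERM
    rhs = {
        "null": "1",
        "inversion": g,
        "covariate": f"{g} + {cov_term}",
        "interaction": f"{g} + {cov_term} + {g}:{cov_term}",
    }
    npar = {"null": 3, "inversion": 5, "covariate": 6, "interaction": 8}
    return [
        ModelSpec(
            trait=trait,
            name=name,
            covariate=covariate,
            formula=f"y ~ {rhs[name]}",
            npar=npar[name],
            transform=transform,
        )
        for name in LADDER_NAMES
    ]


@dataclass
class FitResult:
    """A fitted mixed model with structurally counted parameters."""

    spec: ModelSpec
    npar: int
    loglik: float
    params: pd.Series
    bse: pd.Series
    group_var: float
    resid_var: float
    converged: bool
    at_boundary: bool  # random-intercept variance estimated at 0

    @property
    def aic(self) -> float:
        return 2.0 * self.npar - 2.0 * self.loglik

    def genotype_effect(self, level: str) -> tuple[float, float]:
        """(estimate, SE) of the ``level`` vs STD fixed-effect contrast."""
        key = f"[T.{level}]"
        matches = [
            p for p in self.params.index if key in p and ":" not in p
        ]
        if not matches:
            raise KeyError(f"no genotype contrast {level!r} in this model")
        return float(self.params[matches[0]]), float(self.bse[matches[0]])


def _ols_boundary_fit(formula: str, data: pd.DataFrame):
    """OLS fit of the same fixed effects: the sigma_B = 0 boundary candidate
    of the mixed likelihood."""
    import statsmodels.formula.api as smf

    res = smf.ols(formula, data).fit()
    return res


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one ladder rung by maximum likelihood.

    The data frame must contain the working trait column ``y`` (already
    transformed when the ModelSpec requires it) plus genotype, the
    covariate column and ``experiment_block``.  The ML estimate of the random-intercept variance
    may sit on the sigma_B = 0 boundary, where the mixed log-likelihood
    equals the OLS log-likelihood of the same fixed effects; both candidates
    are evaluated and the valid maximum is kept.
    """
    import statsmodels.formula.api as smf

    if "y" not in data.columns:
        raise ValidationError("data must contain the working trait column 'y'")
    y = data["y"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("trait values must be finite")
    n_blocks = data["experiment_block"].nunique()
    if n_blocks < 2:
        raise ValidationError(
            "need >= 2 experiment blocks to estimate the block random "
            "intercept; pool blocks or drop the random effect upstream"
        )

    ols = _ols_boundary_fit(spec.formula, data)
    k_fe = len(ols.params)
    if k_fe > spec.npar - 2:
        raise ValidationError(
            f"design matrix has {k_fe} fixed effects; spec {spec.name!r} "
            f"expects at most {spec.npar - 2}"
        )
    # k_fe < npar - 2 happens when a factor has a single observed level:
    # the term carries no information, the LRT against the reduced model
    # comes out 0, and npar stays at its structural count.
    # constant response: perfect fit, residual variance on its 0 boundary
    if np.ptp(y) == 0.0:
        return FitResult(
            spec=spec, npar=spec.npar, loglik=np.inf,
            params=ols.params, bse=ols.bse * 0.0,
            group_var=0.0, resid_var=0.0, converged=True, at_boundary=True,
        )
    ols_llf = float(ols.llf)

    best = None
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec.formula, data, groups=data["experiment_block"])
        # cheap optimizers first; the slower ones only when those stall at
        # or below the OLS boundary even though an interior optimum may exist
        for method in ("lbfgs", "bfgs", "cg", "powell", "nm"):
            try:
                res = model.fit(reml=False, method=method)
            except Exception:
                continue
            llf = float(res.llf)
            if not np.isfinite(llf):
                continue
            if best is None or llf > float(best.llf):
                best = res
            if res.converged:
                converged = True
                if llf >= ols_llf - 1e-10:
                    break

    if best is None or float(best.llf) < ols_llf - 1e-10:
        # boundary (or failed) fit: the OLS solution is the ML solution
        return FitResult(
            spec=spec, npar=spec.npar, loglik=ols_llf,
            params=ols.params, bse=ols.bse,
            group_var=0.0, resid_var=float(ols.scale),
            converged=True, at_boundary=True,
        )
    return FitResult(
        spec=spec,
        npar=spec.npar,
        loglik=float(best.llf),
        params=best.fe_params,
        bse=best.bse_fe,
        group_var=float(np.asarray(best.cov_re)[0, 0]),
        resid_var=float(best.scale),
        converged=converged,
        at_boundary=False,
    )


@dataclass
class ModelComparisonTable:
    """The 4-row ladder summary for one trait (npar, AIC, logLik, Chisq,
    Df, p), mirroring an anova() model-comparison printout."""

    trait: str
    covariate: str
    fits: list[FitResult]
    table: pd.DataFrame

    def row_p(self, name: str) -> float:
        return float(
            self.table.loc[self.table["model"] == name, "p"].iloc[0]
        )

    @property
    def genotype_p(self) -> float:
        return self.row_p("inversion")

    @property
    def interaction_p(self) -> float:
        return self.row_p("interaction")

    def gate_passed(self, alpha: float = 0.05) -> bool:
        """True when genotype or the genotype-bearing interaction is
        significant, licensing post-hoc pairwise tests."""
        return self.genotype_p < alpha or self.interaction_p < alpha


def compare_ladder(fits: list[FitResult]) -> ModelComparisonTable:
    """Likelihood-ratio tests between successive nested fits."""
    if len(fits) != 4:
        raise ValidationError("expected the 4 fits of a full ladder")
    if any(f.spec.trait != fits[0].spec.trait for f in fits):
        raise ValidationError("fits mix traits")
    if [f.spec.name for f in fits] != list(LADDER_NAMES):
        raise ValidationError("fits are not the ladder in nested order")
    rows = []
    for i, f in enumerate(fits):
        row = {
            "trait": TRAIT_LABELS[f.spec.trait],
            "model": f.spec.name,
            "Model": f.spec.label,
            "npar": f.npar,
            "AIC": f.aic,
            "logLik": f.loglik,
            "Chisq": np.nan,
            "Df": np.nan,
            "p": np.nan,
        }
        if i > 0:
            prev = fits[i - 1]
            df = f.npar - prev.npar
            if df < 1:
                raise ValidationError("successive fits are not strictly nested")
            chisq = 2.0 * (f.loglik - prev.loglik)
            if np.isnan(chisq) or (np.isinf(f.loglik) and np.isinf(prev.loglik)):
                chisq = 0.0
            if chisq < 0.0:
                if chisq >= -LRT_CLAMP:
                    chisq = 0.0
                else:
                    raise ConvergenceError(
                        f"negative LRT statistic {chisq:.3g} between "
                        f"{prev.spec.name} and {f.spec.name}: convergence failure"
                    )
            row["Chisq"] = chisq
            row["Df"] = df
            row["p"] = float(stats.chi2.sf(chisq, df))
        rows.append(row)
    return ModelComparisonTable(
        trait=fits[0].spec.trait,
        covariate=fits[0].spec.covariate,
        fits=fits,
        table=pd.DataFrame(rows),
    )


@dataclass(frozen=True)
class PosthocResult:
    """One pairwise genotype comparison within a stratum."""

    trait: str
    stratum: object
    pair: tuple[str, str]
    t: float
    df: float
    p: float
    mean_diff: float
    n: tuple[int, int]


def posthoc_pairwise(
    data: pd.DataFrame,
    trait: str,
    stratum_col: str,
    gate_passed: bool,
    welch: bool = True,
) -> list[PosthocResult]:
    """Pairwise genotype t-tests within each stratum, run only when the
    ladder gate passed.  ``mean_diff`` is first minus second group mean.
    Pairs with fewer than 2 observations in a genotype are skipped."""
    if not gate_passed:
        return []
    results: list[PosthocResult] = []
    genotypes = [g for g in ("INV", "HET", "STD") if g in set(data["genotype"])]
    for stratum, grp in data.groupby(stratum_col, sort=True):
        for a, b in itertools.combinations(genotypes, 2):
            xa = grp.loc[grp["genotype"] == a, "y"].to_numpy(dtype=float)
            xb = grp.loc[grp["genotype"] == b, "y"].to_numpy(dtype=float)
            if len(xa) < 2 or len(xb) < 2:
                continue
            res = stats.ttest_ind(xa, xb, equal_var=not welch)
            results.append(
                PosthocResult(
                    trait=trait,
                    stratum=stratum,
                    pair=(a, b),
                    t=float(res.statistic),
                    df=float(res.df),
                    p=float(res.pvalue),
                    mean_diff=float(xa.mean() - xb.mean()),
                    n=(len(xa), len(xb)),
                )
            )
    return results


@dataclass
class AnalysisReport:
    """Model-comparison tables and post-hoc results for all six traits of
    one analysis mode."""

    mode: str  # "sex" or "temperature"
    n_flies: int
    tables: dict = field(default_factory=dict)  # trait -> ModelComparisonTable
    posthoc: list = field(default_factory=list)  # PosthocResult
    warnings: list = field(default_factory=list)

    def comparison_frame(self) -> pd.DataFrame:
        """All ladders stacked into one table shaped like a published
        model-comparison summary (Trait, Model, npar, AIC, logLik, Chisq,
        Df, p)."""
        frames = [self.tables[t].table for t in TRAITS if t in self.tables]
        out = pd.concat(frames, ignore_index=True)
        return out.rename(columns={"trait": "Trait"})[
            ["Trait", "Model", "npar", "AIC", "logLik", "Chisq", "Df", "p"]
        ]

    def posthoc_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trait": TRAIT_LABELS[r.trait],
                "stratum": r.stratum,
                "genotype_1": r.pair[0],
                "genotype_2": r.pair[1],
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "mean_diff": r.mean_diff,
                "n_1": r.n[0],
                "n_2": r.n[1],
            }
            for r in self.posthoc
        ]
        cols = [
            "trait", "stratum", "genotype_1", "genotype_2",
            "t", "df", "p", "mean_diff", "n_1", "n_2",
        ]
        return pd.DataFrame(rows, columns=cols)


def prepare_analysis_data(data: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Subset the joined phenotype/metadata table for one analysis mode.

    ``sex``: both sexes, 25 C only.  ``temperature``: females only, all
    temperatures.  Missing strata are rejected by name.
    """
    if mode == "sex":
        sub = data[data["temperature_c"] == 25.0].copy()
        missing = [s for s in ("F", "M") if s not in set(sub["sex"])]
        if missing:
            raise ValidationError(f"sex analysis: no flies with sex {missing} at 25 C")
    elif mode == "temperature":
        sub = data[data["sex"] == "F"].copy()
        if sub["temperature_c"].nunique() < 2:
            raise ValidationError(
                "temperature analysis: need females at >= 2 temperatures"
            )
    else:
        raise ValidationError(f"unknown analysis mode {mode!r}")
    if sub["experiment_block"].nunique() < 2:
        raise ValidationError(f"{mode} analysis: need >= 2 experiment blocks")
    return sub


def run_analysis(
    data: pd.DataFrame,
    mode: str,
    alpha: float = 0.05,
    welch: bool = True,
    traits: tuple[str, ...] = TRAITS,
) -> AnalysisReport:
    """Run the full ladder -> LRT -> gated post-hoc workflow for one mode.

    ``data`` is the joined phenotype/metadata frame.  Proportion traits are
    arcsin-sqrt transformed before both modeling and post-hoc tests.
    """
    sub = prepare_analysis_data(data, mode)
    covariate = mode
    stratum_col = "sex" if mode == "sex" else "temperature_c"
    report = AnalysisReport(mode=mode, n_flies=len(sub))
    for trait in traits:
        specs = build_ladder(trait, covariate)
        work = sub[
            ["fly_id", "genotype", "sex", "temperature_c", "experiment_block"]
        ].copy()
        work["y"] = (
            arcsin_sqrt(sub[trait].to_numpy())
            if specs[0].transform
            else sub[trait].to_numpy(dtype=float)
        )
        fits = [fit_mixed(spec, work) for spec in specs]
        for f in fits:
            if not f.converged:
                report.warnings.append(
                    f"{trait}/{f.spec.name}: optimizer did not report convergence"
                )
        table = compare_ladder(fits)
        report.tables[trait] = table
        report.posthoc.extend(
            posthoc_pairwise(
                work, trait, stratum_col, table.gate_passed(alpha), welch=welch
            )
        )
    return report
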