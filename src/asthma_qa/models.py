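"""Descriptive contingency analyses and GEE exacerbation models.

One analysis row is a patient x assessment-period observation carrying the
binary measurement-window exacerbation outcome and the premeasurement
covariates: institution grade (reference: Tertiary), severity group I-IV,
total medication rank, MPR adherence level (reference: 3, >80%),
comorbidity, assessment period (reference: last), sex and age band
(reference: 65+).  The whole-group model adjusts for severity as a
covariate; the subgroup specification fits one model per severity group
(dropping the severity term, keeping total rank) and is compared with the
whole-group model by summing the per-stratum QICu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .gee import GEEResult, gee_logistic

AGE_BANDS = ("15-34", "35-44", "45-54", "55-64", "65+")
SEVERITY_LEVELS = ("I", "II", "III", "IV")
GRADE_LEVELS = ("Unsatisfactory", "Satisfactory", "Tertiary")


def age_band(age) -> pd.Series:
    """Map age in years to the five analysis bands (15-34 ... 65+)."""
    age = pd.Series(np.asarray(age))
    bins = [15, 35, 45, 55, 65, np.inf]
    return pd.cut(age, bins=bins, labels=AGE_BANDS, right=False).astype(str)


@dataclass(frozen=True)
class Term:
    """One model term: a covariate column, its type and reference level."""

    name: str
    kind: str = "categorical"  # "categorical" | "numeric"
    ref: Optional[str] = None


WHOLE_GROUP_TERMS: List[Term] = [
    Term("grade", ref="Tertiary"),
    Term("severity", ref="I"),
    Term("total_rank", kind="numeric"),
    Term("mpr_level", ref="3"),
    Term("comorbidity", ref="yes"),
    Term("period", ref=None),  # None -> highest period index
    Term("sex", ref="F"),
    Term("age_band", ref="65+"),
]

SUBGROUP_TERMS: List[Term] = [t for t in WHOLE_GROUP_TERMS if t.name != "severity"]


def build_design(df: pd.DataFrame, terms: Sequence[Term]):
    """Design matrix with intercept and treatment (reference-level) coding."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for term in terms:
        if term.name not in df.columns:
            raise ValueError(f"column {term.name!r} missing from analysis table")
        if term.kind == "numeric":
            cols.append(df[term.name].to_numpy(dtype=float))
            names.append(term.name)
            continue
        vals = df[term.name].astype(str)
        levels = sorted(vals.unique())
        ref = term.ref if term.ref is not None else levels[-1]
        if ref not in levels:
            raise ValueError(
                f"reference level {ref!r} absent from {term.name!r} ({levels})"
            )
        for lev in levels:
            if lev == ref:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{term.name}[{lev}]")
    return np.column_stack(cols), names


def build_analysis_table(
    cohort: pd.DataFrame,
    severity: pd.DataFrame,
    covariates: pd.DataFrame,
    grades: pd.DataFrame,
) -> pd.DataFrame:
    """Join the pipeline stages into one analysis row per patient-period.

    `severity` must carry (patient_id, period, severity, total_rank),
    `covariates` (patient_id, period, mpr_level, comorbidity, exacerbated),
    `grades` (institution_id, period, grade).  Raises on duplicated
    (patient_id, period) keys; warns and returns an empty frame when the
    stage outputs are disjoint; raises listing offending keys when some
    cohort rows lack a match in a stage.
    """
    key = ["patient_id", "period"]
    for name, df in (
        ("cohort", cohort),
        ("severity", severity),
        ("covariates", covariates),
    ):
        if df.duplicated(key).any():
            dup = df[df.duplicated(key)][key].values[:5].tolist()
            raise ValueError(f"duplicate (patient_id, period) in {name}: {dup}")

    out = cohort.merge(severity, on=key, how="left", indicator="_sev")
    out = out.merge(covariates, on=key, how="left", indicator="_cov")
    out = out.merge(
        grades[["institution_id", "period", "grade"]],
        on=["institution_id", "period"],
        how="left",
        indicator="_grade",
    )
    flag_map = {"severity": "_sev", "covariates": "_cov", "grades": "_grade"}
    n_matched = int(
        ((out["_sev"] == "both") & (out["_cov"] == "both") & (out["_grade"] == "both")).sum()
    )
    if n_matched == 0:
        warnings.warn("stage outputs are disjoint: empty analysis table")
        return out.iloc[0:0].drop(columns=list(flag_map.values()))
    offending = {}
    for stage, flag in flag_map.items():
        bad = out.loc[out[flag] == "left_only", key]
        if len(bad):
            offending[stage] = [tuple(r) for r in bad.itertuples(index=False)]
    if offending:
        msg = "; ".join(
            f"{stage}: {keys[:5]}{'...' if len(keys) > 5 else ''}"
            for stage, keys in offending.items()
        )
        raise ValueError(f"analysis-table join keys missing in stages: {msg}")
    out = out.drop(columns=["_sev", "_cov", "_grade"])
    out["comorbidity"] = np.where(out["comorbidity"].astype(bool), "yes", "no")
    out["mpr_level"] = out["mpr_level"].astype(int).astype(str)
    out["exacerbated"] = out["exacerbated"].astype(int)
    out["age_band"] = age_band(out["age"])
    return out


@dataclass
class ContingencyResult:
    counts: pd.DataFrame  # variable levels x {0, 1}
    column_percent: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float
    low_expected: bool = False


def column_percentages(counts: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Percentages within each column (the baseline-table convention)."""
    return (100.0 * counts / counts.sum(axis=0)).round(decimals)


def contingency(
    table: pd.DataFrame, variable: str, outcome: str = "exacerbated"
) -> ContingencyResult:
    """Pearson chi-square (no continuity correction) of variable x outcome.

    Percentages are computed within outcome columns, matching the
    baseline-characteristics convention of national-assessment reports.
    """
    counts = pd.crosstab(table[variable], table[outcome])
    chi2, p, dof, expected = chi2_contingency(counts, correction=False)
    low = bool((expected < 1).any())
    if low:
        warnings.warn(f"{variable}: expected cell count below 1")
    return ContingencyResult(
        counts=counts,
        column_percent=column_percentages(counts),
        chi2=float(chi2),
        dof=int(dof),
        pvalue=float(p),
        low_expected=low,
    )


@dataclass
class GEEFit:
    """Odds-ratio summary of one fitted GEE model."""

    result: GEEResult
    summary: pd.DataFrame  # coef, robust_se, OR, ci_low, ci_high, p
    terms: List[Term]

    @property
    def qicu(self) -> float:
        return self.result.qicu

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.result.params, index=self.result.names)


class ExacerbationGEE:
    """Marginal logistic GEE for the exacerbation outcome.

    scikit-learn style estimator: ``fit(df)`` consumes an analysis table
    (see :func:`build_analysis_table`) and exposes fitted attributes with a
    trailing underscore.  ``group_col`` identifies the repeated-measures
    cluster (patient) and ``time_col`` the AR(1) time metric (assessment
    period index).
    """

    def __init__(
        self,
        terms: Optional[Sequence[Term]] = None,
        corstr: str = "ar1",
        outcome_col: str = "exacerbated",
        group_col: str = "patient_id",
        time_col: str = "period",
        max_iter: int = 100,
        tol: float = 1e-10,
    ):
        self.terms = terms
        self.corstr = corstr
        self.outcome_col = outcome_col
        self.group_col = group_col
        self.time_col = time_col
        self.max_iter = max_iter
        self.tol = tol

    def get_params(self, deep=True):
        return {
            "terms": self.terms,
            "corstr": self.corstr,
            "outcome_col": self.outcome_col,
            "group_col": self.group_col,
            "time_col": self.time_col,
            "max_iter": self.max_iter,
            "tol": self.tol,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _resolved_terms(self, df) -> List[Term]:
        terms = list(self.terms if self.terms is not None else WHOLE_GROUP_TERMS)
        out = []
        for t in terms:
            if t.kind == "categorical" and t.ref is None:
                ref = str(sorted(df[t.name].astype(str).unique())[-1])
                t = Term(t.name, t.kind, ref)
            out.append(t)
        return out

    def fit(self, df: pd.DataFrame, y=None):
        terms = self._resolved_terms(df)
        X, names = build_design(df, terms)
        res = gee_logistic(
            X,
            df[self.outcome_col].to_numpy(dtype=float),
            df[self.group_col].to_numpy(),
            df[self.time_col].to_numpy(dtype=int),
            corstr=self.corstr,
            max_iter=self.max_iter,
            tol=self.tol,
            names=names,
        )
        or_, lo, hi = res.odds_ratios()
        self.terms_ = terms
        self.result_ = res
        self.coef_ = pd.Series(res.params, index=names)
        self.cov_robust_ = pd.DataFrame(res.cov_robust, index=names, columns=names)
        self.rho_ = res.rho
        self.qicu_ = res.qicu
        self.n_clusters_ = res.n_clusters
        self.n_obs_ = res.n_obs
        self.converged_ = res.converged
        self.summary_ = pd.DataFrame(
            {
                "coef": res.params,
                "robust_se": res.bse,
                "OR": or_,
                "ci_low": lo,
                "ci_high": hi,
                "pvalue": res.pvalues,
            },
            index=names,
        )
        return self

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        X, _ = build_design(df, self.terms_)
        p1 = expit(X @ self.result_.params)
        return np.column_stack([1 - p1, p1])

    def to_fit(self) -> GEEFit:
        return GEEFit(result=self.result_, summary=self.summary_, terms=self.terms_)


def fit_gee(
    rows: pd.DataFrame,
    terms: Optional[Sequence[Term]] = None,
    corstr: str = "ar1",
    **kwargs,
) -> GEEFit:
    """Fit one GEE model on analysis rows and return its OR summary."""
    est = ExacerbationGEE(terms=terms, corstr=corstr, **kwargs).fit(rows)
    return est.to_fit()


@dataclass
class SubgroupFits:
    whole: GEEFit
    by_severity: Dict[str, GEEFit]
    total_qicu: float
    skipped: List[str]


def fit_subgroup_models(
    rows: pd.DataFrame,
    corstr: str = "ar1",
    whole_terms: Optional[Sequence[Term]] = None,
    subgroup_terms: Optional[Sequence[Term]] = None,
) -> SubgroupFits:
    """Whole-group model plus one model per severity group.

    The subgroup specification drops the severity covariate (each stratum is
    one severity group) and keeps the total medication rank to absorb
    residual within-group severity.  The summed per-stratum QICu is the
    model-selection statistic against the whole-group QICu; lower wins.
    Strata with a single outcome level are skipped with a warning.
    """
    whole = fit_gee(rows, terms=whole_terms or WHOLE_GROUP_TERMS, corstr=corstr)
    fits: Dict[str, GEEFit] = {}
    skipped: List[str] = []
    for level in sorted(rows["severity"].astype(str).unique()):
        sub = rows[rows["severity"].astype(str) == level]
        if sub["exacerbated"].nunique() < 2:
            warnings.warn(f"severity {level}: single outcome level, skipped")
            skipped.append(level)
            continue
        fits[level] = fit_gee(
            sub, terms=subgroup_terms or SUBGROUP_TERMS, corstr=corstr
        )
    total_qicu = float(sum(f.qicu for f in fits.values()))
    return SubgroupFits(
        whole=whole, by_severity=fits, total_qicu=total_qicu, skipped=skipped
    )
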