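"""Association analyses: baseline table, logistic models, C-statistics, per-SNP scan.

Conventions follow standard case-control reporting: Welch (unequal-variance)
t-tests for quantitative baseline traits and Yates-corrected chi-squared for
2x2 categorical tables; logistic-regression odds ratios with Wald 95%
confidence intervals; model discrimination as the C-statistic (ROC AUC) with
nested models compared by the paired DeLong test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from .panel import GrsVector, SnpPanel, assign_quantiles
from .simulate import Cohort

__all__ = [
    "DEFAULT_COVARIATES",
    "BaselineRow",
    "AssociationReport",
    "FitError",
    "welch_t_from_summary",
    "yates_chi2",
    "baseline_table",
    "fit_logistic",
    "c_statistic",
    "delong_test",
    "compare_c_statistics",
    "per_snp_scan",
]

# Adjustment set used throughout: age, sex, smoking, BMI, diabetes,
# hypertension, prior myocardial infarction, heart failure.
DEFAULT_COVARIATES = [
    "age",
    "male",
    "smoker",
    "bmi",
    "diabetes",
    "hypertension",
    "prior_mi",
    "heart_failure",
]

Z95 = sps.norm.ppf(0.975)


class FitError(RuntimeError):
    """Raised when a logistic fit fails to converge or separates perfectly."""


@dataclass(frozen=True)
class BaselineRow:
    variable: str
    summary_no_af: str
    summary_af: str
    test: str  # "welch_t" | "chi_squared" | "untestable"
    p_value: float


@dataclass(frozen=True)
class AssociationReport:
    coding: str  # "sd" | "quintile" | "ordinal" | "tertile"
    adjusted: bool
    covariates: list[str]
    terms: pd.DataFrame  # term, or, ci_low, ci_high, p_value
    c_statistic_base: float | None = None
    c_statistic_full: float | None = None
    c_comparison_p: float | None = None

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if hit.empty:
            raise KeyError(f"no term {name!r} in report")
        return hit.iloc[0]


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Two-sided Welch t-test from group summaries; returns (t, p)."""
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(t), float(p)


def yates_chi2(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """Continuity-corrected chi-squared for a 2x2 table given per-group
    positive counts ``a``/``n1`` and ``b``/``n2``; returns (stat, p)."""
    table = np.array([[a, n1 - a], [b, n2 - b]])
    stat, p, _, _ = sps.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def _is_binary(x: np.ndarray) -> bool:
    return np.isin(np.unique(x[~np.isnan(x)]), (0.0, 1.0)).all()


def baseline_table(cohort: Cohort, variables: list[str] | None = None) -> list[BaselineRow]:
    """Two-group (AF vs no AF) comparison of baseline characteristics.

    Binary 0/1 columns get a Yates-corrected chi-squared on the 2x2 table and
    an ``n (percent)`` summary; quantitative columns get a Welch t-test and a
    ``mean (SD)`` summary.  A quantitative variable with fewer than two values
    in either group is flagged untestable.
    """
    df = cohort.covariates
    variables = variables if variables is not None else list(df.columns)
    ev = cohort.af_event.astype(bool)
    rows: list[BaselineRow] = []
    for var in variables:
        x = df[var].to_numpy(dtype=float)
        g0, g1 = x[~ev], x[ev]
        if _is_binary(x):
            a, b = int(g0.sum()), int(g1.sum())
            stat, p = yates_chi2(a, g0.size, b, g1.size)
            rows.append(
                BaselineRow(
                    var,
                    f"{a} ({100 * a / g0.size:.0f}%)",
                    f"{b} ({100 * b / g1.size:.0f}%)",
                    "chi_squared",
                    p,
                )
            )
        else:
            s0 = f"{g0.mean():.1f} ({g0.std(ddof=1):.1f})" if g0.size > 1 else "-"
            s1 = f"{g1.mean():.1f} ({g1.std(ddof=1):.1f})" if g1.size > 1 else "-"
            if g0.size < 2 or g1.size < 2:
                rows.append(BaselineRow(var, s0, s1, "untestable", float("nan")))
                continue
            _, p = welch_t_from_summary(
                g0.mean(), g0.std(ddof=1), g0.size, g1.mean(), g1.std(ddof=1), g1.size
            )
            rows.append(BaselineRow(var, s0, s1, "welch_t", p))
    return rows


def _checked_logit(y: np.ndarray, X: pd.DataFrame) -> sm.discrete.discrete_model.BinaryResults:
    if len(np.unique(y)) < 2:
        raise FitError("outcome has a single class; logistic model is undefined")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    if np.abs(res.params).max() > 15:
        raise FitError("implausibly large coefficients; data are likely separated")
    return res


def _design(cohort: Cohort, adjusted: bool, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(cohort.n)})
    if adjusted:
        for c in covariates:
            X[c] = cohort.covariates[c].to_numpy(dtype=float)
    return X

def _or_rows(res, names: list[str]) -> pd.DataFrame:
    beta = res.params[names]
    se = res.bse[names]
    return pd.DataFrame(
        {
            "term": names,
            "or": np.exp(beta.to_numpy()),
            "ci_low": np.exp((beta - Z95 * se).to_numpy()),
            "ci_high": np.exp((beta + Z95 * se).to_numpy()),
            "p_value": res.pvalues[names].to_numpy(),
        }
    )


def fit_logistic(
    cohort: Cohort,
    grs: GrsVector,
    coding: str = "sd",
    adjusted: bool = False,
    covariates: list[str] | None = None,
) -> AssociationReport:
    """Logistic regression of the AF outcome on the risk score.

    Codings: ``"sd"`` — score standardized by its sample SD, one odds ratio
    per SD increase; ``"quintile"``/``"tertile"`` — dummy-coded groups with
    the lowest as reference; ``"ordinal"`` — quintile index 1-5 entered as a
    single quantitative trend term.
    """
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    X = _design(cohort, adjusted, covariates)
    y = cohort.af_event

    if coding == "sd":
        X["grs_per_sd"] = grs.score / grs.score.std(ddof=1)
        focus = ["grs_per_sd"]
    elif coding == "ordinal":
        q = grs.quintile if grs.quintile is not None else assign_quantiles(grs, 5).quintile
        X["grs_quintile"] = q.astype(float)
        focus = ["grs_quintile"]
    elif coding in ("quintile", "tertile"):
        k = 5 if coding == "quintile" else 3
        labels = grs.quintile if k == 5 else grs.tertile
        if labels is None:
            labels = getattr(assign_quantiles(grs, k), "quintile" if k == 5 else "tertile")
        focus = []
        for g in range(2, k + 1):
            name = f"{coding}_{g}"
            X[name] = (labels == g).astype(float)
            focus.append(name)
    else:
        raise ValueError(f"unknown coding {coding!r}")

    res = _checked_logit(y, X)
    terms = _or_rows(res, focus)
    if coding in ("quintile", "tertile"):
        ref = pd.DataFrame(
            {"term": [f"{coding}_1"], "or": [1.0], "ci_low": [np.nan],
             "ci_high": [np.nan], "p_value": [np.nan]}
        )
        terms = pd.concat([ref, terms], ignore_index=True)
    return AssociationReport(coding, adjusted, covariates if adjusted else [], terms)


def c_statistic(y: np.ndarray, score: np.ndarray) -> float:
    """Concordance probability (ROC AUC) of a risk score for a binary outcome."""
    return float(roc_auc_score(y, score))


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def delong_test(y: np.ndarray, score_a: np.ndarray, score_b: np.ndarray) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two AUCs on the same cases.

    Returns (auc_a, auc_b, z, two-sided p).  Uses the structural-component
    (midrank) formulation: for each positive case the fraction of negatives
    it outranks, and vice versa; the AUC difference is tested against the
    variance of the paired component differences.
    """
    y = np.asarray(y, dtype=int)
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes are required to compare AUCs")
    aucs, v10s, v01s = [], [], []
    for s in (score_a, score_b):
        s = np.asarray(s, dtype=float)
        rank_all = _midrank(s)
        rank_pos = _midrank(s[pos])
        rank_neg = _midrank(s[neg])
        auc = (rank_all[pos].sum() - m * (m + 1) / 2) / (m * n)
        v10 = (rank_all[pos] - rank_pos) / n          # per-positive components
        v01 = 1.0 - (rank_all[neg] - rank_neg) / m    # per-negative components
        aucs.append(auc)
        v10s.append(v10)
        v01s.append(v01)
    d10 = v10s[0] - v10s[1]
    d01 = v01s[0] - v01s[1]
    var = np.var(d10, ddof=1) / m + np.var(d01, ddof=1) / n
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(p)


def compare_c_statistics(
    cohort: Cohort,
    grs: GrsVector,
    covariates: list[str] | None = None,
) -> tuple[float, float, float]:
    """C-statistic of the covariate-only model vs covariates + GRS.

    Both logistic models are fit on the same rows; discrimination is the AUC
    of the fitted probabilities, compared by the paired DeLong test.
    Returns (c_base, c_full, p).
    """
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    y = cohort.af_event
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: both classes required")
    X_base = _design(cohort, adjusted=True, covariates=covariates)
    X_full = X_base.copy()
    X_full["grs"] = grs.score
    p_base = _checked_logit(y, X_base).predict(X_base)
    p_full = _checked_logit(y, X_full).predict(X_full)
    c_full, c_base, _, p = delong_test(y, np.asarray(p_full), np.asarray(p_base))
    return c_base, c_full, p


def per_snp_scan(
    cohort: Cohort,
    panel: SnpPanel,
    covariates: list[str] | None = None,
    pitx2_pair: tuple[str, str] = ("rs2200733", "rs10033464"),
    include_adjusted: bool = True,
) -> pd.DataFrame:
    """One additive-dosage logistic fit per SNP, unadjusted and adjusted.

    Monomorphic SNPs are flagged and not fit.  The result carries the dosage
    correlation of the designated PITX2 pair in ``df.attrs["pitx2_dosage_corr"]``
    when both SNPs are present.
    """
    gm = cohort.genotypes.aligned_to(panel)
    if gm.n_missing:
        raise ValueError("impute missing dosages before the per-SNP scan")
    y = cohort.af_event
    rows = []
    for j, rsid in enumerate(gm.rsids):
        dos = gm.dosage[:, j]
        row: dict[str, object] = {"rsid": rsid, "gene": panel.genes[j], "monomorphic": False}
        if np.unique(dos).size < 2:
            row.update(monomorphic=True)
            rows.append(row)
            continue
        model_set = (("unadj", False), ("adj", True)) if include_adjusted else (("unadj", False),)
        for label, adjusted in model_set:
            X = _design(cohort, adjusted, covariates or DEFAULT_COVARIATES)
            X["dosage"] = dos
            try:
                fit = _checked_logit(y, X)
                t = _or_rows(fit, ["dosage"]).iloc[0]
                row.update(
                    {
                        f"or_{label}": t["or"],
                        f"ci_low_{label}": t["ci_low"],
                        f"ci_high_{label}": t["ci_high"],
                        f"p_{label}": t["p_value"],
                    }
                )
            except FitError:
                row.update({f"or_{label}": np.nan, f"p_{label}": np.nan})
        rows.append(row)
    out = pd.DataFrame(rows)
    a, b = pitx2_pair
    if a in gm.rsids and b in gm.rsids:
        da = gm.dosage[:, gm.rsids.index(a)]
        db = gm.dosage[:, gm.rsids.index(b)]
        if np.std(da) > 0 and np.std(db) > 0:
            out.attrs["pitx2_dosage_corr"] = float(np.corrcoef(da, db)[0, 1])
    return out
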