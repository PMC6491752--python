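"""Clinical evaluation battery.

ROC/AUC for case-control discrimination, Spearman correlation of the
index with severity (NIHSS) and outcome (mRS) scores, group
characteristics tables, the P<0.20 univariate screen feeding a
multivariable logistic model, and the edema-corrected infarct-volume
arithmetic used in the transplant experiment.

Severity is dichotomised at NIHSS >= 8 ("severe stroke") and outcome at
mRS > 2 ("unfavorable"); both constants are study definitions and are
exposed read-only.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SEVERE_NIHSS_CUT = 8     # severe stroke: NIHSS >= 8
UNFAVORABLE_MRS_CUT = 2  # unfavorable outcome: mRS > 2


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


@dataclass(frozen=True)
class LogisticResult:
    """Per-covariate logistic estimates with Wald 95% CIs."""

    table: pd.DataFrame  # estimate, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    n: int
    outcome: str = ""


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoid AUC; higher score predicts the positive
    class. Equals the tie-averaged Mann-Whitney U / (n1*n0) identity."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # threshold sweep over distinct score values
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    sens = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(sens, fpr))
    thresholds = np.r_[np.inf, s[distinct]]
    return RocResult(thresholds, sens, 1.0 - fpr, auc)


def _spearman_exact_p(rho: float, n: int) -> float:
    ranks = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(ranks)))
    mean = (n + 1) / 2.0
    denom = ((ranks - mean) ** 2).sum()
    rhos = ((perms - mean) * (ranks - mean)).sum(axis=1) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(x, y) -> tuple[float, float]:
    """Midrank Spearman correlation; exact permutation p for n <= 9
    without ties, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    if len(x) <= 9 and no_ties:
        p = _spearman_exact_p(rho, len(x))
    return float(rho), float(p)


def _is_binary(series: pd.Series) -> bool:
    vals = series.dropna().unique()
    return len(vals) <= 2


def summarize_groups(records: pd.DataFrame, grouping: str, variables=None) -> pd.DataFrame:
    """Two-group characteristics table.

    Continuous variables get mean (SD) with a t-test when Shapiro-Wilk
    does not reject normality in either group (alpha 0.05), otherwise
    median (IQR) with a rank-sum test. Binary variables get n (%) with a
    chi-square test, switching to Fisher's exact test when any expected
    cell is below 5.
    """
    groups = records[grouping].dropna().unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    a_rows = records[records[grouping] == groups[0]]
    b_rows = records[records[grouping] == groups[1]]
    if a_rows.empty or b_rows.empty:
        raise ValueError("empty group")
    if variables is None:
        variables = [c for c in records.columns if c != grouping]

    out = []
    for var in variables:
        a = a_rows[var].dropna()
        b = b_rows[var].dropna()
        if _is_binary(records[var]):
            # count the "1"/true level
            level = sorted(records[var].dropna().unique())[-1]
            ka, kb = int((a == level).sum()), int((b == level).sum())
            tab = np.array([[ka, len(a) - ka], [kb, len(b) - kb]])
            if tab.sum() == 0:
                p = 1.0
                test = "none"
            else:
                expected = stats.contingency.expected_freq(tab) if tab.min() >= 0 else None
                if expected is not None and (expected < 5).any():
                    p = float(stats.fisher_exact(tab)[1])
                    test = "fisher"
                else:
                    p = float(stats.chi2_contingency(tab, correction=False)[1])
                    test = "chi2"
            out.append({
                "variable": var, "type": "categorical",
                "group_a": f"{ka} ({100.0 * ka / len(a):.1f}%)",
                "group_b": f"{kb} ({100.0 * kb / len(b):.1f}%)",
                "pct_a": 100.0 * ka / len(a), "pct_b": 100.0 * kb / len(b),
                "test": test, "p_value": p,
            })
        else:
            same = len(a) and len(b) and np.ptp(pd.concat([a, b])) == 0
            normal = False
            if not same and len(a) >= 3 and len(b) >= 3:
                normal = (stats.shapiro(a)[1] > 0.05) and (stats.shapiro(b)[1] > 0.05)
            if same:
                p, test = 1.0, "degenerate"
            elif normal:
                p = float(stats.ttest_ind(a, b)[1])
                test = "t"
            else:
                p = float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
                test = "rank-sum"
            if normal:
                desc_a = f"{a.mean():.2f} ({a.std(ddof=1):.2f})"
                desc_b = f"{b.mean():.2f} ({b.std(ddof=1):.2f})"
            else:
                desc_a = f"{a.median():.2f} ({a.quantile(.75) - a.quantile(.25):.2f})"
                desc_b = f"{b.median():.2f} ({b.quantile(.75) - b.quantile(.25):.2f})"
            out.append({
                "variable": var, "type": "continuous",
                "group_a": desc_a, "group_b": desc_b,
                "pct_a": np.nan, "pct_b": np.nan,
                "test": test, "p_value": p,
            })
    table = pd.DataFrame(out).set_index("variable")
    table.attrs["groups"] = (groups[0], groups[1])
    return table


def outcome_indicator(records: pd.DataFrame, outcome: str) -> pd.Series:
    """Binary outcome per patient: ``severe`` = NIHSS_in >= 8,
    ``unfavorable`` = mRS_out > 2."""
    if outcome == "severe":
        return (records["nihss_in"] >= SEVERE_NIHSS_CUT).astype(int)
    if outcome == "unfavorable":
        return (records["mrs_out"] > UNFAVORABLE_MRS_CUT).astype(int)
    raise ValueError(f"unknown outcome {outcome!r}")


def logistic_fit(design: pd.DataFrame, outcome, add_constant: bool = True) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    Raises on perfect separation (naming an offending covariate) and on
    outcomes with no events or no non-events. Non-convergence is reported
    in the result, never silent.
    """
    y = pd.Series(outcome).astype(float)
    X = pd.DataFrame(design).astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has no events (or no non-events)")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    # complete separation makes the MLE diverge: flag the covariate up front
    for col in X.columns:
        x1, x0 = X.loc[y == 1, col], X.loc[y == 0, col]
        if len(x1) and len(x0) and (x1.min() > x0.max() or x1.max() < x0.min()):
            raise ValueError(f"perfect separation: covariate {col!r}")
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y.to_numpy(), X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(disp=0, maxiter=100, tol=1e-8)
        except Exception as exc:  # statsmodels PerfectSeparationError etc.
            raise ValueError(f"logistic fit failed: {exc}") from exc
    se = np.asarray(fit.bse)
    if not np.all(np.isfinite(se)) or np.any(se > 1e3):
        bad = [c for c, s in zip(X.columns, se) if not math.isfinite(s) or s > 1e3]
        raise ValueError(f"perfect or quasi-separation: covariate(s) {bad}")
    est = np.asarray(fit.params)
    tab = pd.DataFrame({
        "estimate": est,
        "odds_ratio": np.exp(est),
        "ci_low": np.exp(est - 1.96 * se),
        "ci_high": np.exp(est + 1.96 * se),
        "p_value": np.asarray(fit.pvalues),
    }, index=list(X.columns))
    return LogisticResult(tab, bool(fit.mle_retvals.get("converged", True)), int(len(y)))


#: scores that define the outcomes and are therefore never predictors
_EXCLUDED_PREDICTORS = {"nihss_in", "nihss_out", "mrs_out", "nihss", "mrs"}


def univariate_screen(
    records: pd.DataFrame,
    outcome: str,
    covariates=None,
    p_in: float = 0.20,
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate logistic screen at the inclusion threshold.

    Returns the covariates with p < ``p_in`` plus the full audit table.
    NIHSS/mRS never enter as predictors (they define the outcomes);
    separated covariates are reported with an infinite-OR sentinel and
    excluded from the pass list.
    """
    y = outcome_indicator(records, outcome)
    if covariates is None:
        covariates = [
            c for c in records.columns
            if c not in _EXCLUDED_PREDICTORS | {"sample_id", "group"}
            and pd.api.types.is_numeric_dtype(records[c])
        ]
    rows = []
    for cov in covariates:
        if cov in _EXCLUDED_PREDICTORS:
            continue
        data = pd.concat([records[cov], y], axis=1).dropna()
        try:
            res = logistic_fit(data[[cov]], data.iloc[:, 1])
            r = res.table.loc[cov]
            rows.append((cov, r["odds_ratio"], r["ci_low"], r["ci_high"],
                         r["p_value"], False))
        except ValueError:
            rows.append((cov, np.inf, np.nan, np.nan, np.nan, True))
    audit = pd.DataFrame(
        rows, columns=["covariate", "odds_ratio", "ci_low", "ci_high",
                       "p_value", "separated"],
    ).set_index("covariate")
    passed = list(audit.index[(audit["p_value"] < p_in) & ~audit["separated"]])
    return passed, audit


def multivariable_model(
    records: pd.DataFrame, outcome: str, p_in: float = 0.20
) -> tuple[LogisticResult, list[str]]:
    """Univariate P<p_in screen followed by one multivariable logistic
    fit on the retained covariates."""
    passed, _ = univariate_screen(records, outcome, p_in=p_in)
    if not passed:
        raise ValueError("no covariates passed the univariate screen")
    y = outcome_indicator(records, outcome)
    data = pd.concat([records[passed], y.rename("_y")], axis=1).dropna()
    res = logistic_fit(data[passed], data["_y"])
    return LogisticResult(res.table, res.converged, res.n, outcome), passed


def correct_infarct(
    direct_lesion_areas, ipsi_areas, contra_areas, section_interval: float
) -> float:
    """Edema-corrected infarct volume from serial sections.

    Per section: corrected area = direct lesion area - (ipsilateral -
    contralateral hemisphere area), floored at 0; the volume integrates
    corrected areas over the section interval.
    """
    d = np.asarray(direct_lesion_areas, dtype=float)
    i = np.asarray(ipsi_areas, dtype=float)
    c = np.asarray(contra_areas, dtype=float)
    if not (d.shape == i.shape == c.shape):
        raise ValueError("area lists must have equal lengths")
    if section_interval <= 0:
        raise ValueError("section interval must be positive")
    corrected = np.clip(d - (i - c), 0.0, None)
    return float(corrected.sum() * section_interval)
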