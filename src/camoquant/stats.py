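"""Inferential layer: body condition, AICc model ranking, and rank tests.

The bespoke pieces — the scaled mass index, AICc with its finite-sample
correction, and Akaike-weight model ranking — are implemented here.  Standard
test statistics (Wilcoxon signed-rank and rank-sum, Kruskal–Wallis, Tukey HSD,
OLS, the linear mixed model) are delegated to scipy/statsmodels behind this
module's interface; each result records which method (exact vs. approximate
null) was used.

Scaled mass index (SMI): standardizes each individual's mass to a common
reference length L0 along the standardized-major-axis (SMA) allometry of
ln mass on ln length,

    SMI_i = mass_i * (L0 / SVL_i) ** b_SMA,
    b_SMA = (OLS slope of ln mass on ln SVL) / (Pearson r of ln mass, ln SVL).

AICc: ``-2 loglik + 2k + 2k(k+1)/(n - k - 1)``; candidate mixed models are
ranked ascending with delta-AICc and Akaike weights ``exp(-delta/2)``
normalised to 1.

Mixed models use a random intercept per grouping factor (survey year), fitted
by maximum likelihood.  ``k`` counts fixed coefficients plus two variance
components (residual and intercept variance); AICc comparability depends on
that convention, so it is fixed here.  When the between-group variance
collapses to zero (or there is effectively one group) the fit equals ordinary
least squares at the boundary, and the OLS solution is reported with zero
group variance.

Exact-null thresholds for the rank tests are fixed: signed-rank uses the
exact distribution for n <= 25 (no ties or zeros), rank-sum for combined
n <= 20 (no ties); otherwise the normal approximation with tie correction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DomainError

__all__ = [
    "scaled_mass_index", "aicc", "rank_models", "FittedModel", "fit_lmm",
    "RegressionResult", "linear_regression", "TestResult",
    "paired_signed_rank", "rank_sum_test", "kruskal_wallis",
    "pairwise_contrasts", "ModelComparison",
]

SIGNED_RANK_EXACT_N = 25
RANK_SUM_EXACT_N = 20


# ---------------------------------------------------------------------------
# Body condition
# ---------------------------------------------------------------------------

def sma_exponent(mass, svl) -> float:
    """Standardized-major-axis slope of ln mass on ln SVL."""
    mass = np.asarray(mass, float)
    svl = np.asarray(svl, float)
    if np.any(mass <= 0) or np.any(svl <= 0):
        raise DomainError("mass and SVL must be positive")
    if len(mass) < 3:
        raise DegenerateDataError("need >= 3 individuals for the allometry")
    lm, ls = np.log(mass), np.log(svl)
    if np.var(ls) == 0:
        raise DegenerateDataError("zero variance in SVL; slope undefined")
    slope = np.cov(ls, lm, bias=True)[0, 1] / np.var(ls)
    r = np.corrcoef(ls, lm)[0, 1]
    if r == 0:
        raise DegenerateDataError("ln mass uncorrelated with ln SVL")
    return float(slope / r)


def scaled_mass_index(mass, svl, l0: Optional[float] = None) -> np.ndarray:
    """Scaled mass index per individual (reference length L0 = mean SVL).

    When every SVL already equals L0 the exponent is moot ((L0/SVL)^b = 1)
    and masses are returned unchanged; estimating the allometry from
    zero-variance lengths for any other L0 is an error.
    """
    mass = np.asarray(mass, float)
    svl = np.asarray(svl, float)
    if l0 is None:
        l0 = float(np.mean(svl))
    if np.all(svl == l0):
        return mass.copy()
    b = sma_exponent(mass, svl)
    return mass * (l0 / svl) ** b


# ---------------------------------------------------------------------------
# AICc model ranking
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """AIC with the finite-sample correction; requires n > k + 1."""
    if n <= k + 1:
        raise DomainError(
            f"AICc correction undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class FittedModel:
    """What model ranking and post-hoc contrasts need from one fit."""

    label: str
    loglik: float
    k: int
    n: int
    params: pd.Series
    bse: pd.Series
    group_var: float = 0.0
    converged: bool = True
    formula: str = ""


@dataclass(frozen=True)
class ModelComparison:
    """AICc-ranked candidate table."""

    table: pd.DataFrame

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["label"])


def rank_models(candidates: Sequence[FittedModel]) -> ModelComparison:
    """Rank candidates by AICc; ties broken by fewer parameters then label."""
    if len(candidates) == 0:
        raise DomainError("need at least one fitted candidate")
    ns = {m.n for m in candidates}
    if len(ns) > 1:
        raise DomainError(f"candidates fitted on different n: {sorted(ns)}")
    rows = [{"label": m.label, "k": m.k, "loglik": m.loglik,
             "aicc": aicc(m.loglik, m.k, m.n)} for m in candidates]
    df = pd.DataFrame(rows).sort_values(
        ["aicc", "k", "label"], kind="mergesort").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    rel = np.exp(-0.5 * df["delta_aicc"].to_numpy())
    df["weight"] = rel / rel.sum()
    return ModelComparison(df)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def _check_design(table: pd.DataFrame, formula: str) -> None:
    from patsy import dmatrices
    _, X = dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name a minimal set of columns whose removal restores full rank
        bad = []
        cols = list(X.columns)
        arr = X.to_numpy()
        for i in range(arr.shape[1]):
            keep = [j for j in range(arr.shape[1]) if j != i and cols[j] not in bad]
            if np.linalg.matrix_rank(arr[:, keep]) == rank:
                bad.append(cols[i])
        raise DomainError(f"singular design; collinear terms: {bad}")


def fit_lmm(table: pd.DataFrame, response: str, fixed: Sequence[str],
            group: str, label: Optional[str] = None) -> FittedModel:
    """Random-intercept linear mixed model fitted by maximum likelihood.

    ``fixed`` is a list of formula terms (may be empty for intercept-only).
    """
    if group not in table.columns:
        raise DomainError(f"grouping column '{group}' absent")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    _check_design(table, formula)
    ols = smf.ols(formula, data=table).fit()
    n = int(ols.nobs)
    p_fixed = len(ols.params)
    k = p_fixed + 2
    groups = table[group]
    mixed_res = None
    if groups.nunique() > 1:
        import warnings
        for method in ("powell", "lbfgs", "cg"):
            try:
                with warnings.catch_warnings():
                    # boundary fits (zero group variance) warn; handled below
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM.from_formula(formula, data=table,
                                                    groups=groups)
                    cand = model.fit(reml=False, method=method, maxiter=1000)
            except Exception:
                continue
            if np.isfinite(cand.llf) and (mixed_res is None
                                          or cand.llf > mixed_res.llf):
                mixed_res = cand
    if mixed_res is not None and np.isfinite(mixed_res.llf) \
            and mixed_res.llf > ols.llf + 1e-8:
        return FittedModel(label=label or rhs, loglik=float(mixed_res.llf),
                           k=k, n=n, params=mixed_res.fe_params,
                           bse=mixed_res.bse_fe,
                           group_var=float(mixed_res.cov_re.iloc[0, 0]),
                           converged=bool(mixed_res.converged),
                           formula=formula)
    # zero between-group variance boundary: the ML solution is OLS
    return FittedModel(label=label or rhs, loglik=float(ols.llf), k=k, n=n,
                       params=ols.params, bse=ols.bse, group_var=0.0,
                       converged=True, formula=formula)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    stderr: float
    n: int


def linear_regression(y, x) -> RegressionResult:
    """Ordinary least squares of y on x with r^2 and two-sided slope test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise DegenerateDataError("need >= 3 points")
    if np.var(x) == 0:
        raise DegenerateDataError("zero variance in x")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2),
                            p=float(res.pvalue),
                            stderr=float(res.stderr), n=len(x))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: Optional[int] = None
    n: Optional[int] = None

    def as_dict(self) -> dict:
        out = {"statistic": self.statistic, "p": self.p, "method": self.method}
        if self.df is not None:
            out["df"] = self.df
        if self.n is not None:
            out["n"] = self.n
        return out


def paired_signed_rank(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Exact null (enumeration) for n <= 25 nonzero untied differences; normal
    approximation otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise DomainError("paired samples must have equal length")
    d = a - b
    d_nz = d[d != 0]
    if len(d_nz) == 0:
        raise DegenerateDataError("all paired differences are zero")
    ties = len(np.unique(np.abs(d_nz))) < len(d_nz)
    exact = len(d_nz) <= SIGNED_RANK_EXACT_N and not ties
    method = "exact" if exact else "normal-approx"
    res = sps.wilcoxon(a, b, zero_method="wilcox",
                       correction=False,
                       method="exact" if exact else "approx")
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"wilcoxon-signed-rank/{method}", n=len(d_nz))


def rank_sum_test(group_a, group_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact null for combined n <= 20 with no ties; normal approximation with
    tie correction otherwise.  The statistic reported is the Mann–Whitney U
    of the first group (the convention R prints as W).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise DegenerateDataError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= RANK_SUM_EXACT_N) and not ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    method = "exact" if exact else "normal-approx-tie-corrected"
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon-rank-sum/{method}", n=len(pooled))


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal–Wallis H with tie correction, chi-square null, df = k - 1.

    When every observation is identical the tie-corrected H is defined as 0
    (p = 1) rather than 0/0.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise DegenerateDataError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise DegenerateDataError("every group must be nonempty")
    df = len(labels) - 1
    if len(np.unique(values)) == 1:
        return TestResult(0.0, 1.0, "kruskal-wallis/degenerate-ties", df=df,
                          n=len(values))
    h, p = sps.kruskal(*samples)
    return TestResult(float(h), float(p), "kruskal-wallis/chi2", df=df,
                      n=len(values))


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def pairwise_contrasts(values, groups, adjust: str = "tukey") -> pd.DataFrame:
    """All pairwise group mean differences with family-wise adjustment.

    ``adjust``: "tukey" (single-step, studentized range on the pooled-error
    model) or "holm" (pooled-variance t tests, Holm step-down).  Groups with
    fewer than two observations are flagged in ``df.attrs['skipped']`` and
    their pairs omitted, never silently dropped.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups).astype(str)
    counts = pd.Series(groups).value_counts()
    skipped = sorted(counts[counts < 2].index)
    keep = ~np.isin(groups, skipped)
    values, groups = values[keep], groups[keep]
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise DegenerateDataError("need >= 2 usable groups")

    if adjust == "tukey":
        res = pairwise_tukeyhsd(values, groups)
        pairs = list(itertools.combinations(res.groupsunique, 2))
        out = pd.DataFrame({
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "estimate": np.asarray(res.meandiffs, float),
            "p_adj": np.asarray(res.pvalues, float),
        })
    elif adjust == "holm":
        # pooled residual variance across all groups
        means = {g: values[groups == g].mean() for g in labels}
        ss = sum(((values[groups == g] - means[g]) ** 2).sum() for g in labels)
        dof = len(values) - len(labels)
        mse = ss / dof
        rows = []
        for ga, gb in itertools.combinations(labels, 2):
            na, nb = (groups == ga).sum(), (groups == gb).sum()
            est = means[gb] - means[ga]
            se = np.sqrt(mse * (1 / na + 1 / nb))
            t = est / se
            praw = 2 * sps.t.sf(abs(t), dof)
            rows.append({"group_a": ga, "group_b": gb, "estimate": est,
                         "p_raw": praw})
        out = pd.DataFrame(rows)
        out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
        out = out[["group_a", "group_b", "estimate", "p_adj"]]
    else:
        raise DomainError(f"unknown adjustment '{adjust}'")
    out["method"] = adjust
    out.attrs["skipped"] = skipped
    return out
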