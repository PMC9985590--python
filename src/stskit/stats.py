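"""Cohort-level statistical battery.

The analyses mirror a standard observational screen over extracted movement
parameters: Pearson correlations with Benjamini-Hochberg false-discovery-
rate control over an explicit family size, Kruskal-Wallis plus Dunn's post
hoc test for group comparisons of non-normally distributed parameters,
ordinary least squares and logistic regressions with covariate adjustment,
and standardized mean differences (SMD, |SMD| < 0.1 negligible) for
included-vs-excluded balance checks.

Missing data policy: pairwise complete cases for correlations, listwise
deletion for regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# result records

@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    n: int
    p_raw: float
    p_adj: float = float("nan")
    family_size: int = 1


@dataclass
class RegressionResult:
    model: str                # "linear" | "logistic"
    outcome: str
    terms: list[tuple]        # (name, beta, ci_low, ci_high, p)
    n: int

    def term(self, name: str) -> tuple:
        for t in self.terms:
            if t[0] == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.terms,
                            columns=["term", "beta", "ci_low", "ci_high", "p"])


@dataclass
class GroupComparisonResult:
    groups: list[tuple[str, int]]
    H: float
    p_global: float
    pairwise: list[tuple]     # (group_a, group_b, z, p_raw, p_adj)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairwise,
                            columns=["group_a", "group_b", "z", "p_raw", "p_adj"])


@dataclass
class SMDResult:
    variable: str
    smd: float
    ci_low: float
    ci_high: float

    @property
    def negligible(self) -> bool:
        return abs(self.smd) < 0.1


# ---------------------------------------------------------------------------
# primitives

def pearson(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from the t transform (n - 2 df).

    Pairwise-complete: rows where either value is missing are dropped.
    Binary 0/1 variables are handled as-is (point-biserial correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise StatsError(f"need >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    ``m`` is the explicit family size; it may exceed ``len(p_values)`` when
    the family includes tests reported elsewhere, in which case every
    adjusted value is scaled up accordingly.  Sorted ascending, the i-th
    order statistic is adjusted to ``min_{j >= i} (m / j) * p_(j)``, capped
    at 1, and results are returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise StatsError(f"family size m={m} smaller than number of tests {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


def correlation_screen(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    m: int | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations over named pairs with joint BH adjustment.

    The family size ``m`` defaults to ``len(pairs)`` and is an explicit
    argument so a partial rerun keeps the full published family.
    """
    for x_name, y_name in pairs:
        for name in (x_name, y_name):
            if name not in table.columns:
                raise StatsError(f"unknown variable {name!r} in correlation screen")
    results = []
    for x_name, y_name in pairs:
        r, p, n = pearson(table[x_name], table[y_name])
        results.append(CorrelationResult(x_name=x_name, y_name=y_name,
                                         r=r, n=n, p_raw=p))
    m = m if m is not None else len(pairs)
    adj = bh_adjust([res.p_raw for res in results], m)
    for res, pa in zip(results, adj):
        res.p_adj = float(pa)
        res.family_size = m
    return results


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k - 1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need >= 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise StatsError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatsError("all values identical: H undefined (tie correction is 0)")
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_test(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
) -> list[tuple]:
    """Dunn's post hoc pairwise z tests on pooled ranks, BH-adjusted.

    For groups i, j with mean pooled ranks Ri, Rj out of N observations:

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/ni + 1/nj))

    where T = sum(t^3 - t) over tied-value multiplicities t.  Two-sided
    normal p values are BH-adjusted within the all-pairs family.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise StatsError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if np.all(pooled == pooled[0]):
        raise StatsError("all values identical: Dunn z undefined")
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    tie = _tie_term(pooled)
    var_core = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_core * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append([labels[i], labels[j], float(z), float(p)])
    adj = bh_adjust([r[3] for r in rows])
    return [tuple(r + [float(a)]) for r, a in zip(rows, adj)]


def group_comparison(
    values: pd.Series | np.ndarray,
    group_labels: pd.Series | np.ndarray,
) -> GroupComparisonResult:
    """Kruskal-Wallis global test plus Dunn pairwise follow-up."""
    df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                       "g": np.asarray(group_labels)}).dropna()
    labels = sorted(df["g"].unique())
    groups = [df.loc[df["g"] == lab, "v"].to_numpy() for lab in labels]
    H, p = kruskal_wallis(groups)
    pairwise = dunn_test(groups, labels)
    return GroupComparisonResult(
        groups=[(lab, len(g)) for lab, g in zip(labels, groups)],
        H=H, p_global=p, pairwise=pairwise,
    )


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    X = covariates.astype(float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy()]))
    if rank < X.shape[1] + 1:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax() if X.shape[1] > 1 else X.columns[0]
        raise StatsError(
            f"rank-deficient design matrix (collinear term near {worst!r})"
        )
    return sm.add_constant(X, has_constant="add")


def linear_fit(y, covariates: pd.DataFrame, outcome: str = "y") -> RegressionResult:
    """OLS with normal-theory 95% CIs, listwise-complete cases."""
    df = covariates.copy()
    df["__y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    if len(df) <= covariates.shape[1] + 1:
        raise StatsError("not enough complete cases for the linear model")
    X = _design_matrix(df.drop(columns="__y"))
    fit = sm.OLS(df["__y"], X).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = [(name, float(fit.params[name]), float(ci.loc[name, 0]),
              float(ci.loc[name, 1]), float(fit.pvalues[name]))
             for name in fit.params.index]
    return RegressionResult(model="linear", outcome=outcome, terms=terms, n=len(df))


def logistic_fit(y, covariates: pd.DataFrame, outcome: str = "y") -> RegressionResult:
    """Maximum-likelihood logit with Wald 95% CIs.

    Newton iterations to tolerance 1e-8 (max 100); perfect separation or a
    single-class outcome raises with a diagnostic rather than returning
    divergent coefficients.
    """
    df = covariates.copy()
    df["__y"] = np.asarray(y, dtype=float)
    df = df.dropna()
    classes = set(df["__y"].unique())
    if not classes <= {0.0, 1.0}:
        raise StatsError("logistic outcome must be coded 0/1")
    if len(classes) < 2:
        raise StatsError("logistic outcome has a single class")
    X = _design_matrix(df.drop(columns="__y"))
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(df["__y"], X).fit(method="newton", maxiter=100,
                                             tol=1e-8, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise StatsError(f"logistic fit failed (separation?): {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise StatsError("logistic fit did not converge (perfect separation?)")
    ci = fit.conf_int(alpha=0.05)
    terms = [(name, float(fit.params[name]), float(ci.loc[name, 0]),
              float(ci.loc[name, 1]), float(fit.pvalues[name]))
             for name in fit.params.index]
    return RegressionResult(model="logistic", outcome=outcome, terms=terms, n=len(df))


def smd(group_a, group_b, kind: str = "continuous", variable: str = "") -> SMDResult:
    """Standardized mean difference with a large-sample 95% CI.

    continuous: (mean_a - mean_b) / pooled SD, equal-weight two-group
    pooling; binary: (p_a - p_b) / sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2).
    The CI uses the standard large-sample SMD variance
    1/n_a + 1/n_b + smd^2 / (2 (n_a + n_b)).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise StatsError("both groups need n >= 2")
    if kind == "continuous":
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        if sp == 0:
            raise StatsError("zero pooled SD: SMD undefined")
        d = (a.mean() - b.mean()) / sp
    elif kind == "binary":
        pa, pb = a.mean(), b.mean()
        denom = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        if denom == 0:
            raise StatsError("degenerate proportions: SMD undefined")
        d = (pa - pb) / denom
    else:
        raise StatsError(f"unknown SMD kind {kind!r}")
    se = np.sqrt(1.0 / na + 1.0 / nb + d**2 / (2.0 * (na + nb)))
    z = sps.norm.ppf(0.975)
    return SMDResult(variable=variable, smd=float(d),
                     ci_low=float(d - z * se), ci_high=float(d + z * se))
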