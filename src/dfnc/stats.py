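"""Group-level statistical battery for paired two-group designs.

Mirrors the analysis plan of a paired OFF/ON, two-group (LID / NoLID)
study: Lilliefors-corrected Kolmogorov-Smirnov normality gate, two-sample
t or Mann-Whitney U between groups, Wilcoxon signed-rank within group
across phases, chi-squared for categorical tables, and covariate-adjusted
(partial) Spearman correlation between temporal metrics and symptom
severity, with Benjamini-Hochberg FDR across states within each metric
and contrast.

Exact small-sample paths are enumerated directly (all group assignments
for Mann-Whitney, all sign patterns for Wilcoxon) so that ties are
handled exactly; large samples use the standard normal approximations
with tie correction via scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

EXACT_MW_MAX_N = 20  # combined-sample bound for exact Mann-Whitney
EXACT_WILCOXON_MAX_N = 15  # nonzero-difference bound for exact Wilcoxon


@dataclass
class ComparisonResult:
    metric: str
    state: int | None
    contrast: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class CorrelationResult:
    metric: str
    state: int | None
    rho: float
    p_value: float
    n: int
    covariates: tuple
    significant_fdr: bool | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not -1 <= self.rho <= 1:
            raise ValueError("rho outside [-1, 1]")


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def normality_test(sample) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality with estimated mean/SD (Lilliefors)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.std(x) == 0:
        raise ValueError("sample has zero variance")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def _mw_u_statistic(pooled_ranks: np.ndarray, idx_a, n_a: int) -> float:
    r_a = pooled_ranks[list(idx_a)].sum()
    return r_a - n_a * (n_a + 1) / 2.0


def mannwhitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group assignments.

    Handles ties via midranks; p = P(|U - mu| >= |U_obs - mu|) over all
    C(n_a + n_b, n_a) equally likely assignments.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _mw_u_statistic(ranks, range(n_a), n_a)
    mu = n_a * n_b / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for comb in combinations(range(n_a + n_b), n_a):
        u = _mw_u_statistic(ranks, comb, n_a)
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def wilcoxon_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank over all 2^n sign patterns.

    ``diffs`` must be nonzero; |d| ties handled via midranks.
    """
    d = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    mu = ranks.sum() / 2.0
    dev = abs(w_obs - mu)
    # all sign patterns at once: (2^n, n) boolean matrix @ ranks
    patterns = (
        np.arange(2**n)[:, None] >> np.arange(n)[None, :]
    ) & 1
    w_all = patterns @ ranks
    p = float(np.mean(np.abs(w_all - mu) >= dev - 1e-12))
    return float(w_obs), p


def compare_between(a, b, metric: str = "", state: int | None = None,
                    contrast: str = "", force_test: str | None = None,
                    normality_alpha: float = 0.05) -> ComparisonResult:
    """Two-sample comparison: t-test when both arms pass normality, else
    Mann-Whitney U (exact by enumeration when combined n <= 20)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be nonempty")
    if force_test is None:
        try:
            normal = (
                normality_test(a)[1] > normality_alpha
                and normality_test(b)[1] > normality_alpha
            )
        except ValueError:  # tiny or constant arm: never call it normal
            normal = False
        test = "t" if normal else "mannwhitney"
    else:
        test = force_test
    if test == "t":
        stat, p = sps.ttest_ind(a, b)
        return ComparisonResult(metric, state, contrast, "t",
                                float(stat), float(p), len(a), len(b))
    if test != "mannwhitney":
        raise ValueError(f"unknown test {test!r}")
    if len(a) + len(b) <= EXACT_MW_MAX_N:
        stat, p = mannwhitney_exact(a, b)
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(metric, state, contrast, "mannwhitney",
                            stat, min(p, 1.0), len(a), len(b))


def compare_within(off, on, metric: str = "", state: int | None = None,
                   contrast: str = "") -> ComparisonResult:
    """Paired OFF-to-ON comparison by Wilcoxon signed-rank.

    Zero differences are dropped; the null distribution is enumerated
    exactly for up to 15 nonzero differences.  An all-zero difference
    vector is flagged degenerate with p = 1.
    """
    off, on = np.asarray(off, float), np.asarray(on, float)
    if off.shape != on.shape:
        raise ValueError("paired arms must have equal length")
    d = on - off
    d = d[d != 0]
    if d.size == 0:
        return ComparisonResult(metric, state, contrast, "wilcoxon",
                                0.0, 1.0, len(off), len(on), degenerate=True)
    if d.size < 3:
        raise ValueError("need >= 3 nonzero differences")
    if d.size <= EXACT_WILCOXON_MAX_N:
        stat, p = wilcoxon_exact(d)
    else:
        res = sps.wilcoxon(d, alternative="two-sided", method="approx",
                           correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(metric, state, contrast, "wilcoxon",
                            stat, min(p, 1.0), len(off), len(on))


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def partial_spearman(x, y, covariates=None, metric: str = "",
                     state: int | None = None,
                     covariate_names: tuple = ()) -> CorrelationResult:
    """Covariate-adjusted Spearman correlation via rank residuals.

    All variables are rank-transformed; covariate ranks (plus intercept)
    are removed from x and y by least squares, and the Pearson correlation
    of the residuals is tested against a t reference with
    df = n - 2 - n_covariates.  With no covariates this is exactly the
    ordinary Spearman correlation.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant variable in correlation")
    Z = None
    n_cov = 0
    if covariates is not None:
        Z = np.atleast_2d(np.asarray(covariates, float))
        if Z.shape[0] == n and Z.shape[1] != n:
            pass
        elif Z.shape[1] == n:
            Z = Z.T
        n_cov = Z.shape[1]
    if n <= n_cov + 3:
        raise ValueError("too few observations for the requested adjustment")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if Z is not None and n_cov > 0:
        rz = np.column_stack(
            [np.ones(n)] + [sps.rankdata(Z[:, j]) for j in range(n_cov)]
        )
        rx = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
        ry = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    sx, sy = np.std(rx), np.std(ry)
    if sx < 1e-10 * max(1.0, np.std(sps.rankdata(x))) or sy < 1e-10 * max(
        1.0, np.std(sps.rankdata(y))
    ):
        # x or y fully explained by the covariates
        return CorrelationResult(metric, state, 0.0, 1.0, n,
                                 covariate_names, degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 2 - n_cov
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(metric, state, rho, p, n, covariate_names)


def fdr_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, significance flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

_COVARIATES = ("age_at_onset", "ledd", "disease_duration")
_STATE_METRICS = ("fractional_windows", "mean_dwell_time")


def run_full_comparison(metrics: pd.DataFrame, subjects: pd.DataFrame,
                        alpha: float = 0.05,
                        force_between: str | None = None) -> dict:
    """All contrast families plus severity correlations, FDR-adjusted.

    ``metrics`` is the long-format table from
    :func:`dfnc.metrics.metrics_table`; ``subjects`` the cohort subject
    table.  Contrasts: LID vs NoLID at OFF and at ON (Mann-Whitney / t),
    OFF vs ON within each group (Wilcoxon), for fractional windows, mean
    dwell time (per state) and the transition count; then AIMS
    correlations (partial Spearman adjusted for age at onset, LEDD, and
    disease duration) in the LID group's ON phase, FDR across states
    within each metric.

    Returns {"comparisons": DataFrame, "correlations": DataFrame,
    "n_dropped": int}.
    """
    have_both = (
        metrics.groupby("subject")["phase"].nunique().pipe(lambda s: s[s == 2]).index
    )
    dropped = metrics["subject"].nunique() - len(have_both)
    if dropped:
        warnings.warn(f"dropping {dropped} subject(s) without both phases")
    m = metrics[metrics["subject"].isin(have_both)].merge(
        subjects, on="subject", how="inner"
    )
    k = int(m["state"].max())

    comp_rows = []

    def add(res: ComparisonResult):
        comp_rows.append(res)

    for metric in _STATE_METRICS:
        for phase in ("OFF", "ON"):
            sub = m[(m["phase"] == phase)]
            for s in range(1, k + 1):
                a = sub[(sub["group"] == "LID") & (sub["state"] == s)][metric]
                b = sub[(sub["group"] == "NoLID") & (sub["state"] == s)][metric]
                add(compare_between(a, b, metric, s, f"LIDvsNoLID@{phase}",
                                    force_test=force_between))
        for group in ("LID", "NoLID"):
            sub = m[m["group"] == group]
            for s in range(1, k + 1):
                wide = sub[sub["state"] == s].pivot(
                    index="subject", columns="phase", values=metric
                ).dropna()
                try:
                    res = compare_within(wide["OFF"], wide["ON"], metric, s,
                                         f"OFFvsON@{group}")
                except ValueError:  # < 3 nonzero differences
                    res = ComparisonResult(metric, s, f"OFFvsON@{group}",
                                           "wilcoxon", 0.0, 1.0, len(wide),
                                           len(wide), degenerate=True)
                add(res)

    # transition count: one value per session
    trans = m.drop_duplicates(["subject", "phase"])[
        ["subject", "phase", "group", "n_transitions"]
    ]
    for phase in ("OFF", "ON"):
        sub = trans[trans["phase"] == phase]
        add(compare_between(
            sub[sub["group"] == "LID"]["n_transitions"],
            sub[sub["group"] == "NoLID"]["n_transitions"],
            "n_transitions", None, f"LIDvsNoLID@{phase}",
            force_test=force_between,
        ))
    for group in ("LID", "NoLID"):
        wide = trans[trans["group"] == group].pivot(
            index="subject", columns="phase", values="n_transitions"
        ).dropna()
        try:
            res = compare_within(wide["OFF"], wide["ON"], "n_transitions",
                                 None, f"OFFvsON@{group}")
        except ValueError:
            res = ComparisonResult("n_transitions", None, f"OFFvsON@{group}",
                                   "wilcoxon", 0.0, 1.0, len(wide), len(wide),
                                   degenerate=True)
        add(res)

    comparisons = pd.DataFrame([vars(r) for r in comp_rows])
    # FDR family: the k states within one metric within one contrast
    comparisons["p_fdr"] = np.nan
    comparisons["significant_fdr"] = False
    for (_, _), idx in comparisons.groupby(["metric", "contrast"]).groups.items():
        p_adj, rej = fdr_adjust(comparisons.loc[idx, "p_value"].to_numpy(), alpha)
        comparisons.loc[idx, "p_fdr"] = p_adj
        comparisons.loc[idx, "significant_fdr"] = rej

    # severity correlations: LID group, ON phase
    lid_on = m[(m["group"] == "LID") & (m["phase"] == "ON")
               & np.isfinite(m["aims"])]
    corr_rows = []
    for metric in _STATE_METRICS:
        fam = []
        for s in range(1, k + 1):
            sub = lid_on[lid_on["state"] == s]
            cov = sub[list(_COVARIATES)].to_numpy()
            try:
                res = partial_spearman(sub[metric], sub["aims"], cov,
                                       metric, s, _COVARIATES)
            except ValueError:
                res = CorrelationResult(metric, s, 0.0, 1.0, len(sub),
                                        _COVARIATES, degenerate=True)
            fam.append(res)
        p_adj, rej = fdr_adjust([r.p_value for r in fam], alpha)
        for r, pa, rj in zip(fam, p_adj, rej):
            r.significant_fdr = bool(rj)
            row = vars(r).copy()
            row["p_fdr"] = pa
            corr_rows.append(row)
    t_on = trans[trans["group"] == "LID"].merge(subjects, on="subject")
    t_on = t_on[(t_on["phase"] == "ON") & np.isfinite(t_on["aims"])]
    try:
        res = partial_spearman(
            t_on["n_transitions"], t_on["aims"],
            t_on[list(_COVARIATES)].to_numpy(), "n_transitions", None,
            _COVARIATES,
        )
    except ValueError:
        res = CorrelationResult("n_transitions", None, 0.0, 1.0, len(t_on),
                                _COVARIATES, degenerate=True)
    row = vars(res).copy()
    row["p_fdr"] = res.p_value
    row["significant_fdr"] = bool(res.p_value < alpha)
    corr_rows.append(row)

    return {
        "comparisons": comparisons,
        "correlations": pd.DataFrame(corr_rows),
        "n_dropped": int(dropped),
    }
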