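"""Statistical core: covariates, logistic burden tests, carrier excess,
multiple-testing correction and constraint comparison.

The burden test is a logistic regression of case/control status on a
per-sample aggregate of rare tandem-repeat expansions (a count, or a
base-pair total) plus nuisance covariates: sex, selected principal
components of the normalised anchored in-repeat-read (IRR) matrix, and —
for tests restricted to a target annotation — the sample's global
intergenic burden.  The reported effect is the odds ratio per unit burden
with a Wald 95% confidence interval.  Under (near-)separation the fit is
repeated with Firth's penalised likelihood and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
from statsmodels.api import Logit, OLS
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import ConfigError, DegenerateDataError

Z95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# IRR normalisation and principal components


def normalize_irr(irr: pd.DataFrame, depths: pd.Series) -> pd.DataFrame:
    """Depth-normalise an anchored in-repeat-read count matrix.

    Each sample's counts are rescaled by (median cohort depth / sample
    depth), so equal depths leave the matrix unchanged and a sample at
    twice the median depth has its counts halved.  Invariant to a common
    rescaling of all depths.
    """
    depths = depths.reindex(irr.index)
    if (depths <= 0).any() or depths.isna().any():
        raise ConfigError("depths: must be positive for every sample")
    factor = depths.median() / depths
    return irr.mul(factor, axis=0)


def compute_pcs(matrix: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores of a sample x locus matrix.

    Columns are centred; scores come from the SVD of the centred matrix
    (randomised solver above 200 components of potential rank, exact
    otherwise).  Returns (scores with columns PC1..PCk, explained variance
    ratio, non-increasing).  A constant matrix yields all-zero scores and a
    warning.
    """
    n, m = matrix.shape
    if not 1 <= k <= min(n, m):
        raise ConfigError(f"k: must be in [1, min(n_samples, n_loci)={min(n, m)}]")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if not np.any(X):
        warnings.warn("constant matrix: all PC scores are zero", stacklevel=2)
        scores = np.zeros((n, k))
        evr = np.zeros(k)
    else:
        if min(n, m) > 200:
            from sklearn.decomposition import PCA

            pca = PCA(n_components=k, svd_solver="randomized", random_state=0)
            scores = pca.fit_transform(X)
            evr = pca.explained_variance_ratio_
        else:
            U, S, _ = np.linalg.svd(X, full_matrices=False)
            scores = U[:, :k] * S[:k]
            evr = (S**2 / (S**2).sum())[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), np.asarray(evr)


def select_covariate_pcs(
    pcs: pd.DataFrame,
    reference_burden: pd.Series,
    alpha: float = 0.05,
    override: Sequence[int] | None = None,
) -> list[int]:
    """Indices (1-based) of PCs to use as confounder covariates.

    Default rule: keep every PC nominally associated (per-PC linear
    regression p < alpha) with the genome-wide rare-expansion count.  An
    explicit ``override`` list short-circuits the rule.
    """
    if override is not None:
        k = pcs.shape[1]
        bad = [i for i in override if not 1 <= i <= k]
        if bad:
            raise ConfigError(f"pc override: indices {bad} outside 1..{k}")
        return sorted(set(int(i) for i in override))
    y = reference_burden.reindex(pcs.index).to_numpy(dtype=float)
    selected = []
    for i, col in enumerate(pcs.columns, start=1):
        x = pcs[col].to_numpy()
        if np.ptp(x) == 0:
            continue
        res = sps.linregress(x, y)
        if res.pvalue < alpha:
            selected.append(i)
    return selected


# ---------------------------------------------------------------------------
# logistic burden test


@dataclass
class BurdenResult:
    """One burden test: effect of per-sample burden on case status."""

    target: str
    burden_type: str  # "count" or "bp"
    n_cases: int
    n_controls: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    separation: bool
    converged: bool
    family: str | None = None
    p_bh: float | None = None


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalised logistic regression (Jeffreys-prior score correction).

    Newton iteration on the modified score U*(b) = X'(y - p + h(1/2 - p)),
    h the leverages of the weighted design.  Returns (beta, cov).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        XW = X * w[:, None]
        F = X.T @ XW
        Finv = np.linalg.pinv(F)
        # leverages of sqrt(W) X
        h = np.einsum("ij,jk,ik->i", X, Finv, XW)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Finv @ U
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = expit(eta)
    w = p * (1.0 - p)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


def burden_test(
    labels: Sequence[int] | pd.Series,
    burden: Sequence[float] | pd.Series,
    covariates: pd.DataFrame | None = None,
    target: str = "burden",
    burden_type: str = "count",
) -> BurdenResult:
    """Logistic burden test of case/control status on a per-sample burden.

    Model: label ~ burden + covariates (caller supplies sex, selected PCs
    and, for target-region tests, the global intergenic burden as columns
    of ``covariates``).  Wald 95% CI and p-value for the burden odds
    ratio.  Separation (non-convergence or |beta| > 10) triggers a Firth
    refit, flagged in the result.
    """
    y = np.asarray(labels, dtype=float)
    b = np.asarray(burden, dtype=float)
    if not np.all(np.isfinite(b)):
        raise DegenerateDataError("burden: non-finite values")
    if y.min() == y.max():
        raise DegenerateDataError("labels: need at least one case and one control")
    if np.ptp(b) == 0:
        raise DegenerateDataError(f"burden {target!r} constant across samples")
    cols = [np.ones_like(b), b]
    names = ["const", "burden"]
    if covariates is not None:
        for c in covariates.columns:
            col = np.asarray(covariates[c], dtype=float)
            if np.ptp(col) > 0:
                cols.append(col)
                names.append(c)
    X = np.column_stack(cols)

    beta = se = None
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = Logit(y, X).fit(disp=0, maxiter=100)
            converged = bool(fit.mle_retvals.get("converged", True))
            beta = fit.params[1]
            se = fit.bse[1]
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged = False
    if (
        beta is None
        or not converged
        or not np.isfinite(beta)
        or not np.isfinite(se)
        or abs(beta) > 10
        or se > 50
    ):
        separation = True
        params, cov = _firth_logit(X, y)
        beta = params[1]
        var = float(cov[1, 1])
        # singular information (e.g. a near-empty burden column): report an
        # uninformative interval rather than a spurious one
        se = float(np.sqrt(var)) if np.isfinite(var) and var > 0 else np.inf
        converged = True
    z = beta / se if np.isfinite(se) else 0.0
    p = float(2 * sps.norm.sf(abs(z)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return BurdenResult(
        target=target,
        burden_type=burden_type,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=p,
        beta=float(beta),
        se=float(se),
        separation=separation,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# multiple testing, rank tests


def bh_adjust(pvals: Sequence[float], family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ConfigError("pvals: must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Exact enumeration when n_x + n_y <= 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    ``alternative='less'`` means x tends to be smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# carrier excess and constraint comparison


@dataclass
class CarrierExcessResult:
    """Confounder-adjusted carrier proportions in cases vs controls."""

    proportion_cases: float
    proportion_controls: float
    excess: float
    p: float
    threshold: float
    n_cases: int
    n_controls: int


def carrier_excess(
    counts: pd.Series,
    labels: Sequence[int] | pd.Series,
    covariates: pd.DataFrame | None = None,
    threshold: float = 0.5,
) -> CarrierExcessResult:
    """Adjusted proportion of samples carrying rare expansions, by group.

    Rare-expansion counts are regressed (ordinary least squares, pooled over
    cases and controls; case status itself is never a covariate) on the
    confounders; a sample is an adjusted carrier when its residual is at
    least ``threshold`` (default 0.5 ~ at least one excess expansion after
    adjustment).  The case/control difference in residuals is tested with
    the Wilcoxon rank-sum test.
    """
    y = counts.to_numpy(dtype=float)
    lab = np.asarray(labels, dtype=int)
    X = [np.ones_like(y)]
    if covariates is not None:
        if "label" in covariates.columns or "case" in covariates.columns:
            raise ConfigError("covariates: must exclude case status")
        for c in covariates.columns:
            col = np.asarray(covariates[c], dtype=float)
            if np.ptp(col) > 0:
                X.append(col)
    X = np.column_stack(X)
    resid = OLS(y, X).fit().resid
    carrier = resid >= threshold
    case, ctrl = lab == 1, lab == 0
    prop_cases = float(carrier[case].mean())
    prop_controls = float(carrier[ctrl].mean())
    _, p = wilcoxon_rank_sum(resid[case], resid[ctrl], alternative="two-sided")
    return CarrierExcessResult(
        proportion_cases=prop_cases,
        proportion_controls=prop_controls,
        excess=prop_cases - prop_controls,
        p=p,
        threshold=threshold,
        n_cases=int(case.sum()),
        n_controls=int(ctrl.sum()),
    )


@dataclass
class ConstraintCompareResult:
    p: float
    statistic: float
    median_with: float
    median_without: float
    n_with: int
    n_without: int


def constraint_compare(
    genes_with_tre: Sequence[str],
    genes_without_tre: Sequence[str],
    scores: Mapping[str, float],
    subset: Sequence[str] | None = None,
) -> ConstraintCompareResult:
    """One-sided rank-sum comparison of constraint scores (LOEUF-style).

    Alternative: genes carrying rare expansions have *lower* scores (are
    more constrained) than genes without.  ``subset`` restricts both groups
    (e.g. to a differentially-expressed gene list) before testing.
    """
    if subset is not None:
        allowed = set(subset)
        genes_with_tre = [g for g in genes_with_tre if g in allowed]
        genes_without_tre = [g for g in genes_without_tre if g in allowed]
    a = [scores[g] for g in genes_with_tre if g in scores]
    b = [scores[g] for g in genes_without_tre if g in scores]
    if not a or not b:
        raise DegenerateDataError("no scored genes in one of the groups")
    stat, p = wilcoxon_rank_sum(a, b, alternative="less")
    return ConstraintCompareResult(
        p=p,
        statistic=stat,
        median_with=float(np.median(a)),
        median_without=float(np.median(b)),
        n_with=len(a),
        n_without=len(b),
    )
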