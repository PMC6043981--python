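"""Validation statistics for internode trait tables.

The trait table is long-format with one row per (genotype, plant, internode)
observation.  The fixed-effects model is

    y_ijk = mu + g_i + i(g)_ij + e_ijk

with genotype and internode-within-genotype effects; genotype LS means are
the unweighted averages of the genotype's cell (genotype x internode) means.
For repeatability the same model is refit with all terms random and the
variance components estimated by REML (numeric profile likelihood over the
variance ratios, with the residual variance profiled out); repeatability on
a plot-mean basis is

    H^2 = sigma_G^2 / (sigma_G^2 + sigma_E^2).

The module also provides Pearson correlation matrices over LS means,
univariate regression validated by leave-one-out cross-validation (each
fold's RMSE reduces to the absolute prediction error of its single held-out
point), and the 50%-cutoff quadrant classification accuracy used to judge a
predictor as a selection tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sps
import statsmodels.api as sm

__all__ = [
    "LsMeansResult",
    "RepeatabilityResult",
    "CrossValidationResult",
    "ls_means",
    "repeatability",
    "pearson_matrix",
    "loocv_univariate",
    "quadrant_accuracy",
]


# ---------------------------------------------------------------------------
# LS means
# ---------------------------------------------------------------------------


@dataclass
class LsMeansResult:
    trait: str
    table: pd.DataFrame  # genotype, ls_mean, se, n_obs, n_cells
    sigma2: float
    warnings: list[str] = field(default_factory=list)


def ls_means(
    table: pd.DataFrame,
    trait: str = "value",
    genotype_col: str = "genotype",
    internode_col: str = "internode",
) -> LsMeansResult:
    """Genotype LS means and standard errors under the nested fixed model.

    Fits the cell-means parameterisation of
    ``y = mu + genotype + internode(genotype)`` by OLS; each genotype's LS
    mean is the unweighted average of its cell means, so with balanced data
    it equals the arithmetic genotype mean.  Genotypes whose internode
    coverage is incomplete relative to the rest of the table are reported in
    ``warnings`` (their LS mean averages only the observed cells).
    """
    df = table.dropna(subset=[trait])
    genos = sorted(df[genotype_col].unique())
    if len(genos) < 2:
        raise ValueError("LS means need at least two genotypes")
    cell = df[genotype_col].astype(str) + "\x1f" + df[internode_col].astype(str)
    dummies = pd.get_dummies(cell, dtype=float)
    fit = sm.OLS(df[trait].to_numpy(float), dummies.to_numpy()).fit()
    cov = fit.cov_params()
    cell_names = list(dummies.columns)
    cell_geno = [c.split("\x1f")[0] for c in cell_names]

    max_cells = max(pd.Series(cell_geno).value_counts())
    rows, warns = [], []
    for g in genos:
        idx = [i for i, cg in enumerate(cell_geno) if cg == str(g)]
        L = np.zeros(len(cell_names))
        L[idx] = 1.0 / len(idx)
        se = float(np.sqrt(L @ cov @ L))
        if len(idx) < max_cells:
            warns.append(
                f"genotype {g}: only {len(idx)} internode cell(s); LS mean "
                "averages the observed cells"
            )
        rows.append(
            {
                "genotype": g,
                "ls_mean": float(L @ fit.params),
                "se": se,
                "n_obs": int((df[genotype_col] == g).sum()),
                "n_cells": len(idx),
            }
        )
    return LsMeansResult(
        trait=trait,
        table=pd.DataFrame(rows),
        sigma2=float(fit.scale),
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# REML repeatability
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    trait: str
    sigma_g2: float
    sigma_ig2: float
    sigma_e2: float
    h2: float
    n_genotypes: int
    method: str  # "reml" or "mom"


def _group_blocks(
    df: pd.DataFrame, trait: str, genotype_col: str, internode_col: str
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-genotype (y, internode-dummy) blocks for the nested model."""
    blocks = []
    for _, sub in df.groupby(genotype_col, sort=True):
        y = sub[trait].to_numpy(float)
        z = pd.get_dummies(sub[internode_col]).to_numpy(float)
        blocks.append((y, z))
    return blocks


def _neg2_reml(
    log_gammas: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]]
) -> float:
    gg, gi = np.exp(log_gammas)
    n = sum(len(y) for y, _ in blocks)
    logdet_w = 0.0
    a = 0.0
    b = 0.0
    solves = []
    for y, z in blocks:
        m = len(y)
        w = np.eye(m) + gg * np.ones((m, m)) + gi * (z @ z.T)
        c, low = linalg.cho_factor(w, check_finite=False)
        logdet_w += 2.0 * float(np.sum(np.log(np.diag(c))))
        wi_1 = linalg.cho_solve((c, low), np.ones(m), check_finite=False)
        wi_y = linalg.cho_solve((c, low), y, check_finite=False)
        a += float(wi_1.sum())
        b += float(wi_1 @ y)
        solves.append((y, wi_1, wi_y))
    beta = b / a
    q = 0.0
    for y, wi_1, wi_y in solves:
        r_wi_r = float(y @ wi_y) - 2 * beta * float(wi_1 @ y) + beta**2 * float(wi_1.sum())
        q += r_wi_r
    q = max(q, 1e-300)
    return (n - 1) * np.log(q / (n - 1)) + logdet_w + np.log(a)


def _mom_components(
    df: pd.DataFrame, trait: str, genotype_col: str, internode_col: str
) -> tuple[float, float, float]:
    """ANOVA (expected-mean-squares) estimators; exact REML match for
    balanced data when all estimates are non-negative."""
    grand = df[trait].mean()
    gmeans = df.groupby(genotype_col)[trait].mean()
    cmeans = df.groupby([genotype_col, internode_col])[trait].mean()
    counts = df.groupby([genotype_col, internode_col])[trait].count()
    a = len(gmeans)
    nbar = float(counts.mean())
    bbar = float(counts.groupby(level=0).count().mean())
    ms_g = (
        float(((gmeans - grand) ** 2 * df.groupby(genotype_col)[trait].count()).sum())
        / max(a - 1, 1)
    )
    within_g = cmeans - gmeans.reindex(cmeans.index.get_level_values(0)).to_numpy()
    df_w = max(len(cmeans) - a, 1)
    ms_w = float(((within_g**2) * counts).sum()) / df_w
    cell_of = df.set_index([genotype_col, internode_col]).index
    resid = df[trait].to_numpy(float) - cmeans.reindex(cell_of).to_numpy()
    df_e = max(len(df) - len(cmeans), 1)
    ms_e = float((resid**2).sum()) / df_e
    s_e2 = ms_e
    s_w2 = max((ms_w - ms_e) / nbar, 0.0)
    s_g2 = max((ms_g - ms_w) / (nbar * bbar), 0.0)
    return s_g2, s_w2, s_e2


def repeatability(
    table: pd.DataFrame,
    trait: str = "value",
    genotype_col: str = "genotype",
    internode_col: str = "internode",
) -> RepeatabilityResult:
    """Variance components and repeatability of a trait.

    All model terms are random; (sigma_G^2, sigma_IG^2, sigma_E^2) are
    estimated by REML with the two variance ratios optimised numerically
    and the residual variance profiled out.  Negative components are
    truncated at zero.  If the optimiser fails the ANOVA method-of-moments
    estimates are returned, tagged ``"mom"``.
    """
    df = table.dropna(subset=[trait])
    genos = df[genotype_col].unique()
    if len(genos) < 3:
        raise ValueError("repeatability needs at least three genotypes")
    if df.groupby([genotype_col, internode_col])[trait].count().max() < 2:
        raise ValueError("repeatability needs replication within cells")

    mom = _mom_components(df, trait, genotype_col, internode_col)
    blocks = _group_blocks(df, trait, genotype_col, internode_col)
    n = sum(len(y) for y, _ in blocks)

    x0 = np.log(
        np.clip([mom[0] / max(mom[2], 1e-8), mom[1] / max(mom[2], 1e-8)], 1e-6, 1e6)
    )
    try:
        res = optimize.minimize(
            _neg2_reml,
            x0,
            args=(blocks,),
            method="L-BFGS-B",
            bounds=[(-18.0, 18.0)] * 2,
        )
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(res.message)
        gg, gi = np.exp(res.x)
        # recompute profiled residual variance at the optimum
        s_e2 = _profiled_sigma_e2(res.x, blocks, n)
        s_g2 = gg * s_e2 if gg > 1e-7 else 0.0
        s_ig2 = gi * s_e2 if gi > 1e-7 else 0.0
        method = "reml"
    except Exception:
        s_g2, s_ig2, s_e2 = mom
        method = "mom"
    h2 = s_g2 / (s_g2 + s_e2) if (s_g2 + s_e2) > 0 else 0.0
    return RepeatabilityResult(
        trait=trait,
        sigma_g2=float(s_g2),
        sigma_ig2=float(s_ig2),
        sigma_e2=float(s_e2),
        h2=float(np.clip(h2, 0.0, 1.0)),
        n_genotypes=len(genos),
        method=method,
    )


def _profiled_sigma_e2(
    log_gammas: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]], n: int
) -> float:
    gg, gi = np.exp(log_gammas)
    a = b = 0.0
    solves = []
    for y, z in blocks:
        m = len(y)
        w = np.eye(m) + gg * np.ones((m, m)) + gi * (z @ z.T)
        c = linalg.cho_factor(w, check_finite=False)
        wi_1 = linalg.cho_solve(c, np.ones(m), check_finite=False)
        wi_y = linalg.cho_solve(c, y, check_finite=False)
        a += float(wi_1.sum())
        b += float(wi_1 @ y)
        solves.append((y, wi_1, wi_y))
    beta = b / a
    q = sum(
        float(y @ wi_y) - 2 * beta * float(wi_1 @ y) + beta**2 * float(wi_1.sum())
        for y, wi_1, wi_y in solves
    )
    return q / (n - 1)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def pearson_matrix(
    means: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and two-sided p-values) across traits.

    ``means`` has one row per genotype and one column per trait (typically
    LS means).  Constant traits yield NaN entries.  Returns ``(r, p)``.
    """
    if len(means) < 3:
        raise ValueError("correlations need at least three genotypes")
    traits = list(means.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = means[traits[i]].to_numpy(float)
            y = means[traits[j]].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------


@dataclass
class CrossValidationResult:
    model: str
    fold_rmse: np.ndarray  # |y_k - yhat_k| per held-out point
    predictions: np.ndarray
    mean_rmse: float
    min_rmse: float
    pooled_rmse: float  # sqrt(mean of squared fold errors)
    intercept: float
    slope: float
    r2: float


def loocv_univariate(
    x: np.ndarray, y: np.ndarray, model_name: str = "y = x"
) -> CrossValidationResult:
    """Leave-one-out cross-validation of the simple regression y ~ x.

    Each fold fits on the n-1 remaining points and predicts the single
    held-out observation; with one test point the fold RMSE is the absolute
    prediction error.  Both the mean of the fold RMSEs and the pooled RMSE
    (square root of the mean squared fold error) are reported, along with
    the coefficients and R^2 of the fit to all points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("LOOCV needs at least three observations")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")

    preds = np.empty(n)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        fit = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
        preds[k] = fit.params[0] + fit.params[1] * x[k]
    fold = np.abs(y - preds)

    full = sm.OLS(y, sm.add_constant(x)).fit()
    return CrossValidationResult(
        model=model_name,
        fold_rmse=fold,
        predictions=preds,
        mean_rmse=float(fold.mean()),
        min_rmse=float(fold.min()),
        pooled_rmse=float(np.sqrt((fold**2).mean())),
        intercept=float(full.params[0]),
        slope=float(full.params[1]),
        r2=float(full.rsquared),
    )


# ---------------------------------------------------------------------------
# quadrant classification
# ---------------------------------------------------------------------------


def quadrant_accuracy(
    observed: np.ndarray,
    predicted: np.ndarray,
    cutoff_mode: str = "range_midpoint",
) -> float:
    """Fraction of points on which predicted and observed agree about the
    50% cutoff.

    A cutoff at 50% of each axis's scale (midpoint of the observed range by
    default, or the median) splits the observed-vs-predicted plane into four
    quadrants; points in the two agreeing quadrants (both values above, or
    both below, their cutoffs) count as correctly classified.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) == 0:
        raise ValueError("observed and predicted must be equal-length 1-D arrays")
    if cutoff_mode == "range_midpoint":
        co = (obs.min() + obs.max()) / 2.0
        cp = (pred.min() + pred.max()) / 2.0
        if obs.min() == obs.max() or pred.min() == pred.max():
            raise ValueError("degenerate range; cannot place a 50% cutoff")
    elif cutoff_mode == "median":
        co, cp = float(np.median(obs)), float(np.median(pred))
    else:
        raise ValueError("cutoff_mode must be range_midpoint or median")
    agree = (obs > co) == (pred > cp)
    return float(agree.mean())
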