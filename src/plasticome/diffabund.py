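"""Variance-stabilised moderated differential abundance with repeated measures.

The stack mirrors the limma-voom workflow for RNA-seq but is adapted to
sparse 16S count tables:

1. per-sample size factors by the positive-count median-of-ratios rule
   ("poscounts"), robust to tables where every feature contains zeros;
2. a voom-style mean-variance trend on **asinh**-transformed normalised
   counts (``asinh(count / size_factor)``) — the inverse hyperbolic sine is
   defined at zero and log-like for large counts, suiting negative-binomial
   16S data better than log-CPM — yielding per-observation precision weights;
3. a consensus within-subject correlation (repeated daily samples per
   subject form blocks) plugged into per-feature generalised least squares
   with compound-symmetry blocks;
4. empirical-Bayes moderation of residual variances (method-of-moments on
   log s^2 with digamma/trigamma matching) giving moderated t statistics;
5. within-diet contrasts between weight-loss success groups (VS - US), or a
   per-diet slope on continuous percent weight loss, with Benjamini-Hochberg
   control per contrast at alpha = 0.05.

Features enter a contrast only if detected in at least 10% of the subjects
on that diet (subject-level prevalence filter); both diets are fitted
jointly with a diet x outcome design plus a fixed sequencing-lane effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, solve_triangular
from scipy.special import digamma, polygamma
from skbio import TreeNode
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
from statsmodels.stats.multitest import multipletests

from .cohort import phenotype_table
from .io_formats import CohortMetadata
from .phylo_cluster import aggregate_by_cluster, cut_tree, prevalence_filter

__all__ = [
    "VoomFit",
    "DAResult",
    "poscounts_size_factors",
    "voom_asinh",
    "consensus_correlation",
    "fit_moderated",
    "posterior_variance",
    "bh_adjust",
    "run_da",
]

_TREND_FLOOR = 1e-4  # sqrt-SD floor: keeps precision weights finite


def poscounts_size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-positive-ratios size factors for sparse count tables.

    The per-feature reference is the geometric mean of counts over samples
    where the feature is positive; each sample's factor is the median, over
    features positive in that sample, of count/reference.  Factors are
    rescaled to geometric mean 1.  A sample with no positive counts is an
    error.
    """
    counts = table.to_numpy(dtype=float)
    if counts.shape[0] < 1:
        raise ValueError("empty count table")
    positive = counts > 0
    if np.any(~positive.any(axis=1)):
        bad = table.index[~positive.any(axis=1)].tolist()
        raise ValueError(f"samples with no positive counts: {bad}")
    keep = positive.any(axis=0)  # features positive somewhere
    counts = counts[:, keep]
    positive = positive[:, keep]
    logs = np.zeros_like(counts)
    np.log(counts, where=positive, out=logs)
    log_ref = logs.sum(axis=0) / positive.sum(axis=0)
    ref = np.exp(log_ref)
    factors = np.empty(counts.shape[0])
    for i in range(counts.shape[0]):
        ratios = counts[i, positive[i]] / ref[positive[i]]
        factors[i] = np.median(ratios)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.index, name="size_factor")


@dataclass
class VoomFit:
    """Asinh-voom output: transformed matrix, precision weights and trend."""

    y: pd.DataFrame  # features x samples, asinh(count / size_factor)
    weights: pd.DataFrame  # same shape, strictly positive
    trend_x: np.ndarray  # lowess abscissa (feature mean of y)
    trend_y: np.ndarray  # lowess fit of sqrt(residual SD)
    size_factors: pd.Series
    design: pd.DataFrame  # samples x covariate columns
    block: pd.Series | None  # sample -> subject, for repeated measures


def _check_full_rank(X: np.ndarray, columns) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [c for c, d in zip(columns, diag) if d < 1e-8 * diag.max()]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def voom_asinh(
    table: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.DataFrame,
    block: pd.Series | None = None,
) -> VoomFit:
    """Precision weights from a mean-variance trend on asinh counts.

    ``y = asinh(count / size_factor)`` is fitted per feature by OLS against
    the design; a lowess curve (span 0.5, 3 robustifying iterations) of the
    square-root residual SD against the feature mean of ``y`` is interpolated
    at each fitted value (clamped at the trend endpoints) and inverted to the
    fourth power to give observation weights.
    """
    samples = list(table.index)
    X = design.loc[samples].to_numpy(dtype=float)
    _check_full_rank(X, design.columns)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")
    sf = size_factors.loc[samples].to_numpy(dtype=float)
    Y = np.arcsinh(table.to_numpy(dtype=float).T / sf[None, :])  # features x samples

    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    fitted = beta @ X.T
    resid = Y - fitted
    s = np.sqrt((resid**2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(s)
    mean_y = Y.mean(axis=1)

    trend = _lowess(sqrt_sd, mean_y, frac=0.5, it=3, return_sorted=True)
    trend_x, trend_y = trend[:, 0], np.maximum(trend[:, 1], _TREND_FLOOR)
    pred = np.interp(fitted, trend_x, trend_y)  # clamped at endpoints
    W = pred**-4.0

    features = list(table.columns)
    return VoomFit(
        y=pd.DataFrame(Y, index=features, columns=samples),
        weights=pd.DataFrame(W, index=features, columns=samples),
        trend_x=trend_x,
        trend_y=trend_y,
        size_factors=size_factors.loc[samples],
        design=design.loc[samples],
        block=block.loc[samples] if block is not None else None,
    )


def consensus_correlation(vf: VoomFit) -> float:
    """Consensus intra-subject correlation of the voom residuals.

    Each feature's intra-block (compound-symmetry) correlation is estimated
    from weighted-OLS residuals by moment matching.  The naive ratio of the
    mean within-block residual cross-product to the residual variance is
    biased toward zero because residuals are shrunk by the hat-matrix
    projection; with ``P`` the within-block pair indicator and ``H`` the
    feature's (weighted) hat matrix, both moments are linear in rho,

        E[e' P e / 2]  = sigma^2 (c1 + rho * c2) / 2,
        E[e' e]        = sigma^2 ((n - p) + rho * c1),
        c1 = tr(P (I - H)),   c2 = tr(P (I - H) P (I - H)),

    so the observed ratio is inverted for an (approximately) unbiased rho.
    The consensus is ``tanh(10% two-sided trimmed mean of atanh(rho_g))``,
    clipped to (-0.99, 0.99).  With no block of size >= 2 the consensus is
    0, with a warning.
    """
    if vf.block is None:
        warnings.warn("no block structure supplied; consensus correlation = 0", stacklevel=2)
        return 0.0
    blocks = vf.block
    positions = {s: i for i, s in enumerate(vf.y.columns)}
    n = len(positions)
    P = np.zeros((n, n))
    for _, members in blocks.groupby(blocks).groups.items():
        idx = [positions[s] for s in members]
        for k, a in enumerate(idx):
            for b in idx[k + 1 :]:
                P[a, b] = P[b, a] = 1.0
    n_pairs = int(P.sum() / 2)
    if n_pairs == 0:
        warnings.warn("all blocks are singletons; consensus correlation = 0", stacklevel=2)
        return 0.0

    X = vf.design.to_numpy(dtype=float)
    _, p = X.shape
    Y = vf.y.to_numpy()
    W = vf.weights.to_numpy()
    eye = np.eye(n)
    rhos = np.empty(Y.shape[0])
    for f in range(Y.shape[0]):
        sw = np.sqrt(W[f])
        Xs = X * sw[:, None]
        ys = Y[f] * sw
        pinv = np.linalg.pinv(Xs)
        e = ys - Xs @ (pinv @ ys)
        cross = e @ P @ e / 2.0  # sum over within-block pairs
        rss = e @ e
        if rss <= 0:
            rhos[f] = 0.0
            continue
        ieh = eye - Xs @ pinv
        c1 = float(np.sum(P * ieh))
        pb = P @ ieh
        c2 = float(np.sum(pb * pb.T))
        g = cross / n_pairs / (rss / (n - p))
        denom = 2 * n_pairs * g * c1 - (n - p) * c2
        if denom == 0:
            rhos[f] = g
        else:
            rhos[f] = (n - p) * (c1 - 2 * n_pairs * g) / denom
    z = np.arctanh(np.clip(rhos, -0.99, 0.99))
    consensus = float(np.tanh(stats.trim_mean(z, 0.1)))
    return float(np.clip(consensus, -0.99, 0.99))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/y scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes hyperparameters (d0, s0^2) by moment matching.

    Matches mean and variance of ``log s^2`` to the scaled-F prior implied by
    inverse-chi-square variances; falls back to an infinite prior df (pooled
    variance) when the trigamma equation has no positive solution.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if e.size > 1 else 0.0
    target = e_var - polygamma(1, df / 2.0)
    if target > 0:
        d0 = 2.0 * _trigamma_inverse(target)
        s0_sq = np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        warnings.warn(
            "log-variance spread below sampling noise; using pooled variance (d0 = inf)",
            stacklevel=3,
        )
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return float(d0), float(s0_sq)


def posterior_variance(s2, df, d0: float, s0_sq: float):
    """Empirical-Bayes posterior variance ``(d0*s0^2 + df*s^2) / (d0 + df)``.

    ``d0 = 0`` returns the raw variances, ``d0 = inf`` the prior alone.
    """
    s2 = np.asarray(s2, dtype=float)
    if d0 == 0:
        return s2.copy()
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class DAResult:
    """Moderated differential-abundance results, one table per contrast.

    Each table is indexed by feature with columns ``logFC`` (asinh-scale
    contrast estimate), ``t`` (moderated), ``p``, ``adj_p``, ``significant``
    and ``mean_abundance`` (mean asinh-normalised abundance).
    """

    tables: dict[str, pd.DataFrame]
    consensus_rho: float
    d0: float
    s0_sq: float
    residual_df: float
    alpha: float = 0.05
    filtered_features: dict[str, list[str]] = field(default_factory=dict)

    def significant(self, contrast: str) -> pd.DataFrame:
        tab = self.tables[contrast]
        return tab[tab["significant"]]


def fit_moderated(
    vf: VoomFit,
    design: pd.DataFrame | None = None,
    rho: float = 0.0,
    contrasts: dict[str, np.ndarray] | None = None,
    prior_df: float | None = None,
    alpha: float = 0.05,
) -> DAResult:
    """Weighted GLS with compound-symmetry blocks and moderated statistics.

    For each feature, observations are whitened by the Cholesky factor of the
    block correlation matrix at *rho* combined with the feature's precision
    weights, then fitted by least squares.  Residual variances are shrunk
    toward the empirical-Bayes prior (``prior_df`` overrides the estimated
    d0; 0 disables moderation, ``inf`` pools completely) and each contrast is
    reported with a moderated t on ``d + d0`` degrees of freedom.
    """
    design = vf.design if design is None else design
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, design.columns)
    n, p = X.shape
    if contrasts is None:
        contrasts = {
            str(c): np.eye(p)[k] for k, c in enumerate(design.columns)
        }
    for name, c in contrasts.items():
        if np.asarray(c).shape != (p,):
            raise ValueError(f"contrast {name!r} has wrong length")

    # whitening matrix for the block compound-symmetry correlation
    R = np.eye(n)
    if vf.block is not None and rho != 0.0:
        labels = vf.block.to_numpy()
        same = labels[:, None] == labels[None, :]
        R = np.where(same, rho, 0.0)
        np.fill_diagonal(R, 1.0)
    L = cholesky(R, lower=True)
    Linv = solve_triangular(L, np.eye(n), lower=True)

    Y = vf.y.to_numpy()
    W = vf.weights.to_numpy()
    n_features = Y.shape[0]
    s2 = np.empty(n_features)
    est = {name: np.empty(n_features) for name in contrasts}
    sd_unscaled = {name: np.empty(n_features) for name in contrasts}
    for f in range(n_features):
        A = Linv * np.sqrt(W[f])[None, :]
        Xs = A @ X
        ys = A @ Y[f]
        XtX = Xs.T @ Xs
        cov = np.linalg.inv(XtX)
        beta = cov @ (Xs.T @ ys)
        e = ys - Xs @ beta
        s2[f] = (e @ e) / (n - p)
        for name, c in contrasts.items():
            c = np.asarray(c, dtype=float)
            est[name][f] = c @ beta
            sd_unscaled[name][f] = np.sqrt(c @ cov @ c)

    d = float(n - p)
    if prior_df is None:
        d0, s0_sq = _squeeze_var(s2, d)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.mean(s2)) if d0 > 0 else float("nan")
    s2_post = posterior_variance(s2, d, d0, s0_sq)
    df_total = min(d + d0, 1e6)

    mean_abundance = Y.mean(axis=1)
    features = list(vf.y.index)
    tables = {}
    for name in contrasts:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est[name] / (sd_unscaled[name] * np.sqrt(s2_post))
        pvals = 2 * stats.t.sf(np.abs(t), df=df_total)
        adj, flags = bh_adjust(pvals, alpha=alpha)
        tables[name] = pd.DataFrame(
            {
                "logFC": est[name],
                "t": t,
                "p": pvals,
                "adj_p": adj,
                "significant": flags,
                "mean_abundance": mean_abundance,
            },
            index=pd.Index(features, name="feature"),
        )
    return DAResult(
        tables=tables,
        consensus_rho=float(rho),
        d0=d0,
        s0_sq=s0_sq,
        residual_df=d,
        alpha=alpha,
    )


def bh_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1) | np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    _, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return adj, adj <= alpha


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def run_da(
    table: pd.DataFrame,
    metadata: CohortMetadata,
    phenotypes: pd.DataFrame | None = None,
    mode: str = "categorical",
    level: str = "asv",
    tree: TreeNode | None = None,
    cut_height: float = 0.1,
    alpha: float = 0.05,
    min_frac: float = 0.10,
) -> DAResult:
    """Full pre-diet differential-abundance pipeline.

    Restricts to pre-diet (BL) samples, optionally aggregates ASVs into
    phylogenetic clusters, applies the per-diet subject-prevalence filter,
    normalises (poscounts), runs asinh-voom, estimates the consensus
    within-subject correlation, fits the joint diet x outcome model with a
    sequencing-lane fixed effect, and reports BH-controlled within-diet
    contrasts (VS - US for ``mode='categorical'``, the per-diet slope on %
    weight loss for ``mode='continuous'``).
    """
    if mode not in ("categorical", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    if level not in ("asv", "cluster"):
        raise ValueError(f"unknown level {level!r}")
    if phenotypes is None:
        phenotypes = phenotype_table(metadata.subjects)

    bl = metadata.samples[metadata.samples["window"] == "BL"]
    bl = bl.loc[bl.index.intersection(table.index)]
    if bl.empty:
        raise ValueError("no pre-diet (BL) samples in the table")
    counts = table.loc[bl.index]

    if level == "cluster":
        if tree is None:
            raise ValueError("cluster-level analysis requires a tree")
        ca = cut_tree(tree, cut_height)
        counts = aggregate_by_cluster(counts, ca)

    bl_meta = CohortMetadata(samples=bl, subjects=metadata.subjects)
    per_diet_features = {
        diet: prevalence_filter(counts, bl_meta, diet, min_frac=min_frac)
        for diet in ("low-carb", "low-fat")
    }
    union = sorted(set().union(*per_diet_features.values()), key=list(counts.columns).index)
    if not union:
        raise ValueError("no features pass the prevalence filter")
    counts = counts[union]

    subjects = metadata.subjects
    diet = subjects.loc[bl["subject_id"], "diet"].to_numpy()
    lane = bl["lane"].astype(str)

    if mode == "categorical":
        success = phenotypes.loc[bl["subject_id"], "success"].to_numpy()
        if pd.isna(success).any():
            raise ValueError("samples with missing success category")
        cells = pd.Series(
            [f"{d}.{s}" for d, s in zip(diet, success)], index=bl.index, name="cell"
        )
        design = pd.get_dummies(cells, dtype=float)
        contrast_cols = {}
        for d in ("low-carb", "low-fat"):
            vs, us = f"{d}.VS", f"{d}.US"
            if vs not in design.columns or us not in design.columns:
                raise ValueError(f"diet {d!r} lacks VS or US subjects; contrast not estimable")
            contrast_cols[f"VS-US|{d}"] = {vs: 1.0, us: -1.0}
    else:
        wl = subjects.loc[bl["subject_id"], "weight_loss_pct_12mo"].to_numpy(dtype=float)
        if np.isnan(wl).any():
            raise ValueError("samples with missing weight-loss outcome")
        design = pd.DataFrame(index=bl.index)
        contrast_cols = {}
        for d in ("low-carb", "low-fat"):
            mask = (diet == d).astype(float)
            design[f"{d}.intercept"] = mask
            design[f"{d}.wl_slope"] = mask * wl
            contrast_cols[f"slope|{d}"] = {f"{d}.wl_slope": 1.0}

    lane_dummies = pd.get_dummies(lane, prefix="lane", dtype=float)
    if lane_dummies.shape[1] > 1:
        design = pd.concat([design, lane_dummies.iloc[:, 1:]], axis=1)

    contrasts = {}
    for name, spec_cols in contrast_cols.items():
        c = np.zeros(design.shape[1])
        for col, val in spec_cols.items():
            c[design.columns.get_loc(col)] = val
        contrasts[name] = c

    sf = poscounts_size_factors(counts)
    block = bl["subject_id"]
    vf = voom_asinh(counts, sf, design, block=block)
    rho = consensus_correlation(vf)
    result = fit_moderated(vf, design, rho=rho, contrasts=contrasts, alpha=alpha)

    # restrict each diet's table to that diet's prevalence-filtered features
    # and redo BH within it, so the multiplicity matches the features tested
    for name in list(result.tables):
        d = name.split("|")[1]
        feats = [f for f in result.tables[name].index if f in set(per_diet_features[d])]
        tab = result.tables[name].loc[feats].copy()
        adj, flags = bh_adjust(tab["p"].to_numpy(), alpha=alpha)
        tab["adj_p"] = adj
        tab["significant"] = flags
        result.tables[name] = tab
    result.filtered_features = per_diet_features
    return result
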