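"""Alpha- and beta-diversity engines.

Five beta-diversity metrics are exposed under one interface: Bray-Curtis,
Jaccard and Jensen-Shannon divergence plus unweighted and (normalized)
weighted UniFrac.  Jaccard and unweighted UniFrac see only presence/absence
and quantify turnover in community membership; the other three quantify
turnover in abundance structure.  All five are bounded in [0, 1].

Alpha diversity is Faith's phylogenetic diversity (PD) interpolated to a fixed
rarefaction depth ``m``: the exact expectation of PD over random subsamples of
``m`` reads, computed branch-by-branch from hypergeometric inclusion
probabilities rather than by Monte-Carlo subsampling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import distance as _spdist
from scipy.special import gammaln
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import unweighted_unifrac as _skbio_uu
from skbio.diversity.beta import weighted_unifrac as _skbio_wu

__all__ = [
    "METRICS",
    "asinh_transform",
    "bray_curtis",
    "jaccard",
    "jensen_shannon",
    "unifrac",
    "distance_matrix",
    "faith_pd",
    "expected_pd_rarefied",
    "alpha_table",
]

#: canonical metric names accepted by :func:`distance_matrix`
METRICS = ("braycurtis", "jaccard", "jsd", "unweighted_unifrac", "weighted_unifrac")

_ALIASES = {
    "bray": "braycurtis",
    "bray-curtis": "braycurtis",
    "jensenshannon": "jsd",
    "jensen-shannon": "jsd",
    "uunifrac": "unweighted_unifrac",
    "wunifrac": "weighted_unifrac",
}


def asinh_transform(x):
    """Elementwise inverse hyperbolic sine, ``log(x + sqrt(1 + x^2))``.

    A variance-stabilising alternative to the logarithm that is defined at
    zero (asinh(0) = 0) and behaves like ``log(2x)`` for large ``x`` — the
    reason it suits sparse sequencing counts.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("asinh_transform expects non-negative abundances")
    return np.arcsinh(x)


def _check_pair(u, v) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("expected two 1-D vectors of equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValueError("abundance vectors must be non-negative")
    if u.sum() == 0 or v.sum() == 0:
        raise ValueError("abundance vector with no positive entries")
    return u, v


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity ``sum|u-v| / sum(u+v)``."""
    u, v = _check_pair(u, v)
    return float(_spdist.braycurtis(u, v))


def jaccard(u, v) -> float:
    """Jaccard dissimilarity on presence/absence, ``1 - |A&B|/|A|B|``."""
    u, v = _check_pair(u, v)
    a, b = u > 0, v > 0
    return float(1.0 - np.sum(a & b) / np.sum(a | b))


def jensen_shannon(u, v) -> float:
    """Jensen-Shannon divergence (base 2) between relative abundances.

    Vectors are normalised to proportions internally; the divergence (not its
    square root) is returned, so values lie in [0, 1].
    """
    u, v = _check_pair(u, v)
    return float(_spdist.jensenshannon(u / u.sum(), v / v.sum(), base=2) ** 2)


def unifrac(tree: TreeNode, u, v, taxa, weighted: bool = False) -> float:
    """UniFrac distance between two samples over *tree*.

    Unweighted UniFrac is the fraction of branch length unique to either
    sample among branch length covered by both; the weighted variant moves
    relative abundance along branches and is returned in its normalized
    (bounded [0, 1]) form.
    """
    u, v = _check_pair(u, v)
    if weighted:
        return float(_skbio_wu(u, v, taxa=list(taxa), tree=tree, normalized=True))
    return float(_skbio_uu(u, v, taxa=list(taxa), tree=tree))


def _resolve_metric(metric: str) -> str:
    name = _ALIASES.get(metric.lower(), metric.lower())
    if name not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    return name


def _scaled(table: pd.DataFrame, scale: str) -> pd.DataFrame:
    values = table.to_numpy(dtype=float)
    if scale == "proportion":
        return pd.DataFrame(
            values / values.sum(axis=1, keepdims=True), index=table.index, columns=table.columns
        )
    if scale == "asinh_normalized":
        from .diffabund import poscounts_size_factors  # local import: avoids cycle

        sf = poscounts_size_factors(table).to_numpy()
        return pd.DataFrame(
            np.arcsinh(values / sf[:, None]), index=table.index, columns=table.columns
        )
    if scale == "raw":
        return table.astype(float)
    raise ValueError(f"unknown scale {scale!r}")


def distance_matrix(
    table: pd.DataFrame,
    metric: str,
    scale: str = "proportion",
    tree: TreeNode | None = None,
) -> DistanceMatrix:
    """All pairwise sample distances under one metric.

    ``scale`` selects the abundance scale fed to the quantitative metrics:
    ``proportion`` (relative abundances, the default for plasticity work) or
    ``asinh_normalized`` (asinh of size-factor-normalised counts, the scale
    used for ordination).  Presence/absence metrics and UniFrac operate on
    the raw counts, where scaling is immaterial.
    """
    metric = _resolve_metric(metric)
    ids = list(table.index)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError("UniFrac metrics require a tree")
        tips = {t.name for t in tree.tips()}
        missing = set(table.columns) - tips
        if missing:
            raise ValueError(f"ASVs absent from tree: {sorted(missing)[:5]}...")
        data = table.to_numpy(dtype=float)
        n = len(ids)
        out = np.zeros((n, n))
        taxa = list(table.columns)
        weighted = metric == "weighted_unifrac"
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = unifrac(
                    tree, data[i], data[j], taxa, weighted=weighted
                )
        return DistanceMatrix(out, ids=ids)

    if metric == "jaccard":
        data = (table.to_numpy(dtype=float) > 0).astype(float)
        condensed = _spdist.pdist(data, metric="jaccard")
    else:
        data = _scaled(table, scale).to_numpy()
        if metric == "braycurtis":
            condensed = _spdist.pdist(data, metric="braycurtis")
        else:  # jsd
            prop = data / data.sum(axis=1, keepdims=True)
            # pdist returns sqrt(JSD) in nats; square and rebase to bits
            condensed = _spdist.pdist(prop, metric="jensenshannon") ** 2 / np.log(2)
    return DistanceMatrix(_spdist.squareform(condensed), ids=ids)


# ---------------------------------------------------------------------------
# phylogenetic alpha diversity
# ---------------------------------------------------------------------------


def _branch_tip_sums(tree: TreeNode, counts: pd.Series):
    """Yield (branch length, reads below branch) for every non-root edge."""
    totals: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            totals[id(node)] = float(counts.get(node.name, 0.0))
        else:
            totals[id(node)] = sum(totals[id(c)] for c in node.children)
    for node in tree.traverse(include_self=False):
        yield float(node.length or 0.0), totals[id(node)]


def faith_pd(tree: TreeNode, counts: pd.Series) -> float:
    """Faith's PD: total branch length spanned by tips present in *counts*.

    The root's own subtending edge, if any, is excluded by convention.
    """
    return float(sum(L for L, n_b in _branch_tip_sums(tree, counts) if n_b > 0))


def expected_pd_rarefied(tree: TreeNode, counts: pd.Series, m: int) -> float:
    """Exact expected Faith's PD under rarefaction to depth *m*.

    For each branch ``b`` with length ``L_b`` and ``n_b`` reads descending
    from it, the probability that at least one of the ``m`` subsampled reads
    falls below ``b`` is ``1 - C(N - n_b, m)/C(N, m)`` (hypergeometric), and

        E[PD(m)] = sum_b L_b * (1 - C(N - n_b, m) / C(N, m)).

    Binomial coefficients are evaluated with log-gamma for numerical safety.
    Interpolation only: ``m`` must not exceed the sample's total count.
    """
    counts = counts.astype(float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    N = counts.sum()
    if m > N:
        raise ValueError(f"rarefaction depth m={m} exceeds sample total {int(N)}")
    if m <= 0:
        raise ValueError("rarefaction depth must be positive")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    pd_sum = 0.0
    for L, n_b in _branch_tip_sums(tree, counts):
        if n_b <= 0 or L == 0.0:
            continue
        if N - n_b < m:
            prob = 1.0
        else:
            prob = 1.0 - np.exp(log_choose(N - n_b, m) - log_choose(N, m))
        pd_sum += L * prob
    return float(pd_sum)


def alpha_table(table: pd.DataFrame, tree: TreeNode, m: int = 11000) -> pd.Series:
    """Per-sample expected PD at rarefaction depth *m* (default 11,000 reads).

    Samples with fewer than ``m`` total reads cannot be interpolated and are
    reported as missing, with a warning listing them.
    """
    values = {}
    too_shallow = []
    for sample_id, row in table.iterrows():
        if row.sum() < m:
            too_shallow.append(sample_id)
            values[sample_id] = np.nan
        else:
            values[sample_id] = expected_pd_rarefied(tree, row, m)
    if too_shallow:
        warnings.warn(
            f"{len(too_shallow)} samples below rarefaction depth {m}: "
            f"{too_shallow[:5]}... reported as missing",
            stacklevel=2,
        )
    return pd.Series(values, name=f"expected_pd_m{m}")
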