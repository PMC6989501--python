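"""Community-level analyses and shared nonparametric test utilities.

* Prevotella/Bacteroides (P/B) ratio per sample and subject, with the
  pseudocount-of-1 rule for undetected Prevotella and a high/low
  classification at a configurable cutoff (default 0.003);
* principal coordinates analysis (classical scaling) of a distance matrix;
* PERMANOVA with whole-label permutation;
* two-sided Wilcoxon rank-sum and Spearman rank correlation, exact for small
  samples, used by all group comparisons in the package.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .io_formats import CohortMetadata

__all__ = [
    "PBResult",
    "OrdinationResult",
    "PermanovaResult",
    "pb_ratio",
    "classify_pb",
    "pcoa",
    "permanova",
    "wilcoxon_rank_sum",
    "spearman",
]


# ---------------------------------------------------------------------------
# Prevotella / Bacteroides ratio
# ---------------------------------------------------------------------------


@dataclass
class PBResult:
    """Per-sample and per-subject Prevotella/Bacteroides ratios."""

    per_sample: pd.Series
    per_subject: pd.Series
    excluded_samples: list[str]


def pb_ratio(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    metadata: CohortMetadata | None = None,
    window: str = "BL",
) -> PBResult:
    """Prevotella-to-Bacteroides genus count ratio.

    Per sample, ``P`` is the summed count over Prevotella-genus ASVs with a
    pseudocount of 1 substituted only when ``P`` is exactly zero (roughly half
    of subjects never detect Prevotella), and ``B`` the summed Bacteroides
    count; the ratio is ``P/B`` on raw counts.  Samples with ``B = 0`` have an
    undefined ratio and are excluded with a warning.  When *metadata* is
    given, per-subject values are the mean over that subject's *window*
    samples; otherwise over all their samples in the table.
    """
    genus = taxonomy["genus"].reindex(table.columns).fillna("")
    prev_cols = table.columns[genus == "Prevotella"]
    bact_cols = table.columns[genus == "Bacteroides"]
    if len(prev_cols) == 0 or len(bact_cols) == 0:
        raise ValueError("taxonomy must label both Prevotella and Bacteroides ASVs")
    P = table[prev_cols].sum(axis=1).astype(float)
    B = table[bact_cols].sum(axis=1).astype(float)
    P[P == 0] = 1.0  # pseudocount only when Prevotella is undetected
    excluded = list(table.index[B == 0])
    if excluded:
        warnings.warn(
            f"{len(excluded)} samples with zero Bacteroides excluded from P/B: "
            f"{excluded[:5]}",
            stacklevel=2,
        )
    keep = B > 0
    per_sample = (P[keep] / B[keep]).rename("pb_ratio")

    if metadata is not None:
        samples = metadata.samples.loc[
            metadata.samples.index.intersection(per_sample.index)
        ]
        samples = samples[samples["window"] == window]
        grouped = per_sample.loc[samples.index].groupby(samples["subject_id"])
    else:
        grouped = per_sample.groupby(per_sample.index.str.split("_").str[0])
    per_subject = grouped.mean().rename("pb_ratio")
    return PBResult(per_sample=per_sample, per_subject=per_subject, excluded_samples=excluded)


def classify_pb(pb: PBResult, cutoff: float = 0.003) -> pd.Series:
    """Dichotomise subjects at the P/B cutoff; the boundary classes as high."""
    return pd.Series(
        np.where(pb.per_subject >= cutoff, "high", "low"),
        index=pb.per_subject.index,
        name="pb_class",
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # retained (positive) eigenvalues, non-increasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # dropped negative part, for diagnostics


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Double-centres ``-D^2/2``, eigendecomposes, and scales eigenvectors by
    the square root of their eigenvalues.  Negative eigenvalues (possible for
    non-Euclidean dissimilarities such as Bray-Curtis) are dropped from the
    coordinates and reported separately.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("ordination needs at least 3 samples")
    with warnings.catch_warnings():
        # negative eigenvalues are reported in the result; no need to warn
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", dimensions=0)
    eig = res.eigvals.to_numpy()
    pos = eig[eig > 0]
    neg = eig[eig < 0]
    k = min(n_axes, pos.size)
    coords = res.samples.iloc[:, :k].copy()
    coords.columns = [f"PCo{i + 1}" for i in range(k)]
    coords.index = list(dm.ids)
    total = pos.sum() if pos.size else 1.0
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=pos[:k],
        proportion_explained=pos[:k] / total,
        negative_eigenvalues=neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _permanova_f(sq: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = sq.shape[0]
    a = len(groups)
    ss_total = sq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            sub = sq[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    subjects=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions squared distances into between- and within-group components
    (Anderson's pseudo-F) and assesses significance by whole-label
    permutation: ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)``.

    With repeated measures, pass *subjects* (sample -> subject mapping whose
    group label is constant within subject): labels are then permuted across
    subjects rather than samples, keeping each subject's samples together so
    within-subject correlation does not inflate significance.
    """
    labels = np.asarray(
        grouping.reindex(list(dm.ids)) if isinstance(grouping, pd.Series) else grouping
    )
    if labels.shape[0] != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = pd.Series(labels).value_counts()
    if (counts == 1).any():
        warnings.warn(
            f"groups with a single member: {list(counts.index[counts == 1])}",
            stacklevel=2,
        )
    sq = dm.data.astype(float) ** 2
    f_obs, r2 = _permanova_f(sq, labels, groups)
    rng = np.random.default_rng(seed)

    if subjects is not None:
        subj = np.asarray(
            subjects.reindex(list(dm.ids)) if isinstance(subjects, pd.Series) else subjects
        )
        uniq, inverse = np.unique(subj, return_inverse=True)
        subj_label = np.empty(uniq.size, dtype=labels.dtype)
        for k in range(uniq.size):
            lab = np.unique(labels[inverse == k])
            if lab.size != 1:
                raise ValueError(f"subject {uniq[k]!r} spans multiple groups")
            subj_label[k] = lab[0]

        def permute():
            return rng.permutation(subj_label)[inverse]

    else:

        def permute():
            return rng.permutation(labels)

    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_f(sq, permute(), groups)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, exact_threshold: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the combined sample size is at most
    ``exact_threshold`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns the
    Mann-Whitney U of *x* and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (no_ties and combined.size <= exact_threshold) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (all n! pairings)."""
    n = x_ranks.size
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    target = abs(rho_obs) * denom - 1e-12
    hits = total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        nonlocal hits, total
        perm = np.array(chunk)
        vals = np.abs(perm @ xc)
        hits += int(np.sum(vals >= target))
        total += perm.shape[0]

    for p in itertools.permutations(yc):
        chunk.append(p)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return hits / total


def spearman(x, y, exact_threshold: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Rho is the Pearson correlation of (average) ranks.  For at most
    ``exact_threshold`` pairs the p-value is an exact permutation p over all
    pairings; above that, the usual t approximation.  Constant input yields
    a missing result with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors required")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_threshold:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, float(p)
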