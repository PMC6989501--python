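"""Per-subject gut-microbiota plasticity statistics.

Plasticity is a subject-level trait: the mean pairwise beta-diversity between
a subject's own samples.  Two estimands are computed:

* **daily plasticity** within a sampling window — when a subject provided
  three samples, only distances between *consecutive* samples (in collection
  order) enter the mean, never the first-vs-third pair;
* **cross-period plasticity** between the pre-diet (BL) and ten-week (W10)
  windows — the mean over the full bipartite set of BL x W10 pairs.

Each subject contributes one value per (pairing, metric); group comparisons
(unsuccessful vs very-successful dieters) and covariate correlations operate
on those subject-level means with rank-based tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .community_stats import spearman, wilcoxon_rank_sum
from .diversity import distance_matrix
from .io_formats import CohortMetadata

__all__ = [
    "PAIRINGS",
    "consecutive_pairs",
    "daily_plasticity",
    "cross_period_plasticity",
    "plasticity_table",
    "compare_plasticity_groups",
    "correlate_plasticity",
    "intra_inter_comparison",
]

PAIRINGS = ("BLvBL", "W10vW10", "BLvW10")


def consecutive_pairs(samples: list[str]) -> list[tuple[str, str]]:
    """Successive pairs of samples already sorted by collection day.

    ``[a, b, c] -> [(a, b), (b, c)]`` — the non-adjacent (a, c) pair is never
    used, so a slow drift over several days does not inflate the daily
    estimate.
    """
    return list(zip(samples[:-1], samples[1:]))


def daily_plasticity(samples: list[str], dm: DistanceMatrix):
    """Mean distance over consecutive within-window pairs.

    Returns ``(value, n_pairs)`` or ``(nan, 0)`` when the subject provided
    fewer than two samples in the window.
    """
    pairs = consecutive_pairs(samples)
    if not pairs:
        return float("nan"), 0
    values = [dm[a, b] for a, b in pairs]
    return float(np.mean(values)), len(pairs)


def cross_period_plasticity(bl_samples: list[str], w10_samples: list[str], dm: DistanceMatrix):
    """Mean distance over the full BL x W10 bipartite pair set.

    Returns ``(value, n_pairs)``; either window empty yields ``(nan, 0)``.
    """
    if not bl_samples or not w10_samples:
        return float("nan"), 0
    values = [dm[a, b] for a in bl_samples for b in w10_samples]
    return float(np.mean(values)), len(values)


def plasticity_table(
    table: pd.DataFrame,
    metadata: CohortMetadata,
    metrics=("braycurtis",),
    scale: str = "proportion",
    tree: TreeNode | None = None,
) -> pd.DataFrame:
    """One row per subject x pairing x metric where computable.

    Columns: ``subject_id, pairing, metric, value, n_pairs``.  Subjects with
    too few samples for a pairing are simply absent from it.
    """
    rows = []
    for metric in metrics:
        dm = distance_matrix(table, metric, scale=scale, tree=tree)
        in_table = set(dm.ids)
        for subject in metadata.subjects.index:
            bl = [s for s in metadata.samples_of(subject, "BL") if s in in_table]
            w10 = [s for s in metadata.samples_of(subject, "W10") if s in in_table]
            for pairing, (value, n_pairs) in {
                "BLvBL": daily_plasticity(bl, dm),
                "W10vW10": daily_plasticity(w10, dm),
                "BLvW10": cross_period_plasticity(bl, w10, dm),
            }.items():
                if n_pairs:
                    rows.append(
                        {
                            "subject_id": subject,
                            "pairing": pairing,
                            "metric": metric,
                            "value": value,
                            "n_pairs": n_pairs,
                        }
                    )
    return pd.DataFrame(rows, columns=["subject_id", "pairing", "metric", "value", "n_pairs"])


def _subject_values(
    pt: pd.DataFrame, pairing: str, metric: str, subjects=None
) -> pd.Series:
    rows = pt[(pt["pairing"] == pairing) & (pt["metric"] == metric)]
    values = rows.set_index("subject_id")["value"]
    if subjects is not None:
        values = values.reindex([s for s in subjects if s in values.index])
    return values


def compare_plasticity_groups(
    pt: pd.DataFrame,
    groups: pd.Series | dict,
    pairing: str = "BLvBL",
    metric: str = "braycurtis",
    subjects=None,
) -> tuple[float, float]:
    """Wilcoxon rank-sum test between two groups of subject-level values.

    *groups* maps subject -> group label (typically US / VS); exactly two
    labels must be represented among subjects with a plasticity value.
    Returns ``(U, p)`` (two-sided).
    """
    groups = pd.Series(groups)
    values = _subject_values(pt, pairing, metric, subjects)
    values = values[values.index.isin(groups.index)]
    labels = groups.loc[values.index]
    present = sorted(labels.unique())
    if len(present) != 2:
        raise ValueError(f"need exactly two groups, got {present}")
    x = values[labels == present[0]].to_numpy()
    y = values[labels == present[1]].to_numpy()
    return wilcoxon_rank_sum(x, y)


def correlate_plasticity(
    pt: pd.DataFrame,
    covariate: pd.Series | dict,
    pairing: str = "BLvBL",
    metric: str = "braycurtis",
    subjects=None,
) -> tuple[float, float]:
    """Spearman correlation between subject plasticity and a covariate.

    *subjects* optionally restricts to a subgroup (e.g. one diet and sex).
    Fewer than three complete pairs yields ``(nan, nan)`` with a warning.
    """
    covariate = pd.Series(covariate).astype(float)
    values = _subject_values(pt, pairing, metric, subjects)
    common = values.index.intersection(covariate.dropna().index)
    if len(common) < 3:
        warnings.warn(
            f"only {len(common)} paired observations; correlation not computed",
            stacklevel=2,
        )
        return float("nan"), float("nan")
    return spearman(values.loc[common].to_numpy(), covariate.loc[common].to_numpy())


def intra_inter_comparison(
    dm: DistanceMatrix, metadata: CohortMetadata, window: str = "BL"
):
    """Within-subject vs between-subject pairwise distances in one window.

    Returns ``(intra, inter, p)``: the two distance distributions (all pairs,
    not consecutive-only) and a two-sided rank-sum p-value comparing them.
    """
    samples = metadata.samples[metadata.samples["window"] == window]
    samples = samples.loc[samples.index.intersection(list(dm.ids))]
    if samples["subject_id"].nunique() < 2:
        raise ValueError("need at least two subjects with samples in the window")
    ids = list(samples.index)
    subj = samples["subject_id"]
    intra, inter = [], []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            (intra if subj[a] == subj[b] else inter).append(dm[a, b])
    _, p = wilcoxon_rank_sum(np.asarray(intra), np.asarray(inter))
    return np.asarray(intra), np.asarray(inter), p
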