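"""Phylogenetic ASV clustering and the subject-prevalence filter.

Exact-sequence variants are extremely sparse; grouping phylogenetically
related ASVs recovers overlap between samples.  Because a maximum-likelihood
16S tree is not ultrametric, "cutting the tree at height h" is realised as
average-linkage agglomerative clustering on the patristic (tip-to-tip path
length) distance matrix, cut at merge height h.  The linkage is configurable;
ties are broken deterministically by sorting tips lexicographically first.

A cut height can be translated into the percent sequence identity it roughly
corresponds to via the median pairwise base-pair difference of cluster
members and the amplicon length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .io_formats import CohortMetadata

__all__ = [
    "ClusterAssignment",
    "cut_tree",
    "height_to_identity",
    "aggregate_by_cluster",
    "prevalence_filter",
]


@dataclass
class ClusterAssignment:
    """A partition of ASVs into phylogenetic clusters."""

    assignment: pd.Series  # asv_id -> cluster_id
    cut_height: float
    linkage: str
    summary: pd.DataFrame  # per cluster: n_members, median_patristic

    @property
    def n_clusters(self) -> int:
        return self.assignment.nunique()


def cut_tree(tree: TreeNode, h: float, linkage: str = "average") -> ClusterAssignment:
    """Cluster tips by agglomerating patristic distances up to height *h*.

    ``h = 0`` leaves every tip (with distinct position) in its own cluster;
    ``h`` at or above the largest merge height yields a single cluster.
    Cluster ids are ``Cluster1..K``, numbered by the lexicographically first
    member so the labelling is deterministic.
    """
    if h < 0:
        raise ValueError("cut height must be >= 0")
    dm = tree.tip_tip_distances()
    order = np.argsort(np.asarray(dm.ids))
    tips = [dm.ids[i] for i in order]
    dist = dm.data[np.ix_(order, order)]
    if len(tips) == 1:
        assignment = pd.Series(["Cluster1"], index=tips)
    else:
        Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
        flat = hierarchy.fcluster(Z, t=h, criterion="distance")
        # renumber deterministically by first (lexicographic) member
        first_member: dict[int, str] = {}
        for tip, c in zip(tips, flat):
            first_member.setdefault(c, tip)
        ordered = sorted(first_member, key=lambda c: first_member[c])
        relabel = {c: f"Cluster{i + 1}" for i, c in enumerate(ordered)}
        assignment = pd.Series([relabel[c] for c in flat], index=tips)
    assignment.index.name = "asv_id"
    assignment.name = "cluster_id"

    tip_pos = {t: i for i, t in enumerate(tips)}
    summary_rows = {}
    for cluster_id, members in assignment.groupby(assignment).groups.items():
        idx = [tip_pos[m] for m in members]
        if len(idx) > 1:
            sub = dist[np.ix_(idx, idx)]
            med = float(np.median(sub[np.triu_indices(len(idx), k=1)]))
        else:
            med = 0.0
        summary_rows[cluster_id] = {"n_members": len(idx), "median_patristic": med}
    summary = pd.DataFrame.from_dict(summary_rows, orient="index").sort_index(
        key=lambda ix: ix.str.removeprefix("Cluster").astype(int)
    )
    summary.index.name = "cluster_id"
    return ClusterAssignment(
        assignment=assignment, cut_height=float(h), linkage=linkage, summary=summary
    )


def height_to_identity(median_bp_diff: float, seq_len: int) -> float:
    """Percent sequence identity implied by a median pairwise bp difference.

    ``100 * (seq_len - median_bp_diff) / seq_len``, rounded to one decimal
    for reporting — e.g. a median difference of 7.5 bp over 233 bp amplicons
    corresponds to 96.8% identity, in the range used to delimit genera.
    """
    if seq_len <= 0:
        raise ValueError("sequence length must be positive")
    if not 0 <= median_bp_diff <= seq_len:
        raise ValueError("median bp difference must lie in [0, seq_len]")
    return round(100.0 * (seq_len - median_bp_diff) / seq_len, 1)


def aggregate_by_cluster(table: pd.DataFrame, ca: ClusterAssignment) -> pd.DataFrame:
    """Sum count columns within clusters; per-sample totals are conserved."""
    missing = set(table.columns) - set(ca.assignment.index)
    if missing:
        raise ValueError(f"ASVs without cluster assignment: {sorted(missing)[:5]}")
    grouped = table.T.groupby(ca.assignment.reindex(table.columns)).sum().T
    grouped = grouped[sorted(grouped.columns, key=lambda c: int(c.removeprefix("Cluster")))]
    grouped.index.name = table.index.name
    return grouped


def prevalence_filter(
    table: pd.DataFrame,
    metadata: CohortMetadata,
    diet: str,
    min_frac: float = 0.10,
) -> list[str]:
    """Features detected in at least ``min_frac`` of the diet's subjects.

    Presence is subject-level: a feature counts as present in a subject if it
    has a positive count in any of that subject's samples (any window).  The
    threshold is ``ceil(min_frac * n_subjects_on_diet)``.
    """
    subjects = metadata.subjects_on(diet)
    if not subjects:
        raise ValueError(f"no subjects on diet {diet!r}")
    threshold = math.ceil(min_frac * len(subjects))
    samples = metadata.samples[metadata.samples["subject_id"].isin(subjects)]
    sample_ids = samples.index.intersection(table.index)
    present = (table.loc[sample_ids] > 0).groupby(
        samples.loc[sample_ids, "subject_id"]
    ).any()
    n_subjects_with = present.sum(axis=0)
    return list(n_subjects_with.index[n_subjects_with >= threshold])
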