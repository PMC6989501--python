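"""Reading, writing and cross-validating the package's file formats.

All tabular formats are TSV (tab-delimited, UTF-8, ``.`` decimal separator);
trees are Newick.  The central in-memory containers are deliberately plain:

* count tables are :class:`pandas.DataFrame` objects with samples as rows and
  ASV identifiers as columns, holding non-negative integers;
* phylogenies are :class:`skbio.TreeNode` rooted trees with branch lengths;
* cohort metadata is a :class:`CohortMetadata` pairing a per-sample and a
  per-subject DataFrame.

Validation is strict on read: negative or fractional cells, duplicate labels,
orphan samples and unknown factor levels are all hard errors, so downstream
analyses can assume clean inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "CohortMetadata",
    "DIETS",
    "SEXES",
    "WINDOWS",
    "RECALL_TIMEPOINTS",
    "recall_column",
    "read_count_table",
    "write_count_table",
    "validate_count_table",
    "read_tree",
    "write_tree",
    "validate_tree",
    "check_tree_against_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
]

DIETS = ("low-carb", "low-fat")
SEXES = ("F", "M")
WINDOWS = ("BL", "W10")
#: dietary-recall timepoints: pre-diet baseline plus 3, 6 and 12 months on diet
RECALL_TIMEPOINTS = ("baseline", "3mo", "6mo", "12mo")
MACRONUTRIENTS = ("carb", "fat", "protein")

SAMPLE_COLUMNS = ("subject_id", "window", "day_offset", "lane")


class FormatError(ValueError):
    """A file violated the artifact's format contract."""


def recall_column(macronutrient: str, timepoint: str) -> str:
    """Column name holding %kcal from *macronutrient* at *timepoint*."""
    if macronutrient not in MACRONUTRIENTS:
        raise ValueError(f"unknown macronutrient {macronutrient!r}")
    if timepoint not in RECALL_TIMEPOINTS:
        raise ValueError(f"unknown recall timepoint {timepoint!r}")
    return f"{macronutrient}_pct_{timepoint}"


SUBJECT_COLUMNS = ("diet", "sex", "weight_loss_pct_12mo") + tuple(
    recall_column(m, t) for m in MACRONUTRIENTS for t in RECALL_TIMEPOINTS
)


@dataclass
class CohortMetadata:
    """Joined per-sample and per-subject records for one cohort.

    ``samples`` is indexed by sample_id with columns
    ``subject_id, window, day_offset, lane``; ``subjects`` is indexed by
    subject_id with columns ``diet, sex, weight_loss_pct_12mo`` plus the
    twelve ``<macronutrient>_pct_<timepoint>`` recall columns.
    """

    samples: pd.DataFrame
    subjects: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def samples_of(self, subject_id: str, window: str | None = None) -> list[str]:
        """Sample ids of one subject, ordered by collection-day offset."""
        rows = self.samples[self.samples["subject_id"] == subject_id]
        if window is not None:
            rows = rows[rows["window"] == window]
        return list(rows.sort_values("day_offset").index)

    def subjects_on(self, diet: str) -> list[str]:
        if diet not in DIETS:
            raise ValueError(f"unknown diet {diet!r}")
        return list(self.subjects.index[self.subjects["diet"] == diet])


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------


def validate_count_table(table: pd.DataFrame) -> None:
    """Raise :class:`FormatError` unless *table* is a valid count table."""
    if table.shape[0] == 0:
        raise FormatError("count table has no samples")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    if table.columns.has_duplicates:
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate ASV ids: {dupes}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("count table contains non-numeric cells")
    if np.isnan(values.astype(float)).any():
        raise FormatError("count table contains missing cells")
    frac = values.astype(float) - np.round(values.astype(float))
    if np.any(frac != 0):
        i, j = np.argwhere(frac != 0)[0]
        raise FormatError(
            f"non-integer count at (sample {table.index[i]!r}, ASV {table.columns[j]!r})"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"negative count at (sample {table.index[i]!r}, ASV {table.columns[j]!r})"
        )
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        empty = table.index[row_sums == 0].tolist()
        raise FormatError(f"samples with no positive counts: {empty}")


def read_count_table(path) -> pd.DataFrame:
    """Read a samples x ASVs integer count table from TSV.

    The header row holds ASV ids and the first column sample ids.  Integer
    coercion is strict: any negative, fractional or non-numeric cell raises a
    :class:`FormatError` naming the offending (sample, ASV) cell.
    """
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no samples (empty file)") from None
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    validate_count_table(table)
    return table.astype(np.int64)


def write_count_table(table: pd.DataFrame, path) -> None:
    validate_count_table(table)
    table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def validate_tree(tree: TreeNode) -> None:
    """Require a rooted bifurcating-root tree with non-negative lengths."""
    root = tree.root()
    if len(root.children) != 2:
        raise FormatError(
            f"tree is not rooted: root has {len(root.children)} children "
            "(a bifurcating root is required)"
        )
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        seen, dupes = set(), set()
        for t in tips:
            (dupes if t in seen else seen).add(t)
        raise FormatError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"missing branch length above node {node.name!r}")
        if node.length < 0:
            raise FormatError(f"negative branch length above node {node.name!r}")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths."""
    tree = TreeNode.read(path, format="newick")
    if tree.length is None:
        tree.length = 0.0  # root edge is immaterial; normalise to 0
    validate_tree(tree)
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def check_tree_against_table(
    tree: TreeNode, table: pd.DataFrame, prune: bool = False
) -> TreeNode:
    """Cross-check tree tips against count-table ASVs.

    Any symmetric difference triggers a warning listing both directions.  ASVs
    missing from the tree are always an error for phylogenetic analyses, so
    they are only warned about here; tips absent from the table are pruned
    when ``prune=True``.
    """
    tips = {t.name for t in tree.tips()}
    asvs = set(table.columns)
    extra_tips = sorted(tips - asvs)
    missing_tips = sorted(asvs - tips)
    if extra_tips or missing_tips:
        warnings.warn(
            "tree/table mismatch: "
            f"{len(extra_tips)} tips absent from table {extra_tips[:5]}..., "
            f"{len(missing_tips)} ASVs absent from tree {missing_tips[:5]}...",
            stacklevel=2,
        )
    if prune and extra_tips:
        tree = tree.shear(sorted(tips & asvs))
        tree.prune()
    return tree


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------


def read_taxonomy(path) -> pd.DataFrame:
    """Read an ASV -> genus table; missing genus is the empty string."""
    tax = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    tax.index = tax.index.astype(str)
    if "genus" not in tax.columns:
        raise FormatError("taxonomy table lacks a 'genus' column")
    if tax.index.has_duplicates:
        raise FormatError("duplicate ASV ids in taxonomy table")
    return tax


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    tax.to_csv(path, sep="\t", index_label="asv_id")


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------


def validate_metadata(md: CohortMetadata) -> None:
    samples, subjects = md.samples, md.subjects
    if samples.index.has_duplicates:
        dupes = samples.index[samples.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    if subjects.index.has_duplicates:
        dupes = subjects.index[subjects.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate subject ids: {dupes}")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            raise FormatError(f"sample metadata lacks column {col!r}")
    for col in SUBJECT_COLUMNS:
        if col not in subjects.columns:
            raise FormatError(f"subject metadata lacks column {col!r}")
    orphans = set(samples["subject_id"]) - set(subjects.index)
    if orphans:
        bad = samples.index[samples["subject_id"].isin(orphans)].tolist()
        raise FormatError(f"samples referencing missing subjects: {bad}")
    bad_window = set(samples["window"]) - set(WINDOWS)
    if bad_window:
        raise FormatError(f"unknown window levels: {sorted(bad_window)}")
    if samples["lane"].astype(str).str.len().eq(0).any():
        raise FormatError("empty lane labels")
    bad_diet = set(subjects["diet"]) - set(DIETS)
    if bad_diet:
        raise FormatError(f"unknown diet levels: {sorted(bad_diet)}")
    bad_sex = set(subjects["sex"]) - set(SEXES)
    if bad_sex:
        raise FormatError(f"unknown sex levels: {sorted(bad_sex)}")
    recall_cols = [
        c for c in subjects.columns
        if any(c.startswith(f"{m}_pct_") for m in MACRONUTRIENTS)
    ]
    recalls = subjects[recall_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((recalls < 0) | (recalls > 100)):
            raise FormatError("macronutrient recall percentages outside [0, 100]")


def read_metadata(sample_path, subject_path) -> CohortMetadata:
    """Read and join per-sample and per-subject metadata TSVs."""
    samples = pd.read_csv(sample_path, sep="\t", index_col=0, dtype={0: str})
    subjects = pd.read_csv(subject_path, sep="\t", index_col=0, dtype={0: str})
    samples.index = samples.index.astype(str)
    subjects.index = subjects.index.astype(str)
    samples["subject_id"] = samples["subject_id"].astype(str)
    samples["day_offset"] = samples["day_offset"].astype(int)
    samples["lane"] = samples["lane"].astype(str)
    md = CohortMetadata(samples=samples, subjects=subjects)
    validate_metadata(md)
    return md


def write_metadata(md: CohortMetadata, sample_path, subject_path) -> None:
    validate_metadata(md)
    md.samples.to_csv(sample_path, sep="\t", index_label="sample_id")
    md.subjects.to_csv(subject_path, sep="\t", index_label="subject_id")
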