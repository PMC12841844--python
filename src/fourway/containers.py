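"""Core in-memory containers for the 2x2 factorial RNA-seq pipeline.

The experiment this package models is a two-factor design — surgery
(Sham vs. RYGB, i.e. Roux-en-Y gastric bypass) crossed with diet
(Chow vs. HFD, high-fat diet) — giving four groups.  Counts travel
through the pipeline as a :class:`CountMatrix` (genes x samples plus a
per-sample annotation sheet) and each two-group differential-expression
comparison is returned as a :class:`ContrastResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

SURGERY_LEVELS = ("Sham", "RYGB")
DIET_LEVELS = ("Chow", "HFD")
#: Canonical group ordering (also the heatmap column order).
GROUP_ORDER = ("ShamChow", "RYGBChow", "ShamHFD", "RYGBHFD")

#: Columns of a ContrastResult table, in serialization order.
CONTRAST_COLUMNS = (
    "base_mean",
    "lfc_mle",
    "lfc_se",
    "wald_stat",
    "p_value",
    "p_adj",
    "lfc_shrunk",
    "tested",
)


def make_annotation(sample_ids, surgery, diet) -> pd.DataFrame:
    """Build a sample annotation sheet with surgery, diet and derived group."""
    ann = pd.DataFrame(
        {"surgery": list(surgery), "diet": list(diet)},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    bad_s = set(ann["surgery"]) - set(SURGERY_LEVELS)
    bad_d = set(ann["diet"]) - set(DIET_LEVELS)
    if bad_s or bad_d:
        raise InputError(f"unknown factor levels: surgery={bad_s or '{}'} diet={bad_d or '{}'}")
    ann["group"] = ann["surgery"] + ann["diet"]
    return ann


@dataclass
class CountMatrix:
    """Gene x sample raw counts with per-sample factor annotation.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, genes as rows (index = gene ids),
        samples as columns.
    annotation
        DataFrame indexed by sample id with columns ``surgery``, ``diet``
        and ``group``; must cover every count column.
    """

    counts: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise InputError("gene ids are not unique")
        if not self.counts.columns.is_unique:
            raise InputError("sample ids are not unique")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("counts contain negative entries")
        missing = set(self.counts.columns) - set(self.annotation.index)
        if missing:
            raise InputError(f"annotation missing samples: {sorted(missing)}")
        # keep annotation aligned to the count columns
        self.annotation = self.annotation.loc[self.counts.columns]
        if "group" not in self.annotation.columns:
            self.annotation = self.annotation.assign(
                group=self.annotation["surgery"] + self.annotation["diet"]
            )
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise InputError(f"samples with zero total count: {empty}")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        """Raw per-sample column totals."""
        return self.counts.sum(axis=0)

    @property
    def groups(self) -> pd.Series:
        return self.annotation["group"]

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.annotation.index[self.annotation["group"] == group]
        return list(sel)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.annotation.copy())

    # -- text serialization ----------------------------------------------------

    def to_tsv(self, counts_path, annotation_path=None) -> None:
        out = self.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t")
        if annotation_path is not None:
            ann = self.annotation.copy()
            ann.index.name = "sample_id"
            ann.to_csv(annotation_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, annotation_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        return cls(counts, ann)


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group comparison.

    ``lfc_mle`` is the log2 fold change of ``test`` over ``reference``
    (positive = higher in the test group).  ``tested`` is False for genes
    with zero counts across every sample of the contrast; their statistics
    are NaN and they are excluded from the BH denominator.
    """

    reference: str
    test: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(CONTRAST_COLUMNS) - set(self.table.columns)
        if missing:
            raise InputError(f"contrast table missing columns: {sorted(missing)}")

    @property
    def name(self) -> str:
        return f"{self.reference}_vs_{self.test}"

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        out = self.table.loc[:, list(CONTRAST_COLUMNS)].copy()
        out.index.name = "gene_id"
        out.insert(0, "contrast_reference", self.reference)
        out.insert(1, "contrast_test", self.test)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ContrastResult":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        ref = str(frame["contrast_reference"].iloc[0])
        test = str(frame["contrast_test"].iloc[0])
        table = frame.drop(columns=["contrast_reference", "contrast_test"])
        table["tested"] = table["tested"].astype(bool)
        return cls(ref, test, table)


def common_gene_universe(res_a: ContrastResult, res_b: ContrastResult) -> pd.Index:
    """Shared gene ids of two contrast results; error when disjoint."""
    shared = res_a.gene_ids.intersection(res_b.gene_ids)
    if len(shared) == 0:
        raise InputError("contrast results have disjoint gene universes")
    return shared


def group_means(norm_counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean of (already normalized) counts, columns ordered canonically."""
    means = norm_counts.T.groupby(annotation["group"]).mean().T
    order = [g for g in GROUP_ORDER if g in means.columns]
    extra = [g for g in means.columns if g not in order]
    return means.loc[:, order + extra]


def as_count_frame(counts) -> pd.DataFrame:
    """Accept either a CountMatrix or a plain DataFrame of counts."""
    if isinstance(counts, CountMatrix):
        return counts.counts
    if isinstance(counts, pd.DataFrame):
        return counts
    return pd.DataFrame(np.asarray(counts))
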