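"""Top-gene selection, heatmap preparation, and PubMed hit categorization.

Heatmaps of the derived gene sets display a fixed number of top-ranked genes
per condition.  Because "top N in every contrast simultaneously" depends on
how deep one cuts each ranking, the cut is found iteratively: the smallest
rank fraction whose per-contrast top lists share at least N genes, the
shared set then trimmed to exactly N by mean rank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .containers import ContrastResult, CountMatrix, GROUP_ORDER
from .de import estimate_size_factors
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: Keyword lists used when fetching PubMed hit counts externally.  The
#: package itself never queries PubMed; it consumes cached hit-count tables.
PUBMED_KEYWORDS = {
    "hfd": ("high-fat diet", "HFD", "high-fat feeding", "fat-rich diet"),
    "obesity": ("obesity", "adiposity", "weight gain", "body mass index"),
}

PUBMED_CATEGORIES = ("shared", "obesity_only", "hfd_only", "none")


def _metric_ranks(result: ContrastResult, genes: pd.Index, metric: str) -> pd.Series:
    table = result.table.loc[genes]
    if metric == "p_value":
        values = table["p_value"]
        ascending = True
    elif metric == "abs_lfc":
        values = table["lfc_mle"].abs()
        ascending = False
    else:
        raise ParameterError("metric must be 'p_value' or 'abs_lfc'")
    return values.rank(ascending=ascending, method="first")


def select_top_genes_iterative(
    results,
    gene_universe,
    metric: str = "p_value",
    n: int = 25,
    *,
    bisection_steps: int = 40,
) -> tuple[list, float]:
    """Select ``n`` genes ranking highly on ``metric`` in *every* contrast.

    Bisection finds the smallest rank fraction ``q`` such that the genes in
    the top-``q`` fraction of every contrast number at least ``n``; the
    intersection is trimmed to exactly ``n`` by ascending mean rank across
    contrasts (ties: gene id).  Returns the gene list and the final fraction.
    """
    if n < 1:
        raise ParameterError("n must be at least 1")
    genes = pd.Index(gene_universe)
    if len(genes) == 0:
        raise InputError("empty gene universe")
    results = list(results)
    for res in results:
        missing = genes.difference(res.gene_ids)
        if len(missing):
            raise InputError(f"universe genes absent from {res.name}: {list(missing)[:10]}")

    ranks = pd.DataFrame({i: _metric_ranks(r, genes, metric) for i, r in enumerate(results)})
    mean_rank = ranks.mean(axis=1)
    order = sorted(genes, key=lambda g: (mean_rank[g], g))

    if len(genes) < n:
        logger.info(
            "select_top_genes_iterative: universe has only %d genes (n=%d)", len(genes), n
        )
        return order, 1.0

    g_total = len(genes)

    def shared_at(q: float) -> pd.Index:
        cutoff = np.ceil(q * g_total)
        mask = (ranks <= cutoff).all(axis=1)
        return genes[mask]

    lo, hi = 0.0, 1.0
    for _ in range(bisection_steps):
        mid = (lo + hi) / 2.0
        if len(shared_at(mid)) >= n:
            hi = mid
        else:
            lo = mid
    final_q = hi
    shared = shared_at(final_q)
    trimmed = sorted(shared, key=lambda g: (mean_rank[g], g))[:n]
    return trimmed, float(final_q)


def rlog_proxy_and_scale(counts: CountMatrix, gene_list) -> pd.DataFrame:
    """Row-scaled log expression for heatmap display.

    value(g, s) = log2(count/size_factor + 1), then each row is centered and
    scaled to unit variance (sd with n-1 denominator, matching the row
    scaling of standard heatmap tools).  Constant rows come back all-zero.
    """
    genes = list(gene_list)
    missing = [g for g in genes if g not in counts.gene_ids]
    if missing:
        raise InputError(f"unknown genes: {missing[:10]}")
    sf = estimate_size_factors(counts)
    log_norm = np.log2(counts.counts.loc[genes] / sf + 1.0)
    centered = log_norm.sub(log_norm.mean(axis=1), axis=0)
    sd = log_norm.std(axis=1, ddof=1)
    constant = sd <= 0
    if constant.any():
        logger.info(
            "rlog_proxy_and_scale: %d constant row(s) returned as zeros", int(constant.sum())
        )
    sd = sd.mask(constant, 1.0)
    scaled = centered.div(sd, axis=0)
    scaled.loc[constant] = 0.0
    return scaled


def prepare_heatmap(counts: CountMatrix, gene_list) -> pd.DataFrame:
    """Row-scaled matrix with genes ordered by hierarchical clustering
    (Euclidean distance, complete linkage) and columns in the fixed design
    order ShamChow, RYGBChow, ShamHFD, RYGBHFD."""
    scaled = rlog_proxy_and_scale(counts, gene_list)
    if scaled.shape[0] > 2:
        order = leaves_list(linkage(scaled.to_numpy(), method="complete", metric="euclidean"))
        scaled = scaled.iloc[order]
    col_order = [
        s for g in GROUP_ORDER for s in counts.samples_in_group(g) if s in scaled.columns
    ]
    return scaled.loc[:, col_order]


def categorize_pubmed_hits(table: pd.DataFrame) -> tuple[dict, pd.DataFrame]:
    """Categorize genes by positivity of their HFD / obesity PubMed hit counts.

    ``table`` needs integer columns ``hits_hfd`` and ``hits_obesity``; a gene
    is ``shared`` when both are positive, ``hfd_only``/``obesity_only`` when
    exactly one is, ``none`` otherwise.  Returns (category counts, annotated
    table).
    """
    for col in ("hits_hfd", "hits_obesity"):
        if col not in table.columns:
            raise InputError(f"missing column {col!r}")
        if (table[col] < 0).any():
            raise InputError(f"negative counts in {col!r}")
    hfd = table["hits_hfd"] > 0
    obesity = table["hits_obesity"] > 0
    category = np.select(
        [hfd & obesity, obesity & ~hfd, hfd & ~obesity],
        ["shared", "obesity_only", "hfd_only"],
        default="none",
    )
    annotated = table.assign(category=category)
    counts = {c: int((annotated["category"] == c).sum()) for c in PUBMED_CATEGORIES}
    return counts, annotated
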