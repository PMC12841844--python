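"""Enrichment-term post-processing: over-representation, signal ranking, and
two-step redundancy clustering.

Enrichment tables (from an external tool's export or from the internal
hypergeometric test) are ranked by *signal* — the geometric mean of a term's
strength (log10 observed/expected) and its capped -log10 FDR — then
de-duplicated in two steps: average-linkage hierarchical clustering on
Jaccard distances of member overlap, followed by a text merge of
near-duplicate labels (e.g. the same pathway annotated by two databases)
inside each cluster.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: Cap on -log10(FDR) inside the signal score.
SIGNAL_NEGLOG_CAP = 16.0

#: Stop words removed during text normalization of term labels (versioned:
#: changing this list changes text-merge behavior).
LABEL_STOP_WORDS = frozenset(
    "a an and by for in of on or the to via with process processes pathway pathways gene genes".split()
)


@dataclass(frozen=True)
class EnrichmentTerm:
    """One enrichment result row."""

    term_id: str
    source: str
    label: str
    members: frozenset
    background_members: int
    fdr: float
    strength: float
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"term {self.term_id}: empty member set")
        if not 0.0 < self.fdr <= 1.0:
            raise InputError(f"term {self.term_id}: fdr must lie in (0, 1]")

    def with_signal(self) -> "EnrichmentTerm":
        return EnrichmentTerm(
            self.term_id, self.source, self.label, self.members,
            self.background_members, self.fdr, self.strength,
            compute_signal(self.strength, self.fdr),
        )


@dataclass
class MergedEntry:
    """Terms whose labels were judged near-duplicates of one another."""

    terms: list
    labels: list
    representative: EnrichmentTerm


@dataclass
class TermCluster:
    """A Jaccard cluster of terms with its merged entries and representative."""

    members: list
    entries: list
    representative: EnrichmentTerm
    merged_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise InputError("cluster representative must be one of its members")


@dataclass(frozen=True)
class ORAResult:
    p_value: float
    strength: float | None  # None when observed == 0 (log10 undefined)
    observed: int
    expected: float


def overrepresentation_test(gene_set, pathway_members, background) -> ORAResult:
    """Hypergeometric over-representation test against a custom background.

    p is the upper-tail probability of drawing at least the observed overlap;
    strength = log10(observed/expected), flagged ``None`` when observed is 0.
    """
    background = set(background)
    gene_set = set(gene_set)
    pathway = set(pathway_members)
    stray = gene_set - background
    if stray:
        raise InputError(f"gene set members outside background: {sorted(stray)[:10]}")
    if not pathway <= background:
        raise InputError("pathway members must be a subset of the background")
    M = len(background)
    n = len(pathway)
    N = len(gene_set)
    k = len(gene_set & pathway)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    expected = n * N / M if M else 0.0
    strength = float(np.log10(k / expected)) if k > 0 and expected > 0 else None
    return ORAResult(p_value=min(p, 1.0), strength=strength, observed=k, expected=expected)


def compute_signal(strength: float, fdr: float) -> float:
    """signal = sqrt(max(strength, 0) * min(-log10 fdr, cap)).

    Monotone non-decreasing in strength and in -log10(FDR); zero whenever the
    term is not enriched (strength <= 0) or not significant (fdr = 1).
    """
    if not 0.0 < fdr <= 1.0:
        raise InputError("fdr must lie in (0, 1]")
    neglog = min(-np.log10(fdr), SIGNAL_NEGLOG_CAP)
    return float(np.sqrt(max(strength, 0.0) * neglog))


def jaccard_distance(set_a, set_b) -> float:
    """1 - |a & b| / |a | b|, both sets required non-empty."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise InputError("Jaccard distance of an empty set is undefined")
    return 1.0 - len(a & b) / len(a | b)


def normalize_label(label: str) -> frozenset:
    """Lowercase, strip punctuation and stop words; return the token set."""
    tokens = re.split(r"[^a-z0-9]+", label.lower())
    # crude singularization so "pathways"/"pathway" and "genes"/"gene" merge
    out = set()
    for t in tokens:
        if not t or t in LABEL_STOP_WORDS:
            continue
        if len(t) > 3 and t.endswith("s") and t[:-1] not in LABEL_STOP_WORDS:
            t = t[:-1]
        if t in LABEL_STOP_WORDS:
            continue
        out.add(t)
    return frozenset(out)


def _token_jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def _rep_key(term: EnrichmentTerm):
    """Max signal; ties broken by smaller fdr, then lexicographic term id."""
    return (-term.signal, term.fdr, term.term_id)


def cluster_terms(
    terms, jaccard_cutoff: float = 0.5, text_cutoff: float = 0.8
) -> list[TermCluster]:
    """Two-step redundancy clustering of enrichment terms.

    Step 1: average-linkage hierarchical clustering on pairwise Jaccard
    distances of member sets, cut at ``jaccard_cutoff``.  Step 2: within each
    cluster, terms whose normalized-label token sets have Jaccard similarity
    >= ``text_cutoff`` are merged into one entry.  Every cluster's
    representative is its maximal-signal member.
    """
    if not 0.0 < jaccard_cutoff < 1.0 or not 0.0 < text_cutoff < 1.0:
        raise ParameterError("cutoffs must lie in (0, 1)")
    terms = [t.with_signal() if t.signal == 0.0 else t for t in terms]
    if not terms:
        return []
    # deterministic internal order regardless of input order
    terms = sorted(terms, key=_rep_key)
    if len(terms) == 1:
        only = terms[0]
        return [TermCluster([only], [MergedEntry([only], [only.label], only)], only)]

    n = len(terms)
    condensed = np.array(
        [
            jaccard_distance(terms[i].members, terms[j].members)
            for i in range(n)
            for j in range(i + 1, n)
        ]
    )
    tree = linkage(condensed, method="average")
    labels = fcluster(tree, t=jaccard_cutoff, criterion="distance")

    clusters: list[TermCluster] = []
    for cid in np.unique(labels):
        members = [terms[i] for i in np.nonzero(labels == cid)[0]]
        entries = _text_merge(members, text_cutoff)
        rep = min(members, key=_rep_key)
        rep_entry = next(e for e in entries if rep in e.terms)
        merged = [t.label for t in rep_entry.terms if t is not rep]
        clusters.append(TermCluster(members, entries, rep, merged))
    clusters.sort(key=lambda c: _rep_key(c.representative))
    return clusters


def _text_merge(members, text_cutoff: float) -> list[MergedEntry]:
    """Union-find merge of near-duplicate labels within one cluster."""
    tokens = [normalize_label(t.label) for t in members]
    parent = list(range(len(members)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if _token_jaccard(tokens[i], tokens[j]) >= text_cutoff:
                parent[find(j)] = find(i)

    groups: dict[int, list] = {}
    for i, term in enumerate(members):
        groups.setdefault(find(i), []).append(term)
    entries = []
    for group in groups.values():
        rep = min(group, key=_rep_key)
        entries.append(MergedEntry(group, [t.label for t in group], rep))
    entries.sort(key=lambda e: _rep_key(e.representative))
    return entries


def top_terms(terms, k: int = 10) -> list[EnrichmentTerm]:
    """The k highest-signal terms (descending signal; ties: fdr, term id).

    Typically fed the cluster representatives.  Returns the whole list with a
    logged notice when fewer than k are available.
    """
    if k < 1:
        raise ParameterError("k must be at least 1")
    ranked = sorted(terms, key=_rep_key)
    if len(ranked) < k:
        logger.info("top_terms: only %d terms available (k=%d)", len(ranked), k)
        return ranked
    return ranked[:k]


def gene_set_contribution(gene_set, terms) -> float:
    """Fraction of the union of term members covered by ``gene_set``."""
    terms = list(terms)
    if not terms:
        raise InputError("terms must be non-empty")
    union: set = set()
    for t in terms:
        union |= set(t.members)
    if not union:
        raise InputError("union of term members is empty")
    return len(set(gene_set) & union) / len(union)


def read_terms_tsv(path) -> list[EnrichmentTerm]:
    """Read an enrichment table: term_id, source, description, members
    (comma-separated), background_count, fdr, strength."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for _, row in frame.iterrows():
        out.append(
            EnrichmentTerm(
                term_id=str(row["term_id"]),
                source=str(row["source"]),
                label=str(row["description"]),
                members=frozenset(str(row["members"]).split(",")),
                background_members=int(row["background_count"]),
                fdr=float(row["fdr"]),
                strength=float(row["strength"]),
            ).with_signal()
        )
    return out
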