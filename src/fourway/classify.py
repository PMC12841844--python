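"""Directional overlap classification of the four pairwise contrasts.

Four derived gene sets, each split by direction:

* ``rygb_induced``      — significant (unadjusted p < alpha) in both surgery
  contrasts with the same nonzero LFC sign;
* ``reversal``          — RYGB-induced genes whose obesity-signature
  (ShamChow vs ShamHFD) change is significant and opposite in sign;
* ``hfd_induced``       — the same same-direction intersection applied to the
  two diet contrasts;
* ``rygb_specific_hfd`` — genes of the RYGBChow vs RYGBHFD contrast passing
  an adjusted-p filter after removing the HFD-induced set.

Direction is always taken from the sign of the MLE LFC (never the shrunk
LFC); a gene with LFC exactly zero has no direction and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import ContrastResult, common_gene_universe
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class DirectionalSets:
    """An up/down pair of gene-identifier sets."""

    up: frozenset
    down: frozenset

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise InputError("up and down sets overlap")

    @property
    def all(self) -> frozenset:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class GeneSets:
    """The four derived gene sets plus the provenance of their derivation."""

    rygb_induced: DirectionalSets
    hfd_induced: DirectionalSets
    reversal: DirectionalSets
    rygb_specific_hfd: DirectionalSets
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reversal.all <= self.rygb_induced.all:
            raise InputError("reversal genes must be a subset of the RYGB-induced set")
        if self.rygb_specific_hfd.all & self.hfd_induced.all:
            raise InputError("RYGB-specific set must exclude HFD-induced genes")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for category in ("rygb_induced", "hfd_induced", "reversal", "rygb_specific_hfd"):
            sets = getattr(self, category)
            for direction in ("up", "down"):
                for gene in sorted(getattr(sets, direction)):
                    rows.append((gene, category, direction))
        return pd.DataFrame(rows, columns=["gene_id", "category", "direction"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")


def intersect_common(
    res_a: ContrastResult, res_b: ContrastResult, alpha: float = 0.05
) -> DirectionalSets:
    """Genes significant (p < alpha, unadjusted) in both contrasts with the
    same nonzero LFC direction, split by that shared direction."""
    _check_alpha(alpha)
    shared = common_gene_universe(res_a, res_b)
    a = res_a.table.loc[shared]
    b = res_b.table.loc[shared]
    tested = a["tested"] & b["tested"]
    sig = tested & (a["p_value"] < alpha) & (b["p_value"] < alpha)
    up = sig & (a["lfc_mle"] > 0) & (b["lfc_mle"] > 0)
    down = sig & (a["lfc_mle"] < 0) & (b["lfc_mle"] < 0)
    return DirectionalSets(
        up=frozenset(shared[up]), down=frozenset(shared[down])
    )


def derive_reversal(
    rygb_sets: DirectionalSets, obesity_res: ContrastResult, alpha: float = 0.05
) -> DirectionalSets:
    """RYGB-induced genes whose obesity-signature change is significant and
    points the opposite way.

    ``obesity_res`` must be the ShamChow vs ShamHFD contrast (test = ShamHFD);
    up/down labels follow the RYGB direction.
    """
    _check_alpha(alpha)
    missing = rygb_sets.all - set(obesity_res.gene_ids)
    if missing:
        raise InputError(
            f"RYGB-induced genes absent from obesity contrast: {sorted(missing)[:10]}"
        )
    table = obesity_res.table

    def _opposing(genes, rygb_sign):
        out = set()
        for g in genes:
            row = table.loc[g]
            if not bool(row["tested"]):
                continue
            if row["p_value"] < alpha and row["lfc_mle"] * rygb_sign < 0:
                out.add(g)
        return out

    return DirectionalSets(
        up=frozenset(_opposing(rygb_sets.up, +1.0)),
        down=frozenset(_opposing(rygb_sets.down, -1.0)),
    )


def classify_hfd_induced(
    res_sham: ContrastResult, res_rygb: ContrastResult, alpha: float = 0.05
) -> DirectionalSets:
    """Same-direction significance intersection of the two diet contrasts."""
    return intersect_common(res_sham, res_rygb, alpha)


def refine_specific(
    res: ContrastResult, exclusion, alpha_adj: float = 0.05
) -> DirectionalSets:
    """Adjusted-p filter of a contrast after removing an exclusion set.

    ``res`` should be the RYGBChow vs RYGBHFD contrast, ``exclusion`` the
    HFD-induced genes.  BH adjustment is the one computed over all tested
    genes of the contrast; exclusion is a set subtraction applied afterwards.
    """
    _check_alpha(alpha_adj)
    exclusion = set(exclusion)
    table = res.table
    keep = table["tested"] & ~table.index.isin(exclusion) & (table["p_adj"] < alpha_adj)
    up = keep & (table["lfc_mle"] > 0)
    down = keep & (table["lfc_mle"] < 0)
    return DirectionalSets(
        up=frozenset(table.index[up]), down=frozenset(table.index[down])
    )


def derive_gene_sets(
    contrasts: dict[str, ContrastResult],
    alpha: float = 0.05,
    alpha_adj: float = 0.05,
) -> GeneSets:
    """Derive all four gene sets from the standard four contrasts.

    ``contrasts`` must hold the keys produced by
    :func:`fourway.de.run_standard_contrasts`.
    """
    required = {"surgery_chow", "surgery_hfd", "diet_sham", "diet_rygb"}
    missing = required - set(contrasts)
    if missing:
        raise InputError(f"missing contrasts: {sorted(missing)}")

    rygb = intersect_common(contrasts["surgery_chow"], contrasts["surgery_hfd"], alpha)
    reversal = derive_reversal(rygb, contrasts["diet_sham"], alpha)
    hfd = classify_hfd_induced(contrasts["diet_sham"], contrasts["diet_rygb"], alpha)
    specific = refine_specific(contrasts["diet_rygb"], hfd.all, alpha_adj)

    provenance = {
        "alpha": alpha,
        "alpha_adj": alpha_adj,
        "contrasts": {k: contrasts[k].name for k in sorted(required)},
        "bh_scope": "all tested genes of the contrast, before exclusion",
        "direction_source": "lfc_mle sign",
    }
    return GeneSets(
        rygb_induced=rygb,
        hfd_induced=hfd,
        reversal=reversal,
        rygb_specific_hfd=specific,
        provenance=provenance,
    )
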