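"""Stratified label-permutation validation of directional gene-set overlaps.

The overlap of "significant, same-direction in both contrasts" gene sets is
validated against a null built by shuffling one factor's labels within the
strata of the other factor — surgery labels within each diet when validating
the surgery-common (RYGB-induced) set, diet labels within each surgical group
for the diet-common (HFD-induced) set.  Each iteration re-runs the two
relevant DE contrasts on the permuted labels and records the overlap
statistic; the empirical p-value uses the add-one formula

    p = (#{null overlaps >= observed} + 1) / (N + 1),

which is bounded below by 1/(N + 1) and never exactly zero.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

from .containers import CountMatrix
from .classify import intersect_common
from .de import estimate_size_factors
from .errors import DesignError, InputError, ParameterError

_FACTOR_LEVELS = {"surgery": ("Sham", "RYGB"), "diet": ("Chow", "HFD")}


@dataclass
class PermutationOutcome:
    """Observed overlap, its permutation null, and the empirical p-value."""

    observed_overlap: int
    null_overlaps: np.ndarray = field(repr=False)
    n_permutations: int
    p_empirical: float
    shuffled_factor: str
    strata: str
    seed: int | None
    alpha: float

    def to_json(self, path, *, include_null: bool = False) -> None:
        null = np.asarray(self.null_overlaps)
        payload = {
            "observed_overlap": int(self.observed_overlap),
            "n_permutations": int(self.n_permutations),
            "p_empirical": float(self.p_empirical),
            "shuffled_factor": self.shuffled_factor,
            "strata": self.strata,
            "seed": self.seed,
            "alpha": self.alpha,
            "null_quantiles": {
                str(q): float(np.quantile(null, q)) for q in (0.5, 0.9, 0.95, 0.99, 1.0)
            },
        }
        if include_null:
            payload["null_overlaps"] = [int(v) for v in null]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def empirical_p(n_geq: int, n_total: int) -> float:
    """Add-one empirical p-value: (n_geq + 1) / (n_total + 1)."""
    if n_total < 1:
        raise ParameterError("n_total must be at least 1")
    if not 0 <= n_geq <= n_total:
        raise InputError(f"n_geq must lie in [0, {n_total}], got {n_geq}")
    return (n_geq + 1) / (n_total + 1)


def permute_labels_within_strata(
    annotation: pd.DataFrame,
    shuffle: str,
    stratify_by: str,
    seed=None,
) -> pd.DataFrame:
    """Shuffle one factor's labels within each stratum of the other factor.

    The multiset of shuffled labels is preserved within every stratum; the
    stratifying factor is untouched and the ``group`` column is rebuilt.
    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if shuffle not in _FACTOR_LEVELS or stratify_by not in _FACTOR_LEVELS:
        raise ParameterError("shuffle and stratify_by must be 'surgery' or 'diet'")
    if shuffle == stratify_by:
        raise ParameterError("cannot stratify by the shuffled factor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    out = annotation.copy()
    for stratum in out[stratify_by].unique():
        mask = out[stratify_by] == stratum
        labels = out.loc[mask, shuffle].to_numpy()
        if len(set(labels)) < 2:
            raise DesignError(
                f"stratum {stratum!r} has a single {shuffle} level; cannot permute"
            )
        out.loc[mask, shuffle] = rng.permutation(labels)
    out["group"] = out["surgery"] + out["diet"]
    return out


def overlap_statistic(res_a, res_b, alpha: float = 0.05) -> int:
    """Count of genes significant (p < alpha) in both contrasts with the same
    nonzero LFC sign — |up| + |down| of the directional intersection."""
    sets = intersect_common(res_a, res_b, alpha)
    return len(sets)


def _stratum_contrasts(shuffle: str) -> list[tuple[str, str]]:
    """The two (reference, test) group pairs whose overlap is validated."""
    lo, hi = _FACTOR_LEVELS[shuffle]
    strata_factor = "diet" if shuffle == "surgery" else "surgery"
    out = []
    for stratum in _FACTOR_LEVELS[strata_factor]:
        if shuffle == "surgery":
            out.append((f"{lo}{stratum}", f"{hi}{stratum}"))
        else:
            out.append((f"{stratum}{lo}", f"{stratum}{hi}"))
    return out


class _OverlapEngine:
    """Vectorized overlap statistic for arbitrary relabelings of the samples.

    Every evaluation re-estimates the per-gene moment dispersions under the
    labeling it is handed — mirroring a full re-run of the DE analysis — so
    the observed statistic and the permuted ones are computed identically.
    (Reusing dispersions fitted under the observed grouping would bias the
    observed overlap upward: a gene whose chance between-group difference is
    large under the observed labels has, conditionally, a smaller
    within-group variance under those same labels.)

    ``refit_trend`` controls whether the two-parameter dispersion trend is
    refit per labeling (the "full" backend) or reused from the observed
    grouping (the "fast" backend); the trend is global, so reusing it does
    not couple individual genes to the observed labels.
    """

    def __init__(self, counts: CountMatrix, shuffle: str, alpha: float, refit_trend: bool):
        from .de import MIN_DISPERSION, fit_dispersion_trend

        self.alpha = alpha
        self.refit_trend = refit_trend
        self.shrink_weight = 0.75
        self._fit_trend = fit_dispersion_trend
        self._min_disp = MIN_DISPERSION

        sf = estimate_size_factors(counts)
        self.norm = counts.counts.to_numpy(dtype=float) / sf.to_numpy()
        self.norm_sq = self.norm**2
        self.overall_mean = self.norm.mean(axis=1)

        ann = counts.annotation
        strata_factor = "diet" if shuffle == "surgery" else "surgery"
        lo, hi = _FACTOR_LEVELS[shuffle]
        self.strata: list[dict] = []
        for stratum in _FACTOR_LEVELS[strata_factor]:
            mask = (ann[strata_factor] == stratum).to_numpy()
            cols = np.nonzero(mask)[0]
            labels = ann[shuffle].to_numpy()[cols]
            counts_sub = counts.counts.to_numpy()[:, cols]
            self.strata.append(
                {
                    "cols": cols,
                    "ref_local": np.nonzero(labels == lo)[0],
                    "test_local": np.nonzero(labels == hi)[0],
                    "tested": counts_sub.sum(axis=1) > 0,
                }
            )
        # trend of the observed grouping (all four groups)
        groups = ann["group"].to_numpy()
        raw = self._raw_dispersion(
            [np.nonzero(groups == g)[0] for g in np.unique(groups)]
        )
        self.observed_trend = self._fit_trend(self.overall_mean, raw)

    def _raw_dispersion(self, group_cols: list[np.ndarray]) -> np.ndarray:
        ss = np.zeros(self.norm.shape[0])
        df = 0
        for cols in group_cols:
            n = len(cols)
            gsum = self.norm[:, cols].sum(axis=1)
            gsq = self.norm_sq[:, cols].sum(axis=1)
            ss += gsq - gsum**2 / n
            df += n - 1
        pooled = ss / max(df, 1)
        mu = self.overall_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (pooled - mu) / mu**2
        raw = np.where(np.isfinite(raw), raw, 0.0)
        return np.maximum(raw, 0.0)

    def overlap(self, stratum_assignments: list[tuple[np.ndarray, np.ndarray]]) -> int:
        """Overlap statistic for one labeling.

        ``stratum_assignments`` holds, per stratum, local indices (into the
        stratum's columns) of the reference- and test-labeled samples.
        """
        from .de import PSEUDO_MEAN_FLOOR

        group_cols = []
        for stratum, (ref_local, test_local) in zip(self.strata, stratum_assignments):
            group_cols.append(stratum["cols"][ref_local])
            group_cols.append(stratum["cols"][test_local])
        raw = self._raw_dispersion(group_cols)
        if self.refit_trend:
            a0, a1 = self._fit_trend(self.overall_mean, raw)
        else:
            a0, a1 = self.observed_trend
        trend = a0 + a1 / np.maximum(self.overall_mean, PSEUDO_MEAN_FLOOR)
        alpha_disp = np.maximum(
            self.shrink_weight * trend + (1.0 - self.shrink_weight) * raw,
            self._min_disp,
        )

        sig_mask = None
        sign_ref = None
        for stratum, (ref_local, test_local) in zip(self.strata, stratum_assignments):
            ref_cols = stratum["cols"][ref_local]
            test_cols = stratum["cols"][test_local]
            mu_r = np.maximum(self.norm[:, ref_cols].mean(axis=1), PSEUDO_MEAN_FLOOR)
            mu_t = np.maximum(self.norm[:, test_cols].mean(axis=1), PSEUDO_MEAN_FLOOR)
            lfc = np.log2(mu_t / mu_r)
            se = np.log2(np.e) * np.sqrt(
                (1.0 / mu_t + alpha_disp) / len(test_cols)
                + (1.0 / mu_r + alpha_disp) / len(ref_cols)
            )
            p = 2.0 * stats.norm.sf(np.abs(lfc / se))
            sig = stratum["tested"] & (p < self.alpha) & (lfc != 0.0)
            if sig_mask is None:
                sig_mask, sign_ref = sig, np.sign(lfc)
            else:
                sig_mask = sig_mask & sig & (np.sign(lfc) == sign_ref)
        return int(sig_mask.sum())

    def identity_assignments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(s["ref_local"], s["test_local"]) for s in self.strata]

    def permuted_assignments(self, rng: np.random.Generator):
        out = []
        for stratum in self.strata:
            n = len(stratum["cols"])
            perm = rng.permutation(n)
            n_ref = len(stratum["ref_local"])
            # the permuted positions of the reference labels
            labels = np.empty(n, dtype=bool)
            labels[:] = False
            labels[perm[:n_ref]] = True
            out.append((np.nonzero(labels)[0], np.nonzero(~labels)[0]))
        return out


def _exhaustive_assignments(engine: _OverlapEngine):
    """Yield every distinct within-stratum (reference, test) local assignment."""
    per_stratum = []
    for stratum in engine.strata:
        n = len(stratum["cols"])
        n_ref = len(stratum["ref_local"])
        options = []
        for ref in itertools.combinations(range(n), n_ref):
            ref = np.asarray(ref, dtype=int)
            test = np.setdiff1d(np.arange(n), ref)
            options.append((ref, test))
        per_stratum.append(options)
    yield from itertools.product(*per_stratum)


def run_permutation_test(
    counts: CountMatrix,
    shuffle: str = "surgery",
    alpha: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
    *,
    backend: str = "fast",
    exhaustive: bool = False,
) -> PermutationOutcome:
    """Stratified permutation test of the directional overlap statistic.

    Parameters
    ----------
    shuffle
        Factor whose labels are permuted (``"surgery"`` validates the
        RYGB-induced overlap, ``"diet"`` the HFD-induced one); the other
        factor defines the strata.
    backend
        Both backends re-estimate the per-gene moment dispersions under each
        permuted grouping (a full per-iteration DE re-run); ``"fast"`` reuses
        the two-parameter dispersion *trend* fitted under the observed
        grouping, while ``"full"`` also refits the trend per iteration.  Size
        factors are label-independent and always computed once.
    exhaustive
        Enumerate every distinct within-stratum assignment instead of
        sampling; ``n_permutations`` is then ignored.
    """
    if backend not in ("fast", "full"):
        raise ParameterError("backend must be 'fast' or 'full'")
    if not exhaustive and n_permutations < 1:
        raise ParameterError("n_permutations must be at least 1")
    strata_factor = "diet" if shuffle == "surgery" else "surgery"
    for stratum_level in _FACTOR_LEVELS[strata_factor]:
        sub = counts.annotation[counts.annotation[strata_factor] == stratum_level]
        if sub[shuffle].nunique() < 2:
            raise DesignError(
                f"stratum {stratum_level!r} lacks both {shuffle} levels"
            )

    engine = _OverlapEngine(counts, shuffle, alpha, refit_trend=(backend == "full"))
    observed = engine.overlap(engine.identity_assignments())

    null = []
    if exhaustive:
        for assignment in _exhaustive_assignments(engine):
            null.append(engine.overlap(list(assignment)))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            null.append(engine.overlap(engine.permuted_assignments(rng)))

    null = np.asarray(null, dtype=int)
    n_geq = int((null >= observed).sum())
    return PermutationOutcome(
        observed_overlap=int(observed),
        null_overlaps=null,
        n_permutations=len(null),
        p_empirical=empirical_p(n_geq, len(null)),
        shuffled_factor=shuffle,
        strata=strata_factor,
        seed=seed if not exhaustive else None,
        alpha=alpha,
    )
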