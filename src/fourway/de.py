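"""Self-contained negative-binomial differential-expression core.

This module implements the two-group NB Wald workflow the rest of the
pipeline consumes: median-of-ratios size factors, per-gene moment
dispersion estimates shrunk toward a 1/mu trend, a group-mean Wald test
on normalized counts, Benjamini–Hochberg adjustment, and ridge-style LFC
shrinkage under a zero-centered normal prior.

It is a documented simplification of the DESeq2 family of tools: the
downstream overlap logic consumes only (p, p_adj, LFC sign and
magnitude), which this core supplies, and exact numerical parity with
any particular external tool is not a goal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTRAST_COLUMNS, ContrastResult, CountMatrix, as_count_frame
from .errors import ContrastError, DesignError, InputError, NormalizationError, ParameterError

#: Floor applied to group means before the log-ratio, to avoid infinities.
PSEUDO_MEAN_FLOOR = 1e-8
#: Floor for dispersions entering log-space shrinkage.
MIN_DISPERSION = 1e-8


def estimate_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors.

    factor(s) = median over genes (with positive geometric mean) of
    count(g, s) / geometric_mean_over_samples(count(g, .)).
    """
    frame = as_count_frame(counts).astype(float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(frame.to_numpy())
    finite = np.isfinite(log_counts).all(axis=1)
    if not finite.any():
        raise NormalizationError(
            "no gene has nonzero counts in every sample; size factors undefined"
        )
    log_geo_mean = log_counts[finite].mean(axis=1)
    ratios = np.exp(log_counts[finite] - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=frame.columns, name="size_factor")


def fit_dispersion_trend(
    mean: np.ndarray, disp: np.ndarray, *, n_iter: int = 3
) -> tuple[float, float]:
    """Fit alpha_tr(mu) = a0 + a1/mu to per-gene moment dispersions.

    Moment estimates are strongly heteroskedastic — their sampling standard
    deviation scales with (alpha + 1/mu) — so an unweighted fit is dominated
    by noisy low-mean genes.  The fit is therefore iteratively reweighted
    least squares with weights 1 / (alpha_tr(mu) + 1/mu)^2, starting from an
    unweighted pass.
    """
    ok = (mean > 0) & (disp > 0) & np.isfinite(disp)
    if ok.sum() < 2:
        return (max(float(np.nanmedian(disp)), MIN_DISPERSION), 0.0)
    mu = mean[ok]
    y = disp[ok]
    design = np.column_stack([np.ones(len(mu)), 1.0 / mu])
    w = np.ones(len(mu))
    a0, a1 = MIN_DISPERSION, 0.0
    for _ in range(max(n_iter, 1)):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        a0 = max(float(coef[0]), MIN_DISPERSION)
        a1 = max(float(coef[1]), 0.0)
        scale = a0 + a1 / mu + 1.0 / mu
        w = 1.0 / scale**2
    return a0, a1


def estimate_dispersions(
    counts,
    size_factors: pd.Series | None = None,
    groups: pd.Series | None = None,
    *,
    shrink_weight: float = 0.75,
) -> pd.Series:
    """Per-gene NB dispersions: method-of-moments, shrunk toward a 1/mu trend.

    The raw estimate is ``max(0, (pooled within-group variance - mean)/mean^2)``
    on normalized counts; it is then combined with the fitted trend
    ``a0 + a1/mu`` by a weighted arithmetic average, ``shrink_weight`` on the
    trend.  Averaging on the natural scale (rather than log) keeps the
    estimator unbiased around the trend despite the zero truncation of the
    raw moments; with only a handful of residual degrees of freedom per gene
    the raw moments are very noisy, hence the strong default weight.
    """
    if isinstance(counts, CountMatrix) and groups is None:
        groups = counts.groups
    frame = as_count_frame(counts)
    if groups is None:
        raise DesignError("group labels are required to estimate dispersions")
    groups = pd.Series(groups).loc[frame.columns]
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise DesignError(f"groups with fewer than 2 samples: {small}")
    if not 0.0 <= shrink_weight <= 1.0:
        raise ParameterError("shrink_weight must lie in [0, 1]")

    if size_factors is None:
        size_factors = estimate_size_factors(frame)
    norm = frame.to_numpy(dtype=float) / size_factors.loc[frame.columns].to_numpy()

    overall_mean = norm.mean(axis=1)
    # pooled within-group variance, df = n_samples - n_groups
    ss = np.zeros(frame.shape[0])
    df = 0
    for g in sizes.index:
        cols = np.asarray(groups == g)
        sub = norm[:, cols]
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += cols.sum() - 1
    pooled_var = ss / max(df, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (pooled_var - overall_mean) / overall_mean**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    raw = np.maximum(raw, 0.0)

    a0, a1 = fit_dispersion_trend(overall_mean, raw)
    trend = a0 + a1 / np.maximum(overall_mean, PSEUDO_MEAN_FLOOR)
    shrunk = shrink_weight * trend + (1.0 - shrink_weight) * raw
    shrunk = np.maximum(shrunk, MIN_DISPERSION)
    return pd.Series(shrunk, index=frame.index, name="dispersion")


def raw_moment_dispersion(norm_mean: float, within_var: float) -> float:
    """Single-gene moment estimate max(0, (var - mean)/mean^2)."""
    if norm_mean <= 0:
        return 0.0
    return max(0.0, (within_var - norm_mean) / norm_mean**2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ridge_shrink(lfc: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Posterior mean under a zero-centered normal prior: lfc * t^2/(t^2 + se^2)."""
    if prior_sd <= 0:
        raise ParameterError("prior_sd must be positive")
    return lfc * prior_sd**2 / (prior_sd**2 + np.asarray(se, dtype=float) ** 2)


def shrink_lfc(result: ContrastResult, prior_sd="auto", *, quantile: float = 0.95) -> ContrastResult:
    """Fill ``lfc_shrunk`` with ridge-shrunk LFCs; p-values are untouched.

    ``prior_sd="auto"`` sets the prior scale to the ``quantile`` (default
    95th) of |lfc_mle| over tested genes.
    """
    table = result.table.copy()
    tested = table["tested"].to_numpy(dtype=bool)
    if prior_sd == "auto":
        abs_lfc = table.loc[tested, "lfc_mle"].abs()
        prior_sd = float(np.quantile(abs_lfc, quantile)) if len(abs_lfc) else 1.0
        prior_sd = max(prior_sd, 1e-6)
    if prior_sd <= 0:
        raise ParameterError("prior_sd must be positive")
    shrunk = np.full(len(table), np.nan)
    shrunk[tested] = ridge_shrink(
        table.loc[tested, "lfc_mle"].to_numpy(),
        table.loc[tested, "lfc_se"].to_numpy(),
        prior_sd,
    )
    table["lfc_shrunk"] = shrunk
    return ContrastResult(result.reference, result.test, table)


def wald_contrast(
    counts: CountMatrix,
    reference: str,
    test: str,
    *,
    size_factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    shrink: bool = True,
) -> ContrastResult:
    """Two-group NB Wald test on normalized counts.

    For each gene, the MLE log2 fold change is the log-ratio of the two
    normalized group means (with a small pseudo-mean floor); its standard
    error comes from the NB Fisher information at the fitted means and the
    shrunk dispersion:

        SE = log2(e) * sqrt((1/mu_t + alpha)/n_t + (1/mu_r + alpha)/n_r)

    p-values are two-sided normal tails of lfc/SE.  Genes with all-zero
    counts across both groups are flagged ``tested = False`` and excluded
    from the BH denominator.
    """
    groups = counts.groups
    for g in (reference, test):
        if g not in set(groups):
            raise ContrastError(f"unknown group label: {g!r}")
    if reference == test:
        raise ContrastError("reference and test groups must differ")

    ref_samples = counts.samples_in_group(reference)
    test_samples = counts.samples_in_group(test)
    if len(ref_samples) < 2 or len(test_samples) < 2:
        raise DesignError("both contrast groups need at least 2 samples")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors=size_factors)

    frame = counts.counts
    sf = size_factors.loc[frame.columns]
    norm = frame / sf

    mu_ref = norm[ref_samples].mean(axis=1).to_numpy()
    mu_test = norm[test_samples].mean(axis=1).to_numpy()
    n_ref, n_test = len(ref_samples), len(test_samples)
    alpha = dispersions.loc[frame.index].to_numpy()

    tested = (frame[ref_samples + test_samples].sum(axis=1) > 0).to_numpy()

    mu_r = np.maximum(mu_ref, PSEUDO_MEAN_FLOOR)
    mu_t = np.maximum(mu_test, PSEUDO_MEAN_FLOOR)
    lfc = np.log2(mu_t / mu_r)
    se = np.log2(np.e) * np.sqrt(
        (1.0 / mu_t + alpha) / n_test + (1.0 / mu_r + alpha) / n_ref
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(wald))

    base_mean = norm[ref_samples + test_samples].mean(axis=1).to_numpy()

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "lfc_mle": lfc,
            "lfc_se": se,
            "wald_stat": wald,
            "p_value": p,
            "p_adj": np.nan,
            "lfc_shrunk": np.nan,
            "tested": tested,
        },
        index=frame.index,
    )
    for col in ("base_mean", "lfc_mle", "lfc_se", "wald_stat", "p_value"):
        table.loc[~tested, col] = np.nan
    table.loc[tested, "p_adj"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())

    result = ContrastResult(reference, test, table.loc[:, list(CONTRAST_COLUMNS)])
    if shrink:
        result = shrink_lfc(result)
    return result


def run_standard_contrasts(
    counts: CountMatrix, *, shrink: bool = True
) -> dict[str, ContrastResult]:
    """Run the four pairwise contrasts of the 2x2 design.

    Keys: ``surgery_chow`` (ShamChow vs RYGBChow), ``surgery_hfd`` (ShamHFD vs
    RYGBHFD), ``diet_sham`` (ShamChow vs ShamHFD, the obesity signature) and
    ``diet_rygb`` (RYGBChow vs RYGBHFD).  Size factors and dispersions are
    estimated once and reused across contrasts.
    """
    size_factors = estimate_size_factors(counts)
    dispersions = estimate_dispersions(counts, size_factors=size_factors)
    specs = {
        "surgery_chow": ("ShamChow", "RYGBChow"),
        "surgery_hfd": ("ShamHFD", "RYGBHFD"),
        "diet_sham": ("ShamChow", "ShamHFD"),
        "diet_rygb": ("RYGBChow", "RYGBHFD"),
    }
    return {
        name: wald_contrast(
            counts, ref, test,
            size_factors=size_factors, dispersions=dispersions, shrink=shrink,
        )
        for name, (ref, test) in specs.items()
    }
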