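"""CPM/FPKM computation, noise-transition estimation and low-expression filtering.

Bulk RNA-seq count matrices carry a large population of genes whose counts
are sampling noise around zero.  The filtering contract here is the common
"CPM >= threshold in >= k samples" rule, with the threshold motivated by two
independent reconstructions of the noise/signal transition:

* an SNR method — the per-gene mean/sd ratio of CPM across samples, smoothed
  along mean log2 CPM, crosses a fixed SNR threshold somewhere between the
  noise floor and the expressed population;
* a density method — the pooled log2(CPM + eps) distribution is bimodal
  (noise mode vs. signal mode) and the valley between the modes marks the
  transition.

Both report an interval in CPM units plus its arithmetic mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from .containers import CountMatrix, as_count_frame
from .errors import DegenerateDistributionError, InputError, ParameterError


@dataclass
class FilterReport:
    """Outcome of low-expression filtering and/or transition estimation."""

    cpm_threshold: float | None = None
    min_samples: int | None = None
    transition_range_snr: tuple[float, float] | None = None
    transition_range_density: tuple[float, float] | None = None
    transition_means: tuple[float, float] | None = None
    kept_gene_ids: list[str] = field(default_factory=list)
    n_kept: int = 0

    def __post_init__(self) -> None:
        for rng in (self.transition_range_snr, self.transition_range_density):
            if rng is not None and rng[0] > rng[1]:
                raise InputError("transition range has low > high")
        self.n_kept = len(self.kept_gene_ids) if self.kept_gene_ids else self.n_kept

    def to_json(self, path) -> None:
        payload = {
            "cpm_threshold": self.cpm_threshold,
            "min_samples": self.min_samples,
            "transition_range_snr": self.transition_range_snr,
            "transition_range_density": self.transition_range_density,
            "transition_means": self.transition_means,
            "n_kept": self.n_kept,
            "kept_gene_ids": list(self.kept_gene_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def compute_cpm(counts, library_sizes=None) -> pd.DataFrame:
    """Counts per million: count * 1e6 / library size.

    ``library_sizes`` defaults to the raw column totals of ``counts``; pass
    the totals of an unfiltered parent matrix to keep CPM values stable
    across filtering.
    """
    frame = as_count_frame(counts)
    libsize = frame.sum(axis=0) if library_sizes is None else pd.Series(library_sizes)
    libsize = libsize.loc[frame.columns]
    if (libsize <= 0).any():
        raise InputError("zero library size in CPM computation")
    return frame * 1e6 / libsize


def compute_fpkm(counts, gene_lengths) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (library size * length_bp)."""
    frame = as_count_frame(counts)
    lengths = pd.Series(gene_lengths)
    missing = [g for g in frame.index if g not in lengths.index]
    nonpos = [g for g in frame.index if g in lengths.index and lengths[g] <= 0]
    if missing or nonpos:
        raise InputError(
            f"gene lengths missing for {missing[:10]} / non-positive for {nonpos[:10]}"
        )
    libsize = frame.sum(axis=0)
    if (libsize <= 0).any():
        raise InputError("zero library size in FPKM computation")
    lengths = lengths.loc[frame.index].astype(float)
    return (frame * 1e9).div(libsize, axis=1).div(lengths, axis=0)


def _local_mean_smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Running local mean of y over an x-sorted window covering ``span`` of the points."""
    n = len(x)
    half = max(1, int(span * n / 2))
    smoothed = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        smoothed[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return smoothed


def estimate_noise_transition(
    cpm: pd.DataFrame,
    *,
    snr_threshold: float = 2.0,
    snr_band: float = 0.25,
    span: float = 0.3,
    eps: float = 0.25,
    valley_rel_tol: float = 0.1,
) -> FilterReport:
    """Estimate the noise/signal transition range of a CPM matrix two ways.

    SNR method: per-gene SNR = mean/sd of CPM across samples, smoothed with a
    local-mean smoother (``span`` fraction of genes) along mean log2 CPM; the
    reported interval covers every crossing of ``snr_threshold`` together
    with the contiguous region around them where the smoothed curve stays
    within ``snr_band`` (fractionally) of the threshold.

    Density method: Gaussian KDE (Silverman bandwidth) of pooled
    log2(CPM + eps); the valley is the global density minimum strictly between
    the two largest modes, and the interval is the contiguous region where the
    density stays within ``(1 + valley_rel_tol)`` of the valley minimum.

    Raises
    ------
    DegenerateDistributionError
        If the pooled density has no valley (unimodal input) or the SNR curve
        never crosses the threshold.
    """
    frame = as_count_frame(cpm)
    if frame.shape[1] < 2:
        raise ParameterError("need at least 2 samples")
    if frame.shape[0] < 50:
        raise ParameterError("need at least 50 genes")

    # ---- density method -----------------------------------------------------
    pooled = np.log2(frame.to_numpy().ravel() + eps)
    kde = stats.gaussian_kde(pooled, bw_method="silverman")
    grid = np.linspace(pooled.min(), pooled.max(), 1024)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        raise DegenerateDistributionError(
            f"pooled log2-CPM density is unimodal ({len(maxima)} mode(s) found); "
            "no noise/signal valley exists"
        )
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo_mode, hi_mode = int(top2.min()), int(top2.max())
    seg = slice(lo_mode + 1, hi_mode)
    valley_idx = lo_mode + 1 + int(np.argmin(dens[seg]))
    valley_level = dens[valley_idx] * (1.0 + valley_rel_tol)
    left = valley_idx
    while left > lo_mode and dens[left - 1] <= valley_level:
        left -= 1
    right = valley_idx
    while right < hi_mode and dens[right + 1] <= valley_level:
        right += 1
    dens_lo = max(0.0, 2.0 ** grid[left] - eps)
    dens_hi = max(0.0, 2.0 ** grid[right] - eps)

    # ---- SNR method ---------------------------------------------------------
    mean_cpm = frame.mean(axis=1).to_numpy()
    sd_cpm = frame.std(axis=1, ddof=1).to_numpy()
    ok = (mean_cpm > 0) & (sd_cpm > 0)
    snr = mean_cpm[ok] / sd_cpm[ok]
    x = np.log2(mean_cpm[ok])
    order = np.argsort(x)
    x_sorted, snr_sorted = x[order], snr[order]
    smoothed = _local_mean_smooth(x_sorted, snr_sorted, span)

    above = smoothed >= snr_threshold
    crossings = np.nonzero(above[1:] != above[:-1])[0]
    if len(crossings) == 0:
        # the SNR reconstruction found no transition; report the density
        # method alone rather than discarding a valid valley estimate
        return FilterReport(
            transition_range_snr=None,
            transition_range_density=(float(dens_lo), float(dens_hi)),
            transition_means=(None, float((dens_lo + dens_hi) / 2.0)),
        )
    cross_x = []
    for i in crossings:
        y0, y1 = smoothed[i], smoothed[i + 1]
        frac = (snr_threshold - y0) / (y1 - y0) if y1 != y0 else 0.5
        cross_x.append(x_sorted[i] + frac * (x_sorted[i + 1] - x_sorted[i]))
    # widen to the contiguous near-threshold region around the crossings
    within = np.abs(smoothed - snr_threshold) <= snr_band * snr_threshold
    left = int(crossings.min())
    while left > 0 and within[left - 1]:
        left -= 1
    right = int(crossings.max()) + 1
    while right < len(smoothed) - 1 and within[right + 1]:
        right += 1
    snr_lo = 2.0 ** min(min(cross_x), x_sorted[left])
    snr_hi = 2.0 ** max(max(cross_x), x_sorted[right])

    return FilterReport(
        transition_range_snr=(float(snr_lo), float(snr_hi)),
        transition_range_density=(float(dens_lo), float(dens_hi)),
        transition_means=(
            float((snr_lo + snr_hi) / 2.0),
            float((dens_lo + dens_hi) / 2.0),
        ),
    )


def filter_low_expression(
    counts: CountMatrix, cpm_threshold: float = 2.0, min_samples: int = 3
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes with CPM >= threshold (inclusive) in at least ``min_samples`` samples.

    CPM is computed against the raw library sizes of the *unfiltered* matrix,
    so filtering never changes a kept gene's CPM and is idempotent only up to
    the library sizes of the matrix it is handed; to preserve idempotence the
    returned matrix keeps the original annotation and sample set.
    """
    if cpm_threshold <= 0:
        raise ParameterError("cpm_threshold must be positive")
    n_samples = counts.counts.shape[1]
    if not 1 <= min_samples <= n_samples:
        raise ParameterError(
            f"min_samples must be in [1, {n_samples}], got {min_samples}"
        )
    cpm = compute_cpm(counts)
    keep_mask = (cpm >= cpm_threshold).sum(axis=1) >= min_samples
    kept = list(counts.gene_ids[keep_mask])
    report = FilterReport(
        cpm_threshold=float(cpm_threshold),
        min_samples=int(min_samples),
        kept_gene_ids=kept,
    )
    filtered = CountMatrix(counts.counts.loc[kept], counts.annotation.copy())
    return filtered, report
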