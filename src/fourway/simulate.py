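"""Synthetic factorial RNA-seq count generator with planted effect structure.

Counts are drawn from a negative binomial (NB) noise model with
variance mu + alpha * mu^2 (alpha is the dispersion), the convention of
mainstream RNA-seq DE tools.  The default design mirrors the study
conditions this package targets: four groups (Sham/RYGB surgery crossed
with Chow/HFD diet), five samples per group, and on the order of 12,000
expressed genes.

Effects are planted per gene as log2 fold changes on the group means:

* ``surgery_common`` — one LFC applied to both RYGB groups;
* ``diet_common``    — one LFC applied to both HFD groups;
* ``reversal``       — a surgery LFC and a diet LFC of opposite sign,
  emulating genes whose surgery response opposes the obesity signature;
* ``interaction_only`` — an LFC applied only to the RYGB-HFD group;
* ``null``           — no effect (the remainder).

An optional ``confound_shift`` adds a global log2 shift to the Sham-HFD
group only, emulating the body-weight confound of that condition; it
defaults to 0 and must be set explicitly for confounding experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .containers import CountMatrix, make_annotation
from .errors import ParameterError

EFFECT_CLASSES = (
    "null",
    "surgery_common",
    "diet_common",
    "reversal",
    "interaction_only",
)


@dataclass
class SimulationConfig:
    """Parameters of the factorial NB simulator.

    Baseline per-gene means are log-normal: ``exp(Normal(baseline_log_mean,
    baseline_log_sd))`` (natural-log scale).  The per-gene dispersion follows
    the decreasing trend ``alpha(mu) = dispersion_a0 + dispersion_a1 / mu``.
    Effect fractions refer to the fraction of genes in each planted class;
    the remainder is the null class.  Planted |LFC| values are uniform on
    ``[lfc_low, lfc_high]`` (log2 units) with random sign, except reversal
    genes whose surgery and diet signs are forced opposite.
    """

    n_genes: int = 12000
    n_per_group: int = 5
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    dispersion_a0: float = 0.01
    dispersion_a1: float = 1.0
    frac_surgery_common: float = 0.02
    frac_diet_common: float = 0.05
    frac_reversal: float = 0.01
    frac_interaction: float = 0.01
    lfc_low: float = 1.0
    lfc_high: float = 2.0
    confound_shift: float = 0.0
    confound_dispersion_factor: float = 1.0
    libsize_log_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_per_group < 1:
            raise ParameterError("n_genes and n_per_group must be positive")
        fracs = self.effect_fractions()
        if any(not 0.0 <= f <= 1.0 for f in fracs.values()):
            raise ParameterError("effect fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ParameterError("effect fractions sum to more than 1")
        if not (0.0 < self.lfc_low <= self.lfc_high):
            raise ParameterError("require 0 < lfc_low <= lfc_high")
        if self.dispersion_a0 < 0 or self.dispersion_a1 < 0:
            raise ParameterError("dispersion trend coefficients must be non-negative")
        if self.dispersion_a0 == 0 and self.dispersion_a1 == 0:
            # a flat zero trend degenerates to Poisson everywhere; allow it
            pass
        if self.confound_dispersion_factor <= 0:
            raise ParameterError("confound_dispersion_factor must be positive")
        if self.libsize_log_sd < 0:
            raise ParameterError("libsize_log_sd must be non-negative")

    def effect_fractions(self) -> dict[str, float]:
        return {
            "surgery_common": self.frac_surgery_common,
            "diet_common": self.frac_diet_common,
            "reversal": self.frac_reversal,
            "interaction_only": self.frac_interaction,
        }

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def nb_sample(mean: float, dispersion: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` NB counts with E[X] = mean and Var[X] = mean + dispersion*mean^2.

    ``dispersion = 0`` is the Poisson limit.
    """
    if mean <= 0:
        raise ParameterError("mean must be positive")
    if dispersion < 0:
        raise ParameterError("dispersion must be non-negative")
    if n < 1:
        raise ParameterError("n must be at least 1")
    rng = np.random.default_rng(seed)
    return _nb_draw(rng, np.full(n, float(mean)), np.full(n, float(dispersion)))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorized NB draw in the mean/dispersion parameterization."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha[nb]
        prob = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, prob)
    return out


def _assign_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic per-class gene counts (round(frac*n)); random placement."""
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    order = rng.permutation(cfg.n_genes)
    cursor = 0
    for name, frac in cfg.effect_fractions().items():
        k = int(round(frac * cfg.n_genes))
        classes[order[cursor : cursor + k]] = name
        cursor += k
    return classes


def _draw_lfc(rng: np.random.Generator, cfg: SimulationConfig, size: int) -> np.ndarray:
    mags = rng.uniform(cfg.lfc_low, cfg.lfc_high, size=size)
    signs = rng.choice([-1.0, 1.0], size=size)
    return mags * signs


def generate_factorial_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate a 2x2 factorial count matrix.

    Returns
    -------
    (counts, annotation, truth)
        ``counts`` is a :class:`CountMatrix` (annotation also attached),
        ``annotation`` the sample sheet, and ``truth`` the per-gene truth
        table with columns ``effect_class``, ``lfc_surgery``, ``lfc_diet``,
        ``lfc_interaction``, ``base_mean`` and ``dispersion``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    gene_ids = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    classes = _assign_classes(cfg, rng)

    base_mean = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes))
    dispersion = cfg.dispersion_a0 + cfg.dispersion_a1 / base_mean

    lfc_surgery = np.zeros(cfg.n_genes)
    lfc_diet = np.zeros(cfg.n_genes)
    lfc_interaction = np.zeros(cfg.n_genes)

    m_surg = classes == "surgery_common"
    lfc_surgery[m_surg] = _draw_lfc(rng, cfg, int(m_surg.sum()))
    m_diet = classes == "diet_common"
    lfc_diet[m_diet] = _draw_lfc(rng, cfg, int(m_diet.sum()))
    m_rev = classes == "reversal"
    rev_lfc = _draw_lfc(rng, cfg, int(m_rev.sum()))
    lfc_surgery[m_rev] = rev_lfc
    # diet effect forced to the opposite sign, magnitude drawn independently
    lfc_diet[m_rev] = -np.sign(rev_lfc) * rng.uniform(
        cfg.lfc_low, cfg.lfc_high, size=int(m_rev.sum())
    )
    m_int = classes == "interaction_only"
    lfc_interaction[m_int] = _draw_lfc(rng, cfg, int(m_int.sum()))

    # sample sheet: canonical group order, n_per_group samples each
    surgeries, diets, sample_ids = [], [], []
    for surgery, diet in (("Sham", "Chow"), ("RYGB", "Chow"), ("Sham", "HFD"), ("RYGB", "HFD")):
        for k in range(cfg.n_per_group):
            surgeries.append(surgery)
            diets.append(diet)
            sample_ids.append(f"{surgery}{diet}_{k + 1}")
    annotation = make_annotation(sample_ids, surgeries, diets)

    lib_log = rng.normal(0.0, cfg.libsize_log_sd, size=len(sample_ids))
    lib_factor = np.exp(lib_log - lib_log.mean())  # mean-centered in log space

    is_rygb = np.array([s == "RYGB" for s in surgeries])
    is_hfd = np.array([d == "HFD" for d in diets])
    is_sham_hfd = ~is_rygb & is_hfd
    is_rygb_hfd = is_rygb & is_hfd

    log2_shift = (
        np.outer(lfc_surgery, is_rygb)
        + np.outer(lfc_diet, is_hfd)
        + np.outer(lfc_interaction, is_rygb_hfd)
        + np.outer(np.full(cfg.n_genes, cfg.confound_shift), is_sham_hfd)
    )
    mu = base_mean[:, None] * np.exp2(log2_shift) * lib_factor[None, :]

    alpha = np.repeat(dispersion[:, None], len(sample_ids), axis=1)
    if cfg.confound_dispersion_factor != 1.0:
        alpha[:, is_sham_hfd] *= cfg.confound_dispersion_factor

    counts = _nb_draw(rng, mu, alpha)
    count_frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                               columns=sample_ids)

    truth = pd.DataFrame(
        {
            "effect_class": classes,
            "lfc_surgery": lfc_surgery,
            "lfc_diet": lfc_diet,
            "lfc_interaction": lfc_interaction,
            "base_mean": base_mean,
            "dispersion": dispersion,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    matrix = CountMatrix(count_frame, annotation)
    return matrix, annotation, truth


def expected_group_means(truth: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Noise-free group means implied by the truth table (library factor 1)."""
    shift = {
        "ShamChow": 0.0 * truth["lfc_surgery"],
        "RYGBChow": truth["lfc_surgery"],
        "ShamHFD": truth["lfc_diet"] + config.confound_shift,
        "RYGBHFD": truth["lfc_surgery"] + truth["lfc_diet"] + truth["lfc_interaction"],
    }
    return pd.DataFrame(
        {g: truth["base_mean"] * np.exp2(s) for g, s in shift.items()}
    )


def write_simulation(out_dir, matrix: CountMatrix, truth: pd.DataFrame) -> None:
    """Write counts.tsv, annotation.tsv and truth.tsv under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    matrix.to_tsv(
        os.path.join(out_dir, "counts.tsv"), os.path.join(out_dir, "annotation.tsv")
    )
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t")
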