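"""Tests of the NB differential-expression core."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fourway
from fourway.containers import CONTRAST_COLUMNS, ContrastResult
from fourway.de import (
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    raw_moment_dispersion,
    ridge_shrink,
    shrink_lfc,
    wald_contrast,
)
from fourway.errors import ContrastError, InputError, NormalizationError


def _two_group_matrix(ref_counts, test_counts, n_per_group=5, seed=0):
    """CountMatrix with two groups (ShamChow vs RYGBChow) from count arrays."""
    arr = np.hstack([np.asarray(ref_counts), np.asarray(test_counts)])
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"r{j}" for j in range(np.asarray(ref_counts).shape[1])] + [
        f"t{j}" for j in range(np.asarray(test_counts).shape[1])
    ]
    surgery = ["Sham"] * np.asarray(ref_counts).shape[1] + ["RYGB"] * np.asarray(
        test_counts
    ).shape[1]
    ann = fourway.make_annotation(samples, surgery, ["Chow"] * len(samples))
    return fourway.CountMatrix(pd.DataFrame(arr, index=genes, columns=samples), ann)


class TestSizeFactors:
    def test_worked_three_gene_example(self):
        # rows (100,200), (50,100), (10,20): every ratio-to-geomean column is
        # (1/sqrt(2), sqrt(2)), so the medians are 0.7071 and 1.4142
        frame = pd.DataFrame([[100, 200], [50, 100], [10, 20]])
        sf = estimate_size_factors(frame)
        assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_give_unit_factors(self):
        frame = pd.DataFrame(np.tile([[10], [300], [7]], (1, 4)))
        assert np.allclose(estimate_size_factors(frame), 1.0)

    def test_homogeneity_in_column_scale(self):
        # scaling one column by c multiplies every geometric mean by c^(1/n),
        # so the exact invariants are: all factors scale with a global
        # rescaling, and the scaled column's factor grows by c *relative* to
        # the others
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.integers(1, 500, size=(100, 4)))
        sf = estimate_size_factors(frame)
        # ratios to geometric means are scale-free, so a global rescaling
        # leaves the factors unchanged
        sf_global = estimate_size_factors(frame * 3)
        assert np.allclose(sf_global, sf)
        scaled = frame.copy()
        scaled[2] = scaled[2] * 3
        sf_scaled = estimate_size_factors(scaled)
        n = frame.shape[1]
        assert sf_scaled[2] == pytest.approx(3 ** ((n - 1) / n) * sf[2], rel=1e-9)
        for c in (0, 1, 3):
            rel_before = sf[2] / sf[c]
            rel_after = sf_scaled[2] / sf_scaled[c]
            assert rel_after == pytest.approx(3 * rel_before, rel=1e-9)

    def test_error_when_no_gene_covers_all_samples(self):
        frame = pd.DataFrame([[5, 0], [0, 5]])
        with pytest.raises(NormalizationError):
            estimate_size_factors(frame)


class TestDispersions:
    def test_raw_moment_formula(self):
        # mean 100, within-group variance 600 -> (600-100)/100^2 = 0.05
        assert raw_moment_dispersion(100.0, 600.0) == pytest.approx(0.05)

    def test_raw_moment_truncated_at_zero(self):
        assert raw_moment_dispersion(100.0, 80.0) == 0.0

    def test_poisson_data_yields_near_zero_dispersion(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(200.0, size=(500, 20))
        groups = pd.Series(["A"] * 10 + ["B"] * 10)
        disp = estimate_dispersions(pd.DataFrame(counts), groups=groups)
        assert float(np.median(disp)) < 0.02

    def test_recovers_known_dispersion_scale(self):
        rng = np.random.default_rng(6)
        alpha = 0.1
        size = 1 / alpha
        counts = rng.negative_binomial(size, size / (size + 400.0), size=(800, 20))
        groups = pd.Series(["A"] * 10 + ["B"] * 10)
        disp = estimate_dispersions(pd.DataFrame(counts), groups=groups)
        assert float(np.median(disp)) == pytest.approx(alpha, rel=0.3)


class TestWaldContrast:
    def test_null_identity_equal_group_means(self):
        rng = np.random.default_rng(2)
        flat = rng.integers(50, 500, size=(100, 1))
        counts = np.tile(flat, (1, 10))
        matrix = _two_group_matrix(counts[:, :5], counts[:, 5:])
        res = wald_contrast(matrix, "ShamChow", "RYGBChow")
        assert np.allclose(res.table["lfc_mle"], 0.0)
        assert np.allclose(res.table["p_value"], 1.0)

    def test_log_ratio_of_group_means(self):
        rng = np.random.default_rng(3)
        flat = np.tile(rng.integers(100, 300, size=(200, 1)), (1, 10))
        counts = flat.copy().astype(float)
        counts[:4, 5:] = counts[:4, 5:] * 4  # a few genes at 4x in the test group
        matrix = _two_group_matrix(counts[:, :5].astype(int), counts[:, 5:].astype(int))
        res = wald_contrast(matrix, "ShamChow", "RYGBChow")
        assert np.allclose(res.table["lfc_mle"].iloc[:4], 2.0, atol=0.1)

    def test_power_at_planted_lfc(self):
        # planted LFC = 2 at base mean 500, alpha = 0.01, n = 5/group
        cfg = fourway.SimulationConfig(
            n_genes=400, baseline_log_mean=np.log(500), baseline_log_sd=1e-9,
            dispersion_a0=0.01, dispersion_a1=0.0, frac_surgery_common=0.5,
            frac_diet_common=0.0, frac_reversal=0.0, frac_interaction=0.0,
            lfc_low=2.0, lfc_high=2.0, seed=10,
        )
        matrix, _, truth = fourway.generate_factorial_counts(cfg)
        res = wald_contrast(matrix, "ShamChow", "RYGBChow")
        planted = truth.index[truth["effect_class"] == "surgery_common"]
        assert (res.table.loc[planted, "p_value"] < 0.05).mean() >= 0.95

    def test_swapping_groups_negates_lfc_and_keeps_p(self, small_dataset):
        _, matrix, _ = small_dataset
        sf = estimate_size_factors(matrix)
        disp = estimate_dispersions(matrix, size_factors=sf)
        fwd = wald_contrast(matrix, "ShamChow", "RYGBChow", size_factors=sf,
                            dispersions=disp)
        rev = wald_contrast(matrix, "RYGBChow", "ShamChow", size_factors=sf,
                            dispersions=disp)
        t = fwd.table["tested"]
        assert np.allclose(fwd.table.loc[t, "lfc_mle"], -rev.table.loc[t, "lfc_mle"])
        assert np.allclose(fwd.table.loc[t, "lfc_shrunk"],
                           -rev.table.loc[t, "lfc_shrunk"])
        assert np.allclose(fwd.table.loc[t, "p_value"], rev.table.loc[t, "p_value"])

    def test_all_zero_genes_flagged_untested(self):
        counts = np.vstack([np.zeros((2, 10), dtype=int),
                            np.full((5, 10), 100, dtype=int)])
        matrix = _two_group_matrix(counts[:, :5], counts[:, 5:])
        res = wald_contrast(matrix, "ShamChow", "RYGBChow")
        assert not res.table["tested"].iloc[:2].any()
        assert res.table["p_value"].iloc[:2].isna().all()
        assert res.table["tested"].iloc[2:].all()

    def test_unknown_group_label(self, small_dataset):
        _, matrix, _ = small_dataset
        with pytest.raises(ContrastError):
            wald_contrast(matrix, "ShamChow", "Keto")


def _bh_bruteforce(p):
    """Independent step-up oracle: p_(i) * m / i, cumulative min from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhAdjust:
    def test_worked_example_all_tie_at_004(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=1000))
    def test_matches_bruteforce_oracle(self, p):
        assert np.allclose(bh_adjust(p), _bh_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=200))
    def test_dominates_p_and_preserves_order(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestShrinkLfc:
    def _result(self, lfc, se):
        n = len(lfc)
        table = pd.DataFrame(
            {
                "base_mean": np.full(n, 100.0),
                "lfc_mle": lfc,
                "lfc_se": se,
                "wald_stat": np.asarray(lfc) / np.asarray(se),
                "p_value": np.full(n, 0.5),
                "p_adj": np.full(n, 0.5),
                "lfc_shrunk": np.nan,
                "tested": True,
            },
            index=[f"g{i}" for i in range(n)],
        )
        return ContrastResult("A", "B", table.loc[:, list(CONTRAST_COLUMNS)])

    def test_no_noise_limit(self):
        res = shrink_lfc(self._result([2.0], [1e-9]), prior_sd=1.0)
        assert res.table["lfc_shrunk"].iloc[0] == pytest.approx(2.0)

    def test_degenerate_prior_shrinks_to_zero(self):
        res = shrink_lfc(self._result([2.0], [1.0]), prior_sd=1e-9)
        assert res.table["lfc_shrunk"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_equal_variance_halves(self):
        assert ridge_shrink(np.array([2.0]), np.array([1.0]), 1.0)[0] == pytest.approx(1.0)

    def test_shrunk_never_exceeds_mle_and_keeps_sign(self, small_contrasts):
        for res in small_contrasts.values():
            t = res.table[res.table["tested"]]
            assert (t["lfc_shrunk"].abs() <= t["lfc_mle"].abs() + 1e-12).all()
            sign_ok = (np.sign(t["lfc_shrunk"]) == np.sign(t["lfc_mle"])) | (
                t["lfc_shrunk"] == 0
            )
            assert sign_ok.all()

    def test_padj_monotone_and_dominates_p(self, small_contrasts):
        for res in small_contrasts.values():
            t = res.table[res.table["tested"]].sort_values("p_value")
            assert (t["p_adj"] >= t["p_value"] - 1e-15).all()
            assert (t["p_adj"].diff().dropna() >= -1e-12).all()
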