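"""Instrument selection, multivariable MR fitting, stepwise search, LOCO."""

import numpy as np
import pandas as pd
import pytest

import priorscan as ps
from priorscan.mr import (CollinearityError, EmptyInstrumentError,
                          InstrumentSet)


def make_instruments(B, b_y, n_t=100_000, n_l=100_000, chroms=None):
    B = np.asarray(B, dtype=float)
    s, T = B.shape
    if chroms is None:
        chroms = 1 + (np.arange(s) % 22)
    return InstrumentSet(variant_ids=[f"iv{i}" for i in range(s)],
                         chromosomes=np.asarray(chroms),
                         B=B, b_y=np.asarray(b_y, dtype=float),
                         trait_names=[f"t{j}" for j in range(T)],
                         n_t=np.full(T, float(n_t)), n_l=n_l)


def simulate_summary_mr(rng, alpha, s=500, n_t=100_000, n_l=100_000,
                        b_scale=0.045):
    """Direct summary-level MR data: true B, noisy observed B and b_y.

    ``b_scale`` matches the strong-instrument effect size of the default
    compendium (sqrt(h2_t / n_causal_t) ~ 0.045 at z ~ 14), so instrument
    noise stays small relative to signal as the method requires.
    """
    T = len(alpha)
    B_true = rng.standard_normal((s, T)) * b_scale
    B_obs = B_true + rng.standard_normal((s, T)) / np.sqrt(n_t)
    b_y = B_true @ np.asarray(alpha) + rng.standard_normal(s) / np.sqrt(n_l)
    return B_obs, b_y


class TestSelectInstruments:
    def test_greedy_pruning_hand_case(self):
        """A (p=1e-8) is kept and removes B (r2=0.5); C survives."""
        variants = pd.DataFrame({"snp": ["A", "B", "C"], "chr": [1, 1, 1],
                                 "pos": [1000, 2000, 500_000],
                                 "a1": ["A"] * 3, "a2": ["G"] * 3})
        rng = np.random.default_rng(2)
        base = rng.standard_normal(2000)
        corr_b = base * np.sqrt(0.55) + rng.standard_normal(2000) * np.sqrt(0.45)
        indep = rng.standard_normal(2000)
        dos = np.clip(1 + np.c_[base, corr_b, indep] * 0.4, 0, 2)
        panel = ps.LDPanel(variants, dos)
        r2 = panel.correlation(["A", "B", "C"]) ** 2
        assert r2[0, 1] > 0.2 and r2[0, 2] < 0.2 and r2[1, 2] < 0.2

        zs = [ps.z_from_p_and_direction(p, 1)
              for p in (1e-8, 1e-6, 1e-7)]
        df = variants.copy()
        df["z"] = zs
        df["n"] = 10_000
        trait = ps.SumStatTable(df, trait_name="t1")
        out_df = variants.copy()
        out_df["z"] = [1.0, 1.0, 1.0]
        out_df["n"] = 10_000
        outcome = ps.SumStatTable(out_df)
        inst = ps.select_instruments([trait], outcome, panel)
        assert inst.variant_ids == ["A", "C"]

    def test_no_candidate_is_error(self, small_panel, small_compendium):
        tables, outcome, _ = small_compendium
        weak = ps.SumStatTable(
            tables[0].df.drop(columns=["p", "b"]).assign(z=0.1),
            trait_name="w")
        with pytest.raises(EmptyInstrumentError):
            ps.select_instruments([weak], outcome, small_panel)

    def test_truncation_zeroes_weak_entries(self, small_panel,
                                            small_compendium):
        tables, outcome, _ = small_compendium
        inst = ps.select_instruments(tables, outcome, small_panel)
        # every B entry is either 0 (weak) or strong (P <= 1e-5)
        n_t = inst.n_t[None, :]
        z_equiv = np.abs(inst.B) * np.sqrt(n_t)
        nonzero = inst.B != 0
        assert np.all(z_equiv[nonzero] >= ps.z_from_p_and_direction(1e-5, 1))
        assert np.all(nonzero.any(axis=1))

    def test_pruned_set_has_low_ld(self, small_panel, small_compendium):
        tables, outcome, _ = small_compendium
        inst = ps.select_instruments(tables, outcome, small_panel)
        for chrom in np.unique(inst.chromosomes):
            ids = [v for v, c in zip(inst.variant_ids, inst.chromosomes)
                   if c == chrom]
            if len(ids) < 2:
                continue
            r2 = small_panel.correlation(ids) ** 2
            np.fill_diagonal(r2, 0.0)
            assert r2.max() <= 0.2 + 1e-12


class TestFitMr:
    def test_exact_proportionality(self):
        inst = make_instruments([[0.1], [0.2]], [0.05, 0.1], chroms=[1, 2])
        fit = ps.fit_mr(inst)
        assert fit.alpha[0] == pytest.approx(0.5, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_normal_equations_oracle_case(self):
        inst = make_instruments([[0.1, 0.0], [0.0, 0.2], [0.1, 0.1]],
                                [0.02, -0.02, 0.01], chroms=[1, 2, 3])
        fit = ps.fit_mr(inst)
        np.testing.assert_allclose(fit.alpha, [0.2, -0.1], atol=1e-12)

    def test_agrees_with_brute_force_least_squares(self):
        """Explicit normal equations via generic inversion, random cases."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            s, T = rng.integers(5, 30), rng.integers(1, 4)
            B = rng.standard_normal((s, T))
            b_y = rng.standard_normal(s)
            inst = make_instruments(B, b_y)
            fit = ps.fit_mr(inst)
            oracle = np.linalg.inv(B.T @ B) @ (B.T @ b_y)
            np.testing.assert_allclose(fit.alpha, oracle, atol=1e-10)

    def test_collinearity_error_names_trait(self):
        B = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6]])
        inst = make_instruments(B, [0.01, 0.02, 0.03], chroms=[1, 2, 3])
        with pytest.raises(CollinearityError, match="t1"):
            ps.fit_mr(inst)

    def test_sample_size_invariance_of_fitted_values(self):
        """Scaling one trait's n by k rescales its alpha by sqrt(k) but
        leaves fitted values (hence priors) unchanged."""
        rng = np.random.default_rng(1)
        B, b_y = simulate_summary_mr(rng, [0.2, -0.1], s=50)
        inst = make_instruments(B, b_y)
        fit = ps.fit_mr(inst)
        k = 4.0
        B2 = B.copy()
        B2[:, 0] /= np.sqrt(k)  # same z, misreported n -> b scales by 1/sqrt(k)
        fit2 = ps.fit_mr(make_instruments(B2, b_y))
        assert fit2.alpha[0] == pytest.approx(fit.alpha[0] * np.sqrt(k),
                                              rel=1e-10)
        assert fit2.alpha[1] == pytest.approx(fit.alpha[1], rel=1e-10)
        np.testing.assert_allclose(B2 @ fit2.alpha, B @ fit.alpha, atol=1e-14)

    def test_parameter_recovery_and_sigma2(self):
        rng = np.random.default_rng(42)
        alpha = np.array([0.2, -0.1, 0.0, 0.05, 0.0])
        hits = 0
        sig = []
        for _ in range(50):
            B, b_y = simulate_summary_mr(rng, alpha)
            fit = ps.fit_mr(make_instruments(B, b_y))
            hits += np.all(np.abs(fit.alpha - alpha) < 3 * fit.se)
            sig.append(fit.sigma2)
        assert hits >= 48
        assert 0.5 < np.mean(sig) < 1.5


class TestStepwise:
    def test_single_strong_trait_selected(self):
        rng = np.random.default_rng(3)
        B, b_y = simulate_summary_mr(rng, [0.2], s=200)
        fit = ps.stepwise_select(make_instruments(B, b_y))
        assert fit.selected_traits == ["t0"]

    def test_noise_trait_excluded(self):
        rng = np.random.default_rng(4)
        excluded = 0
        for _ in range(100):
            B, b_y = simulate_summary_mr(rng, [0.2, 0.0], s=300)
            fit = ps.stepwise_select(make_instruments(B, b_y))
            excluded += "t1" not in fit.selected_traits
            assert "t0" in fit.selected_traits
        # expected exclusion ~95% (the trait survives only when its
        # multivariate P lands below 0.05 by chance); allow binomial noise
        assert excluded >= 90

    def test_collinear_duplicate_trait_dropped(self):
        rng = np.random.default_rng(5)
        B, b_y = simulate_summary_mr(rng, [0.2], s=100)
        B2 = np.c_[B, B]  # two perfectly collinear candidates
        fit = ps.stepwise_select(make_instruments(B2, b_y))
        assert len(fit.selected_traits) == 1


class TestLoco:
    def test_single_chromosome_mask_errors_per_mask(self):
        B = np.full((5, 1), 0.1)
        inst = make_instruments(B, 0.05 * np.ones(5), chroms=[1, 1, 1, 1, 2])
        fits = ps.loco_estimates(inst)
        assert isinstance(fits[2], ps.CausalEffectEstimate)
        # chromosome-1 mask removes 4 of 5 instruments but still fits;
        # all-on-one-chromosome is rejected outright
        inst_one = make_instruments(B, 0.05 * np.ones(5), chroms=[1] * 5)
        with pytest.raises(ValueError):
            ps.loco_estimates(inst_one)

    def test_empty_mask_equals_full_fit(self):
        rng = np.random.default_rng(6)
        B, b_y = simulate_summary_mr(rng, [0.2, -0.1], s=100)
        chroms = 1 + (np.arange(100) % 21)  # nothing on chromosome 22
        inst = make_instruments(B, b_y, chroms=chroms)
        fits = ps.loco_estimates(inst)
        full = ps.fit_mr(inst)
        np.testing.assert_allclose(fits[22].alpha, full.alpha, atol=1e-14)

    def test_masked_estimates_mutually_consistent(self):
        rng = np.random.default_rng(7)
        B, b_y = simulate_summary_mr(rng, [0.2, -0.1, 0.05], s=600)
        inst = make_instruments(B, b_y)
        fits = ps.loco_estimates(inst)
        vecs = np.array([fits[c].alpha for c in range(1, 23)])
        corr = np.corrcoef(vecs)
        assert corr.min() > 0.95


class TestResidualDiagnostics:
    def test_zero_residual_fit_unflagged(self):
        inst = make_instruments([[0.1], [0.2]], [0.05, 0.1], chroms=[1, 2])
        fit = ps.fit_mr(inst)
        diag = ps.mr_residual_diagnostics(fit, inst)
        assert not diag["flagged"].any()

    def test_pleiotropic_instrument_flagged(self):
        rng = np.random.default_rng(8)
        B, b_y = simulate_summary_mr(rng, [0.2], s=300)
        b_y = b_y.copy()
        b_y[7] += 10.0 / np.sqrt(100_000)  # direct outcome effect
        inst = make_instruments(B, b_y)
        diag = ps.mr_residual_diagnostics(ps.fit_mr(inst), inst)
        assert diag["flagged"].iloc[7]

    def test_null_residuals_normal_qq_slope(self):
        rng = np.random.default_rng(9)
        B, b_y = simulate_summary_mr(rng, [0.0, 0.0], s=2000)
        inst = make_instruments(B, b_y)
        diag = ps.mr_residual_diagnostics(ps.fit_mr(inst), inst)
        from scipy import stats
        osm, osr = stats.probplot(diag["std_residual"], fit=False)
        slope = np.polyfit(osm, osr, 1)[0]
        assert 0.9 < slope < 1.1
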