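"""EWAS: robust fits, moderation, adjustment, inflation, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylrestore.ewas import (
    EwasModel, adjust_pvalues, build_design, contrast_vector, ebayes_moderate,
    estimate_prior, fit_probe_rlm, genomic_inflation, posterior_variance,
    run_ewas,
)
from methylrestore.containers import MethylationDataset
from methylrestore.synth import SimulationConfig, generate_dataset


def _design(n=96, seed=0):
    r = np.random.default_rng(seed)
    return np.column_stack([np.ones(n), r.normal(size=n)])


class TestFitProbeRlm:
    def test_exact_fit(self):
        X = _design()
        y = X @ np.array([1.0, 2.0])
        coef, se, s2, d = fit_probe_rlm(y, X)
        assert np.allclose(coef, [1.0, 2.0], atol=1e-10)
        assert s2 == 0.0
        assert np.allclose(se, 0.0)
        assert d == 94

    def test_matches_ols_without_downweighting(self):
        """Symmetric two-point noise keeps every residual inside the Huber
        threshold, so the M-estimate must coincide with OLS."""
        r = np.random.default_rng(1)
        X = _design(seed=1)
        y = X @ np.array([0.5, -1.0]) + 0.1 * r.choice([-1.0, 1.0], size=96)
        coef, _, _, _ = fit_probe_rlm(y, X)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.max(np.abs(coef - ols)) < 1e-6

    def test_outlier_robustness(self):
        """One +10 SD outlier at the highest-leverage point: the Huber slope
        beats the OLS slope in >= 95% of 500 fixed-seed simulations."""
        wins = 0
        for i in range(500):
            r = np.random.default_rng(10_000 + i)
            x1 = r.normal(size=96)
            X = np.column_stack([np.ones(96), x1])
            y = X @ np.array([0.0, 1.0]) + r.normal(size=96)
            y[int(np.argmax(np.abs(x1)))] += 10.0
            huber, _, _, _ = fit_probe_rlm(y, X)
            ols = np.linalg.lstsq(X, y, rcond=None)[0]
            wins += abs(huber[1] - 1.0) < abs(ols[1] - 1.0)
        assert wins >= 475

    def test_nonfinite_response_error(self):
        X = _design(10)
        with pytest.raises(ValueError):
            fit_probe_rlm(np.array([np.nan] + [0.0] * 9), X)


class TestEbayes:
    def test_identical_s2_reduces_to_classical_t(self):
        r = np.random.default_rng(2)
        n_probes, d = 500, 90
        coef = r.normal(size=n_probes)
        unscaled = np.full(n_probes, 0.2)
        s2 = np.full(n_probes, 0.04)
        mod = ebayes_moderate(coef, unscaled, s2, d)
        classical = coef / (unscaled * np.sqrt(s2))
        assert np.allclose(mod["t"], classical, atol=1e-10)
        assert np.isinf(mod["d0"])

    def test_hyperparameter_recovery(self):
        d0_true, s0_true, d = 4.0, 0.04, 90
        s2_true = d0_true * s0_true / stats.chi2.rvs(
            d0_true, size=20_000, random_state=1
        )
        obs = s2_true * stats.chi2.rvs(d, size=20_000, random_state=2) / d
        d0, s0 = estimate_prior(obs, d)
        assert 2.0 <= d0 <= 8.0
        assert abs(s0 - s0_true) / s0_true < 0.25

    def test_posterior_closed_form(self):
        assert posterior_variance(
            np.array([0.02]), 90, 4.0, 0.04
        )[0] == pytest.approx((4.0 * 0.04 + 90 * 0.02) / 94.0, rel=1e-12)

    def test_single_probe_plugin(self):
        r = np.random.default_rng(3)
        s2 = 0.05 / stats.chi2.rvs(6.0, size=300, random_state=7) * 6.0
        coef = r.normal(size=300)
        unscaled = np.full(300, 0.3)
        mod = ebayes_moderate(coef, unscaled, s2, 50)
        i = 17
        s2_post = (mod["d0"] * mod["s0_sq"] + 50 * s2[i]) / (mod["d0"] + 50)
        assert mod["t"][i] == pytest.approx(
            coef[i] / (unscaled[i] * np.sqrt(s2_post)), rel=1e-10
        )

    def test_needs_mass(self):
        with pytest.raises(ValueError):
            estimate_prior(np.full(50, 0.1), 10)


class TestAdjustPvalues:
    def test_bonferroni_reference_values(self):
        out = adjust_pvalues(np.array([1.63e-12, 7.53e-31]), "bonferroni",
                             m=714_666)
        assert out[0] == pytest.approx(1.165e-06, rel=5e-3)
        assert out[1] == pytest.approx(5.38e-25, rel=5e-3)

    def test_bonferroni_cap(self):
        assert adjust_pvalues(np.array([0.5]), "bonferroni", m=10)[0] == 1.0

    def test_bh_step_up(self):
        out = adjust_pvalues(np.array([0.01, 0.02, 0.03]), "bh")
        assert np.allclose(out, [0.03, 0.03, 0.03])

    def test_nan_propagation(self):
        out = adjust_pvalues(np.array([0.01, np.nan, 0.02]), "bonferroni")
        assert np.isnan(out[1])
        assert out[0] == pytest.approx(0.02)  # m = 2 finite tests

    def test_ordering(self):
        r = np.random.default_rng(4)
        p = r.uniform(size=200)
        bonf = adjust_pvalues(p, "bonferroni")
        bh = adjust_pvalues(p, "bh")
        assert (bonf >= bh - 1e-15).all()
        assert (bh >= p - 1e-15).all()

    def test_bh_monotone_in_p(self):
        r = np.random.default_rng(5)
        p = r.uniform(size=100)
        bh = adjust_pvalues(p, "bh")
        order = np.argsort(p)
        assert (np.diff(bh[order]) >= -1e-15).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5]), "holm")


class TestGenomicInflation:
    def test_constant_half(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_null(self):
        p = np.random.default_rng(6).uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_halved_p_inflates(self):
        p = np.random.default_rng(7).uniform(size=10_000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_needs_100(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.full(50, 0.5))


class TestDesign:
    def test_columns_and_contrasts(self, small_study):
        meth, truth = small_study["meth"], small_study["truth"]
        X = build_design(meth.samples, truth.true_cell_proportions)
        assert list(X.columns[:3]) == ["intercept", "placebo", "vitc"]
        c_pn = contrast_vector(X.columns, "PN")
        c_vp = contrast_vector(X.columns, "VP")
        assert c_pn[list(X.columns).index("placebo")] == 1.0
        assert c_vp[list(X.columns).index("vitc")] == 1.0
        assert c_vp[list(X.columns).index("placebo")] == -1.0

    def test_rank_deficient_error(self, small_study):
        samples = small_study["meth"].samples.copy()
        samples["dup"] = (samples["infant_sex"] == "M").astype(float)
        with pytest.raises(ValueError, match="rank"):
            build_design(samples, extra_covariates=["dup"])

    def test_missing_cell_props_error(self, small_study):
        meth, truth = small_study["meth"], small_study["truth"]
        with pytest.raises(ValueError):
            build_design(meth.samples, truth.true_cell_proportions.iloc[:-3])


@pytest.fixture(scope="module")
def fitted(small_study):
    return run_ewas(small_study["meth"],
                    small_study["truth"].true_cell_proportions)


class TestRunEwas:
    def test_sign_concordance(self, fitted):
        for name in ("PN", "VP"):
            t = fitted.table(name)
            # near-null probes can flip sign between the two scales through
            # robust-weight noise; the invariant holds for confident effects
            ok = t["coef_m"].notna() & t["coef_beta"].notna()
            strong = ok & (t["p_raw"] < 1e-3) & (t["coef_beta"].abs() > 0.01)
            assert strong.sum() > 20
            assert (np.sign(t.loc[strong, "coef_m"])
                    == np.sign(t.loc[strong, "coef_beta"])).all()

    def test_table_schema(self, fitted):
        t = fitted.table("PN")
        for col in ("chrom", "pos", "coef_m", "se_m", "t_moderated", "p_raw",
                    "coef_beta", "se_beta", "p_bonferroni", "p_bh"):
            assert col in t.columns
        ok = t["p_bonferroni"].notna() & t["p_bh"].notna()
        assert ok.any()
        assert (t.loc[ok, "p_bonferroni"] >= t.loc[ok, "p_bh"] - 1e-15).all()

    def test_sample_permutation_invariance(self, small_study):
        meth = small_study["meth"]
        props = small_study["truth"].true_cell_proportions
        perm = np.random.default_rng(8).permutation(meth.n_samples)
        shuffled = MethylationDataset(
            beta=meth.beta.iloc[:, perm],
            annotation=meth.annotation,
            samples=meth.samples.iloc[perm],
        )
        a = run_ewas(meth, props, contrasts=("PN",)).table("PN")
        b = run_ewas(shuffled, props, contrasts=("PN",)).table("PN")
        assert np.allclose(a["coef_m"], b["coef_m"], atol=1e-8, equal_nan=True)
        assert np.allclose(a["p_raw"], b["p_raw"], atol=1e-8, equal_nan=True)

    def test_recovery_of_smoking_cpgs(self):
        """Spec'd recovery regime (>= 30 per group, |delta| >= 0.05):
        >= 80% of strong smoking CpGs at BH-FDR < 0.05, all recovered
        signs agreeing with truth."""
        cfg = SimulationConfig(seed=0, n_probes=4000, n_never=30)
        meth, _, _, truth = generate_dataset(cfg)
        t = run_ewas(meth, truth.true_cell_proportions,
                     contrasts=("PN",)).table("PN")
        strong = [p for p, d in truth.smoking_cpgs.items() if abs(d) >= 0.05]
        hit = t.loc[strong, "p_bh"] < 0.05
        assert hit.mean() >= 0.8
        signs = np.sign([truth.smoking_cpgs[p] for p in strong])
        assert (np.sign(t.loc[strong, "coef_beta"].to_numpy())[hit.to_numpy()]
                == signs[hit.to_numpy()]).all()

    def test_label_permutation_kills_hits(self):
        cfg = SimulationConfig(seed=4, n_probes=2000)
        meth, _, _, truth = generate_dataset(cfg)
        r = np.random.default_rng(9)
        samples = meth.samples.copy()
        samples["group"] = r.permutation(samples["group"].to_numpy())
        shuffled = MethylationDataset(beta=meth.beta,
                                      annotation=meth.annotation,
                                      samples=samples)
        t = run_ewas(shuffled, truth.true_cell_proportions,
                     contrasts=("PN",)).table("PN")
        assert int((t["p_bonferroni"] < 0.05).sum()) <= 1

    def test_scale_selection(self, small_study):
        meth = small_study["meth"]
        beta_only = run_ewas(meth, scale="beta", contrasts=("PN",)).table("PN")
        assert beta_only["coef_beta"].notna().any()
        assert "coef_m" not in beta_only.columns or beta_only.get("coef_m") is None
        with pytest.raises(ValueError):
            run_ewas(meth, scale="logit")
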