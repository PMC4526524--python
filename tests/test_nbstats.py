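import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mbddmr import nbstats
from mbddmr.model import SampleInfo, SampleSheet
from mbddmr.nbstats import (
    CallPolicy,
    bh_fdr,
    bonferroni_threshold,
    call_dmrs,
    exact_nb_test,
    estimate_dispersion,
    fit_nb_glm,
    normalize,
)
from mbddmr.nbstats import test_dmr as dmr_test
from mbddmr.nbstats import test_interaction as interaction_test

ARM_A = [f"s{i}" for i in range(5)]
ARM_B = [f"s{i}" for i in range(5, 10)]
X2 = np.column_stack([np.ones(10), [1] * 5 + [0] * 5])


def nb_draw(rng, mu, phi):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + np.asarray(mu, dtype=float)))


class TestTMM:
    def test_identical_columns_unit_factors(self, make_counts):
        Y = np.tile(np.arange(1, 101)[:, None], (1, 10))
        norm = normalize(make_counts(Y))
        assert np.allclose(norm.factors, 1.0)

    def test_doubled_column_compensated(self, make_counts):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(500, 10))
        Y = base.copy()
        Y[:, 0] *= 2
        cm = make_counts(Y)
        norm = normalize(cm)
        # doubling all counts and the library leaves relative profiles intact:
        # effective library ends up ~2x the others
        ratio = norm.effective_libsize["s0"] / norm.effective_libsize["s1"]
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_trimming_robust_to_minority_inflation(self, make_counts):
        """5% of probes 8-fold inflated in one sample barely moves its factor."""
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(2000, 10))
        lib = base.sum(axis=0)
        f_clean = normalize(make_counts(base.copy(), libsize=lib)).factors["s0"]
        inflated = base.copy()
        inflated[:100, 0] *= 8
        f_dirty = normalize(make_counts(inflated, libsize=lib)).factors["s0"]
        assert f_dirty == pytest.approx(f_clean, rel=0.03)

    def test_geometric_mean_one(self, make_counts):
        rng = np.random.default_rng(2)
        Y = rng.poisson(rng.uniform(20, 300, size=10), size=(400, 10))
        norm = normalize(make_counts(Y))
        assert np.exp(np.mean(np.log(norm.factors))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_library_rejected(self, make_counts):
        Y = np.ones((10, 10), dtype=int)
        with pytest.raises(ValueError, match="zero library"):
            normalize(make_counts(Y, libsize=[0] + [100] * 9))


class TestGlmFit:
    def test_two_group_mle_matches_group_means(self):
        """With equal offsets the saturated two-group MLE is the group mean."""
        Y = np.array([[12.0, 8, 10, 9, 11, 30, 28, 35, 31, 26]])
        beta, mu, _, _ = fit_nb_glm(Y, X2, np.zeros(10), 0.1)
        assert np.exp(beta[0, 0]) == pytest.approx(30.0, rel=1e-6)
        assert np.exp(beta[0, 0] + beta[0, 1]) == pytest.approx(10.0, rel=1e-6)

    def test_statsmodels_cross_check(self):
        """Coefficients agree with an independent NB GLM implementation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        phi = 0.1
        Y = nb_draw(rng, np.tile([40.0] * 5 + [90.0] * 5, (20, 1)), phi)
        offs = np.log(np.full(10, 1.0))
        beta, _, _, _ = fit_nb_glm(Y.astype(float), X2, offs, phi)
        for g in range(20):
            fam = sm.families.NegativeBinomial(alpha=phi)
            fit = sm.GLM(Y[g], X2, family=fam, offset=offs).fit()
            assert beta[g] == pytest.approx(fit.params, abs=1e-5)


class TestDispersion:
    def test_constant_probe_shrinks_to_common(self, make_counts):
        rng = np.random.default_rng(4)
        Y = nb_draw(rng, np.full((500, 10), 100.0), 0.1)
        Y[0] = 100  # constant counts: probe-wise evidence says Poisson
        cm = make_counts(Y)
        norm = normalize(cm)
        d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
        assert d.per_probe.iloc[0] < d.common  # pulled down by own evidence...
        assert d.per_probe.iloc[0] > 0.25 * d.common  # ...but held near common

    def test_all_zero_matrix_rejected(self, make_counts):
        cm = make_counts(np.zeros((5, 10), dtype=int), libsize=[100] * 10)
        norm_offsets = np.zeros(10)
        with pytest.raises(ValueError, match="all-zero"):
            estimate_dispersion(cm, X2, norm_offsets)


class TestExactTest:
    def test_balanced_split_not_significant(self):
        assert exact_nb_test(50, 50, 5, 5, 0.0) == pytest.approx(1.0, abs=0.05)

    def test_extreme_split_significant(self):
        assert exact_nb_test(100, 10, 5, 5, 0.0) < 1e-10

    def test_zero_total(self):
        assert exact_nb_test(0, 0, 5, 5, 0.1) == 1.0

    def test_dispersion_widens_null(self):
        """Overdispersion makes the same split less surprising."""
        p_poisson = exact_nb_test(70, 30, 5, 5, 0.0)
        p_nb = exact_nb_test(70, 30, 5, 5, 0.5)
        assert p_nb > p_poisson


class TestDmrTest:
    def test_identical_arms(self, make_counts):
        Y = np.tile(np.arange(10, 40)[:, None], (1, 10))
        cm = make_counts(Y)
        norm = normalize(cm)
        d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
        res = dmr_test(cm, ARM_A, ARM_B, d, norm)
        assert np.allclose(res["log2fc"], 0.0, atol=1e-6)
        assert (res["p"] > 0.99).all()

    def test_zero_probe_reported_not_dropped(self, make_counts):
        rng = np.random.default_rng(5)
        Y = rng.poisson(50, size=(20, 10))
        Y[0] = 0
        cm = make_counts(Y)
        norm = normalize(cm)
        d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
        res = dmr_test(cm, ARM_A, ARM_B, d, norm)
        assert res["p"].iloc[0] == 1.0 and res["log2fc"].iloc[0] == 0.0
        assert len(res) == 20

    def test_arm_exchange_negates_log2fc(self, make_counts):
        rng = np.random.default_rng(6)
        Y = nb_draw(rng, np.tile([60.0] * 5 + [110.0] * 5, (50, 1)), 0.05)
        cm = make_counts(Y)
        norm = normalize(cm)
        d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
        r1 = dmr_test(cm, ARM_A, ARM_B, d, norm)
        r2 = dmr_test(cm, ARM_B, ARM_A, d, norm)
        assert np.allclose(r1["log2fc"], -r2["log2fc"], atol=1e-6)
        assert np.allclose(r1["p"], r2["p"], rtol=1e-9)

    def test_scale_invariance_after_normalization(self, make_counts):
        rng = np.random.default_rng(7)
        Y = nb_draw(rng, np.full((300, 10), 80.0), 0.05)
        cm1 = make_counts(Y.copy())
        Y2 = Y.copy()
        Y2[:, 0] *= 3
        lib2 = Y.sum(axis=0).astype(int)
        lib2[0] *= 3
        cm2 = make_counts(Y2, libsize=lib2)
        out = []
        for cm in (cm1, cm2):
            norm = normalize(cm)
            d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
            out.append(dmr_test(cm, ARM_A, ARM_B, d, norm))
        # TMM absorbs the scale; residual differences reflect only the extra
        # NB information carried by larger counts (exact invariance holds in
        # the Poisson limit alone), so no p-value may move materially
        assert np.allclose(np.log10(out[0]["p"]), np.log10(out[1]["p"]), atol=0.15)
        assert np.allclose(out[0]["log2fc"], out[1]["log2fc"], atol=0.05)

    def test_overlapping_arms_rejected(self, make_counts):
        cm = make_counts(np.ones((5, 10), dtype=int))
        norm = normalize(cm)
        d = estimate_dispersion(cm, X2, norm.offsets.to_numpy())
        with pytest.raises(ValueError, match="overlap"):
            dmr_test(cm, ARM_A, ARM_A, d, norm)


class TestCalling:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "p"]).assign(
            probe_id=lambda d: [f"p{i}" for i in range(len(d))]
        ).set_index("probe_id")

    def test_genome_wide_thresholds(self):
        res = self._frame([(1.2, 1e-3), (0.9, 1e-8), (-1.5, 5e-3), (1.5, 0.02)])
        calls = call_dmrs(res, CallPolicy(), mode="genome_wide")
        assert calls.tolist() == ["hyper_in_control", "none", "hypo_in_control", "none"]

    def test_promoter_bonferroni(self):
        res = self._frame([(2.0, 1e-5), (2.0, 1e-7)])
        policy = CallPolicy(promoter_m=22_480)
        calls = call_dmrs(res, policy, mode="promoter")
        # 1e-5 > 0.05/22480 = 2.2e-6: not called; 1e-7 passes
        assert calls.tolist() == ["none", "hyper_in_control"]

    def test_promoter_mode_needs_m(self):
        with pytest.raises(ValueError, match="promoter_m"):
            call_dmrs(self._frame([(2.0, 1e-7)]), CallPolicy(), mode="promoter")

    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 22_480, 2.2e-6), (0.7, 1, 0.7), (0.05, 20, 2.5e-3)],
    )
    def test_bonferroni_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=0.02)

    def test_bonferroni_zero_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_bh_fdr_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=100) ** 2
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), expected)


class TestInteraction:
    def _factorial_counts(self, make_counts, factorial_sheet, Y):
        sheet = factorial_sheet()
        return make_counts(Y, sheet=sheet), sheet

    def test_z_identity_on_noiseless_counts(self, make_counts, factorial_sheet):
        """Z equals the difference of the stratified fits' log2fc exactly."""
        mu = np.tile([80.0] * 5 + [20.0] * 5 + [30.0] * 5 + [60.0] * 5, (10, 1))
        Y = np.round(mu).astype(int)
        cm, sheet = self._factorial_counts(make_counts, factorial_sheet, Y)
        norm = normalize(cm)
        X = np.column_stack([
            np.ones(20),
            [1.0] * 10 + [0.0] * 10,
            ([1.0] * 5 + [0.0] * 5) * 2,
            [1.0] * 5 + [0.0] * 5 + [0.0] * 10,
        ])
        d = estimate_dispersion(cm, X, norm.offsets.to_numpy())
        res = interaction_test(cm, d, norm, strain_order=sheet.strains)
        s0, s1 = sheet.strains
        assert np.allclose(
            res["Z"], res[f"log2fc_{s0}"] - res[f"log2fc_{s1}"], atol=1e-6
        )

    def test_missing_cell_rejected(self, make_counts):
        infos = [SampleInfo(f"s{i}", "A" if i < 5 else "B",
                            "control" if i < 8 else "dehp") for i in range(10)]
        # strain A has no dehp samples
        sheet = SampleSheet(infos)
        cm = make_counts(np.ones((5, 10), dtype=int), sheet=sheet)
        norm = normalize(cm)
        d_dummy = estimate_dispersion(
            cm, np.column_stack([np.ones(10), [1] * 5 + [0] * 5]),
            norm.offsets.to_numpy())
        with pytest.raises(ValueError, match="no samples"):
            interaction_test(cm, d_dummy, norm)

    def test_equal_effects_give_null_z(self, make_counts, factorial_sheet):
        """Same treatment effect in both strains: Z centers on zero."""
        rng = np.random.default_rng(9)
        mu = np.tile([200.0] * 5 + [50.0] * 5 + [200.0] * 5 + [50.0] * 5, (300, 1))
        Y = nb_draw(rng, mu, 0.05)
        cm, sheet = self._factorial_counts(make_counts, factorial_sheet, Y)
        norm = normalize(cm)
        X = np.column_stack([
            np.ones(20), [1.0] * 10 + [0.0] * 10,
            ([1.0] * 5 + [0.0] * 5) * 2,
            [1.0] * 5 + [0.0] * 5 + [0.0] * 10,
        ])
        d = estimate_dispersion(cm, X, norm.offsets.to_numpy())
        res = interaction_test(cm, d, norm, strain_order=sheet.strains)
        assert abs(res["Z"].mean()) < 0.1
        # interaction p-values behave like a null sample
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01
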