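"""Mixed RM-ANOVA, Greenhouse-Geisser, Box-Cox, post-hocs — against oracles.

The brute-force oracle fits the cell-means model by explicit least
squares / direct matrix formulas, independently of the implementation.
"""

import numpy as np
import pandas as pd
import pytest

from ratqeeg import stats as rstats


# ---------------------------------------------------------------------------
# oracles


def oracle_mixed_anova(Y, codes):
    """Cell-means least-squares sums-of-squares decomposition."""
    N, t = Y.shape
    k = int(codes.max()) + 1
    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    g_mean = np.array([Y[codes == g].mean() for g in range(k)])
    t_mean = Y.mean(axis=0)
    cell = np.array([[Y[codes == g, j].mean() for j in range(t)] for g in range(k)])
    n_g = np.bincount(codes)
    ss_treat = t * np.sum(n_g * (g_mean - grand) ** 2)
    ss_subj = t * np.sum((subj_mean - grand) ** 2) - ss_treat
    ss_time = N * np.sum((t_mean - grand) ** 2)
    ss_inter = sum(
        n_g[g] * (cell[g, j] - g_mean[g] - t_mean[j] + grand) ** 2
        for g in range(k) for j in range(t)
    )
    ss_within = np.sum((Y - subj_mean[:, None]) ** 2)
    ss_err = ss_within - ss_time - ss_inter
    ms_err = ss_err / ((N - k) * (t - 1))
    return {
        "treatment": (ss_treat / (k - 1)) / (ss_subj / (N - k)),
        "time": (ss_time / (t - 1)) / ms_err,
        "treatment:time": (ss_inter / ((k - 1) * (t - 1))) / ms_err,
    }


def oracle_gg_epsilon(S):
    """Direct matrix-formula epsilon with an explicit centering matrix."""
    t = S.shape[0]
    P = np.eye(t) - np.ones((t, t)) / t
    C = P @ S @ P
    lam = np.linalg.eigvalsh(C)
    return float(np.clip(np.sum(lam) ** 2 / ((t - 1) * np.sum(lam**2)),
                         1.0 / (t - 1), 1.0))


def _random_design(rng, k=2, t=3, n=5):
    codes = np.repeat(np.arange(k), n)
    Y = rng.normal(size=(k * n, t)) + rng.normal(size=(k * n, 1))
    return Y, codes


def _long(Y, codes):
    rows = []
    for i in range(Y.shape[0]):
        for j in range(Y.shape[1]):
            rows.append({"subject": f"s{i}", "group": f"g{codes[i]}",
                         "time": f"t{j}", "value": Y[i, j]})
    return pd.DataFrame(rows)


class TestBoxCox:
    def test_identity_ratio_maps_to_zero(self):
        assert rstats.boxcox_ratio(3.7, 3.7) == 0.0

    def test_doubling_maps_to_log2(self):
        assert rstats.boxcox_ratio(2.0, 1.0) == pytest.approx(np.log(2.0))

    def test_lambda_limit_approaches_log(self):
        # (r^lam - 1)/lam = log r + lam (log r)^2 / 2 + O(lam^2)
        r = 3.0
        for lam in (1e-4, 1e-6):
            diff = rstats.boxcox_ratio(r, 1.0, lam=lam) - np.log(r)
            assert diff == pytest.approx(lam * np.log(r) ** 2 / 2, rel=1e-3)
        assert abs(rstats.boxcox_ratio(r, 1.0, lam=1e-8) - np.log(r)) < 1e-6

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            rstats.boxcox_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            rstats.boxcox_ratio(1.0, -2.0)


class TestGGEpsilon:
    def test_compound_symmetry_gives_unity(self):
        S = 0.3 * np.ones((4, 4)) + 0.7 * np.eye(4)
        assert rstats.gg_epsilon(S) == pytest.approx(1.0)

    def test_maximally_nonspherical_hits_lower_bound(self):
        # rank-1 centered covariance at t = 3 -> epsilon = 1/(t-1) = 0.5
        v = np.array([1.0, 0.0, -1.0])
        S = np.outer(v, v)
        assert rstats.gg_epsilon(S) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_matrix_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 3))
        S = A.T @ A
        assert rstats.gg_epsilon(S) == pytest.approx(oracle_gg_epsilon(S), abs=1e-10)


class TestRmAnova:
    def test_interaction_df_contract_four_groups_three_epochs(self):
        rng = np.random.default_rng(0)
        Y, codes = _random_design(rng, k=4, t=3, n=8)
        res = rstats.rm_anova(_long(Y, codes))
        e = res.effects["treatment:time"]
        assert e.df_num == 6
        assert e.df_den == (32 - 4) * 2

    def test_error_df_with_34_subjects(self):
        rng = np.random.default_rng(1)
        codes = np.repeat([0, 1, 2, 3], [9, 9, 8, 8])
        Y = rng.normal(size=(34, 3))
        res = rstats.rm_anova(_long(Y, codes))
        assert res.effects["treatment:time"].df_den == (34 - 4) * 2 == 60

    def test_f_values_match_least_squares_oracle_50_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            t = int(rng.integers(2, 5))
            n = int(rng.integers(3, 7))
            Y, codes = _random_design(rng, k, t, n)
            res = rstats.mixed_anova_arrays(Y, codes)
            want = oracle_mixed_anova(Y, codes)
            for name, f_want in want.items():
                assert float(res[name]["F"]) == pytest.approx(f_want, abs=1e-8)

    def test_ss_decomposition_is_exact(self):
        rng = np.random.default_rng(3)
        Y, codes = _random_design(rng, k=3, t=4, n=6)
        res = rstats.mixed_anova_arrays(Y, codes)
        total = (res["treatment"]["ss"] + res["ss_subj_within"] + res["time"]["ss"]
                 + res["treatment:time"]["ss"] + res["ss_err_within"])
        assert float(total) == pytest.approx(float(res["ss_total"]), rel=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        Y, codes = _random_design(rng, k=2, t=3, n=6)
        df = _long(Y, codes).rename(columns={})
        mine = rstats.rm_anova(df)
        theirs = pingouin.mixed_anova(
            df, dv="value", within="time", subject="subject", between="group"
        ).set_index("Source")
        assert mine.effects["treatment"].F == pytest.approx(
            float(theirs.loc["group", "F"]), rel=1e-9)
        assert mine.effects["time"].F == pytest.approx(
            float(theirs.loc["time", "F"]), rel=1e-9)
        assert mine.effects["treatment:time"].F == pytest.approx(
            float(theirs.loc["Interaction", "F"]), rel=1e-9)

    def test_degenerate_zero_variance_flagged(self):
        Y = np.ones((8, 3))
        codes = np.repeat([0, 1], 4)
        res = rstats.rm_anova(_long(Y, codes))
        assert res.degenerate

    def test_too_few_groups_rejected(self):
        Y = np.zeros((4, 3))
        with pytest.raises(ValueError):
            rstats.mixed_anova_arrays(Y, np.zeros(4, dtype=int))

    def test_incomplete_subject_dropped(self):
        rng = np.random.default_rng(5)
        Y, codes = _random_design(rng, k=2, t=3, n=5)
        df = _long(Y, codes)
        df = df[~((df.subject == "s0") & (df.time == "t2"))]
        res = rstats.rm_anova(df)
        assert res.n_subjects == 9


class TestNormality:
    def test_gaussian_samples_mostly_pass(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            rstats.normality_check(rng.normal(size=500)).p < 0.05
            for _ in range(100)
        )
        assert rejections <= 10

    def test_exponential_samples_mostly_fail(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            rstats.normality_check(rng.exponential(size=500)).p < 0.05
            for _ in range(100)
        )
        assert rejections >= 95

    def test_constant_sample_degenerate(self):
        assert rstats.normality_check(np.ones(10)).degenerate

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            rstats.normality_check([1.0, 2.0])


class TestPosthocAndInference:
    def _design_with_interaction(self, strength, rng):
        codes = np.repeat([0, 1], 8)
        Y = rng.normal(scale=0.3, size=(16, 3))
        Y[8:, 0] += strength  # treated group deviates at the first time only
        return _long(Y, codes)

    def test_nonsignificant_interaction_gates_posthocs(self, rng):
        design = self._design_with_interaction(0.0, rng)
        res = rstats.rm_anova(design)
        ph = rstats.bonferroni_posthoc(design, res)
        if not res.interaction_significant:
            assert len(ph) == 0

    def test_bonferroni_arithmetic_and_clipping(self, rng):
        design = self._design_with_interaction(3.0, rng)
        res = rstats.rm_anova(design)
        assert res.interaction_significant
        ph = rstats.bonferroni_posthoc(design, res)
        m = len(ph)
        assert m == 3  # one comparison per time level for k = 2
        assert np.allclose(ph.p_bonferroni, np.minimum(ph.p_raw * m, 1.0))
        assert (ph.p_bonferroni <= 1.0).all()

    def test_inference_interaction_branch(self, rng):
        design = self._design_with_interaction(3.0, rng)
        inf = rstats.gfc_inference(design)
        assert inf.branch == "interaction"
        assert len(inf.posthoc) > 0

    def test_inference_main_effect_branch(self, rng):
        codes = np.repeat([0, 1], 8)
        Y = rng.normal(scale=0.3, size=(16, 3))
        Y[8:] += 2.0  # uniform shift: main effect, no interaction
        inf = rstats.gfc_inference(_long(Y, codes))
        assert inf.branch == "main_effect"
        assert (inf.posthoc.level == "overall").all()

    def test_inference_no_effect_branch(self, rng):
        codes = np.repeat([0, 1], 8)
        Y = rng.normal(scale=0.3, size=(16, 3))
        inf = rstats.gfc_inference(_long(Y, codes))
        assert inf.branch == "none"
        assert len(inf.posthoc) == 0
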