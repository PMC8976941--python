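import itertools
import math

import numpy as np
import pandas as pd
import pytest

import ergflick as ef
from ergflick.errors import DesignError, ModelError


def make_clustered(n_subj=8, n_rep=30, subj_sd=2.0, resid_sd=1.0, effect=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, subj_sd)
        for cond in ("a", "b"):
            shift = effect if cond == "b" else 0.0
            for _ in range(n_rep):
                rows.append({"crab": f"c{s:02d}", "cond": cond,
                             "y": u + shift + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestRandomIntercept:
    def test_zero_subject_variance_matches_ols(self):
        df = make_clustered(n_subj=6, n_rep=20, subj_sd=0.0, effect=1.0, seed=3)
        mf = ef.fit_random_intercept(df, "y ~ C(cond)", "crab")
        X = np.column_stack([np.ones(len(df)), (df["cond"] == "b").astype(float)])
        beta = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert mf.coefficients["Intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert mf.coefficients["C(cond)[T.b]"] == pytest.approx(beta[1], abs=1e-6)
        assert mf.subject_variance < 0.05

    def test_variance_components_recovered(self):
        df = make_clustered(n_subj=30, n_rep=20, subj_sd=2.0, resid_sd=1.0, seed=1)
        mf = ef.fit_random_intercept(df, "y ~ C(cond)", "crab")
        # the between-subject component is sampling-limited by n_subj
        assert mf.subject_variance == pytest.approx(4.0, rel=0.5)
        assert mf.residual_variance == pytest.approx(1.0, rel=0.15)

    def test_effect_coefficient_recovered(self):
        df = make_clustered(n_subj=20, effect=0.8, seed=2)
        mf = ef.fit_random_intercept(df, "y ~ C(cond)", "crab")
        assert mf.coefficients["C(cond)[T.b]"] == pytest.approx(0.8, abs=0.15)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent cross-check of the REML profile against MixedLM."""
        from statsmodels.regression.mixed_linear_model import MixedLM
        import patsy

        df = make_clustered(n_subj=8, n_rep=12, subj_sd=1.5, effect=0.5, seed=4)
        mf = ef.fit_random_intercept(df, "y ~ C(cond)", "crab")
        y, X = patsy.dmatrices("y ~ C(cond)", df, return_type="dataframe")
        sm = MixedLM(np.asarray(y).ravel(), X.to_numpy(),
                     groups=df["crab"].to_numpy()).fit(reml=True)
        assert mf.coefficients["C(cond)[T.b]"] == pytest.approx(
            float(sm.fe_params[1]), abs=1e-5
        )
        assert mf.residual_variance == pytest.approx(float(sm.scale), rel=1e-3)
        assert mf.subject_variance == pytest.approx(
            float(np.asarray(sm.cov_re)[0, 0]), rel=1e-2, abs=1e-4
        )

    def test_singular_design_named(self):
        df = make_clustered(n_subj=3, n_rep=4)
        df["dup"] = (df["cond"] == "b").astype(float)
        with pytest.raises(ModelError, match="collinear"):
            ef.fit_random_intercept(df, "y ~ C(cond) + dup", "crab")

    def test_single_subject_rejected(self):
        df = make_clustered(n_subj=1, n_rep=10)
        with pytest.raises(ModelError):
            ef.fit_random_intercept(df, "y ~ C(cond)", "crab")


class TestPermutationTest:
    def test_strong_effect_hits_the_p_floor(self):
        df = make_clustered(n_subj=6, n_rep=10, effect=5.0, seed=5)
        res = ef.permutation_fixed_effect_test(
            df, "y ~ C(cond)", "cond", "crab", n_perm=199, seed=0
        )
        assert res.p_value == pytest.approx(1 / 200)

    def test_seed_reproducibility(self):
        df = make_clustered(n_subj=5, n_rep=6, effect=0.3, seed=6)
        a = ef.permutation_fixed_effect_test(df, "y ~ C(cond)", "cond", "crab",
                                             n_perm=199, seed=11)
        b = ef.permutation_fixed_effect_test(df, "y ~ C(cond)", "cond", "crab",
                                             n_perm=199, seed=11)
        assert a.p_value == b.p_value and a.observed == b.observed

    def test_exact_enumeration_matches_brute_force(self):
        """3 subjects x 2 conditions: the exact-mode p equals a from-scratch
        enumeration of all within-subject label flips."""
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "crab": ["c0", "c0", "c1", "c1", "c2", "c2"],
                "cond": ["a", "b"] * 3,
                "y": rng.normal(size=6),
            }
        )
        res = ef.permutation_fixed_effect_test(
            df, "y ~ C(cond)", "cond", "crab", exact=True
        )
        # brute force: recompute the whitened RSS-drop statistic for every
        # flip using nothing but numpy
        mf = ef.fit_random_intercept(df, "y ~ C(cond)", "crab")
        s2, t2 = mf.residual_variance, max(mf.subject_variance, 0.0)
        sigma = math.sqrt(s2)

        def whiten(v, groups):
            v = np.array(v, dtype=float)
            out = v.copy()
            for g in set(groups):
                ix = np.nonzero(np.array(groups) == g)[0]
                n = len(ix)
                c = 1 - sigma / math.sqrt(s2 + n * t2)
                out[ix] = (v[ix] - c / n * v[ix].sum()) / sigma
            return out

        def rss(X, y):
            b = np.linalg.lstsq(X, y, rcond=None)[0]
            r = y - X @ b
            return r @ r

        groups = df["crab"].tolist()
        yw = whiten(df["y"].to_numpy(), groups)
        ones_w = whiten(np.ones(6), groups)
        stats = []
        for flips in itertools.product([0, 1], repeat=3):
            dummy = []
            for s, fl in enumerate(flips):
                dummy += [fl, 1 - fl]  # b-indicator, possibly flipped
            dw = whiten(np.array(dummy, dtype=float), groups)
            stat = rss(ones_w[:, None], yw) - rss(np.column_stack([ones_w, dw]), yw)
            stats.append(stat)
        obs = stats[0]  # identity labelling first
        p_brute = np.mean([s >= obs - 1e-12 for s in stats])
        assert res.n_permutations == 8
        assert res.p_value == pytest.approx(p_brute, abs=1e-12)

    def test_null_rejection_rate_near_nominal(self):
        """Rejection rate at alpha=0.05 over replicate null datasets."""
        rej = 0
        reps = 200
        for rep in range(reps):
            df = make_clustered(n_subj=6, n_rep=4, subj_sd=1.0, seed=10_000 + rep)
            p = ef.permutation_fixed_effect_test(
                df, "y ~ C(cond)", "cond", "crab", n_perm=99, seed=rep
            ).p_value
            rej += p <= 0.05
        # binomial(200, 0.05): central 99.9% mass within [0.005, 0.11]
        assert 0.005 <= rej / reps <= 0.11

    def test_between_subject_term_rejected_for_within_shuffle(self):
        df = make_clustered(n_subj=4, n_rep=5, seed=12)
        df["sex"] = np.where(df["crab"].isin(["c00", "c01"]), "M", "F")
        with pytest.raises(DesignError):
            ef.permutation_fixed_effect_test(df, "y ~ sex", "sex", "crab")


class TestWelch:
    def test_identical_samples(self):
        t, df, p = ef.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_fixture_closed_form(self):
        """Hand computation: se^2 = 5/3/4 + 5/3/4, t = -1/sqrt(5/6),
        Welch-Satterthwaite df = 6."""
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        t, df, p = ef.welch_t_test(x, y)
        se2 = (5 / 3) / 4 + (5 / 3) / 4
        t_hand = -1.0 / math.sqrt(se2)
        df_hand = se2**2 / (((5 / 3) / 4) ** 2 / 3 * 2)
        from scipy import stats as sp_stats

        p_hand = 2 * sp_stats.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_zero_variance_convention(self):
        t, df, p = ef.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_type_one_error_with_unequal_variances(self):
        """Welch keeps ~5% size when SDs differ 1 vs 5."""
        rng = np.random.default_rng(21)
        reps = 4000
        x = rng.normal(0, 1, size=(reps, 8))
        y = rng.normal(0, 5, size=(reps, 10))
        rej = 0
        for i in range(reps):
            _, _, p = ef.welch_t_test(x[i], y[i])
            rej += p < 0.05
        assert 0.035 <= rej / reps <= 0.065


class TestPairwiseContrasts:
    def frame(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(6):
            for c in ("c1", "c2", "c3", "c4"):
                y = rng.normal() + (shift if c == "c4" else 0.0)
                rows.append({"crab": f"s{s}", "cond": c, "y": y})
        return pd.DataFrame(rows)

    def test_identical_distributions_give_large_p(self):
        df = self.frame()
        df["y"] = df.groupby("crab")["y"].transform("mean")  # identical per crab
        out = ef.pairwise_contrasts(df, "y", "cond", "crab")
        assert (out["p_holm"] == 1.0).all()

    def test_shifted_condition_dominates(self):
        out = ef.pairwise_contrasts(self.frame(shift=10.0, seed=1), "y", "cond", "crab")
        hit = out[(out["a"] == "c4") | (out["b"] == "c4")]
        null = out[(out["a"] != "c4") & (out["b"] != "c4")]
        # sign-flip floor for n=6 is 2/64
        assert (hit["p_raw"] <= 2 / 64 + 1e-12).all()
        assert null["p_raw"].min() > 0.1

    def test_holm_adjustment_matches_hand_computation(self):
        out = ef.pairwise_contrasts(self.frame(shift=3.0, seed=2), "y", "cond", "crab")
        raw = out["p_raw"].to_numpy()
        order = np.argsort(raw)
        m = len(raw)
        stepped = np.maximum.accumulate((m - np.arange(m)) * raw[order])
        hand = np.minimum(stepped, 1.0)
        assert np.allclose(np.sort(out["p_holm"].to_numpy()), np.sort(hand))
        assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_missing_condition_rejected(self):
        df = self.frame()
        with pytest.raises(DesignError):
            ef.pairwise_contrasts(df[df["cond"] != "c1"], "y", "cond", "crab")
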