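import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from cernet.diffexpr import (
    ExpressionStudy,
    PriorUnavailableError,
    VariancePrior,
    bh_adjust,
    call_directions,
    de_table,
    fit_variance_prior,
    intersect_de,
    log2_normalize,
    moderated_t_test,
)


def make_study(matrix, n_tumor, n_normal, paired=False):
    n = matrix.shape[0]
    feature_ids = [f"f{i}" for i in range(n)]
    samples = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_normal)]
    design = pd.DataFrame(
        {"condition": ["tumor"] * n_tumor + ["normal"] * n_normal},
        index=pd.Index(samples, name="sample_id"),
    )
    if paired:
        assert n_tumor == n_normal
        design["pair_id"] = [f"p{i}" for i in range(n_tumor)] * 2
    mat = pd.DataFrame(matrix, index=pd.Index(feature_ids, name="feature_id"), columns=samples)
    return ExpressionStudy(mat, design)


class TestLog2Normalize:
    @pytest.mark.parametrize("value,pseudo,expected", [(0.0, 1.0, 0.0), (7.0, 1.0, 3.0), (3.0, 1.0, 2.0)])
    def test_known_values(self, value, pseudo, expected):
        df = pd.DataFrame([[value]])
        assert log2_normalize(df, pseudo).iloc[0, 0] == pytest.approx(expected)

    def test_preserves_column_ordering(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.uniform(0, 1000, size=(30, 4)))
        out = log2_normalize(raw)
        for col in raw.columns:
            assert (np.argsort(raw[col].to_numpy()) == np.argsort(out[col].to_numpy())).all()

    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError, match="negative"):
            log2_normalize(pd.DataFrame([[-1.0]]))


class TestVariancePrior:
    def test_equal_variances_give_infinite_prior_df(self):
        prior = fit_variance_prior(np.full(50, 2.5), df=4)
        assert math.isinf(prior.d0)
        # infinite-d0 convention: s0_sq = exp(mean(log s^2) - digamma(df/2) + log(df))
        expected = math.exp(math.log(2.5) - special.digamma(2.0) + math.log(4))
        assert prior.s0_sq == pytest.approx(expected)

    def test_two_feature_case_matches_bisection_oracle(self):
        # s^2 = {1, e^2}, large df: var(log s^2) = 2, trigamma(df/2) ~ 0
        df = 1000
        prior = fit_variance_prior(np.array([1.0, math.e**2]), df=df)
        target = np.var(np.log([1.0, math.e**2]), ddof=1) - special.polygamma(1, df / 2)
        lo, hi = 1e-6, 1e6
        for _ in range(200):  # plain bisection as the independent oracle
            mid = (lo + hi) / 2
            if special.polygamma(1, mid) > target:
                lo = mid
            else:
                hi = mid
        assert prior.d0 == pytest.approx(2 * lo, rel=1e-6)
        assert math.isfinite(prior.d0)

    def test_recovers_planted_hyperparameters(self):
        # s^2 | sigma^2 ~ sigma^2 * chi2_df / df with sigma^2 ~ d0*s0^2/chi2_d0
        rng = np.random.default_rng(42)
        d0, s0_sq, df, n = 4.0, 1.0, 4, 10_000
        sigma_sq = d0 * s0_sq / rng.chisquare(d0, size=n)
        s_sq = sigma_sq * rng.chisquare(df, size=n) / df
        prior = fit_variance_prior(s_sq, df=df)
        assert prior.d0 == pytest.approx(d0, rel=0.2)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.2)

    def test_too_few_features_signals_fallback(self):
        with pytest.raises(PriorUnavailableError):
            fit_variance_prior(np.array([1.0]), df=4)


class TestModeratedT:
    def test_d0_zero_equals_classical_unpaired_t(self):
        rng = np.random.default_rng(3)
        study = make_study(rng.normal(8, 1, size=(40, 9)), 5, 4)
        tab = moderated_t_test(study, VariancePrior(d0=0.0, s0_sq=1.0))
        t_ref, p_ref = stats.ttest_ind(
            study.matrix.iloc[:, :5], study.matrix.iloc[:, 5:], axis=1, equal_var=True
        )
        np.testing.assert_allclose(tab["t_stat"], t_ref, atol=1e-10)
        np.testing.assert_allclose(tab["p_value"], p_ref, atol=1e-10)

    def test_d0_zero_equals_classical_paired_t(self):
        rng = np.random.default_rng(4)
        study = make_study(rng.normal(8, 1, size=(25, 12)), 6, 6, paired=True)
        tab = moderated_t_test(study, prior=None, paired=True)
        t_ref, p_ref = stats.ttest_rel(study.matrix.iloc[:, :6], study.matrix.iloc[:, 6:], axis=1)
        np.testing.assert_allclose(tab["t_stat"], t_ref, atol=1e-10)
        np.testing.assert_allclose(tab["p_value"], p_ref, atol=1e-10)

    def test_paired_hand_example(self):
        # within-pair differences {1, 2, 3}: t = 2/(1/sqrt(3)) = 3.464, df = 2
        tumor = np.array([[11.0, 12.0, 13.0], [5.0, 6.0, 7.0]])
        normal = np.array([[10.0, 10.0, 10.0], [4.0, 4.0, 4.0]])
        study = make_study(np.hstack([tumor, normal]), 3, 3, paired=True)
        tab = moderated_t_test(study, prior=None, paired=True)
        assert tab.loc["f0", "t_stat"] == pytest.approx(2 * math.sqrt(3), abs=1e-3)
        assert tab.loc["f0", "df_total"] == 2

    def test_infinite_d0_uses_prior_variance_exactly(self):
        rng = np.random.default_rng(5)
        study = make_study(rng.normal(0, 1, size=(10, 8)), 4, 4)
        s0_sq = 0.7
        tab = moderated_t_test(study, VariancePrior(d0=math.inf, s0_sq=s0_sq))
        log_fc = study.matrix.iloc[:, :4].mean(axis=1) - study.matrix.iloc[:, 4:].mean(axis=1)
        c = math.sqrt(1 / 4 + 1 / 4)
        np.testing.assert_allclose(tab["t_stat"], log_fc / (math.sqrt(s0_sq) * c), atol=1e-12)

    def test_zero_variance_feature_flagged_not_dropped(self):
        mat = np.vstack([np.array([5.0, 5.0, 5.0, 4.0, 4.0, 4.0]), np.random.default_rng(0).normal(size=6)])
        study = make_study(mat, 3, 3)
        tab = moderated_t_test(study, prior=None)
        assert tab.loc["f0", "zero_variance"]
        assert np.isnan(tab.loc["f0", "p_value"])
        assert len(tab) == 2


def bh_bruteforce(p):
    """Direct min-scan: adj_i = min over j with p_j >= p_i of p_j * m / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    adj = np.empty(m)
    for i in range(m):
        candidates = [p[j] * m / rank[j] for j in range(m) if p[j] >= p[i]] + [1.0]
        adj[i] = min(candidates)
    return adj


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_bruteforce_and_bounds(self, p):
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_bruteforce(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDirections:
    def table(self, log_fc, adj_p):
        return pd.DataFrame({"log_fc": log_fc, "adj_p": adj_p})

    @pytest.mark.parametrize(
        "log_fc,adj_p,cutoff,expected",
        [
            (2.0, 0.01, 1.5, "up"),
            (-2.0, 0.01, 1.5, "down"),
            (1.5, 0.01, 1.5, "ns"),  # boundary is ns: strict inequality
            (2.0, 0.05, 1.5, "ns"),  # alpha boundary
            (0.1, 0.01, 0.0, "up"),  # relaxed |logFC| > 0 rule
            (0.0, 0.01, 0.0, "ns"),
        ],
    )
    def test_threshold_rules(self, log_fc, adj_p, cutoff, expected):
        out = call_directions(self.table([log_fc], [adj_p]), lfc_cutoff=cutoff)
        assert out["direction"].iloc[0] == expected

    def test_directions_partition_features(self):
        rng = np.random.default_rng(1)
        out = call_directions(self.table(rng.normal(0, 2, 100), rng.uniform(size=100)))
        assert out["direction"].isin(["up", "down", "ns"]).all()


class TestIntersect:
    def de(self, ups, downs):
        ids = list(ups) + list(downs)
        return pd.DataFrame(
            {"direction": ["up"] * len(ups) + ["down"] * len(downs)},
            index=pd.Index(ids, name="feature_id"),
        )

    def test_set_intersection(self):
        overlap = intersect_de(self.de(["x", "y"], []), self.de(["y", "z"], []))
        assert overlap == {"up": {"y"}, "down": set()}

    def test_sign_conflict_excluded(self):
        overlap = intersect_de(self.de(["a"], ["b"]), self.de(["b"], ["a"]))
        assert overlap == {"up": set(), "down": set()}


class TestRecoveryOnSyntheticData:
    def test_planted_directions_recovered(self, default_study, default_truth):
        """Strong planted effects: >=95% recovery, few false direction calls."""
        study = default_study.mrna_study
        tab = de_table(study, paired=True, lfc_cutoff=1.5, alpha=0.05)
        planted = {f: d for f, d in default_truth.de_features.items() if f.startswith("gene")}
        hits = sum(tab.loc[f, "direction"] == d for f, d in planted.items())
        assert hits / len(planted) >= 0.95
        non_de = [f for f in study.matrix.index if f not in planted]
        false_calls = (tab.loc[non_de, "direction"] != "ns").sum()
        assert false_calls <= 0.05 * 2 * len(non_de)
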