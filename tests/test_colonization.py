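import numpy as np
import pandas as pd
import pytest

from glvmap.colonization import (
    extract_colonization_times,
    fit_interaction_network,
    helpfulness_regression,
    mixed_model_predictability,
    normalize_alpha,
    predictability_scores,
    read_cohort_csv,
    test_mean_predictability,
)


def long_table(rows):
    return pd.DataFrame(rows, columns=["subject", "taxon", "time_days", "abundance"])


def cohort_from_regression(r, alpha, eps, n_subjects=3, n_days=30, seed=0):
    """Generate a cohort exactly following the discrete regression model, so
    coefficients are recoverable to numerical precision."""
    rng = np.random.default_rng(seed)
    taxa = [f"t{i}" for i in range(len(r))]
    rows = []
    for s in range(n_subjects):
        X = rng.uniform(0.5, 2.0, size=len(r))
        abx = rng.integers(0, 2, size=n_days).astype(float)
        for day in range(n_days):
            for i, taxon in enumerate(taxa):
                rows.append({"subject": f"s{s}", "taxon": taxon, "time_days": float(day),
                             "abundance": X[i], "abx0": abx[day]})
            # step the *log* abundances with the regression RHS evaluated at
            # the geometric mean of consecutive samples -- implicit midpoint,
            # solved by fixed-point iteration
            Xn = X.copy()
            for _ in range(200):
                G = np.sqrt(X * Xn)
                e_mid = 0.5 * (abx[day] + abx[min(day + 1, n_days - 1)])
                rate = r + alpha @ G + eps[:, 0] * e_mid
                Xn_new = X * np.exp(rate)
                if np.allclose(Xn_new, Xn, rtol=1e-14):
                    Xn = Xn_new
                    break
                Xn = Xn_new
            X = Xn
    return pd.DataFrame(rows)


class TestColonizationTimes:
    def test_threshold_boundary_inclusive(self):
        df = long_table([("a", "x", 1.0, 0.2), ("a", "x", 3.0, 0.5), ("a", "x", 5.0, 0.9)])
        ev = extract_colonization_times(df, 0.5)
        row = ev[(ev.subject == "a") & (ev.taxon == "x")].iloc[0]
        assert row.time_days == 3.0 and row.detected

    def test_never_detected(self):
        df = long_table([("a", "x", 1.0, 0.1), ("a", "y", 1.0, 2.0)])
        ev = extract_colonization_times(df, 0.5)
        row = ev[(ev.taxon == "x")].iloc[0]
        assert not row.detected and np.isnan(row.time_days)

    def test_all_zero_subject_warns(self):
        df = long_table([("a", "x", 1.0, 0.0), ("b", "x", 1.0, 2.0)])
        with pytest.warns(UserWarning, match="subject 'a'"):
            extract_colonization_times(df, 0.5)


class TestInteractionFit:
    def test_noise_free_exact_recovery(self):
        rng = np.random.default_rng(5)
        S = 3
        alpha = np.array([[-0.05, 0.02, 0.0], [0.0, -0.04, -0.03], [0.06, 0.0, -0.05]])
        r = np.array([0.1, 0.05, 0.08])
        eps = np.array([[-0.2], [-0.1], [0.0]])
        df = cohort_from_regression(r, alpha, eps, seed=5)
        net = fit_interaction_network(df, penalty="ols")
        for i, ti in enumerate(net.taxa):
            assert net.r[ti] == pytest.approx(r[i], abs=1e-6)
            for j, tj in enumerate(net.taxa):
                if i != j:
                    assert net.alpha.loc[ti, tj] == pytest.approx(alpha[i, j], abs=1e-6)
            assert net.epsilon.loc[ti, "abx0"] == pytest.approx(eps[i, 0], abs=1e-6)

    def test_all_zero_antibiotic_column_unidentifiable(self):
        rng = np.random.default_rng(6)
        rows = []
        for day in range(20):
            for i in range(2):
                rows.append({"subject": "s0", "taxon": f"t{i}", "time_days": float(day),
                             "abundance": float(rng.uniform(0.5, 2.0)), "abx0": 0.0})
        df = pd.DataFrame(rows)
        net = fit_interaction_network(df)
        assert (net.epsilon["abx0"] == 0).all()
        assert any(col == "abx0" for _, col in net.unidentifiable)

    def test_taxon_without_positive_windows_excluded(self):
        rows = [{"subject": "s0", "taxon": "dead", "time_days": float(d), "abundance": 0.0}
                for d in range(5)]
        rows += [{"subject": "s0", "taxon": "live", "time_days": float(d), "abundance": 1.0 + d}
                 for d in range(5)]
        with pytest.warns(UserWarning, match="dead"):
            net = fit_interaction_network(pd.DataFrame(rows))
        assert np.isnan(net.r["dead"])

    def test_normalization_by_max(self):
        alpha = pd.DataFrame([[0.0, 0.2], [-0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        norm = normalize_alpha(alpha)
        assert norm.loc["a", "b"] == pytest.approx(0.5)
        assert norm.loc["b", "a"] == pytest.approx(1.0)


class TestPredictability:
    def make_events(self, records):
        rows = []
        for subject, times in records.items():
            for taxon, t in times.items():
                rows.append({"subject": subject, "taxon": taxon,
                             "time_days": t if t is not None else np.nan,
                             "detected": t is not None})
        return pd.DataFrame(rows)

    def test_single_subject_orders(self):
        ev = self.make_events({"s1": {"f": 5.0, "p": 2.0}})
        scores = predictability_scores(ev)
        get = lambda f, p: scores[(scores.focal == f) & (scores.partner == p)].score.iloc[0]
        assert get("f", "p") == 1.0
        assert get("p", "f") == 0.0

    def test_tie_counts_as_with(self):
        ev = self.make_events({"s1": {"f": 3.0, "p": 3.0}})
        scores = predictability_scores(ev)
        assert (scores.score == 1.0).all()

    def test_partner_never_detected_counts_against(self):
        ev = self.make_events({"s1": {"f": 3.0, "p": None}})
        with pytest.warns(UserWarning, match="focal never detected"):
            scores = predictability_scores(ev)  # the (p, f) pair is omitted
        row = scores[(scores.focal == "f") & (scores.partner == "p")]
        assert row.score.iloc[0] == 0.0 and row.n_subjects.iloc[0] == 1

    def test_reciprocal_scores_sum_at_least_one(self):
        rng = np.random.default_rng(8)
        records = {
            f"s{k}": {t: float(rng.integers(0, 10)) for t in "abc"} for k in range(6)
        }
        scores = predictability_scores(self.make_events(records))
        for f in "abc":
            for p in "abc":
                if f >= p:
                    continue
                fp = scores[(scores.focal == f) & (scores.partner == p)].score.iloc[0]
                pf = scores[(scores.focal == p) & (scores.partner == f)].score.iloc[0]
                assert fp + pf >= 1.0 - 1e-12


class TestPermutationTest:
    def test_null_scores_give_p_near_one(self):
        obs, p = test_mean_predictability(np.full(8, 0.5), n_perm=500, seed=0)
        assert obs == 0.5 and p == pytest.approx(1.0)

    def test_all_ones_exact_enumeration(self):
        # 4 scores of 1.0: only the all-positive sign pattern (prob 1/16)
        # reaches the observed mean, so p -> (1 + n_perm/16) / (1 + n_perm)
        obs, p = test_mean_predictability(np.ones(4), n_perm=10_000, seed=1)
        assert obs == 1.0
        assert p == pytest.approx(1 / 16, rel=0.2)

    def test_seed_reproducible_and_order_invariant(self):
        scores = np.array([0.9, 0.7, 0.55, 1.0, 0.8])
        _, p1 = test_mean_predictability(scores, n_perm=2000, seed=42)
        _, p2 = test_mean_predictability(scores, n_perm=2000, seed=42)
        _, p3 = test_mean_predictability(scores[::-1], n_perm=2000, seed=42)
        assert p1 == p2 == p3

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="n_perm"):
            test_mean_predictability(np.array([0.6, 0.7]), n_perm=50, seed=0)


class TestHelpfulness:
    def _network(self, helpfulness):
        from glvmap.colonization import InteractionNetwork

        taxa = sorted(helpfulness)
        alpha = pd.DataFrame(0.0, index=taxa, columns=taxa)
        for t, h in helpfulness.items():
            for other in taxa:
                if other != t:
                    alpha.loc[other, t] = h
        return InteractionNetwork(taxa=taxa, r=pd.Series(0.0, index=taxa), alpha=alpha,
                                  epsilon=pd.DataFrame(index=taxa))

    def _events(self, times):
        return pd.DataFrame(
            [{"subject": "s", "taxon": t, "time_days": d, "detected": True} for t, d in times.items()]
        )

    def test_exact_linear_relation(self):
        helpf = {"a": 0.1, "b": 0.3, "c": 0.6, "d": 0.9}
        times = {t: 10 - 2.0 * h for t, h in helpf.items()}
        res = helpfulness_regression(self._network(helpf), self._events(times))
        assert res.slope == pytest.approx(-2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_permuted_helpfulness_low_r2(self):
        rng = np.random.default_rng(12)
        helpf = {f"t{i}": float(h) for i, h in enumerate(rng.uniform(0, 1, 12))}
        times = {t: 10 - 2.0 * h for t, h in helpf.items()}
        perm = rng.permutation(list(helpf.values()))
        shuffled = {t: float(p) for t, p in zip(helpf, perm)}
        res = helpfulness_regression(self._network(shuffled), self._events(times))
        assert res.r_squared < 0.3

    def test_degenerate_predictor_rejected(self):
        helpf = {"a": 0.5, "b": 0.5, "c": 0.5}
        with pytest.raises(ValueError, match="variance"):
            helpfulness_regression(self._network(helpf), self._events({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestMixedModel:
    def _scores(self, beta, noise, seed, n_genera=8):
        rng = np.random.default_rng(seed)
        genera = [f"g{i}" for i in range(n_genera)]
        rows = []
        for f in genera:
            for p in genera:
                if f == p:
                    continue
                a = rng.normal(0, 0.3)
                rows.append({"focal": f, "partner": p, "alpha": a,
                             "score": 0.5 + beta * a + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_recovers_generating_slope(self):
        df = self._scores(beta=0.8, noise=0.02, seed=3)
        res = mixed_model_predictability(df, iterations=3000, seed=1)
        assert res.ci_low <= 0.8 <= res.ci_high
        assert res.slope == pytest.approx(0.8, abs=0.05)

    def test_identical_alpha_unidentifiable(self):
        df = self._scores(beta=0.8, noise=0.02, seed=4)
        df["alpha"] = 0.2
        with pytest.raises(ValueError, match="unidentifiable"):
            mixed_model_predictability(df, iterations=500, seed=0)

    def test_deterministic_given_seed(self):
        df = self._scores(beta=0.5, noise=0.05, seed=5)
        a = mixed_model_predictability(df, iterations=1000, seed=9)
        b = mixed_model_predictability(df, iterations=1000, seed=9)
        assert a.slope == b.slope and a.ci_low == b.ci_low


class TestIO:
    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"subject": ["a"], "taxon": ["x"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_cohort_csv(path)

    def test_negative_abundance_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        long_table([("a", "x", 1.0, -2.0)]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="nonnegative"):
            read_cohort_csv(path)
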