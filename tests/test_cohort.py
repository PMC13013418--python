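"""Harmonisation, standardisation and the feature-filtering cascade."""

import numpy as np
import pandas as pd
import pytest

from nhocrad.cohort import (
    ClinicalRecord,
    clinical_frame,
    combat_harmonise,
    cox_univariable,
    icc_2_1,
    icc_filter,
    prune_correlated,
    univariable_cox_screen,
    zscore,
)

from conftest import simulate_survival


def _table(arr, prefix="f"):
    arr = np.asarray(arr, float)
    return pd.DataFrame(arr, columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
                        index=[f"p{i}" for i in range(arr.shape[0])])


class TestClinicalRecord:
    def test_validation(self):
        with pytest.raises(ValueError):
            ClinicalRecord("a", time_days=-1, event=1)
        with pytest.raises(ValueError):
            ClinicalRecord("a", time_days=10, event=2)
        with pytest.raises(ValueError):
            ClinicalRecord("a", time_days=10, event=1, stage_simple=5)
        df = clinical_frame([ClinicalRecord("a", 100, 1, stage_simple=2, site="X")])
        assert df.loc["a", "stage_simple"] == 2


class TestComBat:
    def test_single_batch_is_identity(self, rng):
        t = _table(rng.normal(0, 1, (30, 5)))
        out = combat_harmonise(t, pd.Series("A", index=t.index))
        np.testing.assert_allclose(out.values, t.values, atol=1e-8)

    def test_injected_shift_removed(self, rng):
        n = 120
        base = rng.normal(0, 1, (n, 8))
        batch = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        shifted = base.copy()
        shifted[batch == "B"] += 5.0
        t = _table(shifted)
        out = combat_harmonise(t, batch)
        pre_gap = np.abs(shifted[batch == "B"].mean(0) - shifted[batch == "A"].mean(0))
        post_gap = np.abs(
            out.values[batch == "B"].mean(0) - out.values[batch == "A"].mean(0)
        )
        assert (post_gap < 0.05 * pre_gap).all()

    def test_scale_effects_shrunk(self, rng):
        n = 200
        base = rng.normal(0, 1, (n, 10))
        batch = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        scaled = base.copy()
        scaled[batch == "B"] *= 3.0
        out = combat_harmonise(_table(scaled), batch)
        sd_a = out.values[batch == "A"].std(0)
        sd_b = out.values[batch == "B"].std(0)
        assert np.abs(sd_b / sd_a - 1).mean() < 0.2

    def test_singleton_batch_rejected(self, rng):
        t = _table(rng.normal(0, 1, (5, 3)))
        with pytest.raises(ValueError, match="'B'"):
            combat_harmonise(t, np.array(["A", "A", "A", "A", "B"]))


class TestZScore:
    def test_training_column_values(self):
        t = _table([[2.0], [4.0], [6.0]])
        out, params = zscore(t)
        np.testing.assert_allclose(
            out["f0"].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_idempotence_and_validation_transform(self, rng):
        t = _table(rng.normal(3, 2, (50, 4)))
        out, params = zscore(t, fit_on=list(t.index[:30]))
        train = out.loc[t.index[:30]]
        np.testing.assert_allclose(train.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(train.std(ddof=0), 1, atol=1e-10)
        again, _ = zscore(train)
        np.testing.assert_allclose(again.values, train.values, atol=1e-10)

    def test_constant_column_dropped(self, rng):
        t = _table(rng.normal(0, 1, (10, 2)))
        t["const"] = 7.0
        out, params = zscore(t)
        assert "const" not in out.columns


class TestICC:
    def test_identical_tables_icc_one(self, rng):
        a = _table(rng.normal(0, 1, (10, 3)))
        res = icc_filter(a, a.copy())
        assert all(r.icc == pytest.approx(1.0) and r.retained for r in res)

    def test_offset_penalised_matches_anova_oracle(self):
        # a=(1,2,3), b=a+1: two-way ANOVA gives MS_R=2, MS_C=1.5, MS_E=0
        # → ICC(2,1) = 2 / (2 + 2·1.5/3) = 2/3, strictly below 1
        val = icc_2_1([1, 2, 3], [2, 3, 4])
        assert val == pytest.approx(2 / 3, abs=1e-12)
        assert val < 1

    def test_matches_pingouin_reference(self, rng):
        import pingouin as pg

        a = rng.normal(0, 1, 20)
        b = a + rng.normal(0, 0.5, 20)
        ours = icc_2_1(a, b)
        long = pd.DataFrame({
            "target": list(range(20)) * 2,
            "rater": ["r1"] * 20 + ["r2"] * 20,
            "score": np.concatenate([a, b]),
        })
        ref = pg.intraclass_corr(long, targets="target", raters="rater",
                                 ratings="score")
        # ICC(2,1) = two-way random, absolute agreement = pingouin's ICC(A,1)
        ref_val = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(ref_val, abs=1e-8)

    def test_independent_noise_near_zero(self, rng):
        n = 200
        a = _table(rng.normal(0, 1, (n, 1)))
        b = _table(rng.normal(0, 1, (n, 1)))
        res = icc_filter(a, b, threshold=0.8)
        assert abs(res[0].icc) < 0.15
        assert not res[0].retained

    def test_too_few_patients_rejected(self, rng):
        a = _table(rng.normal(0, 1, (2, 2)))
        with pytest.raises(ValueError, match="3"):
            icc_filter(a, a.copy())


class TestPruneCorrelated:
    def test_duplicate_column_drops_exactly_one(self, rng):
        x = rng.normal(0, 1, 30)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 30)})
        out, dropped = prune_correlated(t)
        assert len(dropped) == 1 and dropped[0] in ("a", "b")
        assert "c" in out.columns

    def test_anticorrelation_detected(self, rng):
        x = rng.normal(0, 1, 30)
        t = pd.DataFrame({"x": x, "y": -x})
        out, dropped = prune_correlated(t)
        assert len(out.columns) == 1

    def test_no_surviving_pair_above_threshold(self, rng):
        base = rng.normal(0, 1, 100)
        t = pd.DataFrame({
            "a": base + rng.normal(0, 0.25, 100),
            "b": base + rng.normal(0, 0.25, 100),
            "c": base + rng.normal(0, 0.25, 100),
            "d": rng.normal(0, 1, 100),
        })
        out, _ = prune_correlated(t, r_threshold=0.9)
        # brute-force verification over all survivor pairs
        corr = out.corr().abs().to_numpy()
        iu = np.triu_indices(len(out.columns), 1)
        assert (corr[iu] <= 0.9).all()

    def test_lower_variance_member_dropped(self, rng):
        x = rng.normal(0, 1, 50)
        t = pd.DataFrame({"wide": 3 * x, "narrow": x})
        _, dropped = prune_correlated(t)
        assert dropped == ["narrow"]


class TestCoxScreen:
    def test_bh_step_up_worked_example(self, rng):
        # p = (0.001, 0.02, 0.8) at q ≤ 0.01: only 0.001 ≤ 0.01·1/3 survives
        n = 200
        lp = rng.normal(0, 1, n)
        time, event = simulate_survival(rng, n, lp)
        clin = pd.DataFrame({"time_days": time, "event": event},
                            index=[f"p{i}" for i in range(n)])
        from nhocrad.cohort import ScreenResult
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.001, 0.02, 0.8], method="fdr_bh")
        assert (q <= 0.01).tolist() == [True, False, False]

    def test_informative_feature_retained_noise_not(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        time, event = simulate_survival(rng, n, x)
        idx = [f"p{i}" for i in range(n)]
        t = pd.DataFrame({"true": x, "noise": rng.normal(0, 1, n)}, index=idx)
        clin = pd.DataFrame({"time_days": time, "event": event}, index=idx)
        res = {r.feature_name: r for r in univariable_cox_screen(t, clin)}
        assert res["true"].retained
        assert not res["noise"].retained
        assert res["true"].fdr_q >= res["true"].wald_p

    def test_null_false_positive_rate(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            time, event = simulate_survival(rng, n, np.zeros(n))
            idx = [f"p{i}" for i in range(n)]
            t = pd.DataFrame({"noise": rng.normal(0, 1, n)}, index=idx)
            clin = pd.DataFrame({"time_days": time, "event": event}, index=idx)
            res = univariable_cox_screen(t, clin)
            hits += res[0].retained
        assert hits <= 2

    def test_too_few_events_rejected(self, rng):
        idx = [f"p{i}" for i in range(30)]
        t = pd.DataFrame({"x": rng.normal(0, 1, 30)}, index=idx)
        clin = pd.DataFrame({"time_days": np.arange(1, 31.0),
                             "event": [1] * 5 + [0] * 25}, index=idx)
        with pytest.raises(ValueError, match="events"):
            univariable_cox_screen(t, clin)


class TestCoxAgainstPartialLikelihoodOracle:
    @staticmethod
    def _oracle_beta(x, time, event):
        """Grid/scalar maximisation of the Cox partial likelihood (no ties)."""
        from scipy.optimize import minimize_scalar

        x = np.asarray(x, float)
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        order = np.argsort(time)
        x, time, event = x[order], time[order], event[order]

        def negll(beta):
            ll = 0.0
            for i in np.nonzero(event)[0]:
                risk = time >= time[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return -ll

        res = minimize_scalar(negll, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_beta_matches_oracle_on_small_data(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        x = rng.normal(0, 1, n)
        time = rng.permutation(np.arange(1.0, n + 1))  # distinct times, no ties
        event = np.ones(n, int)
        beta, _ = cox_univariable(x, time, event)
        assert beta == pytest.approx(self._oracle_beta(x, time, event), abs=1e-4)


class TestBHAgainstBruteForce:
    @staticmethod
    def _brute_force_bh(pvals, q):
        """Step-up: largest k with p_(k) ≤ q·k/m; reject the k smallest."""
        p = np.asarray(pvals, float)
        m = len(p)
        order = np.argsort(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= q * k / m:
                k_star = k
        reject = np.zeros(m, bool)
        reject[order[:k_star]] = True
        return reject

    def test_matches_statsmodels_exhaustively(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for n in range(1, 13):
            for _ in range(25):
                p = np.round(rng.random(n), 3)
                for q in (0.01, 0.05, 0.2):
                    ref, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
                    np.testing.assert_array_equal(ref, self._brute_force_bh(p, q))
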