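"""Chained-equation multiple imputation: mechanics, recovery, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from hrvequiv import scoring, simulate
from hrvequiv.impute import (
    ImputationConfig,
    chained_impute,
    decode_missing,
    missingness_screen,
    passive_derive,
)
from hrvequiv._polr import fit_polr, predict_probs


class TestDecode:
    def test_codes_become_nan_and_numerics_survive(self):
        df = pd.DataFrame({"a": ["1", "dont_know", "3"], "b": [1.0, 2.0, 3.0]})
        out = decode_missing(df)
        assert out["a"].isna().sum() == 1
        assert out["a"].dtype.kind == "f"
        pd.testing.assert_series_equal(out["b"], df["b"])

    def test_nominal_column_preserved(self):
        df = pd.DataFrame({"g": ["male", "female", "prefer_not_to_say"]})
        out = decode_missing(df)
        assert out["g"].isna().sum() == 1
        assert set(out["g"].dropna()) == {"male", "female"}


class TestMissingnessScreen:
    def test_no_missing_gives_empty_report(self, small_cohort):
        rep = missingness_screen(small_cohort[["age", "outcome"]], ["age"])
        assert rep.empty

    def test_mcar_correlations_small(self):
        df = simulate.simulate_cohort(
            simulate.CohortSimConfig(n_per_country=600, seed=10, missing_rate=0.05)
        )
        rep = missingness_screen(df, ["age", "log_rmssd"])
        assert (rep["r"].abs().dropna() < 0.1).all()

    def test_mar_on_age_flagged(self):
        df = simulate.simulate_cohort(
            simulate.CohortSimConfig(
                n_per_country=800, seed=11, missing_rate=0.15,
                missing_mechanism="MAR",
            )
        )
        items = [c for c in df.columns if c in scoring.MMAPP_ITEMS]
        rep = missingness_screen(df[items + ["age"]], ["age"])
        assert rep["flagged"].any()


class TestChainedImputation:
    def test_no_missing_yields_identical_copies(self, small_cohort):
        cfg = ImputationConfig(m=3, maxit=1, seed=0)
        res = chained_impute(small_cohort, cfg)
        assert res.m == 3
        base = res.complete(0)
        for i in (1, 2):
            pd.testing.assert_frame_equal(res.complete(i), base)
        # between-imputation variance of any column is exactly zero
        assert base["outcome"].equals(res.complete(1)["outcome"])

    def test_completes_all_cells_and_preserves_observed(self, cohort_with_missing, imputed_small):
        dec = decode_missing(cohort_with_missing)
        cols = [c for c in dec.columns if c in scoring.MMAPP_ITEMS + scoring.DERS_ITEMS
                + scoring.DBIS_ITEMS] + ["height_m", "weight_kg"]
        for i in range(imputed_small.m):
            comp = imputed_small.complete(i)
            assert comp[cols].isna().sum().sum() == 0
            for c in cols:
                obs = dec[c].notna()
                np.testing.assert_allclose(
                    comp.loc[obs, c].astype(float), dec.loc[obs, c].astype(float)
                )

    def test_imputed_ordinals_in_observed_category_set(self, cohort_with_missing, imputed_small):
        dec = decode_missing(cohort_with_missing)
        comp = imputed_small.complete(0)
        for c in [c for c in dec.columns if c in scoring.MMAPP_ITEMS][:10]:
            observed = set(dec[c].dropna().astype(int))
            assert set(comp[c].astype(int)) <= observed

    def test_determinism_under_seed(self, cohort_with_missing):
        cfg = ImputationConfig(m=2, maxit=2, seed=77)
        a = chained_impute(cohort_with_missing, cfg)
        b = chained_impute(cohort_with_missing, cfg)
        for i in range(2):
            pd.testing.assert_frame_equal(a.complete(i), b.complete(i))

    def test_ordinal_marginal_recovered_under_mcar(self):
        # 10% MCAR on one item of a 600-person cohort: pooled imputed-category
        # frequencies within +-5 percentage points of the generating marginal
        df = simulate.simulate_cohort(simulate.CohortSimConfig(n_per_country=200, seed=12))
        item = "nervous_anxious"
        truth_freq = df[item].value_counts(normalize=True).sort_index()
        rng = np.random.default_rng(0)
        corrupted = df.copy()
        corrupted[item] = corrupted[item].astype(object)
        mask = rng.random(len(df)) < 0.10
        corrupted.loc[mask, item] = "empty"
        res = chained_impute(corrupted, ImputationConfig(m=5, maxit=5, seed=13))
        pooled = pd.concat([r.complete(i)[item] for i, r in [(i, res) for i in range(5)]])
        freq = pooled.value_counts(normalize=True).sort_index()
        for cat in truth_freq.index:
            assert abs(freq.get(cat, 0.0) - truth_freq[cat]) < 0.05

    def test_chain_traces_finite_without_drift(self, imputed_small):
        tr = imputed_small.traces
        assert np.isfinite(tr["mean"]).all()
        assert np.isfinite(tr["sd"]).all()

    def test_chains_stationary_under_mcar(self):
        """Per-variable trace means show no monotone drift across sweeps:
        the 1%-level slope test rejects for at most ~5% of chains."""
        from scipy import stats as sps

        df = simulate.simulate_cohort(
            simulate.CohortSimConfig(n_per_country=100, seed=60, missing_rate=0.05)
        )
        res = chained_impute(df, ImputationConfig(m=5, maxit=10, seed=61))
        tr = res.traces
        n_tests = rejections = 0
        for (_, _), g in tr.groupby(["chain", "variable"]):
            if len(g) < 5 or g["mean"].nunique() < 3:
                continue
            slope = sps.linregress(g["iteration"], g["mean"])
            n_tests += 1
            rejections += slope.pvalue < 0.01
        assert n_tests > 50
        assert rejections / n_tests <= 0.08


class TestPooledMeanCoverage:
    def test_rubin_pooled_mean_covers_truth_under_mcar(self):
        """MCAR deletion of a continuous variable: the Rubin-pooled mean CI
        covers the generating mean in about 95% of replicates."""
        from scipy import stats as sps

        from hrvequiv.modeling import pool_rubin

        mu, sd, n, rate = 50.0, 10.0, 150, 0.25
        covered = 0
        n_reps = 200
        root = np.random.SeedSequence(20)
        for child in root.spawn(n_reps):
            rng = np.random.default_rng(child)
            y = rng.normal(mu, sd, n)
            aux = 0.6 * y + rng.normal(0, sd, n)
            df = pd.DataFrame({"y": y, "aux": aux, "country": "A"})
            df.loc[rng.random(n) < rate, "y"] = np.nan
            cfg = ImputationConfig(
                m=5, maxit=3, seed=int(child.generate_state(1)[0] % 2**31),
                predictors=("aux",), passive=False,
            )
            res = chained_impute(df, cfg)
            means = [res.complete(i)["y"].mean() for i in range(5)]
            variances = [res.complete(i)["y"].var(ddof=1) / n for i in range(5)]
            est = pool_rubin(means, variances, df_com=n - 1)
            half = sps.t.ppf(0.975, est.df) * est.se
            covered += est.qbar - half <= mu <= est.qbar + half
        assert 0.90 <= covered / n_reps <= 1.0


class TestPassiveDerivation:
    def test_bmi_arithmetic(self):
        df = pd.DataFrame({"height_m": [1.60], "weight_kg": [51.2]})
        out = passive_derive(df)
        assert out["bmi"].iloc[0] == pytest.approx(20.0)

    def test_zero_items_zero_totals(self):
        df = pd.DataFrame(
            {c: [0] for c in scoring.MMAPP_ITEMS + scoring.DERS_ITEMS + scoring.DBIS_ITEMS}
        )
        out = passive_derive(df)
        assert out["mmapp_total"].iloc[0] == 0
        assert out["dbis"].iloc[0] == 0
        assert out["ders"].iloc[0] == 12  # reverse-coded floor

    def test_derived_columns_consistent_with_constituents(self, imputed_small):
        comp = imputed_small.complete(0)
        audit = scoring.score_items_table(comp)
        for c in audit.columns:
            np.testing.assert_allclose(comp[c], audit[c])
        np.testing.assert_allclose(
            comp["bmi"], comp["weight_kg"] / comp["height_m"] ** 2
        )

    def test_nonpositive_height_flagged(self):
        df = pd.DataFrame({"height_m": [0.0], "weight_kg": [50.0]})
        out = passive_derive(df)
        assert out["_invalid_height"].iloc[0]


class TestOrdinalEngineAgainstReference:
    def test_fit_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(3)
        n, p = 400, 5
        X = rng.normal(size=(n, p))
        z = 0.8 * X[:, 0] - 0.5 * X[:, 2] + rng.logistic(size=n)
        y = np.digitize(z, [-1.0, 0.3, 1.4])
        params, cov, _ = fit_polr(X, y, 4, ridge=0.0)
        ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        np.testing.assert_allclose(params[:p], ref.params[:p], atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(cov))[:p], ref.bse[:p], atol=1e-4
        )
        probs = predict_probs(params, X[:20], 4)
        np.testing.assert_allclose(probs, ref.predict(exog=X[:20]), atol=1e-4)
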