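"""Harmonization, MANCOVA, stratified permutations, and follow-ups."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainasym import (
    combat_fit_apply,
    default_catalog,
    mancova_wilks,
    run_mega,
    stratified_permutation_test,
    univariate_followup,
)
from brainasym.mega import (
    correlation_screen,
    permutation_p,
    post_harmonization_qc,
    rao_f,
)


def _batch_data(seed=0, n_per=150, p=12, shift=0.0, dx_effect=0.0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    batch = np.repeat(["b1", "b2"], n_per)
    # diagnosis balanced within batch so group contrasts are batch-unconfounded
    dx = np.tile(np.repeat([0.0, 1.0], n_per // 2), 2)
    age = rng.normal(35, 9, n)
    sex = rng.integers(0, 2, n).astype(float)
    X = rng.normal(10, 1, (n, p))
    X[:, 0] += shift * (batch == "b2")
    X += dx_effect * dx[:, None]
    cov = np.column_stack([dx, age, sex])
    return X, batch, cov, dx


class TestComBat:
    def test_no_batch_effect_leaves_data_nearly_unchanged(self):
        X, batch, cov, _ = _batch_data(seed=1)
        adj = combat_fit_apply(X, batch, cov)
        rms = np.sqrt(((adj - X) ** 2).mean(axis=0))
        assert (rms < 0.25).all()  # well below the unit noise floor

    def test_injected_batch_shift_removed(self):
        shift = 10.0
        X, batch, cov, _ = _batch_data(seed=2, shift=shift)
        adj = combat_fit_apply(X, batch, None)
        gap = abs(adj[batch == "b2", 0].mean() - adj[batch == "b1", 0].mean())
        assert gap < 0.02 * shift

    def test_diagnosis_effect_preserved(self):
        effect = 1.0
        X, batch, cov, dx = _batch_data(seed=3, shift=6.0, dx_effect=effect)
        adj = combat_fit_apply(X, batch, cov)
        diff = adj[dx == 1].mean(axis=0) - adj[dx == 0].mean(axis=0)
        raw_diff = X[dx == 1].mean(axis=0) - X[dx == 0].mean(axis=0)
        np.testing.assert_allclose(diff, raw_diff, atol=0.05 * effect)

    def test_reapplication_is_a_strong_contraction(self):
        """Re-harmonizing changes almost nothing relative to the first pass.

        Empirical-Bayes shrinkage leaves a small residual batch offset, so
        exact idempotence is not a property of parametric ComBat (the
        Bioconductor reference behaves identically, ~5e-4 relative change
        on re-application); the second pass must be orders of magnitude
        smaller than the first and below 1e-3 relative RMS.
        """
        X, batch, cov, _ = _batch_data(seed=4, shift=5.0)
        once = combat_fit_apply(X, batch, cov)
        twice = combat_fit_apply(once, batch, cov)
        scale = np.sqrt((once**2).mean())
        first_change = np.sqrt(((once - X) ** 2).mean()) / scale
        second_change = np.sqrt(((twice - once) ** 2).mean()) / scale
        assert second_change < 1e-3
        assert second_change < first_change / 50

    def test_rejects_singleton_batch_and_zero_variance(self):
        X, batch, cov, _ = _batch_data(seed=5, n_per=10)
        bad_batch = batch.copy()
        bad_batch[0] = "lonely"
        with pytest.raises(ValueError, match="singleton"):
            combat_fit_apply(X, bad_batch, cov)
        Xz = X.copy()
        Xz[batch == "b1", 2] = 7.0
        with pytest.raises(ValueError, match="variance"):
            combat_fit_apply(Xz, batch, None)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_sva_combat(self, tmp_path):
        """Independent cross-check against the Bioconductor ComBat."""
        X, batch, cov, _ = _batch_data(seed=6, n_per=60, p=6, shift=4.0)
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        np.savetxt(tmp_path / "cov.csv", cov, delimiter=",")
        pd.Series(batch).to_csv(tmp_path / "batch.csv", index=False, header=False)
        script = tmp_path / "combat.R"
        script.write_text(
            "suppressMessages(library(sva))\n"
            f"x <- t(as.matrix(read.csv('{tmp_path}/x.csv', header=FALSE)))\n"
            f"batch <- scan('{tmp_path}/batch.csv', what='character', quiet=TRUE)\n"
            f"cov <- as.matrix(read.csv('{tmp_path}/cov.csv', header=FALSE))\n"
            "mod <- model.matrix(~cov)\n"
            "adj <- ComBat(dat=x, batch=batch, mod=mod, par.prior=TRUE)\n"
            f"write.table(t(adj), '{tmp_path}/adj.csv', sep=',', "
            "row.names=FALSE, col.names=FALSE)\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.loadtxt(tmp_path / "adj.csv", delimiter=",")
        adj = combat_fit_apply(X, batch, cov)
        np.testing.assert_allclose(adj, ref, rtol=1e-4, atol=1e-6)


class TestQCAndScreen:
    def test_all_positive_data_keeps_everyone(self):
        rng = np.random.default_rng(7)
        L = pd.DataFrame(rng.uniform(1, 2, (20, 3)), columns=["a", "b", "vol_x"])
        R = pd.DataFrame(rng.uniform(1, 2, (20, 3)), columns=["a", "b", "vol_x"])
        assert len(post_harmonization_qc(L, R, ["vol_x"])) == 20

    def test_negative_adjusted_volume_drops_exactly_one(self):
        rng = np.random.default_rng(8)
        L = pd.DataFrame(rng.uniform(1, 2, (20, 2)), columns=["a", "vol_x"])
        R = L.copy()
        R.loc[4, "vol_x"] = -0.5
        keep = post_harmonization_qc(L, R, ["vol_x"])
        assert len(keep) == 19 and 4 not in keep

    def test_incomplete_individual_dropped(self):
        rng = np.random.default_rng(9)
        L = pd.DataFrame(rng.uniform(1, 2, (10, 2)), columns=["a", "b"])
        R = L.copy()
        L.loc[2, "a"] = np.nan
        keep = post_harmonization_qc(L, R, [])
        assert len(keep) == 9 and 2 not in keep

    def test_correlation_screen(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(2000, 5)), columns=list("abcde"))
        max_r, corr = correlation_screen(df)
        assert max_r < 0.1
        shared = rng.normal(size=2000)
        df2 = pd.DataFrame(
            {
                "x": np.sqrt(0.4) * shared + np.sqrt(0.6) * rng.normal(size=2000),
                "y": np.sqrt(0.4) * shared + np.sqrt(0.6) * rng.normal(size=2000),
            }
        )
        max_r2, _ = correlation_screen(df2)
        assert max_r2 == pytest.approx(0.4, abs=0.05)
        dup = pd.concat([df, df["a"].rename("a2")], axis=1)
        max_r3, _ = correlation_screen(dup)
        assert max_r3 == pytest.approx(1.0, abs=1e-12)


class TestWilksRao:
    def test_reported_configuration_reproduced(self):
        """Lambda 0.932, 76 AIs, N=2,029, design rank 4 -> F(76,1950)=1.87."""
        F, df1, df2, p = rao_f(0.932, p=76, N=2029, design_rank=4)
        assert (df1, df2) == (76, 1950)
        assert round(F, 2) == 1.87
        assert round((1 - 0.932) * 100) == 7  # percent variance explained

    def test_null_lambda_near_one(self):
        rng = np.random.default_rng(11)
        n, p = 800, 10
        Y = pd.DataFrame(rng.normal(size=(n, p)))
        res = mancova_wilks(
            Y, rng.integers(0, 2, n), rng.normal(35, 8, n), rng.integers(0, 2, n)
        )
        assert res.Lambda > 0.95
        assert res.F == pytest.approx(1.0, abs=0.6)

    def test_single_response_reduces_to_univariate_ancova(self):
        rng = np.random.default_rng(12)
        n = 300
        dx = rng.integers(0, 2, n).astype(float)
        age = rng.normal(35, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        Y = pd.DataFrame({"y": rng.normal(size=n) + 0.3 * dx + 0.01 * age})
        res = mancova_wilks(Y, dx, age, sex)
        uni = univariate_followup(Y, dx, age, sex)
        assert res.F == pytest.approx(uni["F"].iloc[0], rel=1e-10)
        assert res.p_nominal == pytest.approx(uni["p"].iloc[0], rel=1e-8)

    def test_det_ratio_equals_rank_one_eigenvalue_form(self):
        rng = np.random.default_rng(13)
        n, p = 400, 8
        Y = rng.normal(size=(n, p))
        dx = rng.integers(0, 2, n).astype(float)
        age = rng.normal(35, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        res = mancova_wilks(pd.DataFrame(Y), dx, age, sex)
        Z = np.column_stack([np.ones(n), age, sex])
        Yt = Y - Z @ np.linalg.lstsq(Z, Y, rcond=None)[0]
        dt = dx - Z @ np.linalg.lstsq(Z, dx, rcond=None)[0]
        h = Yt.T @ dt
        T = Yt.T @ Yt
        E = T - np.outer(h, h) / (dt @ dt)
        lam_eig = np.linalg.eigvals(np.linalg.solve(E, np.outer(h, h) / (dt @ dt)))
        assert res.Lambda == pytest.approx(1.0 / (1.0 + lam_eig.real.max()), rel=1e-9)

    def test_rank_deficient_responses_rejected_with_names(self):
        rng = np.random.default_rng(14)
        n = 200
        a = rng.normal(size=n)
        Y = pd.DataFrame({"a": a, "b": rng.normal(size=n), "dup": a})
        with pytest.raises(ValueError, match="dup"):
            mancova_wilks(
                Y, rng.integers(0, 2, n), rng.normal(35, 8, n), rng.integers(0, 2, n)
            )


class TestStratifiedPermutation:
    def test_permutation_p_arithmetic(self):
        assert permutation_p(3, 1_000_000) == 3.0e-6
        assert permutation_p(0, 100) == 0.0
        with pytest.raises(ValueError):
            permutation_p(5, 4)
        with pytest.raises(ValueError):
            permutation_p(1, 0)

    @staticmethod
    def _small_problem(seed=15, n_per_stratum=60, n_strata=4, p=6, effect=0.0):
        rng = np.random.default_rng(seed)
        n = n_per_stratum * n_strata
        strata = np.repeat([f"s{i}" for i in range(n_strata)], n_per_stratum)
        dx = np.tile(np.repeat([0.0, 1.0], n_per_stratum // 2), n_strata)
        age = rng.normal(35, 8, n)
        sex = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(size=(n, p)) + effect * dx[:, None]
        return pd.DataFrame(Y), dx, age, sex, strata

    def test_counts_preserved_within_every_stratum(self):
        from brainasym.mega import _perm_rng

        Y, dx, age, sex, strata = self._small_problem()
        groups = {g: np.flatnonzero(strata == g) for g in np.unique(strata)}
        for j in range(50):
            rng = _perm_rng(seed=3, index=j)
            lab = dx.copy()
            for idx in groups.values():
                lab[idx] = lab[idx][rng.permutation(len(idx))]
            for idx in groups.values():
                assert lab[idx].sum() == dx[idx].sum()

    def test_deterministic_given_seed_and_invariant_to_chunking(self):
        Y, dx, age, sex, strata = self._small_problem(effect=0.3)
        a = stratified_permutation_test(Y, dx, age, sex, strata, n_perm=300, seed=7, chunk_size=64)
        b = stratified_permutation_test(Y, dx, age, sex, strata, n_perm=300, seed=7, chunk_size=300)
        assert a.p_perm == b.p_perm and a.n_exceed == b.n_exceed
        c = stratified_permutation_test(Y, dx, age, sex, strata, n_perm=300, seed=8)
        assert a.seed == 7 and c.seed == 8

    def test_ordering_invariance_of_permutation_p(self):
        Y, dx, age, sex, strata = self._small_problem(effect=0.25)
        a = stratified_permutation_test(Y, dx, age, sex, strata, n_perm=200, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dx))
        b = stratified_permutation_test(
            Y.iloc[perm].reset_index(drop=True), dx[perm], age[perm], sex[perm],
            strata[perm], n_perm=200, seed=5,
        )
        # same strata contents => same null distribution; p within Monte Carlo noise
        assert abs(a.p_perm - b.p_perm) <= 0.05
        assert a.F == pytest.approx(b.F, rel=1e-9)

    def test_strong_effect_gives_small_p_and_consistency(self):
        Y, dx, age, sex, strata = self._small_problem(effect=0.5)
        res = stratified_permutation_test(Y, dx, age, sex, strata, n_perm=500, seed=1)
        assert res.p_perm == permutation_p(res.n_exceed, res.n_perm)
        assert res.p_perm < 0.05
        assert res.p_nominal < 1e-6

    def test_single_class_stratum_is_noop(self):
        Y, dx, age, sex, strata = self._small_problem(effect=0.4)
        dx2 = dx.copy()
        dx2[strata == "s0"] = 1.0  # case-only stratum: labels fixed
        res = stratified_permutation_test(Y, dx2, age, sex, strata, n_perm=100, seed=2)
        assert res.n_perm == 100


class TestUnivariateFollowup:
    def test_injected_effect_ranks_first(self):
        rng = np.random.default_rng(16)
        n, p = 600, 10
        dx = rng.integers(0, 2, n).astype(float)
        Y = rng.normal(size=(n, p))
        Y[:, 3] += 0.5 * dx
        cols = [f"ai{i}" for i in range(p)]
        out = univariate_followup(
            pd.DataFrame(Y, columns=cols), dx, rng.normal(35, 8, n), rng.integers(0, 2, n)
        )
        assert out["measure_id"].iloc[0] == "ai3"
        assert (out["p"].diff().dropna() >= 0).all()  # ranked by p

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(17)
        n, p = 500, 30
        out = univariate_followup(
            pd.DataFrame(rng.normal(size=(n, p))),
            rng.integers(0, 2, n),
            rng.normal(35, 8, n),
            rng.integers(0, 2, n),
        )
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01


def test_run_mega_end_to_end_structure(null_cohort):
    table, _ = null_cohort
    res = run_mega(table, default_catalog(), n_perm=200, seed=9)
    rep = res["mancova"]
    assert rep["df1"] == 76
    assert rep["df2"] == rep["n_individuals"] - 4 - 76 + 1
    assert 0 < rep["lambda"] <= 1
    assert rep["p_perm"] == rep["n_exceed"] / rep["n_perm"]
    assert rep["variance_explained"] == pytest.approx(1 - rep["lambda"], abs=1e-12)
    assert len(res["univariate"]) == 76
    assert rep["max_abs_pairwise_ai_correlation"] < 0.5
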