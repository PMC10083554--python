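"""REML pooling, FDR, meta-regression, and outlier sensitivity."""

import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brainasym import (
    bh_fdr,
    meta_analyze_sites,
    meta_regress,
    outlier_sensitivity,
    pool_correlations,
    reml_pool,
    z_to_p_two_sided,
)


def _restricted_loglik_intercept(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2))


def _grid_search_tau2(y, v, n_grid=4000):
    grid = np.linspace(0.0, 10.0 * v.max(), n_grid)
    ll = [_restricted_loglik_intercept(t, y, v) for t in grid]
    return grid[int(np.argmax(ll))], grid[1] - grid[0]


class TestRemlPool:
    def test_single_study(self):
        res = reml_pool([0.3], [0.1])
        assert res.d == 0.3 and res.se == 0.1 and res.tau2 == 0.0 and res.k == 1

    def test_no_heterogeneity_when_effects_identical(self):
        res = reml_pool([0.2] * 6, [0.1, 0.2, 0.15, 0.12, 0.3, 0.08])
        assert res.tau2 == pytest.approx(0.0, abs=1e-10)
        assert res.d == pytest.approx(0.2, abs=1e-12)
        assert res.I2 == 0.0

    def test_tau2_matches_restricted_likelihood_grid_search(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            k = 10
            se = rng.uniform(0.05, 0.3, k)
            tau = rng.uniform(0.0, 0.3)
            y = rng.normal(0.1, np.sqrt(se**2 + tau**2))
            res = reml_pool(y, se)
            t_grid, step = _grid_search_tau2(y, se**2)
            assert abs(res.tau2 - t_grid) <= step

    def test_zero_tau2_recovers_fixed_effect_estimate(self):
        y = np.array([0.11, 0.09, 0.1, 0.105])
        se = np.array([0.05, 0.04, 0.06, 0.05])
        res = reml_pool(y, se)
        if res.tau2 == 0.0:
            w = 1.0 / se**2
            assert res.d == pytest.approx(np.sum(w * y) / np.sum(w), abs=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        y, se = rng.normal(0, 0.3, 12), rng.uniform(0.05, 0.2, 12)
        a = reml_pool(y, se)
        perm = rng.permutation(12)
        b = reml_pool(y[perm], se[perm])
        assert a.d == pytest.approx(b.d, abs=1e-12)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            reml_pool([], [])
        with pytest.raises(ValueError):
            reml_pool([0.1, np.nan], [0.1, 0.1])
        with pytest.raises(ValueError):
            reml_pool([0.1, 0.2], [0.1, 0.0])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_metafor_rma(self, tmp_path):
        """Independent cross-check against the metafor REML implementation."""
        rng = np.random.default_rng(12)
        k = 12
        se = rng.uniform(0.08, 0.25, k)
        y = rng.normal(-0.08, np.sqrt(se**2 + 0.02))
        res = reml_pool(y, se)
        script = tmp_path / "rma.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"yi <- c({', '.join(map(repr, y.tolist()))})\n"
            f"sei <- c({', '.join(map(repr, se.tolist()))})\n"
            "m <- rma(yi=yi, sei=sei, method='REML')\n"
            "cat(sprintf('%.10f %.10f %.10f %.10f', m$beta[1], m$se, m$tau2, m$pval))\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        mu_r, se_r, tau2_r, p_r = map(float, out.stdout.split())
        # metafor's Fisher scoring stops at a 1e-5 threshold; compare at that level
        assert res.d == pytest.approx(mu_r, abs=1e-5)
        assert res.se == pytest.approx(se_r, abs=1e-5)
        assert res.tau2 == pytest.approx(tau2_r, abs=1e-5)
        assert res.p == pytest.approx(p_r, rel=1e-3)


class TestZtoP:
    @pytest.mark.parametrize(
        "z, printed",
        [(-3.21, 1.3e-3), (-2.99, 2.8e-3), (-1.92, 0.055), (1.23, 0.22)],
    )
    def test_two_sided_p_reproduces_reported_values(self, z, printed):
        p = z_to_p_two_sided(z)
        assert float(f"{p:.2g}") == pytest.approx(printed, rel=1e-9)

    def test_z_zero_gives_one(self):
        assert z_to_p_two_sided(0.0) == 1.0


def _bh_brute_force(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[i] = min(m * sorted_p[j] / (j + 1) for j in range(i, m))
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


class TestBHFDR:
    def test_all_equal_p_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.03] * 7), 0.03)

    def test_hand_example_family_of_eight(self):
        p = [0.001] + [0.5] * 7
        q = bh_fdr(p)
        assert q[0] == pytest.approx(0.008, abs=1e-12)
        np.testing.assert_allclose(q[1:], 0.5)

    @given(st.lists(st.floats(min_value=1e-10, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_fdr(p), _bh_brute_force(p), rtol=1e-12, atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestMetaRegress:
    def test_null_moderator_calibrated(self):
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(100):
            se = rng.uniform(0.05, 0.2, 45)
            y = rng.normal(0, se)
            mod = rng.choice(["a", "b", "c"], 45)
            pvals.append(meta_regress(y, se, mod)["p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constructed_moderator_signal_detected(self):
        rng = np.random.default_rng(14)
        se = np.full(40, 0.01)
        mod = np.repeat(["lo", "hi"], 20)
        y = rng.normal(0, se) + np.where(mod == "hi", 0.2, 0.0)
        res = meta_regress(y, se, mod)
        assert res["p"] < 1e-10

    def test_single_level_moderator_skipped(self):
        res = meta_regress([0.1, 0.2, 0.15], [0.1, 0.1, 0.1], ["x", "x", "x"])
        assert res is None


class TestOutlierSensitivity:
    def test_homogeneous_effects_rarely_flagged(self):
        rng = np.random.default_rng(15)
        n_flagged = 0
        for _ in range(40):
            se = rng.uniform(0.08, 0.2, 15)
            df = pd.DataFrame(
                {"dataset_id": [f"d{i}" for i in range(15)], "d": rng.normal(0, se), "se_d": se}
            )
            flagged, _, _ = outlier_sensitivity(df)
            n_flagged += len(flagged) > 0
        assert n_flagged <= 8  # >= 80% of runs without any flag

    def test_constructed_outlier_flagged_and_repool_consistent(self):
        rng = np.random.default_rng(16)
        se = np.full(21, 0.05)
        d = rng.normal(0, 0.05, 21)
        d[7] += 1.0
        df = pd.DataFrame(
            {"dataset_id": [f"d{i}" for i in range(21)], "d": d, "se_d": se}
        )
        flagged, repooled, full = outlier_sensitivity(df)
        assert flagged == ["d7"]
        mask = np.arange(21) != 7
        direct = reml_pool(d[mask], se[mask])
        assert repooled.d == pytest.approx(direct.d, abs=1e-12)
        assert repooled.tau2 == pytest.approx(direct.tau2, abs=1e-12)
        assert abs(full.d) > abs(repooled.d)


class TestCorrelationPooling:
    def test_fisher_round_trip(self):
        for r in (-0.9999, -0.5, 0.0, 0.3, 0.97):
            assert np.tanh(np.arctanh(r)) == pytest.approx(r, abs=1e-12)

    def test_pooled_r_recovers_common_correlation(self):
        rng = np.random.default_rng(17)
        rs, ns = [], []
        for _ in range(25):
            n = 150
            x = rng.normal(size=n)
            y = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(size=n)
            rs.append(np.corrcoef(x, y)[0, 1])
            ns.append(n)
        res = pool_correlations(rs, ns)
        assert res.d == pytest.approx(0.3, abs=0.03)
        assert abs(res.d) < 1


def test_meta_analyze_sites_family_fdr(null_ai):
    from brainasym import fit_all_sites

    measures = null_ai.family_members("subcortical")
    s = fit_all_sites(null_ai.data, measures, "m1")
    m = meta_analyze_sites(s, null_ai.families)
    assert len(m) == 8
    assert (m["q"] >= m["p"] - 1e-15).all()
    # q matches a direct BH pass over the 8-member family
    np.testing.assert_allclose(
        np.sort(m["q"]), np.sort(bh_fdr(m["p"].to_numpy())), rtol=1e-12
    )
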