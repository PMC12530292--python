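import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import trophitv as tv
from trophitv.paths import (
    basis_set,
    effect_decomposition,
    fishers_c,
    fit_lmm,
    fit_path_model,
    initial_path_spec,
    prune_correlated,
    r2_mixed,
    select_model,
    standardized_estimates,
    vif_prune,
    vif_scores,
)


def correlated_pair(rng, n, r):
    """Two columns with exact sample correlation r."""
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=0)
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)
    z /= z.std(ddof=0)
    return x, r * x + np.sqrt(1 - r**2) * z


class TestPruneCorrelated:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        assert sorted(prune_correlated(df)) == ["a", "c"]

    def test_r_069_pair_both_retained(self):
        rng = np.random.default_rng(1)
        a, b = correlated_pair(rng, 200, 0.69)
        df = pd.DataFrame({"a": a, "b": b})
        assert sorted(prune_correlated(df)) == ["a", "b"]

    def test_planted_r09_pair_drops_cv_member(self):
        rng = np.random.default_rng(2)
        a, b = correlated_pair(rng, 200, 0.9)
        df = pd.DataFrame({"MeanX": a, "cv-MeanX": b, "other": rng.standard_normal(200)})
        kept = prune_correlated(df)
        assert "MeanX" in kept and "cv-MeanX" not in kept


class TestVIF:
    def test_orthogonal_predictors_all_kept(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        scores = vif_scores(df, list("abc"))
        assert (scores < 1.3).all()
        assert vif_prune(df, list("abc")) == list("abc")

    def test_r09_pair_closed_form_and_dropped(self):
        rng = np.random.default_rng(4)
        a, b = correlated_pair(rng, 500, 0.9)
        df = pd.DataFrame({"a": a, "b": b})
        scores = vif_scores(df, ["a", "b"])
        assert scores["a"] == pytest.approx(1 / (1 - 0.81), abs=1e-6)
        assert len(vif_prune(df, ["a", "b"])) == 1

    def test_r08_pair_both_kept(self):
        rng = np.random.default_rng(5)
        a, b = correlated_pair(rng, 500, 0.8)
        df = pd.DataFrame({"a": a, "b": b})
        assert vif_scores(df, ["a", "b"])["a"] == pytest.approx(1 / (1 - 0.64), abs=1e-6)
        assert vif_prune(df, ["a", "b"]) == ["a", "b"]


def lmm_frame(rng, n_sites=10, n_obs=30, slope=2.0, sd_site=1.0, sd_e=0.5):
    site = np.repeat(np.arange(n_sites), n_obs)
    x = rng.standard_normal(n_sites * n_obs)
    u = rng.normal(0, sd_site, n_sites)
    y = slope * x + u[site] + rng.normal(0, sd_e, len(x))
    return pd.DataFrame(
        {
            "campaign_id": [f"c{s}_{i}" for s, i in zip(site, range(len(site)))],
            "site": [f"s{s}" for s in site],
            "year": ["y1" if s % 2 else "y2" for s in site],
            "x": x,
            "y": y,
        }
    )


class TestFitLMM:
    def test_zero_random_variance_matches_ols(self):
        rng = np.random.default_rng(6)
        data = lmm_frame(rng, sd_site=0.0)
        # pin the empirical group means to zero so the REML optimum is
        # exactly on the zero-variance boundary
        resid = data["y"] - 2 * data["x"]
        for col in ("site", "year"):
            resid = resid - resid.groupby(data[col]).transform("mean")
        data["y"] = 2 * data["x"] + resid
        fit = fit_lmm(data, "y", ["x"])
        import statsmodels.api as sm

        ols = sm.OLS(data["y"], sm.add_constant(data["x"])).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(7)
        data = lmm_frame(rng).assign(k=1.0)
        with pytest.raises(ValueError, match="constant"):
            fit_lmm(data, "y", ["k"])

    def test_slope_ci_coverage_under_simulation(self):
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            data = lmm_frame(rng)
            fit = fit_lmm(data, "y", ["x"], group_cols=("site",))
            lo = fit.params["x"] - 1.96 * fit.bse["x"]
            hi = fit.params["x"] + 1.96 * fit.bse["x"]
            hits += lo <= 2.0 <= hi
        assert hits >= int(0.87 * n_rep)

    def test_recovers_variance_components(self):
        rng = np.random.default_rng(9)
        data = lmm_frame(rng, n_sites=30, n_obs=40)
        fit = fit_lmm(data, "y", ["x"], group_cols=("site",))
        assert fit.vcomp["site"] == pytest.approx(1.0, abs=0.5)
        assert fit.scale == pytest.approx(0.25, abs=0.1)


class TestStandardizedEstimates:
    def test_prezscored_data_equals_raw(self):
        rng = np.random.default_rng(10)
        data = lmm_frame(rng)
        for c in ("x", "y"):
            data[c] = (data[c] - data[c].mean()) / data[c].std(ddof=1)
        fit = fit_lmm(data, "y", ["x"])
        std = standardized_estimates(fit)
        assert std["x"] == pytest.approx(fit.params["x"], abs=1e-10)

    def test_invariant_to_predictor_rescaling(self):
        rng = np.random.default_rng(11)
        data = lmm_frame(rng)
        fit1 = fit_lmm(data, "y", ["x"])
        fit2 = fit_lmm(data.assign(x=data["x"] * 10), "y", ["x"])
        assert fit2.params["x"] == pytest.approx(fit1.params["x"] / 10, rel=1e-4)
        assert standardized_estimates(fit2)["x"] == pytest.approx(
            standardized_estimates(fit1)["x"], rel=1e-4
        )

    def test_matches_refit_on_zscored_data(self):
        rng = np.random.default_rng(12)
        data = lmm_frame(rng, sd_site=0.0)
        # pin empirical group means to zero so both fits take the exact
        # (boundary) solution and the equivariance is exact, not numerical
        resid = data["y"] - 2 * data["x"]
        for col in ("site", "year"):
            resid = resid - resid.groupby(data[col]).transform("mean")
        data["y"] = 2 * data["x"] + resid
        fit = fit_lmm(data, "y", ["x"])
        z = data.copy()
        for c in ("x", "y"):
            z[c] = (z[c] - z[c].mean()) / z[c].std(ddof=1)
        zfit = fit_lmm(z, "y", ["x"])
        assert standardized_estimates(fit)["x"] == pytest.approx(
            zfit.params["x"], abs=1e-5
        )


class TestBasisSet:
    def test_chain_gives_single_claim(self):
        g = nx.DiGraph([("X", "Y"), ("Y", "Z")])
        assert basis_set(g) == [("X", "Z", ("Y",))]

    def test_complete_dag_is_saturated(self):
        g = nx.DiGraph([("A", "B"), ("A", "C"), ("B", "C")])
        assert basis_set(g) == []
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_cyclic_graph_rejected(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        with pytest.raises(ValueError, match="cyclic"):
            basis_set(g)

    def test_matches_brute_force_adjacency_scan(self):
        # two habitat variables: H1 -> P -> T, H1 -> T, H2 isolated from P
        g = nx.DiGraph([("H1", "P"), ("P", "T"), ("H1", "T"), ("H2", "T")])
        claims = basis_set(g)
        expected_pairs = set()
        for a, b in itertools.combinations(sorted(g.nodes), 2):
            if not (g.has_edge(a, b) or g.has_edge(b, a)):
                expected_pairs.add(frozenset((a, b)))
        assert {frozenset((x, y)) for x, y, _ in claims} == expected_pairs
        by_pair = {frozenset((x, y)): (x, y, set(c)) for x, y, c in claims}
        # H2 vs P: P is downstream of nothing shared; union of parents = {H1}
        assert by_pair[frozenset(("H2", "P"))][2] == {"H1"}
        # correlated links count as adjacency
        assert basis_set(g, {frozenset(("H2", "P")), frozenset(("H1", "H2"))}) == []


class TestFishersC:
    def test_all_ones_gives_zero(self):
        c, df, p = fishers_c([1.0, 1.0, 1.0])
        assert (c, df, p) == (0.0, 6, 1.0)

    def test_closed_form(self):
        c, df, p = fishers_c([0.05, 0.05])
        assert c == pytest.approx(-4 * np.log(0.05), abs=1e-9)
        assert c == pytest.approx(11.983, abs=1e-3)
        assert df == 4
        assert p == pytest.approx(0.0175, abs=1e-4)

    def test_zero_pvalue_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])


class TestSelectModel:
    def test_strong_paths_all_survive_selection(self):
        data, _ = tv.simulate_path_data(
            seed=21, n_campaigns=40, n_individuals=30, direct=0.4, b=0.6, c=0.4
        )
        spec = initial_path_spec(["H1"], ["P1"], ["S1"], "T")
        model = select_model(data, spec)
        assert set(model.spec.edges) == set(spec.edges)

    def test_noise_predictor_removed(self):
        removed = 0
        n_rep = 20
        for s in range(n_rep):
            data, _ = tv.simulate_path_data(
                seed=500 + s, n_campaigns=40, n_individuals=15, n_noise_habitat=1
            )
            spec = initial_path_spec(["H1", "H2"], ["P1"], ["S1"], "T")
            model = select_model(data, spec)
            removed += ("H2", "T") not in model.spec.edges
        assert removed >= int(0.8 * n_rep)

    def test_selection_is_idempotent(self):
        data, _ = tv.simulate_path_data(seed=23, n_campaigns=40, n_individuals=15)
        spec = initial_path_spec(["H1"], ["P1"], ["S1"], "T")
        model1 = select_model(data, spec)
        model2 = select_model(data, model1.spec)
        assert model1.spec.edges == model2.spec.edges
        assert model1.spec.correlated == model2.spec.correlated
        pd.testing.assert_frame_equal(model1.edges, model2.edges)


class TestEffectDecomposition:
    def test_single_mediated_chain(self):
        data, truth = tv.simulate_path_data(
            seed=24, n_campaigns=200, n_individuals=10, direct=0.0, b=0.5, c=0.4
        )
        spec = initial_path_spec(["H1"], ["P1"], ["S1"], "T")
        spec.edges.discard(("H1", "T"))
        model = fit_path_model(data, spec)
        eff = effect_decomposition(model).set_index("habitat")
        assert eff.loc["H1", "direct"] == 0.0
        assert eff.loc["H1", "indirect"] == pytest.approx(truth["indirect"], abs=0.07)

    def test_matches_brute_force_path_enumeration(self):
        data, _ = tv.simulate_path_data(seed=25, n_campaigns=60, n_individuals=10)
        spec = initial_path_spec(["H1"], ["P1"], ["S1"], "T")
        model = fit_path_model(data, spec)
        g = nx.DiGraph()
        for _, e in model.edges.iterrows():
            g.add_edge(e["predictor"], e["response"], w=e["std_estimate"])
        eff = effect_decomposition(model).set_index("habitat")
        for h in model.spec.habitat:
            total = 0.0
            direct = 0.0
            for path in nx.all_simple_paths(g, h, model.spec.trait):
                w = np.prod([g[u][v]["w"] for u, v in zip(path, path[1:])])
                total += w
                if len(path) == 2:
                    direct = w
            assert eff.loc[h, "direct"] == pytest.approx(direct, abs=1e-12)
            assert eff.loc[h, "total"] == pytest.approx(total, abs=1e-12)


class TestR2Mixed:
    def test_zero_random_variance_marginal_equals_conditional(self):
        rng = np.random.default_rng(26)
        data = lmm_frame(rng, sd_site=0.0)
        fit = fit_lmm(data, "y", ["x"])
        rm, rc = r2_mixed(fit)
        assert rc == pytest.approx(rm, abs=0.02)

    def test_variance_budget_simulation(self):
        # planted variances: fixed 1, site 1, residual 2 -> R2m 0.25, R2c 0.5
        rng = np.random.default_rng(27)
        n_sites, n_obs = 40, 50
        site = np.repeat(np.arange(n_sites), n_obs)
        x = rng.standard_normal(len(site))
        y = x + rng.normal(0, 1, n_sites)[site] + rng.normal(0, np.sqrt(2), len(site))
        data = pd.DataFrame(
            {
                "campaign_id": np.arange(len(site)),
                "site": [f"s{s}" for s in site],
                "year": ["y1"] * len(site),
                "x": x,
                "y": y,
            }
        )
        fit = fit_lmm(data, "y", ["x"], group_cols=("site",))
        rm, rc = r2_mixed(fit)
        assert rm == pytest.approx(0.25, abs=0.05)
        assert rc == pytest.approx(0.50, abs=0.05)
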