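import itertools

import numpy as np
import pandas as pd
import pytest

from herdlevels.network import SnapshotGroups, UnitNetwork, unit_sri
from herdlevels.permutation import (datastream_permute, sd_test, edge_weight_sd,
                                    DyadicDesign, mrqap_dsp, MRQAPRegressor,
                                    NodalDesign, nodal_dsp, NodalDSPRegressor,
                                    build_dyadic_design, build_nodal_design)


def groups_fixture():
    units = ["A", "B", "C", "D"]
    strata = [
        ("P1", "Z1", [frozenset({"A", "B"}), frozenset({"C", "D"})]),
        ("P2", "Z1", [frozenset({"A", "C"}), frozenset({"B", "D"})]),
        ("P3", "Z1", [frozenset({"A", "B", "C"}), frozenset({"D"})]),
    ]
    presence = {p: frozenset(units) for p in ("P1", "P2", "P3")}
    return SnapshotGroups(units=units, strata=strata, presence=presence)


def sym(rng, n):
    m = rng.normal(size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestDatastream:
    def test_degenerate_grouping_raises(self):
        sg = SnapshotGroups(units=["A", "B"],
                            strata=[("P1", "Z1", [frozenset({"A", "B"})])],
                            presence={"P1": frozenset({"A", "B"})})
        with pytest.raises(ValueError, match="degenerate"):
            datastream_permute(sg, n_perm=10, seed=0)

    def test_conservation_laws_every_replicate(self):
        sg = groups_fixture()
        observed = unit_sri(sg)
        nets = datastream_permute(sg, n_perm=200, seed=0, burn_in=50,
                                  return_networks=True)
        base_counts = {(p, z): len(gs) for p, z, gs in sg.strata}
        for net in nets[::20]:
            np.testing.assert_array_equal(net.either_counts,
                                          observed.either_counts)
        # group counts per stratum conserved inside the chain
        nulls = datastream_permute(sg, n_perm=50, seed=1, burn_in=0)
        assert len(nulls) == 50
        for m in nulls:
            assert m.shape == observed.sri.shape
            assert np.allclose(m, m.T)
        assert all(len(gs) == base_counts[(p, z)] for p, z, gs in sg.strata)

    def test_together_counts_stay_consistent_with_groups(self):
        # after many swaps, the incrementally maintained network must equal
        # a from-scratch recount of the final grouping
        sg = groups_fixture()
        nets, final_groups = datastream_permute(
            sg, n_perm=137, seed=3, burn_in=0, return_networks=True,
            return_final_groups=True)
        rebuilt = unit_sri(final_groups)
        np.testing.assert_array_equal(nets[-1].together_counts,
                                      rebuilt.together_counts)
        # per-stratum group counts conserved by the whole chain
        for (p, z, gs), (_, _, gs0) in zip(final_groups.strata, sg.strata):
            assert len(gs) == len(gs0)

    def test_sd_right_tail_on_herd_data(self, herd_pipeline):
        sg = herd_pipeline["groups"]
        net = herd_pipeline["net"]
        nulls = datastream_permute(sg, n_perm=200, seed=2, burn_in=200)
        res = sd_test(net, nulls)
        assert res.observed > np.median(res.null_values)
        assert res.p <= 0.05

    def test_sd_test_bounds(self):
        rng = np.random.default_rng(0)
        n = 6
        m = np.abs(sym(rng, n))
        either = np.ones((n, n), int)
        obs = UnitNetwork([f"U{i}" for i in range(n)], m,
                          np.zeros((n, n), int), either)
        same = [m.copy() for _ in range(150)]
        assert sd_test(obs, same).p == 1.0
        smaller = [m * 0.01 for _ in range(150)]
        assert sd_test(obs, smaller).p == pytest.approx(1 / 151)


class TestMRQAP:
    def test_exact_copy_predictor_maximally_significant(self):
        rng = np.random.default_rng(0)
        n = 10
        x = sym(rng, n)
        noise = sym(rng, n)
        design = DyadicDesign(response=x.copy(),
                              predictors={"signal": x, "noise": noise})
        res = mrqap_dsp(design, n_perm=500, seed=1)
        assert res.loc["signal", "p(|beta|<=|r|)"] == pytest.approx(1 / 501)
        assert res.loc["signal", "partial_correlation"] > 0.999

    def test_exact_mode_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(1)
        n = 5
        y = sym(rng, n)
        x1, x2 = sym(rng, n), sym(rng, n)
        design = DyadicDesign(response=y, predictors={"x1": x1, "x2": x2})
        res = mrqap_dsp(design, exact=True)

        iu = np.triu_indices(n, 1)
        yv = y[iu]
        others = np.column_stack([np.ones(iu[0].size), x2[iu]])
        q, _ = np.linalg.qr(others)
        e = x1[iu] - q @ (q.T @ x1[iu])
        e_mat = np.zeros((n, n))
        e_mat[iu] = e
        e_mat = e_mat + e_mat.T
        obs = e @ yv / (e @ e)
        stats = []
        for perm in itertools.permutations(range(n)):
            ev = e_mat[np.ix_(perm, perm)][iu]
            r = ev - q @ (q.T @ ev)
            stats.append(r @ yv / (r @ r))
        stats = np.array(stats)
        assert res.loc["x1", "p(beta>=r)"] == pytest.approx(
            np.mean(stats >= obs - 1e-12))
        assert res.loc["x1", "p(|beta|<=|r|)"] == pytest.approx(
            np.mean(np.abs(stats) >= abs(obs) - 1e-12))

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        n = 15
        pvals = []
        for run in range(20):
            y = sym(rng, n)
            design = DyadicDesign(response=y, predictors={
                "a": sym(rng, n), "b": sym(rng, n)})
            res = mrqap_dsp(design, n_perm=1000, seed=100 + run)
            pvals.append(res.loc["a", "p(|beta|<=|r|)"])
        rejections = sum(p <= 0.05 for p in pvals)
        assert rejections <= 3  # binomial(20, 0.05) upper bound
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(2)
        x = sym(rng, 6)
        design = DyadicDesign(response=sym(rng, 6),
                              predictors={"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            mrqap_dsp(design, n_perm=10, seed=0)

    def test_single_predictor_reduces_to_simple_qap(self):
        rng = np.random.default_rng(3)
        n = 6
        y, x = sym(rng, n), sym(rng, n)
        res = mrqap_dsp(DyadicDesign(response=y, predictors={"x": x}),
                        exact=True)
        iu = np.triu_indices(n, 1)
        obs_r = np.corrcoef(y[iu], x[iu])[0, 1]
        rs = []
        for perm in itertools.permutations(range(n)):
            xp = x[np.ix_(perm, perm)]
            rs.append(np.corrcoef(y[iu], xp[iu])[0, 1])
        # coefficient-based and correlation-based enumeration agree in rank
        assert res.loc["x", "p(beta>=r)"] == pytest.approx(
            np.mean(np.asarray(rs) >= obs_r - 1e-12), abs=1e-9)


class TestNodalDSP:
    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(4)
        n = 20
        ind = np.repeat([1.0, -1.0], n // 2)
        noise = rng.normal(0, 1, n)
        y = 5.0 * ind + noise
        X = pd.DataFrame({"indicator": ind, "covariate": rng.normal(size=n)})
        res = nodal_dsp(NodalDesign(response=pd.Series(y), predictors=X),
                        n_perm=1000, seed=0)
        coef, se = res.loc["indicator", ["coefficient", "se"]]
        assert abs(coef - 5.0) < 2 * se
        assert res.loc["indicator", "p(perm)"] < 0.05
        assert np.isnan(res.loc["(Intercept)", "p(perm)"])

    def test_null_covariate_p_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for run in range(20):
            n = 18
            X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
            y = pd.Series(rng.normal(size=n))
            res = nodal_dsp(NodalDesign(response=y, predictors=X),
                            n_perm=1000, seed=run)
            pvals.append(res.loc["a", "p(perm)"])
        assert sum(p <= 0.05 for p in pvals) <= 3
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_ols_matches_hand_computed_four_points(self):
        # y = 1 + 2x fit exactly except symmetric residuals at x = 0, 3
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
        y = pd.Series([2.0, 3.0, 5.0, 6.0])
        est = NodalDSPRegressor(n_perm=50, seed=0).fit(X, y)
        r = est.results_
        # closed form: slope = cov/var = (7/2)/(5/2)? hand values below
        xs = np.array([0, 1, 2, 3.0])
        slope = np.sum((xs - xs.mean()) * (y - y.mean())) / np.sum((xs - xs.mean()) ** 2)
        inter = y.mean() - slope * xs.mean()
        assert r.loc["x", "coefficient"] == pytest.approx(slope)
        assert r.loc["(Intercept)", "coefficient"] == pytest.approx(inter)
        resid = y - (inter + slope * xs)
        s2 = (resid @ resid) / 2
        se_slope = np.sqrt(s2 / np.sum((xs - xs.mean()) ** 2))
        assert r.loc["x", "se"] == pytest.approx(se_slope)
        assert r.loc["x", "t"] == pytest.approx(slope / se_slope)

    def test_rank_deficiency_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(ValueError, match="rank"):
            NodalDSPRegressor(n_perm=10).fit(X, pd.Series([1.0, 2, 3, 4, 5]))


class TestDesignBuilders:
    def test_dyadic_design_shapes_and_values(self, herd_pipeline):
        net = herd_pipeline["net"]
        truth = herd_pipeline["truth"]
        design = build_dyadic_design(net, herd_pipeline["track"],
                                     truth.unit_types, truth.unit_sizes)
        n = len(net.units)
        for name, m in design.predictors.items():
            assert m.shape == (n, n)
        ts = design.predictors["type_similarity"]
        a = net.units.index([u for u in net.units
                             if truth.unit_types[u] == "AMU"][0])
        h = net.units.index([u for u in net.units
                             if truth.unit_types[u] == "harem"][0])
        assert ts[a, h] == 1.0 and ts[a, a] == 0.0
        lo = design.predictors["location_overlap"]
        assert (lo >= 0).all() and (lo <= 1).all()

    def test_nodal_design_models(self, herd_pipeline):
        net = herd_pipeline["net"]
        truth = herd_pipeline["truth"]
        meta = herd_pipeline["table"].meta.set_index("individual_id")
        stallions = {}
        for name, members, _ in herd_pipeline["part"].units:
            sub = meta.loc[sorted(members)]
            stallions[name] = int(((sub["sex"] == "M")
                                   & (sub["age_class"] == "adult")).sum())
        obs = {u: sum(u in p for p in herd_pipeline["groups"].presence.values())
               for u in net.units}
        d_type = build_nodal_design(net, truth.unit_types, truth.unit_sizes,
                                    stallions, obs, model="type")
        assert set(d_type.predictors.columns) == {"harem_vs_amu",
                                                  "observation_no"}
        assert d_type.predictors["observation_no"].mean() == pytest.approx(0.0)
        d_harem = build_nodal_design(net, truth.unit_types, truth.unit_sizes,
                                     stallions, obs, model="harem")
        assert len(d_harem.response) == sum(
            1 for t in truth.unit_types.values() if t == "harem")

    def test_strength_centrality_gradient(self, herd_pipeline):
        # planted periphery: AMU strength below harem mean strength
        net = herd_pipeline["net"]
        types = herd_pipeline["truth"].unit_types
        s = net.strength()
        amu = [s[u] for u in net.units if types[u] == "AMU"]
        harem = [s[u] for u in net.units if types[u] == "harem"]
        assert np.mean(amu) < np.mean(harem)
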