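import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from clineselect import cline_models as cm
from clineselect.io_formats import GenotypeRecord
from clineselect.synthetic_data import ClineScenario, generate_cline_panel


class TestZTransform:
    def test_examples(self):
        assert cm.z_transform([1, 2, 3]) == pytest.approx([-1, 0, 1])
        z = cm.z_transform([5.0, -3.0, 1.2, 0.4])
        assert cm.z_transform(z) == pytest.approx(z, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            cm.z_transform([2.0, 2.0, 2.0])


def _tree_path_lengths(tree, labels):
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return D


class TestTrees:
    def test_three_taxon_exact(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = cm.nj_tree(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_additive_distances_recovered(self):
        # distances generated from a known 5-taxon additive tree
        import dendropy
        newick = "((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);"
        t = dendropy.Tree.get(data=newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        labels = ["A", "B", "C", "D", "E"]
        taxa = {x.label: x for x in t.taxon_namespace}
        D = np.array([[pdm.distance(taxa[a], taxa[b]) for b in labels] for a in labels])
        tree = cm.nj_tree(D, labels)
        assert _tree_path_lengths(tree, labels) == pytest.approx(D, abs=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            cm.nj_tree(np.array([[0, 1], [2, 0]], float), ["A", "B"])

    def test_midpoint_two_leaves(self):
        from skbio import TreeNode
        tree = TreeNode.read(["(A:1.0,B:3.0);"])
        rooted = cm.midpoint_root(tree)
        depths = {t.name: t.distance(rooted.root()) for t in rooted.tips()}
        assert depths == pytest.approx({"A": 2.0, "B": 2.0})


class TestPgls:
    def _star_tree(self, labels):
        n = len(labels)
        d = np.full((n, n), 2.0); np.fill_diagonal(d, 0.0)
        return cm.midpoint_root(cm.nj_tree(d, labels))

    def test_star_tree_equals_ols(self):
        labels = [f"P{i}" for i in range(8)]
        rng = np.random.default_rng(0)
        x = rng.normal(size=8)
        y = 0.3 + 0.5 * x + rng.normal(0, 0.1, 8)
        tree = self._star_tree(labels)
        fit = cm.pgls_fit(y, {"x": x}, tree, labels)
        X = np.column_stack([np.ones(8), cm.z_transform(x)])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)

    def test_gls_closed_form_oracle(self):
        import dendropy
        labels = ["A", "B", "C", "D", "E"]
        newick = "((A:1,B:2):1.5,(C:0.5,D:1):2,E:3);"
        t = dendropy.Tree.get(data=newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        D = np.array([[pdm.distance(taxa[a], taxa[b]) for b in labels] for a in labels])
        tree = cm.midpoint_root(cm.nj_tree(D, labels))
        C = cm.brownian_covariance(tree, labels)
        rng = np.random.default_rng(1)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        fit = cm.pgls_fit(y, {"x": x}, tree, labels, z_predictors=False)
        X = np.column_stack([np.ones(5), x])
        Ci = np.linalg.inv(C)
        beta = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ y)
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-8)

    def test_zero_predictor_leaves_loglik(self):
        labels = [f"P{i}" for i in range(6)]
        tree = self._star_tree(labels)
        rng = np.random.default_rng(2)
        y = rng.normal(size=6)
        f0 = cm.pgls_fit(y, {}, tree, labels)
        f1 = cm.pgls_fit(y, {"zero": np.zeros(6)}, tree, labels, z_predictors=False)
        assert f1.log_likelihood == pytest.approx(f0.log_likelihood, abs=1e-8)
        assert f1.k == f0.k + 1


def _records(scenario_seed=4, **kw):
    sc = ClineScenario(n_pops=kw.pop("n_pops", 12),
                       n_individuals=kw.pop("n_individuals", 25),
                       seed=scenario_seed, **kw)
    return generate_cline_panel(sc)


class TestGlmm:
    def test_single_population_glm_limit(self):
        rng = np.random.default_rng(3)
        recs = [GenotypeRecord(f"i{k}", "P", int(g), 2 - int(g))
                for k, g in enumerate(rng.binomial(2, 0.3, 200))]
        fit = cm.glmm_fit(recs, include_fst=False, sigma_bounds=(-8.0, -8.0))
        pooled = np.mean([r.derived_count for r in recs]) / 2
        assert fit.coefficients["intercept"] == pytest.approx(math.log(pooled / (1 - pooled)), abs=1e-3)

    def test_matches_lme4_reference(self, tmp_path):
        recs, metas = _records(beta_lat=1.0, drift_fst=0.03)
        rng = np.random.default_rng(5)
        fst = {m.name: float(rng.normal(0.1, 0.03)) for m in metas}
        fit = cm.glmm_fit(recs, fixed=("latitude",), fst_to_reference=fst)
        df = pd.DataFrame({
            "id": [r.individual_id for r in recs],
            "pop": [r.population for r in recs],
            "der": [r.derived_count for r in recs],
            "anc": [r.ancestral_count for r in recs],
            "lat": [r.latitude for r in recs],
            "fst": [fst[r.population] for r in recs],
        })
        csv = tmp_path / "glmm.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$zlat <- as.numeric(scale(d$lat)); d$zfst <- as.numeric(scale(d$fst))
            m <- glmer(cbind(der, anc) ~ zfst + zlat + (1|pop) + (1|id),
                       data=d, family=binomial)
            cat(as.numeric(logLik(m)), fixef(m), "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True, text=True)
        vals = [float(v) for v in out.stdout.split()[-4:]]
        ll_r, int_r, fst_r, lat_r = vals
        assert fit.log_likelihood == pytest.approx(ll_r, abs=0.05)
        assert fit.coefficients["intercept"] == pytest.approx(int_r, abs=0.02)
        assert fit.coefficients["fst"] == pytest.approx(fst_r, abs=0.05)
        assert fit.coefficients["latitude"] == pytest.approx(lat_r, abs=0.05)

    def test_ancient_mode_has_eight_models(self):
        recs, metas = _records()
        for r in recs:
            r.age_years = float(np.random.default_rng(0).uniform(3000, 8500))
        rng = np.random.default_rng(1)
        ages = rng.uniform(3000, 8500, len(recs))
        for r, a in zip(recs, ages):
            r.age_years = float(a)
        fits = cm.glmm_model_set(recs, None, ancient=True)
        assert len(fits) == 8

    def test_modern_mode_has_four_models(self):
        recs, metas = _records()
        fst = {m.name: 0.05 + 0.01 * i for i, m in enumerate(metas)}
        fits = cm.glmm_model_set(recs, fst)
        assert len(fits) == 4
        assert {f.k for f in fits} == {4, 5, 6}


class TestLrt:
    def test_identical_fits(self):
        recs, metas = _records()
        fst = {m.name: 0.05 + 0.01 * i for i, m in enumerate(metas)}
        fit = cm.glmm_fit(recs, fixed=("latitude",), fst_to_reference=fst)
        fit2 = cm.RegressionFit(**{**fit.__dict__, "k": fit.k + 1})
        chi2, df, p = cm.lrt(fit, fit2)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_full_vs_null_df_two(self):
        recs, metas = _records()
        fst = {m.name: 0.05 + 0.01 * i for i, m in enumerate(metas)}
        null = cm.glmm_fit(recs, fixed=(), fst_to_reference=fst)
        full = cm.glmm_fit(recs, fixed=("temperature", "latitude"), fst_to_reference=fst)
        chi2, df, p = cm.lrt(null, full)
        assert df == 2 and chi2 >= 0

    def test_gaussian_closed_form_oracle(self):
        rng = np.random.default_rng(6)
        n = 40
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + rng.normal(size=n)

        def gauss_fit(X, label, k):
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            s2 = (resid ** 2).mean()
            ll = -n / 2 * (math.log(2 * math.pi * s2) + 1)
            return cm.RegressionFit(label, {}, {}, ll, k, n, -2 * ll + 2 * k, np.nan)

        f0 = gauss_fit(np.ones((n, 1)), "null", 2)
        f1 = gauss_fit(np.column_stack([np.ones(n), x]), "full", 3)
        chi2, df, p = cm.lrt(f0, f1)
        # analytic: chi2 = n log(RSS0 / RSS1)
        rss0 = ((y - y.mean()) ** 2).sum()
        X = np.column_stack([np.ones(n), x])
        rss1 = ((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2).sum()
        assert chi2 == pytest.approx(n * math.log(rss0 / rss1), abs=1e-9)

    def test_lrt_invariant_to_z_transform(self):
        recs, metas = _records()
        fst = {m.name: 0.05 + 0.01 * i for i, m in enumerate(metas)}
        null = cm.glmm_fit(recs, fixed=(), fst_to_reference=fst)
        full = cm.glmm_fit(recs, fixed=("latitude",), fst_to_reference=fst)
        # latitude is z-transformed internally; scaling the raw values must
        # not change the statistic
        for r in recs:
            r.latitude = r.latitude * 3.0 + 7.0
        full2 = cm.glmm_fit(recs, fixed=("latitude",), fst_to_reference=fst)
        c1 = cm.lrt(null, full)[0]
        c2 = cm.lrt(null, full2)[0]
        assert c1 == pytest.approx(c2, abs=1e-3)


class TestMultiModel:
    def test_published_pgls_weights(self):
        rows = cm.multimodel_table([-49.43, -49.186, -44.147, -42.255],
                                   labels=["lat", "lat+temp", "temp", "null"],
                                   ks=[5, 6, 5, 4])
        w = [round(r.akaike_weight, 3) for r in rows]
        assert w == [0.504, 0.446, 0.036, 0.014]
        assert [r.in_confidence_set for r in rows] == [True, True, False, False]
        assert rows[0].delta_aicc == 0.0

    def test_published_glmm_weights(self):
        best = cm.multimodel_table([0.0, 0.09, 10.633, 16.964])[0]
        assert round(best.akaike_weight, 3) == 0.510
        best = cm.multimodel_table([435.206, 440.841, 451.699, 452.458])[0]
        assert round(best.akaike_weight, 3) == 0.943

    def test_single_model_and_weight_sum(self):
        rows = cm.multimodel_table([10.0])
        assert rows[0].akaike_weight == 1.0
        rng = np.random.default_rng(7)
        aics = rng.uniform(100, 120, 6).tolist()
        rows = cm.multimodel_table(aics)
        assert sum(r.akaike_weight for r in rows) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        aics = [12.0, 10.0, 15.5, 11.2]
        labels = ["a", "b", "c", "d"]
        r1 = cm.multimodel_table(aics, labels=labels)
        r2 = cm.multimodel_table(aics[::-1], labels=labels[::-1])
        assert [(r.model_label, round(r.akaike_weight, 12)) for r in r1] == \
               [(r.model_label, round(r.akaike_weight, 12)) for r in r2]

    def test_nonfinite_excluded(self):
        with pytest.warns(UserWarning):
            rows = cm.multimodel_table([5.0, np.inf, 7.0])
        assert len(rows) == 2


class TestStability:
    def _ols_fit_func(self, xs, ys):
        def fit(units):
            x = np.array([xs[u] for u in units])
            y = np.array([ys[u] for u in units])
            X = np.column_stack([np.ones(len(x)), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            return cm.RegressionFit("ols", {"intercept": beta[0], "x": beta[1]},
                                    {}, 0.0, 2, len(x), 0.0, 0.0)
        return fit

    def test_replica_exclusion_is_neutral(self):
        xs = {"a": 0.0, "b": 1.0, "c": 2.0, "c2": 2.0}
        ys = {"a": 0.1, "b": 1.2, "c": 1.8, "c2": 1.8}
        fit = self._ols_fit_func(xs, ys)
        # removing one of two identical units barely moves an OLS slope when
        # the duplicate remains; check the range machinery reports it
        table = cm.stability_analysis(fit, list(xs))
        assert set(table.index) == {"intercept", "x"}
        assert (table["min"] <= table["original"]).all()
        assert (table["original"] <= table["max"]).all()

    def test_refit_count(self):
        calls = []
        def fit(units):
            calls.append(tuple(units))
            return cm.RegressionFit("f", {"b": float(len(units))}, {}, 0.0, 1,
                                    len(units), 0.0, 0.0)
        cm.stability_analysis(fit, ["u1", "u2", "u3", "u4"])
        assert len(calls) == 5  # full fit + one per excluded unit

    def test_outlier_widest_range(self):
        xs = {f"u{i}": float(i) for i in range(6)}
        ys = {u: 2 * x for u, x in xs.items()}
        ys["u5"] = 30.0  # outlier
        fit = self._ols_fit_func(xs, ys)
        table = cm.stability_analysis(fit, list(xs))
        # excluding the outlier moves the slope the most: range is wide
        assert table.loc["x", "max"] - table.loc["x", "min"] > 1.0


class TestPearson:
    def test_perfect_and_formula(self):
        r, p = cm.pearson_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r, _ = cm.pearson_correlation(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        expect = (xm * ym).sum() / math.sqrt((xm ** 2).sum() * (ym ** 2).sum())
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cm.pearson_correlation([1, 1, 1], [1, 2, 3])
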