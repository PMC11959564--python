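"""Distance table, modeling-set restriction, score adjustment, and the
per-gene distance regression (cross-checked against statsmodels)."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm

from conftest import brute_force_nearest

from spotdist import (
    CountMatrix,
    adjust_signature_scores,
    call_significant,
    fit_distance_models,
    nearest_high_distance,
    restrict_modeling_set,
)
from spotdist.datatypes import SpotGrid
from spotdist.signatures import EXCLUDED, HIGH, LOW, SpotClassification
from spotdist.synthetic import make_hex_grid


def labels_for(grid, high_ids=(), excluded_ids=()):
    lab = pd.Series(LOW, index=pd.Index(grid.spot_ids, name="spot_id"), dtype=object)
    lab.loc[list(high_ids)] = HIGH
    lab.loc[list(excluded_ids)] = EXCLUDED
    return SpotClassification(labels=lab, thresholds=pd.DataFrame())


class TestNearestHighDistance:
    def test_lattice_geometry_examples(self):
        g = make_hex_grid(6, 6, 100.0, "s1")
        anchor = "s1_2_4"  # row 2, col 4
        cls = labels_for(g, high_ids=[anchor])
        d = nearest_high_distance(g, cls).set_index("spot_id")["d"]
        assert d.loc["s1_2_6"] == pytest.approx(1.0)        # in-row neighbor
        assert d.loc["s1_2_8"] == pytest.approx(2.0)        # two in-row steps
        assert d.loc["s1_4_4"] == pytest.approx(np.sqrt(3))  # diagonal 2nd ring
        assert d.loc["s1_3_5"] == pytest.approx(1.0)        # diagonal neighbor

    def test_matches_all_pairs_brute_force(self):
        g = make_hex_grid(25, 20, 100.0, "s1")
        rng = np.random.default_rng(11)
        ids = g.spot_ids
        high = rng.choice(ids, 30, replace=False)
        cls = labels_for(g, high_ids=high)
        table = nearest_high_distance(g, cls).set_index("spot_id")
        pos = g.table.set_index("spot_id")[["x_um", "y_um"]]
        low_ids = table.index.to_numpy()
        oracle = brute_force_nearest(
            pos.loc[low_ids].to_numpy(), pos.loc[high].to_numpy(), 100.0
        )
        assert np.allclose(table["d"].to_numpy(), oracle)
        assert (table["d"] >= 1.0 - 1e-12).all()  # a spot is never its own anchor

    def test_section_without_high_yields_infinite(self, caplog):
        g = make_hex_grid(3, 3, 100.0, "s1")
        cls = labels_for(g)  # every spot LOW
        with caplog.at_level("WARNING"):
            d = nearest_high_distance(g, cls)
        assert np.isinf(d["d"]).all()
        assert "no HIGH spots" in caplog.text


class TestRestrictModelingSet:
    def make_inputs(self):
        dist = pd.DataFrame(
            {"spot_id": ["a", "b", "c", "d", "e"],
             "section_id": "s1",
             "d": [10.0, 10.5, 2.0, 3.0, np.inf]}
        )
        ann = pd.DataFrame(
            {"spot_id": ["a", "b", "c", "d", "e"],
             "compartment": ["tumor", "tumor", "stroma", "tumor", "tumor"],
             "pathology_class": ["cancer", "cancer", "cancer", "non-cancer", "cancer"]}
        )
        return dist, ann

    def test_threshold_and_exclusions(self):
        dist, ann = self.make_inputs()
        kept = restrict_modeling_set(dist, ann, d_max=10.0)
        # a: d=10 tumor/cancer kept; b: 10.5 out; c: stroma out;
        # d: non-cancer out; e: infinite out
        assert list(kept) == ["a"]

    def test_equals_brute_force_conjunction(self):
        rng = np.random.default_rng(5)
        n = 300
        dist = pd.DataFrame(
            {"spot_id": [f"s{i}" for i in range(n)], "section_id": "s1",
             "d": rng.uniform(0.5, 15, n)}
        )
        ann = pd.DataFrame(
            {"spot_id": dist["spot_id"],
             "compartment": rng.choice(["tumor", "stroma"], n),
             "pathology_class": rng.choice(["cancer", "non-cancer"], n)}
        )
        kept = set(restrict_modeling_set(dist, ann, d_max=10.0))
        oracle = {
            r.spot_id
            for r, a in zip(dist.itertuples(), ann.itertuples())
            if r.d <= 10.0 and a.compartment == "tumor" and a.pathology_class == "cancer"
        }
        assert kept == oracle

    def test_unknown_labels_listed(self):
        dist, ann = self.make_inputs()
        ann.loc[0, "compartment"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            restrict_modeling_set(dist, ann)


class TestAdjustScores:
    def dist_table(self, n, rng):
        return pd.DataFrame(
            {"spot_id": [f"s{i}" for i in range(n)], "section_id": "s1",
             "d": rng.uniform(1, 10, n)}
        )

    def test_flat_scores_become_centered(self):
        rng = np.random.default_rng(0)
        dist = self.dist_table(200, rng)
        s = pd.Series(0.42, index=dist["spot_id"])
        adj = adjust_signature_scores(s, dist)
        assert np.allclose(adj.to_numpy(), 0.0, atol=1e-12)

    def test_exact_linear_decay_adjusts_to_zero(self):
        rng = np.random.default_rng(1)
        dist = self.dist_table(100, rng)
        s = pd.Series(0.8 - 0.05 * dist["d"].to_numpy(), index=dist["spot_id"])
        adj = adjust_signature_scores(s, dist)
        assert np.allclose(adj.to_numpy(), 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_distance(self):
        rng = np.random.default_rng(2)
        dist = self.dist_table(500, rng)
        s = pd.Series(
            0.6 - 0.03 * dist["d"].to_numpy() + rng.normal(0, 0.05, 500),
            index=dist["spot_id"],
        )
        adj = adjust_signature_scores(s, dist)
        assert abs(np.corrcoef(adj.to_numpy(), dist["d"].to_numpy())[0, 1]) < 1e-8
        assert abs(adj.mean()) < 1e-12

    def test_tiny_section_passes_raw(self, caplog):
        rng = np.random.default_rng(3)
        dist = self.dist_table(2, rng)
        s = pd.Series([0.1, 0.9], index=dist["spot_id"])
        with caplog.at_level("WARNING"):
            adj = adjust_signature_scores(s, dist)
        assert np.allclose(adj.to_numpy(), [0.1, 0.9])
        assert "raw scores" in caplog.text


def make_fit_inputs(seed=0, n=400, n_genes=12, beta=0.0, two_samples=True):
    rng = np.random.default_rng(seed)
    spot_ids = [f"s{i}" for i in range(n)]
    d = rng.uniform(1, 10, n)
    mu = np.exp(3.0 + beta * d)
    counts = rng.negative_binomial(5.0, 5.0 / (5.0 + mu), size=(n_genes, n))
    counts[0] += 5  # keep every gene detected
    cm = CountMatrix(
        np.array([f"g{i}" for i in range(n_genes)], object),
        np.array(spot_ids, object),
        sp.csr_matrix(counts),
    )
    dist = pd.DataFrame({"spot_id": spot_ids, "section_id": "s1", "d": d})
    samples = pd.Series(
        np.where(np.arange(n) % 2 == 0, "sampA", "sampB") if two_samples else "sampA",
        index=spot_ids,
    )
    adj = pd.Series(rng.normal(0, 0.05, n), index=spot_ids)
    return cm, dist, samples, adj


class TestFitDistanceModels:
    def test_matches_statsmodels_ols_exactly(self):
        cm, dist, samples, adj = make_fit_inputs(seed=4)
        models = fit_distance_models(
            cm, list(cm.spots), dist, samples, adj, "R", min_detect_frac=0.0
        ).set_index("gene")
        totals = cm.spot_totals().astype(float)
        x = pd.DataFrame(
            {"const": 1.0, "d": dist["d"].to_numpy(),
             "samp": (samples.to_numpy() == "sampB").astype(float),
             "adj": adj.to_numpy()}
        )
        for gi in (0, 5, 11):
            y = np.log1p(cm.dense()[gi] * 1e4 / totals)
            fit = sm.OLS(y, x).fit()
            row = models.loc[f"g{gi}"]
            assert row["beta_d"] == pytest.approx(fit.params["d"], rel=1e-10)
            assert row["se"] == pytest.approx(fit.bse["d"], rel=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues["d"], rel=1e-8, abs=1e-300)

    def test_near_noiseless_linear_recovery(self):
        # Poisson-limit counts with log-mean 5 - 0.3 d: slope recovered closely
        rng = np.random.default_rng(9)
        n = 2000
        d = rng.uniform(1, 10, n)
        # target stays a small fraction of the library so depth normalization
        # does not cancel its own trend
        mu = np.exp(6.0 - 0.3 * d)
        counts = np.vstack([rng.poisson(mu), rng.poisson(np.full(n, 1e5))])
        cm = CountMatrix(
            np.array(["target", "filler"], object),
            np.array([f"s{i}" for i in range(n)], object),
            sp.csr_matrix(counts),
        )
        dist = pd.DataFrame({"spot_id": cm.spots, "section_id": "s1", "d": d})
        samples = pd.Series("one", index=cm.spots)
        adj = pd.Series(0.0, index=cm.spots)
        models = fit_distance_models(cm, list(cm.spots), dist, samples, adj, "R",
                                     scale=1e6)
        row = models.set_index("gene").loc["target"]
        assert row["beta_d"] == pytest.approx(-0.3, abs=0.01)
        assert row["p"] < 1e-10

    def test_bonferroni_and_invariants(self):
        cm, dist, samples, adj = make_fit_inputs(seed=6)
        models = fit_distance_models(cm, list(cm.spots), dist, samples, adj, "R",
                                     min_detect_frac=0.0)
        assert (models["p_bonf"] >= models["p"]).all()
        assert (models["p_bonf"] <= 1.0).all()
        assert models["n_spots"].nunique() == 1

    def test_invariant_to_sample_relabeling_and_spot_order(self):
        cm, dist, samples, adj = make_fit_inputs(seed=7)
        base = fit_distance_models(cm, list(cm.spots), dist, samples, adj, "R",
                                   min_detect_frac=0.0)
        renamed = samples.map({"sampA": "zebra", "sampB": "aard"})
        alt = fit_distance_models(cm, list(cm.spots), dist, renamed, adj, "R",
                                  min_detect_frac=0.0)
        assert np.allclose(base["beta_d"], alt["beta_d"])
        perm = np.random.default_rng(0).permutation(len(cm.spots))
        shuffled = [cm.spots[i] for i in perm]
        alt2 = fit_distance_models(cm, shuffled, dist, samples, adj, "R",
                                   min_detect_frac=0.0)
        assert np.allclose(base["beta_d"], alt2["beta_d"])

    def test_signature_genes_excluded_from_modeling(self):
        cm, dist, samples, adj = make_fit_inputs(seed=8)
        models = fit_distance_models(cm, list(cm.spots), dist, samples, adj, "R",
                                     signature_genes=("g0", "g1"),
                                     min_detect_frac=0.0)
        assert not {"g0", "g1"} & set(models["gene"])

    def test_single_sample_design_drops_dummies(self, caplog):
        cm, dist, samples, adj = make_fit_inputs(seed=10, two_samples=False)
        with caplog.at_level("INFO"):
            models = fit_distance_models(cm, list(cm.spots), dist, samples, adj, "R",
                                         min_detect_frac=0.0)
        assert len(models) == 12  # fit succeeds without sample indicators


class TestCallSignificant:
    def base_table(self, betas, p_bonf):
        n = len(betas)
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "group": "R",
             "beta_d": betas, "se": 0.01, "p": p_bonf, "p_bonf": p_bonf,
             "significant": False, "n_spots": 100}
        )

    def test_zero_spread_flags_nothing(self):
        m = call_significant(self.base_table([0.2] * 12, [1e-9] * 12))
        assert not m["significant"].any()

    def test_displaced_coefficient_flagged_exactly(self):
        rng = np.random.default_rng(0)
        betas = list(rng.normal(0, 0.01, 29)) + [0.2]
        pb = [1e-6] * 30
        m = call_significant(self.base_table(betas, pb))
        assert m.loc[m["significant"], "gene"].tolist() == ["g29"]

    def test_conjunction_requires_small_p(self):
        rng = np.random.default_rng(1)
        betas = list(rng.normal(0, 0.01, 29)) + [0.2]
        pb = [1e-6] * 29 + [0.2]
        m = call_significant(self.base_table(betas, pb))
        assert not m["significant"].any()

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            call_significant(self.base_table([0.1] * 5, [0.01] * 5))
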