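"""PLS fit, association scoring and edge selection contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_block
from tests.oracles import correlation_p_closed_form
from tmwas import pls, preprocess, synth
from tmwas.types import Block


def univariate_pair(x, y):
    samples = [f"s{i}" for i in range(len(x))]
    xb = make_block([x], Block.FUNCTIONAL, ["x1"], samples)
    yb = make_block([y], Block.METABOLOME, ["y1"], samples)
    return xb, yb


class TestFitPls:
    def test_self_integration_scores_collinear(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(4, 6))
        xb = make_block(values, Block.FUNCTIONAL)
        yb = make_block(values, Block.METABOLOME)
        model = pls.fit_pls(xb, yb, n_components=1)
        r = np.corrcoef(model.x_scores[:, 0], model.y_scores[:, 0])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)

    def test_univariate_score_correlation_is_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        model = pls.fit_pls(*univariate_pair(x, y), n_components=1)
        score_r = np.corrcoef(model.x_scores[:, 0], model.y_scores[:, 0])[0, 1]
        assert abs(score_r) == pytest.approx(abs(np.corrcoef(x, y)[0, 1]),
                                             abs=1e-8)

    def test_sparsity_budget_enforced(self):
        rng = np.random.default_rng(2)
        xb = make_block(rng.normal(size=(8, 6)), Block.METABOLOME)
        yb = make_block(rng.normal(size=(5, 6)), Block.TRANSCRIPTOME)
        model = pls.fit_pls(xb, yb, n_components=2, keep_x=1)
        for h in range(2):
            assert np.count_nonzero(model.x_weights[:, h]) == 1

    def test_successive_x_scores_orthogonal(self):
        rng = np.random.default_rng(3)
        xb = make_block(rng.normal(size=(10, 6)), Block.METABOLOME)
        yb = make_block(rng.normal(size=(10, 6)), Block.TRANSCRIPTOME)
        model = pls.fit_pls(xb, yb, n_components=3)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_component_cap(self):
        rng = np.random.default_rng(4)
        xb = make_block(rng.normal(size=(3, 4)), Block.FUNCTIONAL)
        yb = make_block(rng.normal(size=(3, 4)), Block.METABOLOME)
        with pytest.raises(ValueError, match="n_components"):
            pls.fit_pls(xb, yb, n_components=4)

    def test_constant_block_errors(self):
        xb = make_block(np.ones((2, 5)), Block.FUNCTIONAL)
        yb = make_block(np.random.default_rng(0).normal(size=(2, 5)),
                        Block.METABOLOME)
        with pytest.raises(ValueError, match="variable features"):
            pls.fit_pls(xb, yb, n_components=1)

    def test_matches_sklearn_scores_without_sparsity(self):
        # independent cross-check: scikit-learn's NIPALS on the same data
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        xm = rng.normal(size=(8, 5))   # samples x features
        ym = rng.normal(size=(8, 4))
        xb = make_block(xm.T, Block.METABOLOME)
        yb = make_block(ym.T, Block.TRANSCRIPTOME)
        model = pls.fit_pls(xb, yb, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(xm, ym)
        for h in range(2):
            r = np.corrcoef(model.x_scores[:, h], sk.x_scores_[:, h])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-6)


class TestAssociationMatrix:
    def test_univariate_equals_pearson_many_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            x, y = rng.normal(size=6), rng.normal(size=6)
            xb, yb = univariate_pair(x, y)
            model = pls.fit_pls(xb, yb, n_components=1)
            r = pls.association_matrix(model, xb, yb).iat[0, 0]
            assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-8)

    def test_orthogonal_feature_scores_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        xb, _ = univariate_pair(x, x)
        model = pls.fit_pls(xb, xb.with_values(
            xb.values.rename(index={"x1": "y1"})), n_components=1)
        # y orthogonal to the latent score (which is proportional to x)
        y_orth = np.array([1.0, 1.0, -1.0, -1.0])
        yb = make_block([y_orth], Block.METABOLOME, ["y1"],
                        xb.sample_ids)
        r = pls.association_matrix(model, xb, yb).iat[0, 0]
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_zero_noise_planted_pair_perfect_association(self):
        scenario = synth.Scenario(
            n_planted_met=2, n_planted_tx=2, n_noise_met=0, n_noise_tx=0,
            noise_sd={b: 0.0 for b in Block})
        blocks, design, truth = synth.generate(scenario, seed=0)
        func = preprocess.median_collapse(blocks[Block.FUNCTIONAL], design)
        met = preprocess.median_collapse(blocks[Block.METABOLOME], design)
        model = pls.fit_pls(func, met, n_components=3)
        r = pls.association_matrix(model, func, met)
        for fid in met.feature_ids:
            anchor = truth.anchor_assignment[fid]
            assert r.loc[anchor, fid] == pytest.approx(truth.sign[fid],
                                                       abs=1e-6)

    def test_invariant_to_feature_scaling(self):
        rng = np.random.default_rng(7)
        xb = make_block(rng.normal(size=(4, 6)), Block.FUNCTIONAL)
        yb = make_block(rng.normal(size=(5, 6)), Block.METABOLOME)
        model = pls.fit_pls(xb, yb, n_components=2)
        base = pls.association_matrix(model, xb, yb)
        scaled_y = yb.with_values(yb.values * 37.5 + 2.0)
        rescored = pls.association_matrix(model, xb, scaled_y)
        np.testing.assert_allclose(rescored.to_numpy(), base.to_numpy(),
                                   atol=1e-10)


class TestEdgePValue:
    def test_trivial_endpoints(self):
        assert pls.edge_p_value(0.0, 6) == pytest.approx(1.0)
        assert pls.edge_p_value(1.0, 6) == 0.0
        assert pls.edge_p_value(-1.0, 6) == 0.0

    def test_against_closed_form(self):
        for r, n in [(0.9, 6), (0.5, 10), (-0.8, 6), (0.3, 20)]:
            assert pls.edge_p_value(r, n) == pytest.approx(
                correlation_p_closed_form(r, n), rel=1e-10)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            pls.edge_p_value(0.5, 2)

    def test_null_calibration_univariate(self):
        # at n=20, 500 independent univariate pairs: the association score
        # is the Pearson r, so the t-test rejects ~5% under the null
        rng = np.random.default_rng(8)
        hits = 0
        n_pairs = 500
        for _ in range(n_pairs):
            x, y = rng.normal(size=20), rng.normal(size=20)
            xb, yb = univariate_pair(x, y)
            model = pls.fit_pls(xb, yb, n_components=1)
            r = pls.association_matrix(model, xb, yb).iat[0, 0]
            hits += pls.edge_p_value(r, 20) < 0.05
        assert abs(hits / n_pairs - 0.05) <= 0.02


class TestSelectEdges:
    def matrix(self, values, rows=None, cols=None):
        rows = rows or [f"x{i}" for i in range(len(values))]
        cols = cols or [f"y{j}" for j in range(len(values[0]))]
        return pd.DataFrame(values, index=rows, columns=cols)

    def test_exact_threshold_excluded(self):
        r = self.matrix([[0.8]])
        assert pls.select_edges(r, 6, Block.FUNCTIONAL, Block.METABOLOME,
                                r_threshold=0.8) == []

    def test_hand_enumerated_toy(self):
        r = self.matrix([[0.95, -0.85, 0.10],
                         [0.79, 0.81, -0.99],
                         [0.0, 0.5, 0.805]])
        edges = pls.select_edges(r, 6, Block.FUNCTIONAL, Block.METABOLOME,
                                 r_threshold=0.8, p_threshold=0.05)
        got = [(e.source_id, e.target_id, round(e.r, 3)) for e in edges]
        # sorted by |r| descending; p at n=6 keeps |r| >= ~0.811
        assert got == [("x1", "y2", -0.99), ("x0", "y0", 0.95),
                       ("x0", "y1", -0.85)]
        # note |r|=0.81 and 0.805 pass the r cut but fail p < 0.05 at n=6
        assert ("x1", "y1") not in {(e.source_id, e.target_id) for e in edges}

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        r = self.matrix(np.clip(rng.uniform(-1, 1, size=(4, 5)), -1, 1))
        loose = pls.select_edges(r, 8, Block.FUNCTIONAL, Block.METABOLOME,
                                 r_threshold=0.6)
        strict = pls.select_edges(r, 8, Block.FUNCTIONAL, Block.METABOLOME,
                                  r_threshold=0.85)
        loose_pairs = {(e.source_id, e.target_id) for e in loose}
        strict_pairs = {(e.source_id, e.target_id) for e in strict}
        assert strict_pairs <= loose_pairs
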