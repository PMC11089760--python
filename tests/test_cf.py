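import numpy as np
import pandas as pd
import pytest

from lncda.cf import (
    CF,
    NGHCF,
    RelationshipMatrix,
    als_fit,
    cf_rank,
    fill_cf_binary,
    fill_nghcf,
    nghcf_rank,
    predict_scores,
)
from lncda.graph import build_tripartite
from lncda.ngh import ngh_score
from lncda.synthetic import implant_block, random_tripartite


def _rm(values) -> RelationshipMatrix:
    return RelationshipMatrix(pd.DataFrame(np.asarray(values, dtype=float)))


class TestFill:
    def test_binary_entries(self, toy_graph):
        R = fill_cf_binary(toy_graph)
        # both lncRNAs share a miRNA with d1
        assert R.values.loc["l1", "d1"] == 1.0
        assert R.values.loc["l2", "d1"] == 1.0
        assert set(np.unique(R.values.to_numpy())) <= {0.0, 1.0}

    def test_binary_zero_for_disjoint_profiles(self):
        g = build_tripartite({("l1", "m1")}, {("m2", "d1")})
        assert fill_cf_binary(g).values.loc["l1", "d1"] == 0.0

    def test_empty_universe_rejected(self):
        g = build_tripartite(set(), set())
        with pytest.raises(ValueError):
            fill_cf_binary(g)

    def test_nghcf_entries_sum_to_one(self, toy_graph):
        R = fill_nghcf(toy_graph, alpha=0.5)
        assert R.values.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)

    def test_nghcf_zero_scores_excluded_from_chi(self):
        g = build_tripartite(
            {("l1", "m1"), ("l2", "m2")}, {("m1", "d1"), ("m3", "d2")}
        )
        R = fill_nghcf(g, alpha=0.5)
        assert R.values.loc["l2", "d2"] == 0.0
        positions = set(R.chi)
        i, j = (list(R.values.index).index("l2"),
                list(R.values.columns).index("d2"))
        assert (i, j) not in positions

    def test_nghcf_matches_normalised_score(self, toy_graph):
        R = fill_nghcf(toy_graph, alpha=0.5)
        raw = ngh_score(toy_graph, "l1", "d1", 0.5).s
        total = sum(
            ngh_score(toy_graph, l, "d1", 0.5).s for l in ("l1", "l2")
        )
        assert R.values.loc["l1", "d1"] == pytest.approx(raw / total)

    def test_nghcf_all_zero_graph_rejected(self):
        g = build_tripartite({("l1", "m1")}, {("m2", "d1")})
        with pytest.raises(ValueError, match="factorize"):
            fill_nghcf(g, alpha=0.5)


class TestAls:
    def test_rank1_pattern_recovered_exactly(self):
        u, v = np.array([1.0, 2.0]), np.array([1.0, 0.0, 1.0])
        R = _rm(np.outer(u, v))
        model = als_fit(R, f=1, reg=0.0, max_iter=50, tol=1e-12, seed=0)
        assert model.objective_trace[-1] <= 1e-9
        pred = predict_scores(model).to_numpy()
        obs = R.values.to_numpy() != 0
        assert np.allclose(pred[obs], np.outer(u, v)[obs], atol=1e-6)

    @pytest.mark.parametrize("seed", range(50))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 6)) * (rng.random((8, 6)) < 0.5)
        if not vals.any():
            vals[0, 0] = 0.5
        model = als_fit(_rm(vals), f=3, reg=0.01, max_iter=15, tol=1e-12,
                        seed=seed + 1)
        trace = np.array(model.objective_trace)
        full = trace[1::2]  # after each complete alternation
        assert np.all(np.diff(full) <= 1e-9 * np.maximum(full[:-1], 1.0))

    def test_bit_identical_refit_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        vals = rng.random((6, 5)) * (rng.random((6, 5)) < 0.6)
        a = als_fit(_rm(vals), f=2, reg=0.01, seed=7)
        b = als_fit(_rm(vals), f=2, reg=0.01, seed=7)
        assert np.array_equal(a.lnc_factors.to_numpy(), b.lnc_factors.to_numpy())
        assert np.array_equal(a.dis_factors.to_numpy(), b.dis_factors.to_numpy())

    def test_empty_chi_rejected(self):
        with pytest.raises(ValueError, match="chi"):
            als_fit(_rm(np.zeros((3, 3))))

    def test_overparameterized_f_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            als_fit(_rm(np.eye(3)), f=5, reg=0.1, max_iter=3)

    def test_half_step_optimality(self):
        """After a block solve, perturbing one factor raises the objective."""
        rng = np.random.default_rng(2)
        vals = rng.random((5, 4)) * (rng.random((5, 4)) < 0.7)
        R = _rm(vals)
        model = als_fit(R, f=2, reg=0.05, max_iter=30, tol=1e-14, seed=3)
        L = model.lnc_factors.to_numpy()
        D = model.dis_factors.to_numpy()
        mask = vals != 0

        def objective(Lm, Dm):
            resid = vals - Lm @ Dm.T
            return (resid[mask] ** 2).sum() + 0.05 * (
                (Lm**2).sum() + (Dm**2).sum()
            )

        base = objective(L, D)
        for j in range(D.shape[0]):
            for eps in (1e-4, -1e-4):
                Dp = D.copy()
                Dp[j, 0] += eps
                assert objective(L, Dp) >= base - 1e-12

    def test_predictions_cover_unobserved_pairs(self, benchmark):
        g, _ = benchmark
        R = fill_cf_binary(g)
        model = als_fit(R, f=3, reg=0.01, seed=0)
        pred = predict_scores(model)
        assert pred.shape == R.values.shape
        zeros = R.values.to_numpy() == 0
        # the imputation effect: some unobserved pairs get a positive score
        assert (pred.to_numpy()[zeros] > 0).any()


class TestPipelines:
    def test_deterministic_rank(self, benchmark):
        g, _ = benchmark
        a = cf_rank(g, f=3, seed=5)
        b = cf_rank(g, f=3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_cf_and_nghcf_cover_same_universe(self, benchmark):
        g, _ = benchmark
        a = cf_rank(g, f=3, seed=1)
        b = nghcf_rank(g, alpha=0.5, f=3, seed=1)
        assert set(zip(a.lncrna, a.disease)) == set(zip(b.lncrna, b.disease))

    def test_top_decile_stable_across_latent_dims(self):
        """The leading predictions should not hinge on the exact rank f."""
        import warnings

        g = random_tripartite(30, 60, 20, p_lm=0.08, p_md=0.08, seed=7)
        g = implant_block(
            g, [f"l{i}" for i in range(1, 7)],
            [f"m{i}" for i in range(1, 13)], [f"d{i}" for i in range(1, 5)],
        )
        tops = []
        for f in (5, 10, 20):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rank = cf_rank(g, f=f, seed=42)
            n = len(rank) // 10
            tops.append(set(zip(rank.lncrna[:n], rank.disease[:n])))
        for other in tops[1:]:
            overlap = len(tops[0] & other) / len(tops[0] | other)
            assert overlap >= 0.5

    def test_implanted_block_enriched_in_top_decile(self):
        """Dense planted associations beat a permutation null."""
        rng = np.random.default_rng(0)
        g = random_tripartite(15, 30, 10, p_lm=0.05, p_md=0.05, seed=10)
        block_l = ["l1", "l2", "l3", "l4"]
        block_m = [f"m{i}" for i in range(1, 9)]
        block_d = ["d1", "d2", "d3"]
        g = implant_block(g, block_l, block_m, block_d)
        rank = cf_rank(g, f=3, seed=0)
        n_top = len(rank) // 10
        top = set(zip(rank.lncrna[:n_top], rank.disease[:n_top]))
        planted = {(l, d) for l in block_l for d in block_d}
        hits = len(planted & top)
        null_hits = []
        pairs = list(zip(rank.lncrna, rank.disease))
        for _ in range(100):
            perm = rng.permutation(len(pairs))[:n_top]
            null_top = {pairs[i] for i in perm}
            null_hits.append(len(planted & null_top))
        assert hits > np.percentile(null_hits, 95)


class TestModelApi:
    def test_results_carry_diagnostics(self, benchmark):
        g, _ = benchmark
        res = NGHCF(g, alpha=0.5, f=3).fit(seed=42)
        assert res.converged in (True, False)
        assert len(res.objective_trace) >= 2
        text = res.summary()
        assert "NGH-CF" in text and "objective" in text

    def test_invalid_reg_rejected(self, benchmark):
        g, _ = benchmark
        with pytest.raises(ValueError):
            CF(g, reg=-1.0)
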