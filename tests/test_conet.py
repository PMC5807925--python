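import warnings

import numpy as np
import pandas as pd
import pytest

import commstable as cs
from commstable import ConetConfig, RelAbundTable
from commstable.conet import (MeasureScores, _reboot_draws, bh_fdr,
                              measure_scores, select_initial_thresholds)


@pytest.fixture
def rel_table():
    rng = np.random.default_rng(5)
    vals = rng.dirichlet(np.ones(6), size=40)
    return RelAbundTable(pd.DataFrame(
        vals, index=[f"S{i}" for i in range(40)], columns=list("ABCDEF")))


class TestMeasureScores:
    def test_bray_curtis_extremes(self):
        # identical columns -> BC 0; disjoint support -> BC 1
        vals = np.array([[0.3, 0.3, 0.4, 0.0],
                         [0.2, 0.2, 0.0, 0.6]])
        r = RelAbundTable(pd.DataFrame(vals, index=["S1", "S2"],
                                       columns=list("ABCD")))
        bc = measure_scores(r, "bray_curtis").scores
        assert bc.loc["A", "B"] == pytest.approx(0.0)
        assert bc.loc["C", "D"] == pytest.approx(1.0)

    def test_kl_self_zero_and_symmetry(self, rel_table):
        kl = measure_scores(rel_table, "kl").scores.to_numpy()
        assert np.allclose(np.diag(kl), 0.0)
        assert np.allclose(kl, kl.T)
        assert kl.min() >= 0

    def test_correlation_measures_bounded(self, rel_table):
        for m in ("pearson", "spearman"):
            mat = measure_scores(rel_table, m).scores.to_numpy()
            assert mat.min() >= -1 - 1e-12 and mat.max() <= 1 + 1e-12
            assert np.allclose(np.diag(mat), 1.0)

    def test_all_zero_otu_rejected(self):
        vals = np.array([[1.0, 0.0], [1.0, 0.0]])
        r = RelAbundTable(pd.DataFrame(vals, index=["S1", "S2"],
                                       columns=["A", "B"]))
        with pytest.raises(ValueError, match="all-zero"):
            measure_scores(r, "kl")


def _fake_scores(ranking: dict[str, np.ndarray], otu_ids: list[str]):
    """Build four MeasureScores whose pairwise co-presence ranking is given
    by a score vector over the upper-triangle pairs."""
    d = len(otu_ids)
    iu, ju = np.triu_indices(d, k=1)
    out = {}
    for name, vec in ranking.items():
        mat = np.zeros((d, d))
        mat[iu, ju] = vec
        mat[ju, iu] = vec
        out[name] = MeasureScores(name, pd.DataFrame(
            mat, index=otu_ids, columns=otu_ids), +1)
    return out


class TestThresholdSelection:
    def test_perfect_concordance(self):
        otus = list("ABCDE")  # 10 pairs
        base = np.arange(10, dtype=float)
        scores = {m: s for m, s in _fake_scores(
            {m: base for m in ("pearson", "spearman", "bray_curtis", "kl")},
            otus).items()}
        cfg = ConetConfig(target_pos_edges=3, target_neg_edges=2,
                          n_permutations=10)
        sel = select_initial_thresholds(scores, cfg)
        iu, ju = np.triu_indices(5, k=1)
        pairs = [tuple(sorted((otus[i], otus[j]))) for i, j in zip(iu, ju)]
        top3 = {pairs[k] for k in np.argsort(-base)[:3]}
        bottom2 = {pairs[k] for k in np.argsort(base)[:2]}
        assert set(sel.pos_pairs) == top3
        assert set(sel.neg_pairs) == bottom2

    def test_targets_met_unless_exhausted(self, rel_table):
        scores = {m: measure_scores(rel_table, m)
                  for m in ("pearson", "spearman", "bray_curtis", "kl")}
        cfg = ConetConfig(target_pos_edges=4, target_neg_edges=4,
                          n_permutations=10)
        sel = select_initial_thresholds(scores, cfg)
        assert len(sel.pos_pairs) >= 4
        assert len(sel.neg_pairs) >= 4
        assert not set(sel.pos_pairs) & set(sel.neg_pairs)

    def test_disagreeing_rankings_match_exhaustive_oracle(self):
        # two measures with partially conflicting rankings over 10 pairs
        otus = list("ABCDE")
        rng = np.random.default_rng(2)
        v1 = rng.permutation(10).astype(float)
        v2 = rng.permutation(10).astype(float)
        scores = _fake_scores({"pearson": v1, "spearman": v2}, otus)
        cfg = ConetConfig(measures=("pearson", "spearman"),
                          target_pos_edges=3, target_neg_edges=1,
                          n_permutations=10)
        sel = select_initial_thresholds(scores, cfg)
        # oracle: smallest lock-step cutoff k with |top-k(1) & top-k(2)| >= 3
        iu, ju = np.triu_indices(5, k=1)
        pairs = [tuple(sorted((otus[i], otus[j]))) for i, j in zip(iu, ju)]
        for k in range(1, 11):
            tops = [set(np.argsort(-v)[:k]) for v in (v1, v2)]
            inter = tops[0] & tops[1]
            if len(inter) >= 3:
                assert set(sel.pos_pairs) == {pairs[x] for x in inter}
                break

    def test_exhaustion_warns_and_returns_all(self, rel_table):
        scores = {m: measure_scores(rel_table, m)
                  for m in ("pearson", "spearman", "bray_curtis", "kl")}
        cfg = ConetConfig(n_permutations=10)  # targets 2000 >> 15 pairs
        with pytest.warns(RuntimeWarning, match="returning all"):
            sel = select_initial_thresholds(scores, cfg)
        assert len(sel.pos_pairs) + len(sel.neg_pairs) == 15


class TestReboot:
    def test_renormalisation_keeps_compositions(self, rel_table):
        values = rel_table.values.to_numpy()
        rng = np.random.default_rng(0)
        u, v = _reboot_draws(values, 0, 1, 50, rng)
        rest = 1.0 - values[:, 0] - values[:, 1]
        # renormalised pair fractions plus rescaled rest sum to 1
        denom_inv_rest = 1.0 - u - v  # = rest/denom
        assert (u >= 0).all() and (v >= 0).all()
        assert np.all(u + v <= 1 + 1e-12)
        assert np.allclose(u + v + denom_inv_rest, 1.0)

    def test_perfect_covariation_min_p(self):
        rng = np.random.default_rng(8)
        x = rng.dirichlet(np.ones(3), size=100)
        vals = np.column_stack([x[:, 0] / 2, x[:, 0] / 2, x[:, 1], x[:, 2]])
        r = RelAbundTable(pd.DataFrame(
            vals, index=[f"S{i}" for i in range(100)], columns=list("ABCD")))
        p, direction = cs.reboot_pvalue(r, ("A", "B"), "pearson",
                                        n_permutations=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert direction == 1

    def test_seed_determinism(self, rel_table):
        a = cs.reboot_pvalue(rel_table, ("A", "C"), "kl", 200, seed=3)
        b = cs.reboot_pvalue(rel_table, ("A", "C"), "kl", 200, seed=3)
        assert a == b

    def test_distance_polarity(self):
        # perfectly co-varying pair under Bray-Curtis: observed distance far
        # below the null mean -> co-presence (+1)
        rng = np.random.default_rng(9)
        x = rng.dirichlet(np.ones(3), size=80)
        vals = np.column_stack([x[:, 0] / 2, x[:, 0] / 2, x[:, 1], x[:, 2]])
        r = RelAbundTable(pd.DataFrame(
            vals, index=[f"S{i}" for i in range(80)], columns=list("ABCD")))
        p, direction = cs.reboot_pvalue(r, ("A", "B"), "bray_curtis",
                                        n_permutations=200, seed=2)
        assert direction == 1 and p < 0.05


class TestBhFdr:
    def test_step_up_examples(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_independent_step_up_oracle(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(bh_fdr(p), oracle(p))


class TestConetEdges:
    def test_planted_block_recovered(self):
        spec = cs.BlockSpec(n_samples=300, block_sizes=(8,),
                            n_background_otus=16, rho_within=0.7, seed=5)
        t, truth = cs.simulate_block_table(spec)
        r = cs.relative_abundance(t)
        # liberal candidate targets: the concordance screen is an initial
        # cut, not the detector; recovery happens at the ReBoot/FDR stage
        cfg = ConetConfig(target_pos_edges=138, target_neg_edges=138,
                          n_permutations=199, n_bootstraps=200, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            edges = cs.conet_edges(r, cfg)
        blk = truth.block_of
        sig = edges.edges[edges.edges.p < 0.05]
        recovered = sum(1 for a, b in zip(sig.otu_a, sig.otu_b)
                        if blk[a] == blk[b] and blk[a] != 0)
        assert recovered >= 0.8 * (8 * 7 // 2)

    def test_null_table_calibrated(self):
        false_rates = []
        for seed in (0, 1):
            spec = cs.BlockSpec(n_samples=80, block_sizes=(2, 2),
                                n_background_otus=16, rho_within=0.0,
                                depth_range=(5_000, 10_000), seed=200 + seed)
            t, _ = cs.simulate_block_table(spec)
            cfg = ConetConfig(target_pos_edges=20, target_neg_edges=20,
                              n_permutations=199, n_bootstraps=200, seed=seed)
            edges = cs.conet_edges(cs.relative_abundance(t), cfg)
            n_pairs = 20 * 19 // 2
            false_rates.append((edges.edges.p < 0.05).sum() / n_pairs)
        assert np.mean(false_rates) <= 0.05

    def test_merged_p_is_minimum_over_measures(self, rel_table):
        from commstable.conet import _evaluate_candidate, _kl_pseudocount

        values = rel_table.values.to_numpy()
        cfg = ConetConfig(n_permutations=99, bootstrap_screen=False)
        rng = np.random.default_rng(13)
        p_by, dir_by, support = _evaluate_candidate(
            values, 0, 3, cfg, rng, None, _kl_pseudocount(values.shape[0], None))
        assert all(support.values())
        assert min(p_by.values()) <= min(p_by[m] for m in cfg.measures)
        assert set(dir_by.values()) <= {-1, 0, 1}

    def test_bh_q_at_least_raw_merged_p(self, rel_table):
        cfg = ConetConfig(target_pos_edges=3, target_neg_edges=3,
                          n_permutations=99, bootstrap_screen=False, seed=7)
        edges = cs.conet_edges(rel_table, cfg)
        assert len(edges.edges) > 0
        assert (edges.edges.p >= edges.edges.p_raw - 1e-12).all()
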