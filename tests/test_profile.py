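import numpy as np
import pandas as pd
import pytest

import commstable as cs
from commstable import (AlignmentScoring, CountTable, Partition, RepSeqSet,
                        SampleMetadata, TaxonomyTable)
from commstable.communities import _canonical_ids


def _part(groups) -> Partition:
    return Partition(_canonical_ids([set(g) for g in groups]),
                     float("nan"), float("nan"))


@pytest.fixture
def toy_table():
    df = pd.DataFrame(
        [[10, 20, 30, 40], [5, 5, 40, 50], [25, 25, 25, 25]],
        index=["S1", "S2", "S3"], columns=["A", "B", "C", "D"])
    return CountTable(df)


class TestCommunityAbundance:
    def test_hand_summed_ratios(self, toy_table):
        part = _part([{"A", "B"}, {"C"}, {"D"}])
        ab = cs.community_abundance(toy_table, part).values
        # community ids are size-ordered: {A,B} -> 1, then {C} and {D}
        cid_ab = part.assignment["A"]
        assert ab.loc["S1", cid_ab] == pytest.approx(30 / 100)
        assert ab.loc["S2", cid_ab] == pytest.approx(10 / 100)
        assert ab.loc["S3", part.assignment["D"]] == pytest.approx(0.25)

    def test_full_partition_sums_to_one(self, toy_table):
        part = _part([{"A", "B"}, {"C", "D"}])
        ab = cs.community_abundance(toy_table, part).values
        assert np.allclose(ab.sum(axis=1), 1.0)

    def test_scaling_invariance(self, toy_table):
        part = _part([{"A", "C"}, {"B", "D"}])
        a1 = cs.community_abundance(toy_table, part).values
        scaled = CountTable(toy_table.counts * 7)
        a2 = cs.community_abundance(scaled, part).values
        pd.testing.assert_frame_equal(a1, a2)

    def test_absent_otu_rejected(self, toy_table):
        with pytest.raises(ValueError, match="absent"):
            cs.community_abundance(toy_table, _part([{"A", "nope"}]))


class TestLogAbundance:
    def test_pseudocount_endpoints(self):
        tab = cs.CommunityAbundanceTable(pd.DataFrame(
            {"c1": [0.0, 1.0 - 1e-6]}, index=["S1", "S2"]))
        out = cs.log_abundance(tab)
        assert out.loc["S1", "c1"] == pytest.approx(-6.0)
        assert out.loc["S2", "c1"] == pytest.approx(0.0, abs=1e-6)

    def test_monotone(self):
        vals = np.sort(np.random.default_rng(0).random(10))
        tab = cs.CommunityAbundanceTable(pd.DataFrame({"c1": vals}))
        out = cs.log_abundance(tab)["c1"].to_numpy()
        assert (np.diff(out) >= 0).all()


class TestAssociate:
    @staticmethod
    def _metadata(n, seed=0):
        rng = np.random.default_rng(seed)
        return SampleMetadata(pd.DataFrame({
            "age": rng.normal(50, 10, n).round(1),
            "bmi": rng.normal(26, 4, n).round(2),
            "sex": rng.choice(["male", "female"], n),
            "depth": rng.integers(20_000, 60_000, n),
        }, index=[f"S{i}" for i in range(n)]))

    def test_betas_match_normal_equations(self):
        meta = self._metadata(5, seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(size=5)
        log_ab = pd.DataFrame({1: y}, index=meta.data.index)
        results, _ = cs.associate(log_ab, meta)
        # closed-form OLS with intercept + bmi + age + sex dummy + depth
        sex_dummy = (meta.data["sex"] == "male").astype(float)
        x = np.column_stack([np.ones(5), sex_dummy, meta.data["bmi"],
                             meta.data["age"], meta.data["depth"]])
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        by_pheno = {r.phenotype: r for r in results}
        assert by_pheno["bmi"].beta == pytest.approx(beta[2])
        assert by_pheno["age"].beta == pytest.approx(beta[3])

    def test_planted_effect_recovered(self):
        n = 500
        meta = self._metadata(n, seed=3)
        rng = np.random.default_rng(4)
        bmi = meta.data["bmi"].to_numpy()
        signal = -0.1 * bmi + rng.normal(0, 0.3, n)
        noise = rng.normal(-3, 0.5, n)
        log_ab = pd.DataFrame({1: signal, 2: noise}, index=meta.data.index)
        results, _ = cs.associate(log_ab, meta)
        hit = [r for r in results if r.phenotype == "bmi"
               and r.community_id == 1][0]
        assert hit.beta < 0 and hit.q < 0.05

    def test_permuted_phenotype_calibrated(self):
        n = 300
        false_pos, families = 0, 0
        for seed in range(5):
            meta = self._metadata(n, seed=seed)
            rng = np.random.default_rng(100 + seed)
            log_ab = pd.DataFrame(
                {k: rng.normal(-3, 0.5, n) for k in range(1, 9)},
                index=meta.data.index)
            results, _ = cs.associate(log_ab, meta)
            false_pos += sum(r.q < 0.05 for r in results)
            families += len(results)
        assert false_pos / families <= 0.05

    def test_constant_community_excluded(self):
        meta = self._metadata(10, seed=5)
        log_ab = pd.DataFrame({1: np.full(10, -4.0),
                               2: np.random.default_rng(0).normal(size=10)},
                              index=meta.data.index)
        results, excluded = cs.associate(log_ab, meta)
        assert excluded == [1]
        assert {r.community_id for r in results} == {2}


class TestTaxonomySummary:
    @pytest.fixture
    def taxonomy(self):
        return TaxonomyTable(pd.Series({
            "A": "k__Bacteria; p__Firmicutes; c__Clostridia",
            "B": "k__Bacteria; p__Firmicutes; c__Bacilli",
            "C": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia",
            "D": "k__Bacteria; p__Firmicutes; c__",
        }))

    def test_counts_sum_to_community_size(self, taxonomy):
        part = _part([{"A", "B", "C"}, {"D"}])
        out = cs.taxonomy_summary(part, taxonomy, "class")
        sizes = out.groupby("community_id")["n_otus"].sum().to_dict()
        assert sizes == {1: 3, 2: 1}

    def test_manual_tally_at_phylum(self, taxonomy):
        part = _part([{"A", "B", "C", "D"}])
        out = cs.taxonomy_summary(part, taxonomy, "phylum")
        tally = dict(zip(out.taxon, out.n_otus))
        assert tally == {"p__Firmicutes": 3, "p__Bacteroidetes": 1}

    def test_unassigned_bucketed_by_prefix(self, taxonomy):
        part = _part([{"D", "A"}])
        out = cs.taxonomy_summary(part, taxonomy, "class")
        assert "k__Bacteria;p__Firmicutes;c__" in set(out.taxon)


class TestPairwiseIdentity:
    def test_worked_micro_example(self):
        seqs = RepSeqSet({"x": "ACGT", "y": "ACGA"})
        part = _part([{"x", "y"}])
        out = cs.mean_pairwise_identity(part, seqs)
        assert out.loc[1] == pytest.approx(0.75)

    def test_identical_sequences(self):
        seqs = RepSeqSet({"x": "ACGTACGT", "y": "ACGTACGT"})
        out = cs.mean_pairwise_identity(_part([{"x", "y"}]), seqs)
        assert out.loc[1] == 1.0

    def test_symmetry(self):
        from commstable.profile import _identity

        scoring = AlignmentScoring()
        pairs = [("ACGTT", "AGT"), ("AAAA", "AAAT"), ("GATTACA", "GCATGCG")]
        for a, b in pairs:
            assert _identity(a, b, scoring) == pytest.approx(
                _identity(b, a, scoring))

    def test_singleton_nan_and_missing_error(self):
        seqs = RepSeqSet({"x": "ACGT"})
        out = cs.mean_pairwise_identity(_part([{"x"}]), seqs)
        assert np.isnan(out.loc[1])
        with pytest.raises(ValueError, match="missing"):
            cs.mean_pairwise_identity(_part([{"x", "z"}]),
                                      RepSeqSet({"x": "ACGT"}))


class TestAbundanceSizeCorrelation:
    def test_perfect_rank_agreement(self):
        # abundance increases with community size
        df = pd.DataFrame([[1, 1, 10, 10, 10, 100, 100, 100, 100]],
                          index=["S1"],
                          columns=[f"O{i}" for i in range(9)])
        t = CountTable(pd.DataFrame(np.tile(df.to_numpy(), (4, 1)),
                                    index=[f"S{i}" for i in range(4)],
                                    columns=df.columns))
        part = _part([{"O0", "O1"}, {"O2", "O3", "O4"},
                      {"O5", "O6", "O7", "O8"}])
        rho, p = cs.abundance_size_correlation(t, part)
        assert rho == pytest.approx(1.0)

    def test_anti_ranked(self):
        df = pd.DataFrame([[100, 100, 10, 10, 10, 1, 1, 1, 1]],
                          index=["S1"],
                          columns=[f"O{i}" for i in range(9)])
        t = CountTable(pd.DataFrame(np.tile(df.to_numpy(), (4, 1)),
                                    index=[f"S{i}" for i in range(4)],
                                    columns=df.columns))
        part = _part([{"O0", "O1"}, {"O2", "O3", "O4"},
                      {"O5", "O6", "O7", "O8"}])
        rho, _ = cs.abundance_size_correlation(t, part)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 5, size=(6, 8))
        t = CountTable(pd.DataFrame(
            counts, index=[f"S{i}" for i in range(6)],
            columns=[f"O{i}" for i in range(8)]))
        part = _part([{"O0", "O1", "O2"}, {"O3", "O4"},
                      {"O5", "O6", "O7"}])
        rho, _ = cs.abundance_size_correlation(t, part)

        # mid-rank oracle: rank by hand, then Pearson on the ranks
        otus = sorted(part.assignment)
        rel = t.counts.div(t.counts.sum(axis=1), axis=0)
        mean_ab = rel[otus].mean(axis=0).to_numpy()
        sizes = np.array([len(part.members(part.assignment[o])) for o in otus],
                         dtype=float)

        def midrank(x):
            order = np.argsort(x)
            ranks = np.empty(len(x))
            sx = x[order]
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and sx[j + 1] == sx[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        ra, rs = midrank(mean_ab), midrank(sizes)
        oracle = np.corrcoef(ra, rs)[0, 1]
        assert rho == pytest.approx(oracle)
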