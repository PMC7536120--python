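import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pavpop import pangenome, synthdata
from pavpop.dataio import PAVMatrix
from pavpop.errors import DataError
from pavpop.pangenome import CROSS_GENUS, WITHIN_GENUS, call_presence
from pavpop.synthdata import PAVClassSpec


class TestCallPresence:
    @pytest.mark.parametrize(
        "rule,identity,coverage,n_contigs,expected",
        [
            # same-genus rule: strict > 85 on one contig
            (WITHIN_GENUS, 86, 86, 1, True),
            (WITHIN_GENUS, 85, 86, 1, False),
            # split alignments need >= 90 on <= 3 contigs
            (WITHIN_GENUS, 89, 89, 3, False),
            (WITHIN_GENUS, 90, 90, 3, True),
            (WITHIN_GENUS, 95, 95, 4, False),
            # cross-genus preset: strict > 70 identity / > 75 coverage
            (CROSS_GENUS, 70.0, 75.0, 1, False),
            (CROSS_GENUS, 70.1, 75.1, 1, True),
            (CROSS_GENUS, 80.0, 80.0, 2, True),
        ],
    )
    def test_threshold_boundaries(self, rule, identity, coverage, n_contigs, expected):
        assert call_presence(identity, coverage, n_contigs, rule) is expected

    def test_coverage_over_100_rejected(self):
        with pytest.raises(DataError):
            call_presence(90, 101, 1, WITHIN_GENUS)

    @settings(max_examples=200, deadline=None)
    @given(
        identity=st.floats(0, 99),
        coverage=st.floats(0, 99),
        n_contigs=st.integers(1, 5),
        bump=st.floats(0, 1),
    )
    def test_monotone_in_identity_and_coverage(self, identity, coverage, n_contigs, bump):
        before = call_presence(identity, coverage, n_contigs, WITHIN_GENUS)
        after = call_presence(
            min(identity + bump, 100), min(coverage + bump, 100), n_contigs, WITHIN_GENUS
        )
        assert after or not before  # raising scores never flips present -> absent


class TestFilterLibraries:
    def _pav(self, counts):
        n_genes = max(counts) + 1
        data = {
            f"l{i}": [1] * c + [0] * (n_genes - c) for i, c in enumerate(counts)
        }
        return PAVMatrix(pd.DataFrame(data, index=[f"g{j}" for j in range(n_genes)]))

    def test_boundary_at_min_present(self):
        pav = self._pav([38_999, 39_000, 39_500])
        kept, excluded = pangenome.filter_libraries(pav, 39_000)
        assert excluded == ["l0"]
        assert list(kept.libraries) == ["l1", "l2"]

    def test_zero_threshold_is_identity(self):
        pav = self._pav([0, 5])
        kept, excluded = pangenome.filter_libraries(pav, 0)
        assert excluded == []
        assert kept.data.equals(pav.data)


class TestClassifyOccupancy:
    def test_all_equal_occupancy_selects_single_cluster(self):
        res = pangenome.classify_occupancy(np.ones(200), seed=0)
        assert res.k == 1
        assert res.labels.unique().tolist() == ["core"]

    @pytest.mark.parametrize(
        "means,expected_k",
        [((1.0,), 1), ((0.95, 0.2), 2), ((0.98, 0.56, 0.12), 3)],
    )
    def test_recovers_planted_cluster_count(self, means, expected_k):
        specs = [PAVClassSpec(1200, m) for m in means]
        pav, _ = synthdata.gen_pav_matrix(specs, 302, seed=41)
        res = pangenome.classify_occupancy(pav.occupancy(), seed=41)
        assert res.k == expected_k
        for est, true in zip(res.cluster_means, means):
            assert est == pytest.approx(true, abs=0.03)

    def test_cluster_means_descend_and_core_is_top(self):
        occ = np.concatenate([np.full(500, 0.1), np.full(500, 0.9)])
        res = pangenome.classify_occupancy(occ, seed=1)
        assert (np.diff(res.cluster_means) < 0).all()
        assert res.labels[occ > 0.5].unique().tolist() == ["core"]

    def test_bic_trace_covers_all_k(self):
        res = pangenome.classify_occupancy(np.linspace(0, 1, 300), k_max=4, seed=2)
        assert sorted(res.bic) == [1, 2, 3, 4]


class TestChisqEnrichment:
    SIZES = {"Central": 35, "Central-East": 59, "Central-North": 78, "West-Coast": 130}

    def _inputs(self, gene_rows):
        libs, subpop = [], []
        for name, size in self.SIZES.items():
            for i in range(size):
                libs.append(f"{name}_{i}")
                subpop.append(name)
        meta = pd.DataFrame({"subpop": subpop, "qi": 1.0}, index=pd.Index(libs))
        data = {}
        for g, counts in gene_rows.items():
            row = []
            for name, size in self.SIZES.items():
                c = counts[name]
                row += [1] * c + [0] * (size - c)
            data[g] = row
        pav = PAVMatrix(pd.DataFrame(data, index=libs).T.astype(np.int8))
        return pav, meta

    def test_proportional_counts_give_zero_statistic(self):
        pav, meta = self._inputs({"g1": self.SIZES})
        res = pangenome.chisq_enrichment(pav, meta)
        assert res.loc["g1", "chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_all_in_one_subpop(self):
        counts = {"Central": 0, "Central-East": 0, "Central-North": 0, "West-Coast": 130}
        pav, meta = self._inputs({"g1": counts})
        res = pangenome.chisq_enrichment(pav, meta)
        sizes = np.array(list(self.SIZES.values()), dtype=float)
        expected = 130 * sizes / 302  # O * n_i / N
        np.testing.assert_allclose(
            res.loc["g1", [f"expected_{s}" for s in self.SIZES]].to_numpy(dtype=float),
            expected,
        )
        np.testing.assert_allclose(expected, [15.07, 25.40, 33.58, 55.96], atol=0.005)
        assert res.loc["g1", "chi2"] == pytest.approx(172.0, abs=0.1)
        assert res.loc["g1", "df"] == 3
        assert bool(res.loc["g1", "candidate"])  # 172 > 7.81

    def test_critical_value_for_four_subpops(self):
        assert pangenome.chisq_critical_value(3, 0.05) == pytest.approx(7.81, abs=0.005)

    def test_expected_counts_sum_to_observed(self):
        rng = np.random.default_rng(3)
        gene_rows = {
            f"g{i}": {s: int(rng.integers(0, n + 1)) for s, n in self.SIZES.items()}
            for i in range(20)
        }
        pav, meta = self._inputs(gene_rows)
        res = pangenome.chisq_enrichment(pav, meta)
        obs = res[[f"observed_{s}" for s in self.SIZES]].sum(axis=1)
        exp = res[[f"expected_{s}" for s in self.SIZES]].sum(axis=1)
        np.testing.assert_allclose(obs, exp)

    def test_zero_observation_genes_excluded(self):
        gene_rows = {"g1": dict.fromkeys(self.SIZES, 0), "g2": dict.fromkeys(self.SIZES, 5)}
        pav, meta = self._inputs(gene_rows)
        res = pangenome.chisq_enrichment(pav, meta)
        assert "g1" not in res.index and "g2" in res.index

    def test_q_values_monotone_in_p_and_at_least_p(self):
        rng = np.random.default_rng(4)
        gene_rows = {
            f"g{i}": {s: int(rng.binomial(n, 0.5)) for s, n in self.SIZES.items()}
            for i in range(100)
        }
        pav, meta = self._inputs(gene_rows)
        res = pangenome.chisq_enrichment(pav, meta).sort_values("p")
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert res["q"].is_monotonic_increasing

    def test_type_i_error_near_alpha_under_null(self):
        # null model of the test: each gene's observations fall into
        # subpopulations multinomially, proportional to subpop sizes
        rng = np.random.default_rng(5)
        sizes = np.array(list(self.SIZES.values()))
        probs = sizes / sizes.sum()
        n_genes = 2000
        gene_rows = {}
        for i in range(n_genes):
            counts = rng.multinomial(60, probs)
            gene_rows[f"g{i}"] = dict(zip(self.SIZES, counts.tolist()))
        pav, meta = self._inputs(gene_rows)
        res = pangenome.chisq_enrichment(pav, meta)
        rate = (res["p"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)


class TestPrivateGenes:
    def _inputs(self, freq_by_subpop):
        sizes = {"A": 20, "B": 20}
        libs, subpop = [], []
        for name, size in sizes.items():
            libs += [f"{name}{i}" for i in range(size)]
            subpop += [name] * size
        meta = pd.DataFrame({"subpop": subpop, "qi": 1.0}, index=pd.Index(libs))
        data = {}
        for g, freqs in freq_by_subpop.items():
            row = []
            for name, size in sizes.items():
                c = int(round(freqs[name] * size))
                row += [1] * c + [0] * (size - c)
            data[g] = row
        return PAVMatrix(pd.DataFrame(data, index=libs).T.astype(np.int8)), meta

    def test_private_detection_and_strict_boundaries(self):
        pav, meta = self._inputs(
            {
                "private": {"A": 0.5, "B": 0.0},
                "leaky": {"A": 0.5, "B": 0.05},
                "at_threshold": {"A": 0.1, "B": 0.0},
            }
        )
        res = pangenome.private_genes(pav, meta, min_freq=0.1)
        assert list(res.index) == ["private"]
        assert res.loc["private", "subpop"] == "A"


class TestJaccard:
    def test_identical_and_disjoint_profiles(self):
        m = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        d = pangenome.jaccard_distance(m).to_numpy()
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_worked_example(self):
        m = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
        d = pangenome.jaccard_distance(m).to_numpy()
        assert d[0, 1] == pytest.approx(1 - 1 / 3)

    def test_empty_profiles_have_zero_distance(self):
        m = np.zeros((2, 4), dtype=int)
        d = pangenome.jaccard_distance(m).to_numpy()
        assert d[0, 1] == 0.0

    def test_triangle_inequality_exhaustive_length_6(self):
        profiles = np.array(
            [[(v >> b) & 1 for b in range(6)] for v in range(64)], dtype=bool
        )
        d = pangenome.jaccard_distance(profiles).to_numpy()
        # d[i,k] <= d[i,j] + d[j,k] over all 64^3 triples
        lhs = d[:, None, :]
        rhs = d[:, :, None] + d[None, :, :]
        assert (lhs <= rhs + 1e-12).all()
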