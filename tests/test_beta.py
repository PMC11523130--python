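from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mycodiv import (
    DissimilarityMatrix,
    FeatureTable,
    SampleMetadata,
    anosim,
    bray_curtis,
    pcoa,
)

skbio = pytest.importorskip("skbio")


def _table(counts):
    counts = np.asarray(counts)
    return FeatureTable(pd.DataFrame(
        counts, index=[f"f{i}" for i in range(counts.shape[0])],
        columns=[f"s{i}" for i in range(counts.shape[1])]))


def _meta(groups):
    return SampleMetadata(pd.DataFrame(
        {"group": groups, "replicate": list(range(1, len(groups) + 1))},
        index=[f"s{i}" for i in range(len(groups))]))


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        d = bray_curtis(_table([[3, 3], [1, 1]]))
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = bray_curtis(_table([[3, 0], [0, 5]]))
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_evaluation(self):
        # x=(1,1,0), y=(1,0,1): sum|x-y| = 2, sum(x+y) = 4
        d = bray_curtis(_table([[1, 1], [1, 0], [0, 1]]))
        assert d.matrix[0, 1] == pytest.approx(0.5)

    def test_matches_direct_formula_oracle(self, random_table):
        d = bray_curtis(random_table).matrix
        x = random_table.counts
        for i in range(x.shape[1]):
            for j in range(x.shape[1]):
                expected = (np.abs(x[:, i] - x[:, j]).sum()
                            / (x[:, i] + x[:, j]).sum())
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_scale_invariant(self, random_table):
        d1 = bray_curtis(random_table).matrix
        assert np.allclose(d1, d1.T)
        scaled = FeatureTable(random_table.data * 7)
        assert np.allclose(bray_curtis(scaled).matrix, d1)


class TestPcoa:
    def test_two_samples_distance_two(self):
        dm = DissimilarityMatrix(["a", "b"], np.array([[0.0, 2.0],
                                                       [2.0, 0.0]]))
        res = pcoa(dm)
        assert res.eigenvalues[0] == pytest.approx(2.0)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_euclidean_embedding_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DissimilarityMatrix(list("abcdef"), d))
        recon = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=2)
        assert np.allclose(recon, d, atol=1e-9)

    def test_eigenvalue_sum_equals_centering_trace(self):
        rng = np.random.default_rng(1)
        x = rng.random((8, 5))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))
        dm = DissimilarityMatrix([f"s{i}" for i in range(8)], d)
        n = 8
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        res = pcoa(dm)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_equidistant_matrix_equal_eigenvalues(self):
        d = np.full((4, 4), 0.7)
        np.fill_diagonal(d, 0.0)
        res = pcoa(DissimilarityMatrix(list("abcd"), d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert np.allclose(pos, pos[0])

    def test_matches_skbio_coordinates(self, random_table):
        from skbio.stats.ordination import pcoa as sk_pcoa
        dm = bray_curtis(random_table)
        mine = pcoa(dm)
        theirs = sk_pcoa(skbio.DistanceMatrix(dm.matrix, dm.sample_ids))
        k = mine.coordinates.shape[1]
        sk_coords = theirs.samples.to_numpy()[:, :k]
        # axes are sign-arbitrary; compare per-axis up to sign
        for ax in range(min(k, 4)):
            a, b = mine.coordinates[:, ax], sk_coords[:, ax]
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], np.array([[0.0, 1.0],
                                                      [0.5, 0.0]]))
        with pytest.raises(ValueError):
            DissimilarityMatrix(["a", "b"], np.array([[0.0, -1.0],
                                                      [-1.0, 0.0]]))


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # two tight clusters far apart
        t = _table(np.array([
            [100, 99, 98, 0, 1, 2],
            [0, 1, 2, 100, 99, 98],
        ]))
        res = anosim(bray_curtis(t), _meta(["A"] * 3 + ["B"] * 3),
                     permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_null_permuted_r_centred_at_zero(self):
        rng = np.random.default_rng(2)
        rs = []
        for seed in range(60):
            t = _table(rng.integers(1, 50, size=(15, 6)))
            res = anosim(bray_curtis(t), _meta(["A"] * 3 + ["B"] * 3),
                         permutations=49, seed=seed)
            rs.append(res.r)
        assert abs(np.mean(rs)) < 0.1

    def test_exhaustive_enumeration_oracle_2plus2(self):
        """Monte-Carlo p agrees with full enumeration of the 4!=24 label
        assignments on a 2+2 design."""
        rng = np.random.default_rng(4)
        t = _table(rng.integers(1, 30, size=(10, 4)))
        dm = bray_curtis(t)
        labels = np.array(["A", "A", "B", "B"])
        iu, ju = np.triu_indices(4, k=1)
        ranks = rankdata(dm.condensed())

        def r_of(lab):
            within = lab[iu] == lab[ju]
            return ((ranks[~within].mean() - ranks[within].mean())
                    / (len(ranks) / 2))

        r_obs = r_of(labels)
        perm_rs = [r_of(labels[list(p)])
                   for p in iter_permutations(range(4))]
        exact_p = np.mean([r >= r_obs for r in perm_rs])
        res = anosim(dm, _meta(labels), permutations=999, seed=7)
        assert res.r == pytest.approx(r_obs, abs=1e-12)
        # MC estimate within binomial sampling error of the exact value
        se = np.sqrt(exact_p * (1 - exact_p) / 999) + 1e-3
        assert abs(res.p_value - exact_p) < 4 * se + 1 / 1000

    def test_matches_skbio_r_statistic(self, random_table, grouped_meta):
        from skbio.stats.distance import anosim as sk_anosim
        dm = bray_curtis(random_table)
        mine = anosim(dm, grouped_meta, permutations=9, seed=0)
        theirs = sk_anosim(
            skbio.DistanceMatrix(dm.matrix, dm.sample_ids),
            list(grouped_meta.groups_for(dm.sample_ids)), permutations=9)
        assert mine.r == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_requires_replicated_groups(self, random_table):
        meta = _meta(["A"] + ["B"] * 8)
        with pytest.raises(ValueError, match="< 2 samples"):
            anosim(bray_curtis(random_table), meta)
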