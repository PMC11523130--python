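import numpy as np
import pandas as pd
import pytest

from mycodiv import (
    LESS_IS_BETTER,
    MORE_IS_BETTER,
    ScoringSpec,
    SoilTable,
    compute_sqi,
    gen_known_sqi_case,
    load_reference_soil_table,
    score_indicator,
    select_mds,
    sqi_pipeline,
    standardized_pca,
)


def charpoly_eigenvalues(a: np.ndarray) -> np.ndarray:
    """Independent eigen-oracle: characteristic-polynomial coefficients
    by the Faddeev-LeVerrier recursion, roots via np.roots."""
    n = a.shape[0]
    coeffs = np.zeros(n + 1)
    coeffs[0] = 1.0
    m = np.zeros_like(a)
    for k in range(1, n + 1):
        m = a @ m + coeffs[k - 1] * np.eye(n)
        coeffs[k] = -(a @ m).trace() / k
    roots = np.roots(coeffs)
    return np.sort(roots.real)[::-1]


class TestStandardizedPca:
    def test_perfectly_correlated_pair_gives_single_component(self):
        x = np.array([1.0, 2, 3, 4, 5])
        soil = SoilTable(pd.DataFrame({"a": x, "b": 2 * x + 1},
                                      index=[f"o{i}" for i in range(5)]))
        res = standardized_pca(soil)
        assert res.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)
        assert res.variance_pct[0] == pytest.approx(100.0, abs=1e-9)

    def test_uncorrelated_pair_splits_evenly(self):
        # empirically orthogonal patterns
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, -1, -2, -1, 2])  # quadratic, orthogonal to linear
        soil = SoilTable(pd.DataFrame(
            {"a": a, "b": b - b.min() + 1},
            index=[f"o{i}" for i in range(5)]))
        res = standardized_pca(soil)
        assert res.variance_pct[0] == pytest.approx(50.0, abs=1e-9)

    def test_constant_indicator_named_in_error(self):
        soil = SoilTable(pd.DataFrame({"a": [1.0, 2, 3], "flat": [5.0] * 3},
                                      index=list("xyz")))
        with pytest.raises(ValueError, match="flat"):
            standardized_pca(soil)

    def test_eigenvalues_match_charpoly_oracle(self, small_soil):
        res = standardized_pca(small_soil)
        corr = np.corrcoef(small_soil.data.to_numpy(), rowvar=False)
        expected = charpoly_eigenvalues(corr)
        np.testing.assert_allclose(res.eigenvalues, expected, atol=1e-8)

    def test_loadings_are_unit_eigenvectors(self, small_soil):
        res = standardized_pca(small_soil)
        corr = np.corrcoef(small_soil.data.to_numpy(), rowvar=False)
        v = res.loadings.to_numpy()
        np.testing.assert_allclose(np.linalg.norm(v, axis=0), 1.0, atol=1e-12)
        for k in range(v.shape[1]):
            np.testing.assert_allclose(corr @ v[:, k],
                                       res.eigenvalues[k] * v[:, k],
                                       atol=1e-9)

    def test_variance_percent_sums_to_100(self, small_soil):
        res = standardized_pca(small_soil)
        assert res.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)


class TestSelectMds:
    def test_single_dominant_indicator_gets_full_weight(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rng = np.random.default_rng(0)
        soil = SoilTable(pd.DataFrame(
            {"dom": x, "n1": rng.uniform(1, 2, 6), "n2": rng.uniform(1, 2, 6)},
            index=[f"o{i}" for i in range(6)]))
        pca = standardized_pca(soil)
        # keep only PC1 by raising the eigenvalue threshold
        sel = select_mds(pca, soil, eig_min=pca.eigenvalues[0] - 1e-9,
                         var_min=5.0)
        assert sum(sel.weights.values()) == pytest.approx(1.0)
        assert len(sel.retained_pcs) == 1

    def test_correlated_candidates_pruned_with_audit(self):
        # two near-duplicates + orthogonal noise: PC1's two candidates
        # correlate ~0.99, so only the higher-loaded one survives
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rng = np.random.default_rng(1)
        soil = SoilTable(pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.05, 6),
             "c": rng.uniform(1, 2, 6)},
            index=[f"o{i}" for i in range(6)]))
        pca = standardized_pca(soil)
        sel = select_mds(pca, soil)
        pc1_kept = [i for i, pc in sel.source_pc.items() if pc == "PC1"]
        assert len(pc1_kept) == 1
        assert any("exclude" in line and "|r| = " in line for line in sel.log)

    def test_weight_arithmetic_two_pcs(self):
        """Two retained PCs at 60%/30% variance, one indicator each,
        give weights (2/3, 1/3) after renormalization."""
        from mycodiv.soil_quality import MdsSelection, PcaResult
        pca = PcaResult(
            eigenvalues=np.array([6.0, 3.0, 1.0]),
            loadings=pd.DataFrame(
                np.array([[0.9, 0.1, 0.1],
                          [0.1, 0.9, 0.1],
                          [0.1, 0.1, 0.9]]).T,
                index=["i1", "i2", "i3"], columns=["PC1", "PC2", "PC3"]),
            variance_pct=np.array([60.0, 30.0, 10.0]),
            means=pd.Series(1.0, index=["i1", "i2", "i3"]),
            sds=pd.Series(1.0, index=["i1", "i2", "i3"]),
        )
        rng = np.random.default_rng(2)
        soil = SoilTable(pd.DataFrame(rng.uniform(1, 2, (6, 3)),
                                      columns=["i1", "i2", "i3"],
                                      index=[f"o{i}" for i in range(6)]))
        sel = select_mds(pca, soil, eig_min=2.0, var_min=5.0)
        assert sel.weights["i1"] == pytest.approx(2 / 3)
        assert sel.weights["i2"] == pytest.approx(1 / 3)

    def test_no_retained_pc_is_an_error(self, small_soil):
        pca = standardized_pca(small_soil)
        with pytest.raises(ValueError, match="lower the thresholds"):
            select_mds(pca, small_soil, eig_min=100.0)


class TestScoreIndicator:
    def _spec(self, direction, x0=4.0):
        return ScoringSpec(directions={"v": direction},
                           baselines={"v": x0})

    @pytest.mark.parametrize("direction", [MORE_IS_BETTER, LESS_IS_BETTER])
    def test_midpoint_is_half(self, direction):
        s = score_indicator(4.0, "v", self._spec(direction))
        assert s == pytest.approx(0.5, abs=0)

    def test_more_is_better_at_double(self):
        s = score_indicator(8.0, "v", self._spec(MORE_IS_BETTER))
        assert s == pytest.approx(1 / (1 + 2 ** -2.5), abs=1e-9)
        assert s == pytest.approx(0.84977, abs=1e-5)

    def test_less_is_better_at_double_is_complement(self):
        s = score_indicator(8.0, "v", self._spec(LESS_IS_BETTER))
        assert s == pytest.approx(0.15023, abs=1e-5)
        more = score_indicator(8.0, "v", self._spec(MORE_IS_BETTER))
        assert s == pytest.approx(1 - more, abs=1e-12)

    def test_monotone_and_bounded(self):
        xs = np.linspace(0.1, 20, 50)
        up = [score_indicator(x, "v", self._spec(MORE_IS_BETTER)) for x in xs]
        down = [score_indicator(x, "v", self._spec(LESS_IS_BETTER)) for x in xs]
        assert (np.diff(up) > 0).all() and (np.diff(down) < 0).all()
        assert all(0 < s < 1 for s in up + down)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError, match="x must be > 0"):
            score_indicator(0.0, "v", self._spec(MORE_IS_BETTER))


class TestComputeSqi:
    def test_weighted_dot_product(self):
        """W=(0.5,0.3,0.2), S=(0.8,0.6,0.4) -> SQI = 0.66."""
        from mycodiv.soil_quality import MdsSelection
        sel = MdsSelection(retained_pcs=[("PC1", 1.0, 100.0)], candidates={},
                           weights={"a": 0.5, "b": 0.3, "c": 0.2},
                           source_pc={"a": "PC1", "b": "PC1", "c": "PC1"})
        # choose x so that S(x) hits 0.8 / 0.6 / 0.4 with x0 = 1
        def x_for(s):
            return (s / (1 - s)) ** (1 / 2.5)
        soil = SoilTable(pd.DataFrame(
            {"a": [x_for(0.8)], "b": [x_for(0.6)], "c": [x_for(0.4)]},
            index=["obs"]))
        spec = ScoringSpec(
            directions={k: MORE_IS_BETTER for k in "abc"},
            baselines={k: 1.0 for k in "abc"})
        res = compute_sqi(soil, sel, spec)
        assert res.sqi["obs"] == pytest.approx(0.66, abs=1e-9)

    def test_all_scores_half_gives_half(self):
        from mycodiv.soil_quality import MdsSelection
        sel = MdsSelection(retained_pcs=[("PC1", 1.0, 100.0)], candidates={},
                           weights={"a": 0.7, "b": 0.3},
                           source_pc={"a": "PC1", "b": "PC1"})
        soil = SoilTable(pd.DataFrame({"a": [2.0], "b": [5.0]}, index=["o"]))
        spec = ScoringSpec(directions={"a": MORE_IS_BETTER,
                                       "b": LESS_IS_BETTER},
                           baselines={"a": 2.0, "b": 5.0})
        assert compute_sqi(soil, sel, spec).sqi["o"] == pytest.approx(0.5)

    def test_missing_indicator_rejected(self, small_soil):
        from mycodiv.soil_quality import MdsSelection
        sel = MdsSelection(retained_pcs=[], candidates={},
                           weights={"ghost": 1.0}, source_pc={"ghost": "PC1"})
        spec = ScoringSpec(directions={"ghost": MORE_IS_BETTER},
                           baselines={"ghost": 1.0})
        with pytest.raises(KeyError, match="ghost"):
            compute_sqi(small_soil, sel, spec)


class TestSqiPipeline:
    def test_reference_table_ranks_full_ca_on_top(self):
        res = sqi_pipeline(load_reference_soil_table())
        assert res.ranking().index[0] in {"T4", "T5", "T7"}
        assert sum(res.selection.weights.values()) == pytest.approx(1.0)

    def test_scale_invariance_under_column_rescaling(self):
        soil = load_reference_soil_table()
        base = sqi_pipeline(soil)
        scaled = SoilTable(soil.data * pd.Series(
            {c: 10.0 ** i for i, c in enumerate(soil.data.columns)}))
        res = sqi_pipeline(scaled)
        np.testing.assert_allclose(res.sqi.to_numpy(),
                                   base.sqi.to_numpy(), atol=1e-12)
        np.testing.assert_allclose(res.scores.to_numpy(),
                                   base.scores.to_numpy(), atol=1e-12)

    def test_dominant_observation_attains_top_sqi(self):
        """An observation above every other in all more-is-better
        indicators must rank first (monotonicity)."""
        rng = np.random.default_rng(9)
        data = pd.DataFrame(rng.uniform(1, 5, (6, 5)),
                            index=[f"o{i}" for i in range(6)],
                            columns=list("abcde"))
        data.loc["o0"] = data.max() * 1.5
        res = sqi_pipeline(SoilTable(data),
                           directions={c: MORE_IS_BETTER for c in data})
        assert res.ranking().index[0] == "o0"


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [0, 3, 17])
    def test_planted_mds_recovered_exactly(self, seed):
        soil, expected_mds, _ = gen_known_sqi_case(seed=seed)
        res = sqi_pipeline(
            soil, directions={c: MORE_IS_BETTER for c in soil.indicators})
        assert sorted(res.selection.weights) == sorted(expected_mds)

    def test_expected_ordering_recovered(self):
        soil, _, expected_order = gen_known_sqi_case(seed=5)
        res = sqi_pipeline(
            soil, directions={c: MORE_IS_BETTER for c in soil.indicators})
        assert list(res.ranking().index) == expected_order

    def test_permuting_observations_permutes_sqi(self):
        soil, _, _ = gen_known_sqi_case(seed=2)
        res = sqi_pipeline(
            soil, directions={c: MORE_IS_BETTER for c in soil.indicators})
        perm = soil.data.iloc[::-1]
        res_p = sqi_pipeline(
            SoilTable(perm),
            directions={c: MORE_IS_BETTER for c in soil.indicators})
        pd.testing.assert_series_equal(res.sqi.iloc[::-1], res_p.sqi)
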