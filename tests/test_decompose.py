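"""Profile unfolding, PCA, association/enrichment tests, UPGMA clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from stromascreen import (
    PCAModel,
    ScreenUsageError,
    cluster_sensitivity,
    loading_class_enrichment,
    normalize_to_baseline,
    pc_subtype_association,
    run_pca,
    unfold_profiles,
)
from stromascreen.decompose import ProfileMatrix


def _pm_from_array(X: np.ndarray, columns=None) -> ProfileMatrix:
    values = pd.DataFrame(X, columns=columns)
    meta = pd.DataFrame({"line": [f"L{i}" for i in range(len(X))]})
    meta["condition"] = ""
    meta["subtype"] = ""
    return ProfileMatrix(
        values=values,
        sample_meta=meta,
        col_means=values.mean(),
        col_stds=values.std(ddof=0),
    )


class TestUnfold:
    def test_influence_unfold_has_one_row_per_culture_pair(self, default_run):
        pm = default_run.profile_matrix
        assert pm.shape == (6 * 16, 42 * 4 * 9)
        assert np.allclose(pm.values.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(pm.values.std(axis=0, ddof=0), 1.0, atol=1e-9)

    def test_viability_unfold_row_counts(self, default_run):
        viab = default_run.viability
        all_pairs = unfold_profiles(viab, value="viability", conditions="all")
        assert all_pairs.shape[0] == 6 * 17
        mono = unfold_profiles(viab, value="viability", conditions="monoculture")
        assert mono.shape[0] == 6
        per_line = unfold_profiles(viab, value="viability", conditions="all", per_line=True)
        assert per_line.shape[0] == 6

    def test_constant_column_dropped_and_logged(self, small_screen):
        tensor, _, _ = small_screen
        viab = normalize_to_baseline(tensor, background="alamethicin")
        df = viab.data.copy()
        low = df.loc[df["drug"] == "D01", "dose_uM"].min()
        flat = (df["drug"] == "D01") & (df["dose_uM"] == low)
        df.loc[flat, "viability"] = 0.5
        from stromascreen.normalize import ViabilityTensor

        pm = unfold_profiles(
            ViabilityTensor(data=df), value="viability", conditions="all"
        )
        dropped_drugs = {c[0] for c in pm.dropped_columns}
        assert "D01" in dropped_drugs
        assert len(pm.dropped_columns) == len(set(df.loc[flat, "time_h"]))


class TestPCA:
    def test_rank_one_matrix_loads_everything_on_pc1(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 0.5])
        with pytest.warns(RuntimeWarning, match="rank"):
            model = run_pca(_pm_from_array(X), n_components=3)
        assert model.explained_fraction[0] == pytest.approx(1.0)

    def test_full_spectrum_fractions_sum_to_one(self, default_run):
        assert default_run.pca.full_spectrum_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(default_run.pca.explained_fraction) <= 1e-12)

    def test_loadings_are_orthonormal(self, default_run):
        L = default_run.pca.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)

    def test_fixed_matrix_matches_covariance_eigendecomposition(self):
        X = np.array(
            [
                [1.0, 2.0, 0.5, -1.0],
                [0.0, 1.0, -0.5, 2.0],
                [2.0, -1.0, 1.5, 0.0],
                [-1.0, 0.5, 2.0, 1.0],
                [0.5, -2.0, -1.0, -0.5],
            ]
        )
        model = run_pca(_pm_from_array(X), n_components=4)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(Xc.T)))[::-1]
        oracle = eigvals / eigvals.sum()
        assert np.allclose(model.full_spectrum_fraction[:4], oracle, atol=1e-10)

    def test_scores_invariant_under_row_permutation(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 5))
        m1 = run_pca(_pm_from_array(X), n_components=3)
        perm = rng.permutation(8)
        m2 = run_pca(_pm_from_array(X[perm]), n_components=3)
        assert np.allclose(m2.explained_fraction, m1.explained_fraction)
        assert np.allclose(m2.scores.to_numpy(), m1.scores.to_numpy()[perm], atol=1e-9)


def _model_with_scores(scores_by_line: dict[str, float]) -> PCAModel:
    lines = list(scores_by_line)
    scores = pd.DataFrame({"PC1": list(scores_by_line.values())}, index=lines)
    meta = pd.DataFrame({"line": lines, "condition": "", "subtype": ""})
    return PCAModel(
        scores=scores,
        loadings=pd.DataFrame({"PC1": [1.0]}, index=pd.Index(["f"], name="feature")),
        explained_fraction=np.array([1.0]),
        full_spectrum_fraction=np.array([1.0]),
        n_components=1,
        sample_meta=meta,
    )


def _fisher_two_sided_oracle(a, b, c, d):
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-12)
    )


class TestSubtypeAssociation:
    def test_perfect_split_matches_hypergeometric_extreme(self):
        scores = {f"BL{i}": 1.0 + i for i in range(9)}
        scores |= {f"ML{i}": -1.0 - i for i in range(9)}
        model = _model_with_scores(scores)
        table = pc_subtype_association(
            model, {ln: ln[:2] for ln in scores}
        ).set_index("pc")
        expected = _fisher_two_sided_oracle(9, 0, 0, 9)
        assert table.loc[1, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_three_vs_three_perfect_split(self):
        scores = {"BL1": 3.0, "BL2": 2.0, "BL3": 1.0, "ML1": -1.0, "ML2": -2.0, "ML3": -3.0}
        model = _model_with_scores(scores)
        p = pc_subtype_association(model, {ln: ln[:2] for ln in scores})["p_value"][0]
        assert p == pytest.approx(_fisher_two_sided_oracle(3, 0, 0, 3), rel=1e-9)
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_random_scores_rarely_reach_significance(self):
        lines = [f"BL{i}" for i in range(8)] + [f"ML{i}" for i in range(8)]
        subtype_map = {ln: ln[:2] for ln in lines}
        n_sig = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            model = _model_with_scores(dict(zip(lines, rng.standard_normal(16))))
            p = pc_subtype_association(model, subtype_map)["p_value"][0]
            n_sig += p < 0.05
        assert n_sig <= 0.10 * n_seeds

    def test_single_subtype_rejected(self):
        scores = {"BL1": 1.0, "BL2": -1.0, "BL3": 0.5, "BL4": -0.5}
        with pytest.raises(ScreenUsageError, match="both subtypes"):
            pc_subtype_association(
                _model_with_scores(scores), {ln: "BL" for ln in scores}
            )

    def test_subtype_shift_surfaces_in_default_screen(self, default_run):
        table = default_run.subtype_association
        assert table["p_value"].min() < 0.05


def _model_with_loadings(loadings_by_drug: dict[str, list[float]]) -> PCAModel:
    idx = pd.MultiIndex.from_tuples(
        [(d, i) for d, vals in loadings_by_drug.items() for i in range(len(vals))],
        names=["drug", "feature"],
    )
    vals = [v for vals in loadings_by_drug.values() for v in vals]
    loadings = pd.DataFrame({"PC1": vals}, index=idx)
    meta = pd.DataFrame({"line": ["L0"], "condition": [""], "subtype": [""]})
    return PCAModel(
        scores=pd.DataFrame({"PC1": [0.0]}, index=["L0"]),
        loadings=loadings,
        explained_fraction=np.array([1.0]),
        full_spectrum_fraction=np.array([1.0]),
        n_components=1,
        sample_meta=meta,
    )


class TestLoadingEnrichment:
    def test_class_filling_top_quartile_reaches_enumeration_minimum(self):
        loadings = {f"A{i}": [10.0 - i] for i in range(4)}
        loadings |= {f"B{i}": [-float(i)] for i in range(12)}
        class_map = {d: d[0] for d in loadings}
        model = _model_with_loadings(loadings)
        table = loading_class_enrichment(model, class_map, pc=1).set_index("drug_class")
        assert table.loc["A", "n_in_top"] == 4
        assert table.loc["A", "p_value"] == pytest.approx(
            _fisher_two_sided_oracle(4, 0, 0, 12), rel=1e-9
        )

    def test_uniformly_ranked_class_has_unit_odds(self):
        # classes alternate along the ranking -> each occupies its share of the top
        loadings = {f"D{i}": [16.0 - i] for i in range(16)}
        class_map = {f"D{i}": ("A" if i % 2 == 0 else "B") for i in range(16)}
        table = loading_class_enrichment(
            _model_with_loadings(loadings), class_map, pc=1
        ).set_index("drug_class")
        assert table.loc["A", "odds_ratio"] == pytest.approx(1.0)
        assert table.loc["A", "p_value"] == pytest.approx(1.0)

    def test_chemo_classes_enriched_on_subtype_component(self, default_run):
        # the generator couples the BL/ML shift to conventional chemo classes,
        # so the subtype-associated component should rank them at the top
        table = default_run.loading_enrichment.set_index("drug_class")
        conventional = [
            "topoisomerase inhibitor", "microtubule poison", "platinum",
            "antimetabolite", "alkylating agent",
        ]
        best = table.loc[conventional].sort_values("p_value").iloc[0]
        assert best["odds_ratio"] > 1.0
        assert best["p_value"] < 0.05

    def test_unknown_component_rejected(self, default_run):
        with pytest.raises(ScreenUsageError, match="PC99"):
            loading_class_enrichment(
                default_run.pca, default_run.meta.class_map, pc=99
            )


class TestUPGMA:
    def test_hand_computed_linkage_on_one_dimensional_quadruple(self):
        mat = pd.DataFrame({"x": [0.0, 1.0, 10.0, 11.0]}, index=list("abcd"))
        result = cluster_sensitivity(mat)
        heights = sorted(result.row_linkage[:, 2])
        # UPGMA: (a,b) at 1, (c,d) at 1, then the two clusters at mean distance 10
        assert heights == pytest.approx([1.0, 1.0, 10.0])
        assert set(result.row_order[:2]) in ({"a", "b"}, {"c", "d"})

    def test_identical_rows_merge_first_at_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0], [5.0, 6.0]], index=["r1", "r2", "r3"]
        )
        result = cluster_sensitivity(mat)
        assert result.row_linkage[0, 2] == 0.0
        assert set(result.row_linkage[0, :2]) == {0.0, 1.0}  # r1, r2 merge first
        assert abs(result.row_order.index("r1") - result.row_order.index("r2")) == 1

    def test_row_permutation_leaves_tree_heights_invariant(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.standard_normal((6, 4)), index=list("abcdef"))
        base = cluster_sensitivity(mat)
        shuffled = cluster_sensitivity(mat.iloc[[3, 1, 5, 0, 4, 2]])
        assert np.allclose(
            np.sort(base.row_linkage[:, 2]), np.sort(shuffled.row_linkage[:, 2])
        )

    def test_newick_serialization_is_well_formed(self):
        mat = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        nwk = cluster_sensitivity(mat).row_newick
        assert nwk.endswith(";")
        assert all(label in nwk for label in "abc")
        assert nwk.count("(") == nwk.count(")")

    def test_single_row_rejected(self):
        with pytest.raises(ScreenUsageError, match="2 rows"):
            cluster_sensitivity(pd.DataFrame({"x": [1.0]}, index=["a"]))
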