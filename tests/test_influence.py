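"""Influence ratios, hit calling, enrichment, tiles, tissue divergence."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stromascreen import (
    InfluenceTensor,
    ScreenUsageError,
    call_hits,
    compute_influence,
    hit_enrichment,
    influence_tile,
    mean_influence,
    normalize_to_baseline,
    simulate_screen,
    tissue_divergence_test,
)
from stromascreen.normalize import ViabilityTensor
from stromascreen.simulate import SimConfig


def _viab(records) -> ViabilityTensor:
    df = pd.DataFrame(
        records,
        columns=["line", "condition", "drug", "dose_uM", "time_h", "replicate", "viability"],
    )
    df["subtype"] = df["line"].str[:2]
    df["tissue"] = np.where(df["condition"] == "monoculture", "", "lung")
    df["drug_class"] = "topo"
    df["baseline"] = 1000.0
    df["background"] = 0.0
    return ViabilityTensor(data=df)


def _pairs(v_mono, v_co, drug="dox", dose=1.0, time=8.0):
    rows = []
    for rep, (vm, vc) in enumerate(zip(v_mono, v_co), start=1):
        rows.append(("BL1", "monoculture", drug, dose, time, rep, vm))
        rows.append(("BL1", "F01", drug, dose, time, rep, vc))
    return rows


def test_equal_viabilities_give_zero_ratio():
    viab = _viab(_pairs([0.8, 0.7], [0.8, 0.7]) + _pairs([0.5, 0.6], [0.5, 0.6], drug="cis"))
    inf = compute_influence(viab)
    assert np.allclose(inf.unmasked["r_mean"], 0.0)


def test_halved_coculture_viability_gives_minus_one():
    viab = _viab(_pairs([0.8, 0.8], [0.4, 0.4]) + _pairs([0.5, 0.52], [0.5, 0.5], drug="cis"))
    inf = compute_influence(viab)
    row = inf.unmasked.set_index("drug").loc["dox"]
    assert row["r_mean"] == pytest.approx(-1.0)


def test_zero_monoculture_viability_is_masked_with_reason():
    viab = _viab(_pairs([0.0, 0.0], [0.4, 0.4]) + _pairs([0.5, 0.5], [0.4, 0.41], drug="cis"))
    inf = compute_influence(viab)
    assert inf.n_masked == 1
    masked = inf.data.loc[inf.data["mask_reason"] != ""]
    assert masked["drug"].tolist() == ["dox"]
    rr = inf.replicate_ratios
    assert (rr.loc[rr["drug"] == "dox", "mask_reason"] == "v_mono=0").all()


def test_line_without_monoculture_is_named():
    rows = _pairs([0.8, 0.8], [0.4, 0.4])
    rows += [("ML1", "F01", "dox", 1.0, 8.0, 1, 0.5), ("ML1", "F01", "dox", 1.0, 8.0, 2, 0.5)]
    with pytest.raises(ScreenUsageError, match="ML1"):
        compute_influence(_viab(rows))


def test_swapping_cultures_negates_every_ratio(small_screen):
    tensor, _, _ = small_screen
    viab = normalize_to_baseline(tensor, background="alamethicin")
    fwd = compute_influence(viab)
    swapped_df = viab.data.copy()
    swapped_df["condition"] = swapped_df["condition"].map(
        lambda c: "monoculture" if c == "F01" else ("F01" if c == "monoculture" else c)
    )
    swapped = compute_influence(
        ViabilityTensor(data=swapped_df.loc[swapped_df["condition"].isin(["monoculture", "F01"])])
    )
    key = ["line", "drug", "dose_uM", "time_h"]
    merged = (
        fwd.unmasked.query("fibroblast == 'F01'")
        .merge(swapped.unmasked, on=key, suffixes=("_fwd", "_swp"))
    )
    assert len(merged) > 0
    assert np.allclose(merged["r_mean_fwd"], -merged["r_mean_swp"], atol=1e-12)


def test_noise_free_ratios_match_ledger_dead_fractions(small_cfg):
    cfg = dataclasses.replace(small_cfg, measurement_cv=0.0)
    tensor, _, truth = simulate_screen(cfg)
    viab = normalize_to_baseline(tensor, background="alamethicin")
    inf = compute_influence(viab)
    dead = truth.dead_fraction
    mono = dead.query("condition == 'monoculture'").rename(
        columns={"dead_fraction": "d_mono"}
    )[["line", "drug", "dose_uM", "time_h", "d_mono"]]
    co = dead.query("condition != 'monoculture'").rename(
        columns={"condition": "fibroblast", "dead_fraction": "d_co"}
    )
    expect = co.merge(mono, on=["line", "drug", "dose_uM", "time_h"])
    expect["r_true"] = np.log2((1.0 - expect["d_co"]) / (1.0 - expect["d_mono"]))
    merged = inf.unmasked.merge(
        expect, on=["line", "fibroblast", "drug", "dose_uM", "time_h"]
    )
    assert len(merged) == len(inf.unmasked)
    assert np.allclose(merged["r_mean"], merged["r_true"], atol=1e-10)


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

def _toy_inf(r_values, sigma=0.1, levels=None) -> InfluenceTensor:
    n = len(r_values)
    data = pd.DataFrame(
        {
            "line": "BL1",
            "fibroblast": "F01",
            "drug": [f"d{i}" for i in range(n)],
            "dose_uM": 1.0,
            "time_h": (levels if levels is not None else [8.0] * n),
            "subtype": "BL",
            "tissue": "lung",
            "drug_class": "topo",
            "r_mean": r_values,
            "n_pairs": 2,
            "n_reps": 2,
            "mask_reason": "",
        }
    )
    return InfluenceTensor(
        data=data, replicate_ratios=data.assign(replicate=1, r=data["r_mean"]),
        sigma=sigma, sigma_method="half_diff", n_masked=0,
        doses=[1.0], times=sorted(set(data["time_h"])), replicates=[1, 2],
    )


class TestHitCalling:
    def test_threshold_arithmetic_at_three_sigma(self):
        inf = _toy_inf([0.31, 0.29, -0.35])
        hits = call_hits(inf, k=3.0)
        assert set(hits.data["drug"]) == {"d0", "d2"}
        directions = hits.data.set_index("drug")["direction"]
        assert directions["d0"] == "desensitized"
        assert directions["d2"] == "sensitized"

    def test_infinite_k_empty_and_hits_monotone_in_k(self, small_influence):
        inf, _, _ = small_influence
        assert call_hits(inf, k=np.inf).n_hits == 0
        sets = [
            set(map(tuple, call_hits(inf, k=k).data[["drug", "dose_uM", "time_h"]].itertuples(index=False)))
            for k in (1.0, 2.0, 3.0)
        ]
        assert sets[0] >= sets[1] >= sets[2]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ScreenUsageError, match="positive"):
            call_hits(_toy_inf([0.1]), k=0.0)


def _fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x) / math.comb(n, row1)
        )

    p_obs = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if pmf(x) <= p_obs * (1 + 1e-12)
    )


class TestEnrichment:
    def test_fisher_p_matches_enumeration_oracle(self):
        a, b, c, d = 2, 8, 8, 2
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(_fisher_two_sided_oracle(a, b, c, d), rel=1e-9)

    def test_balanced_level_has_unit_odds_and_p_one(self):
        # two timepoints, identical hit proportions -> OR = 1, p = 1
        r = [0.4, 0.4, 0.0, 0.0, 0.01, -0.02, 0.4, 0.4, 0.0, 0.0, 0.02, -0.01]
        levels = [8.0] * 6 + [16.0] * 6
        inf = _toy_inf(r, sigma=0.1, levels=levels)
        hits = call_hits(inf, k=3.0)
        table = hit_enrichment(hits, inf, factor="time").set_index("level")
        assert table.loc[8.0, "odds_ratio"] == pytest.approx(1.0)
        assert table.loc[8.0, "p_value"] == pytest.approx(1.0)

    def test_inert_drug_class_depleted_in_default_screen(self, default_run):
        table = default_run.enrichment["drug_class"].set_index("level")
        row = table.loc["anti-estrogen"]
        assert row["odds_ratio"] < 1.0
        assert row["p_value"] < 0.05
        assert row["direction"] == "depleted"

    def test_unknown_factor_rejected(self, small_influence):
        inf, _, _ = small_influence
        with pytest.raises(ScreenUsageError, match="factor"):
            hit_enrichment(call_hits(inf), inf, factor="plate")


# ---------------------------------------------------------------------------
# Tiles and summaries
# ---------------------------------------------------------------------------

class TestTiles:
    def test_full_design_tile_has_72_entries(self, default_run):
        inf = default_run.influence
        tile = influence_tile(inf, "BL1", "F01", "D01")
        assert tile.size == 72
        assert tile.values.shape == (4, 9, 2)
        assert not np.isnan(tile.values).any()

    def test_missing_cells_propagate_as_nan_without_shrinking(self, small_screen):
        tensor, _, _ = small_screen
        viab = normalize_to_baseline(tensor, background="alamethicin")
        df = viab.data
        low = df.loc[df["drug"] == "D01", "dose_uM"].min()
        drop = (
            (df["condition"] == "F01") & (df["drug"] == "D01")
            & (df["dose_uM"] == low)
            & (df["time_h"] == 8.0) & (df["replicate"] == 1)
        )
        inf = compute_influence(ViabilityTensor(data=df.loc[~drop]))
        tile = influence_tile(inf, "BL1", "F01", "D01")
        assert tile.size == 4 * 3 * 2
        assert np.isnan(tile.values).sum() == 1

    def test_tile_means_reassemble_mean_influence(self, small_influence):
        inf, _, _ = small_influence
        summary = mean_influence(inf, group_by="all")
        fib, drug = "F01", "D01"
        tiles = [influence_tile(inf, line, fib, drug) for line in ("BL1", "ML1")]
        reassembled = np.mean([t.mean() for t in tiles])
        assert reassembled == pytest.approx(summary.tables["all"].loc[fib, drug], abs=1e-12)

    def test_unknown_key_rejected(self, small_influence):
        inf, _, _ = small_influence
        with pytest.raises(ScreenUsageError, match="no influence data"):
            influence_tile(inf, "BL1", "F99", "D01")


class TestMeanInfluence:
    def test_constant_field_gives_constant_summaries(self):
        inf = _toy_inf([0.25] * 6)
        summary = mean_influence(inf, group_by="all")
        assert np.allclose(summary.tables["all"].to_numpy(), 0.25)
        assert summary.grand_mean["all"]["F01"] == pytest.approx(0.25)

    def test_subtype_split_recombines_to_pooled_mean(self, default_run):
        inf = default_run.influence
        pooled = mean_influence(inf, group_by="all")
        split = mean_influence(inf, group_by="subtype")
        fib, drug = "F03", "D07"
        num = sum(
            split.tables[s].loc[fib, drug] * split.n_conditions[s].loc[fib, drug]
            for s in ("BL", "ML")
        )
        den = sum(split.n_conditions[s].loc[fib, drug] for s in ("BL", "ML"))
        assert pooled.tables["all"].loc[fib, drug] == pytest.approx(num / den)

    def test_tissue_sign_recovery_with_strong_effects(self):
        cfg = SimConfig(seed=21, tissue_effects=(1.2, -1.2, 1.4, -1.0, 1.0, -1.4, 1.1, -1.1))
        tensor, meta, truth = simulate_screen(cfg)
        viab = normalize_to_baseline(tensor, background="alamethicin")
        grand = mean_influence(compute_influence(viab), group_by="all").grand_mean["all"]
        for tissue, mu in truth.tissue_effects.items():
            fibs = [f for f, t in meta.tissue_map.items() if t == tissue]
            # positive priming shift kills more cells -> negative log2 ratio
            assert np.sign(grand[fibs].mean()) == -np.sign(mu)


# ---------------------------------------------------------------------------
# Tissue divergence
# ---------------------------------------------------------------------------

def _ks_exact_oracle(within, between):
    """Exact two-sample KS p by enumerating group assignments of pooled values."""
    pooled = np.asarray(list(within) + list(between))
    n_w = len(within)

    def ks_d(x, y):
        allv = np.sort(np.unique(pooled))
        cx = np.searchsorted(np.sort(x), allv, side="right") / len(x)
        cy = np.searchsorted(np.sort(y), allv, side="right") / len(y)
        return np.max(np.abs(cx - cy))

    d_obs = ks_d(np.asarray(within), np.asarray(between))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_w):
        total += 1
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        if ks_d(pooled[mask], pooled[~mask]) >= d_obs - 1e-12:
            count += 1
    return d_obs, count / total


def test_separated_correlation_sets_give_d_one_with_exact_enumeration_p():
    within, between = [0.9, 0.9], [0.1, 0.1]
    d_obs, p_oracle = _ks_exact_oracle(within, between)
    ks = stats.ks_2samp(within, between, method="exact")
    assert d_obs == pytest.approx(1.0)
    assert ks.statistic == pytest.approx(d_obs)
    assert ks.pvalue == pytest.approx(p_oracle, rel=1e-9)


def test_divergence_p_matches_enumeration_on_small_screen(small_influence):
    inf, meta, _ = small_influence
    result = tissue_divergence_test(inf, meta.tissue_map)
    d_oracle, p_oracle = _ks_exact_oracle(result.within, result.between)
    assert result.ks_statistic == pytest.approx(d_oracle)
    assert result.p_value == pytest.approx(p_oracle, rel=1e-6)


def test_identical_profiles_degenerate_to_d_zero():
    cfg = SimConfig(
        seed=3, n_lines_bl=1, n_lines_ml=1, n_fibroblasts=4, n_tissues=2,
        n_drugs=4, times=(0.0, 8.0), tissue_effects=(0.0, 0.0),
        fibroblast_effect_sd=0.0, pair_noise_sd=0.0, measurement_cv=0.0,
    )
    tensor, meta, _ = simulate_screen(cfg)
    inf = compute_influence(normalize_to_baseline(tensor, background="alamethicin"))
    result = tissue_divergence_test(inf, meta.tissue_map)
    assert result.ks_statistic == 0.0
    assert result.p_value == 1.0
    assert np.allclose(result.within, 1.0) and np.allclose(result.between, 1.0)


def test_divergence_requires_tissue_structure(small_influence):
    inf, meta, _ = small_influence
    with pytest.raises(ScreenUsageError, match="2 tissues"):
        tissue_divergence_test(inf, {f: "lung" for f in meta.tissue_map})
    distinct = {f: f"t{i}" for i, f in enumerate(meta.tissue_map)}
    with pytest.raises(ScreenUsageError, match=">= 2 fibroblasts"):
        tissue_divergence_test(inf, distinct)
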