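"""End-to-end orchestration: simulate/load -> normalize -> influence -> stats.

:func:`run_full_analysis` chains every stage of the screen analysis on one
configuration and returns a :class:`ReportBundle`; with an output directory it
also writes every table, the divergence/correlation JSONs and a manifest
carrying the seed, a configuration hash, library versions and the counts of
masked / imputed / floored data.  Re-running the same configuration and seed
reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import decompose, influence, mechanism, normalize, simulate
from .screen import (
    MONOCULTURE,
    PanelMetadata,
    ScreenTensor,
    ScreenUsageError,
    load_screen_table,
    validate_screen,
)

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis"]

logger = logging.getLogger("stromascreen")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``input_path`` (a deposited/exported screen table) or
    ``sim`` (a synthetic-screen configuration) must be set.  ``background``
    defaults to alamethicin subtraction for simulated screens and to none for
    loaded tables, whose normalization state is generally unknown.
    """

    sim: simulate.SimConfig | None = None
    input_path: str | None = None
    input_column_map: dict[str, str] | None = None
    input_sheet: str | int = 0
    background: str | None = None
    sigma_method: str = "half_diff"
    k_sigma: float = 3.0
    pca_components: int = 10
    pca_value: str = "viability"
    loading_tail: str = "positive"
    loading_quantile: float = 0.25
    min_overlap: float = 0.5
    n_perm: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def simulated(cls, seed: int = 0, **kwargs: Any) -> "RunConfig":
        return cls(sim=simulate.SimConfig(seed=seed), seed=seed, **kwargs)

    def validate(self) -> None:
        if (self.sim is None) == (self.input_path is None):
            raise ScreenUsageError(
                "exactly one of sim / input_path must be set in RunConfig"
            )
        if self.sim is not None:
            self.sim.validate()
        if self.k_sigma <= 0:
            raise ScreenUsageError("k_sigma must be positive")
        if self.pca_components < 1:
            raise ScreenUsageError("pca_components must be >= 1")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location is not analysis-relevant
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run plus the run manifest."""

    config: RunConfig
    tensor: ScreenTensor
    meta: PanelMetadata
    truth: simulate.GroundTruth | None
    validation: Any
    viability: normalize.ViabilityTensor
    influence: influence.InfluenceTensor
    hits: influence.HitTable
    hit_convention_counts: dict[str, dict[str, Any]]
    enrichment: dict[str, pd.DataFrame]
    profile_matrix: decompose.ProfileMatrix
    pca: decompose.PCAModel
    subtype_association: pd.DataFrame
    loading_enrichment: pd.DataFrame
    mean_influence: influence.MeanInfluenceSummary
    divergence: influence.DivergenceResult
    sensitivity_clustering: decompose.ClusterResult
    bh3_scores: pd.DataFrame | None = None
    priming_correlation: dict[str, float] | None = None
    h2ax_correlation: dict[str, float] | None = None
    combination: dict[str, dict[str, Any]] = field(default_factory=dict)
    growth_auc: pd.DataFrame | None = None
    manifest: dict[str, Any] = field(default_factory=dict)
    errors: list[dict[str, str]] = field(default_factory=list)


def _acquire(cfg: RunConfig):
    if cfg.sim is not None:
        tensor, meta, truth = simulate.simulate_screen(cfg.sim)
        background = cfg.background or "alamethicin"
        return tensor, meta, truth, background
    tensor = load_screen_table(
        cfg.input_path, column_map=cfg.input_column_map, sheet=cfg.input_sheet
    )
    meta = PanelMetadata.from_tensor(tensor)
    background = cfg.background or "none"
    return tensor, meta, None, background


def _mechanism_stages(cfg: RunConfig, bundle: ReportBundle) -> None:
    """Simulation-backed mechanism follow-up: BH3 priming, γ-H2AX, Bliss CI."""
    sim_cfg, truth = cfg.sim, bundle.truth
    assert sim_cfg is not None and truth is not None
    lines = [sim_cfg.lines[0]]
    if sim_cfg.n_lines_ml:
        lines.append(f"ML{1}")
    fibs = sim_cfg.fibroblasts

    # BH3 priming: score every (line, fibroblast) plus monoculture baselines
    pairs = [(ln, MONOCULTURE) for ln in lines] + [
        (ln, f) for ln in lines for f in fibs
    ]
    profiles = simulate.simulate_bh3_profiles(sim_cfg, pairs, truth)
    scores = pd.DataFrame(
        {
            "line": [p.line for p in profiles],
            "condition": [p.condition for p in profiles],
            "priming_score": [mechanism.priming_auc(p) for p in profiles],
        }
    )
    bundle.bh3_scores = scores
    mono_score = scores.loc[scores["condition"] == MONOCULTURE].set_index("line")[
        "priming_score"
    ]
    co = scores.loc[scores["condition"] != MONOCULTURE].copy()
    co["delta_priming"] = co["priming_score"] - co["line"].map(mono_score).to_numpy()
    grand = (
        bundle.influence.unmasked.groupby(["line", "fibroblast"])["r_mean"]
        .mean()
        .rename("delta_sensitivity")
    )
    co = co.join(grand, on=["line", "condition"]).dropna(subset=["delta_sensitivity"])
    r, p = mechanism.priming_sensitivity_correlation(
        co["delta_priming"].to_numpy(), co["delta_sensitivity"].to_numpy()
    )
    bundle.priming_correlation = {"r": r, "p_value": p, "n": len(co)}

    # γ-H2AX: genotoxic drugs, intensity independent of priming by default
    roster = sim_cfg.drug_roster()
    genotoxic = list(
        roster.index[roster["drug_class"] == "topoisomerase inhibitor"][:4]
    )
    h2ax_pairs = [(lines[0], MONOCULTURE)] + [(lines[0], f) for f in fibs]
    table = simulate.simulate_gamma_h2ax(sim_cfg, h2ax_pairs, genotoxic, truth)
    ratios = mechanism.gamma_h2ax_ratio(table)
    per_fib = (
        ratios.loc[ratios["mask_reason"] == ""]
        .groupby("fibroblast")["log2_ratio"]
        .mean()
        .rename("h2ax_ratio")
        .to_frame()
        .join(grand.loc[lines[0]].rename("delta_sensitivity"))
        .dropna()
    )
    r_obs, p_perm = mechanism.permutation_correlation(
        per_fib["h2ax_ratio"].to_numpy(),
        per_fib["delta_sensitivity"].to_numpy(),
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    bundle.h2ax_correlation = {"r": r_obs, "p_perm": p_perm, "n": len(per_fib)}

    # combination grids: Bliss-independent and priming-shifted examples
    topo = roster.index[roster["drug_class"] == "topoisomerase inhibitor"][0]
    mimetic_rows = roster.index[roster["drug_class"] == "BH3 mimetic"]
    partner = mimetic_rows[0] if len(mimetic_rows) else roster.index[-1]
    for label, interaction, shift in (
        ("bliss_independent", "bliss_independent", 0.0),
        ("priming_shifted", "priming_shifted", 1.0),
    ):
        grid = simulate.simulate_combination_grid(
            sim_cfg,
            (str(topo), str(partner)),
            interaction=interaction,
            priming_shift=shift,
            truth=truth,
            line=lines[0],
        )
        ci, defined = mechanism.ci_map(grid)
        bundle.combination[label] = {
            "drug_a": grid.drug_a,
            "drug_b": grid.drug_b,
            "ci": ci,
            "defined": defined,
            "median_ci": float(np.nanmedian(ci[defined & (grid.doses_a[:, None] > 0) & (grid.doses_b[None, :] > 0)])),
        }

    # growth: fibroblasts leave tumor fitness unchanged by default
    growth = simulate.simulate_growth_curves(
        sim_cfg, [(lines[0], MONOCULTURE)] + [(lines[0], f) for f in fibs[:4]]
    )
    bundle.growth_auc = normalize.growth_auc_table(growth)


def run_full_analysis(cfg: RunConfig) -> ReportBundle:
    """Execute every analysis stage in order and assemble the report bundle.

    Core stages (normalization, influence, hit calling, enrichment, PCA,
    divergence, clustering) run unconditionally; mechanism stages require a
    simulated run (they need assay-level generators) and record any failure in
    ``bundle.errors`` without aborting the bundle.
    """
    cfg.validate()
    errors: list[dict[str, str]] = []

    tensor, meta, truth, background = _acquire(cfg)
    validation = validate_screen(tensor, meta)
    normalizer = normalize.BaselineNormalizer(background=background)
    viability = normalizer.fit(tensor).transform(tensor)
    inf = influence.compute_influence(viability, sigma_method=cfg.sigma_method)
    hits = influence.call_hits(inf, k=cfg.k_sigma)

    convention_counts: dict[str, dict[str, Any]] = {}
    for method in influence.SIGMA_METHODS:
        sigma_m = inf.sigma_under(method)
        universe = inf.unmasked
        n = int((np.abs(universe["r_mean"]) > cfg.k_sigma * sigma_m).sum())
        convention_counts[method] = {"sigma": sigma_m, "n_hits": n}

    enrichment = {
        factor: influence.hit_enrichment(hits, inf, factor)
        for factor in ("time", "dose", "drug_class")
    }

    # the subtype overview decomposes the coculture response matrix itself;
    # the influence-ratio unfold is available behind the pca_value flag
    if cfg.pca_value == "influence":
        matrix = decompose.unfold_profiles(inf, value="influence")
    else:
        matrix = decompose.unfold_profiles(
            viability, value="viability", conditions="coculture"
        )
    pca = decompose.run_pca(matrix, n_components=cfg.pca_components)
    association = decompose.pc_subtype_association(pca, meta.subtype_map)
    best_pc = int(association.loc[association["p_value"].idxmin(), "pc"])
    load_enrich = decompose.loading_class_enrichment(
        pca, meta.class_map, pc=best_pc, tail=cfg.loading_tail,
        quantile=cfg.loading_quantile,
    )
    summary = influence.mean_influence(inf, group_by="all")
    divergence = influence.tissue_divergence_test(
        inf, meta.tissue_map, min_overlap=cfg.min_overlap
    )

    # monoculture sensitivity overview: max effect per (line, drug), z-scored
    max_eff = (
        viability.drug_rows()
        .query("condition == @MONOCULTURE")
        .groupby(["line", "drug", "dose_uM", "time_h"])["viability"]
        .mean()
        .groupby(["line", "drug"])
        .min()
        .rsub(1.0)
        .clip(lower=0.0)
        .unstack("drug")
    )
    z = (max_eff - max_eff.mean()) / max_eff.std(ddof=0).replace(0.0, 1.0)
    clustering = decompose.cluster_sensitivity(z)

    bundle = ReportBundle(
        config=cfg,
        tensor=tensor,
        meta=meta,
        truth=truth,
        validation=validation,
        viability=viability,
        influence=inf,
        hits=hits,
        hit_convention_counts=convention_counts,
        enrichment=enrichment,
        profile_matrix=matrix,
        pca=pca,
        subtype_association=association,
        loading_enrichment=load_enrich,
        mean_influence=summary,
        divergence=divergence,
        sensitivity_clustering=clustering,
        errors=errors,
    )

    if cfg.sim is not None:
        try:
            _mechanism_stages(cfg, bundle)
        except Exception as exc:  # pragma: no cover - defensive
            logger.exception("mechanism stage failed")
            errors.append({"stage": "mechanism", "error": repr(exc)})

    bundle.manifest = _manifest(cfg, bundle)
    if cfg.out_dir is not None:
        _write_outputs(Path(cfg.out_dir), bundle)
    return bundle


def _manifest(cfg: RunConfig, bundle: ReportBundle) -> dict[str, Any]:
    import sklearn

    from . import __version__

    pc12 = float(bundle.pca.explained_fraction[: min(2, bundle.pca.n_components)].sum())
    return {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "versions": {
            "stromascreen": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "counts": {
            "n_measurements": bundle.tensor.n_measurements,
            "n_drug_response_measurements": bundle.tensor.n_drug_response_measurements,
            "n_floored": bundle.viability.n_floored,
            "n_masked_influence": bundle.influence.n_masked,
            "n_imputed_cells": bundle.profile_matrix.n_imputed,
            "n_dropped_columns": len(bundle.profile_matrix.dropped_columns),
            "n_hits": bundle.hits.n_hits,
        },
        "sigma": bundle.influence.sigma,
        "sigma_method": bundle.influence.sigma_method,
        "hit_convention_counts": bundle.hit_convention_counts,
        "pc1_pc2_explained_fraction": pc12,
        "validation_valid": bundle.validation.valid,
        "errors": bundle.errors,
    }


def _write_outputs(out_dir: Path, bundle: ReportBundle) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.hits.data.to_csv(out_dir / "hits.csv", index=False)
    for factor, table in bundle.enrichment.items():
        table.to_csv(out_dir / f"enrichment_{factor}.csv", index=False)
    bundle.pca.scores.to_csv(out_dir / "pca_scores.csv")
    bundle.pca.loadings.to_csv(out_dir / "pca_loadings.csv")
    pd.DataFrame(
        {
            "pc": np.arange(1, bundle.pca.n_components + 1),
            "explained_fraction": bundle.pca.explained_fraction,
        }
    ).to_csv(out_dir / "pca_variance.csv", index=False)
    bundle.subtype_association.to_csv(out_dir / "subtype_association.csv", index=False)
    bundle.loading_enrichment.to_csv(out_dir / "loading_enrichment.csv", index=False)
    for name, table in bundle.mean_influence.tables.items():
        table.to_csv(out_dir / f"mean_influence_{name}.csv")
    (out_dir / "divergence.json").write_text(bundle.divergence.to_json())
    (out_dir / "validation.json").write_text(bundle.validation.to_json())
    (out_dir / "dendrogram_lines.nwk").write_text(
        bundle.sensitivity_clustering.row_newick
    )
    (out_dir / "dendrogram_drugs.nwk").write_text(
        bundle.sensitivity_clustering.col_newick
    )
    if bundle.bh3_scores is not None:
        bundle.bh3_scores.to_csv(out_dir / "bh3_priming_scores.csv", index=False)
    if bundle.priming_correlation is not None:
        (out_dir / "priming_correlation.json").write_text(
            json.dumps(bundle.priming_correlation, indent=2)
        )
    if bundle.h2ax_correlation is not None:
        (out_dir / "h2ax_correlation.json").write_text(
            json.dumps(bundle.h2ax_correlation, indent=2)
        )
    for label, combo in bundle.combination.items():
        pd.DataFrame(combo["ci"]).to_csv(out_dir / f"ci_map_{label}.csv", index=False)
        pd.DataFrame(combo["defined"]).to_csv(
            out_dir / f"ci_map_{label}_defined.csv", index=False
        )
    if bundle.growth_auc is not None:
        bundle.growth_auc.to_csv(out_dir / "growth_auc.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True, default=str)
    )
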