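"""Synthetic coculture drug-death screens with a ground-truth ledger.

The generator emulates the data-generating structure the analysis pipeline
assumes: a panel of basal-like (BL) and mesenchymal-like (ML) tumor lines
grown alone or with one of a panel of tissue-annotated fibroblasts, treated
with a drug x dose grid and read kinetically on a plate reader in replicate,
with vehicle and alamethicin control wells.

Fibroblast influence acts through a single mechanism: a signed mitochondrial
priming shift ``p`` carried by each fibroblast (tissue-level mean ``mu_tissue``
plus a per-fibroblast deviation ``eps``, plus per-pair interaction noise).
Positive ``p`` moves a tumor line closer to its apoptotic threshold, raising
the effective maximal kill and lowering the effective EC50 of every drug:

    logit(Emax_eff) = logit(Emax) + p          ln(EC50_eff) = ln(EC50) - g*p

with the coupling ``g`` fixed at 1.  Death commits after a delay and proceeds
exponentially, so the dead fraction of a well is

    D(t; dose) = Emax_eff * dose^h / (dose^h + EC50_eff^h)
                 * max(0, 1 - exp(-kappa * (t - tau)))

and the fluorescent signal is ``F0 * [(1 - D) * (1 - bg) + bg]`` times
multiplicative Gaussian measurement noise.  Alamethicin wells read the
background floor ``bg * F0``; vehicle wells stay at full signal.  Every draw
comes from streams derived from one global seed in a documented order, and a
:class:`GroundTruth` ledger records the realized parameters so downstream
estimates can be checked against what was simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .mechanism import (
    DEFAULT_BIM_DOSES,
    BH3Profile,
    CombinationGrid,
    NucleusIntensityTable,
)
from .screen import (
    ALAMETHICIN,
    MONOCULTURE,
    VEHICLE,
    PanelMetadata,
    ScreenTensor,
    ScreenUsageError,
)

__all__ = [
    "ConfigError",
    "SimConfig",
    "GroundTruth",
    "simulate_screen",
    "simulate_bh3_profiles",
    "simulate_gamma_h2ax",
    "simulate_combination_grid",
    "simulate_growth_curves",
    "GrowthCurveSet",
]


class ConfigError(ValueError):
    """A simulation configuration value is non-finite or out of range."""


# Drug-class roster: (class label, n drugs, conventional chemo?, inert?).
# 24 cytotoxic chemotherapies + 18 targeted agents; the anti-estrogen class is
# inert in receptor-negative tumor lines and exists to exercise depletion
# statistics.
_CLASS_ROSTER: tuple[tuple[str, int, bool, bool], ...] = (
    ("topoisomerase inhibitor", 6, True, False),
    ("microtubule poison", 6, True, False),
    ("platinum", 4, True, False),
    ("antimetabolite", 4, True, False),
    ("alkylating agent", 4, True, False),
    ("anti-estrogen", 4, False, True),
    ("CDK inhibitor", 3, False, False),
    ("PARP inhibitor", 3, False, False),
    ("kinase inhibitor", 5, False, False),
    ("BH3 mimetic", 3, False, False),
)

_TISSUE_NAMES = (
    "breast", "lung", "uterus", "skin", "bone", "liver", "heart", "prostate",
)

# Stream ids for the per-assay random generators spawned from the global seed.
_STREAM_SCREEN = 0
_STREAM_BH3 = 1
_STREAM_H2AX = 2
_STREAM_COMBO = 3
_STREAM_GROWTH = 4


def _rng(cfg: "SimConfig", stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(cfg.seed), spawn_key=(stream,))
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic screen; defaults are the study conditions.

    The default design is 3 BL + 3 ML tumor lines, 16 fibroblasts spanning 8
    tissues (two each), 42 drugs at four doses plus the two controls, read
    every 8 h to 72 h in duplicate — which yields 312,120 post-drug
    measurements.
    """

    # Panel design
    n_lines_bl: int = 3
    n_lines_ml: int = 3
    n_fibroblasts: int = 16
    n_tissues: int = 8
    n_drugs: int = 42
    doses: tuple[float, ...] = (0.1, 1.0, 3.2, 10.0)
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 73, 8))
    n_replicates: int = 2

    # Fibroblast influence (priming-shift hierarchy)
    tissue_effect_range: tuple[float, float] = (-1.5, 1.5)
    tissue_effects: tuple[float, ...] | None = None
    fibroblast_effect_sd: float = 0.3
    pair_noise_sd: float = 0.2
    priming_ec50_gamma: float = 1.0
    drug_specific_shifts: Mapping[tuple[str, str], float] | None = None

    # Per-(line, drug) pharmacology draws
    emax_range: tuple[float, float] = (0.3, 0.95)
    inert_emax: float = 0.02
    ec50_log10_range: tuple[float, float] = (-1.0, 1.0)
    hill_range: tuple[float, float] = (0.8, 2.5)
    delay_range_h: tuple[float, float] = (4.0, 16.0)
    rate_range_per_h: tuple[float, float] = (0.05, 0.2)
    subtype_sensitivity_shift: float = 0.8

    # Plate reader
    baseline_fluorescence: float = 1000.0
    measurement_cv: float = 0.05
    background_frac: float = 0.05

    # BH3 profiling
    bim_doses_uM: tuple[float, ...] = DEFAULT_BIM_DOSES
    bh3_midpoint_uM: float = 10.0
    bh3_slope: float = 1.0
    bh3_noise_sd_pct: float = 2.0

    # γ-H2AX imaging
    h2ax_nuclei_mean: int = 758
    h2ax_nuclei_range: tuple[int, int] = (93, 1632)
    h2ax_sigma: float = 0.4
    h2ax_coupling: float = 0.0

    # Combination grids
    combo_doses_uM: tuple[float, ...] = (0.0316, 0.1, 0.316, 1.0, 3.16, 10.0)
    interaction_margin: float = 0.25

    # Growth curves
    growth_times_h: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 96.0)
    growth_rate_per_h: float = 0.02
    growth_noise_cv: float = 0.05

    seed: int = 0

    # -- derived rosters ---------------------------------------------------
    @property
    def lines(self) -> list[str]:
        return [f"BL{i + 1}" for i in range(self.n_lines_bl)] + [
            f"ML{i + 1}" for i in range(self.n_lines_ml)
        ]

    @property
    def subtype_map(self) -> dict[str, str]:
        return {ln: ln[:2] for ln in self.lines}

    @property
    def fibroblasts(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_fibroblasts)]

    @property
    def tissues(self) -> list[str]:
        names = list(_TISSUE_NAMES)
        while len(names) < self.n_tissues:
            names.append(f"tissue{len(names) + 1}")
        return names[: self.n_tissues]

    @property
    def tissue_map(self) -> dict[str, str]:
        tissues = self.tissues
        return {
            fib: tissues[i % self.n_tissues]
            for i, fib in enumerate(self.fibroblasts)
        }

    @property
    def drugs(self) -> list[str]:
        return [f"D{i + 1:02d}" for i in range(self.n_drugs)]

    def drug_roster(self) -> pd.DataFrame:
        """Drug -> (class, conventional-chemo flag, inert flag).

        The full 42-drug panel uses the roster's per-class counts (24
        cytotoxic + 18 targeted); smaller panels cycle over the class labels
        so every class, the inert one included, stays represented.
        """
        if self.n_drugs == sum(c for _, c, _, _ in _CLASS_ROSTER):
            expanded: list[tuple[str, bool, bool]] = []
            for label, count, conv, inert in _CLASS_ROSTER:
                expanded.extend([(label, conv, inert)] * count)
            rows = list(expanded)
        else:
            labels = [(label, conv, inert) for label, _, conv, inert in _CLASS_ROSTER]
            rows = [labels[i % len(labels)] for i in range(self.n_drugs)]
        return pd.DataFrame(
            rows, columns=["drug_class", "conventional", "inert"], index=self.drugs
        ).rename_axis("drug")

    @property
    def class_map(self) -> dict[str, str]:
        return self.drug_roster()["drug_class"].to_dict()

    @property
    def post_times(self) -> list[float]:
        return [t for t in self.times if t > 0]

    @property
    def declared_post_drug_count(self) -> int:
        n_lines = self.n_lines_bl + self.n_lines_ml
        n_cond = 1 + self.n_fibroblasts
        per_culture = self.n_drugs * len(self.doses) + 2  # + vehicle, alamethicin
        return n_lines * n_cond * per_culture * len(self.post_times) * self.n_replicates

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None or isinstance(value, (str, Mapping)):
                continue
            arr = np.asarray(value, dtype=float) if not np.isscalar(value) else np.asarray([value], dtype=float)
            if not np.isfinite(arr).all():
                raise ConfigError(f"non-finite value in SimConfig.{f.name}")
        if min(self.n_lines_bl + self.n_lines_ml, self.n_fibroblasts, self.n_drugs) < 1:
            raise ConfigError("panel axes must be non-empty")
        if self.n_tissues < 1 or self.n_tissues > self.n_fibroblasts:
            raise ConfigError("need 1 <= n_tissues <= n_fibroblasts")
        if self.tissue_effects is not None and len(self.tissue_effects) != self.n_tissues:
            raise ConfigError("tissue_effects must have one entry per tissue")
        if any(d <= 0 for d in self.doses):
            raise ConfigError("doses must be positive")
        if 0.0 not in self.times or any(t < 0 for t in self.times):
            raise ConfigError("time grid must include 0 and be non-negative")
        if not (0 <= self.emax_range[0] <= self.emax_range[1] <= 1):
            raise ConfigError("emax_range must lie within [0, 1]")
        if not (0 <= self.inert_emax <= 1):
            raise ConfigError("inert_emax must lie within [0, 1]")
        if not (0 <= self.background_frac < 1):
            raise ConfigError("background_frac must lie within [0, 1)")
        if self.measurement_cv < 0 or self.rate_range_per_h[0] <= 0:
            raise ConfigError("measurement_cv must be >= 0 and death rates > 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """Ledger of every realized simulation parameter, for recovery tests.

    All entries are reproduced exactly under the same seed.  ``dead_fraction``
    is the noise-free dead-fraction trajectory per treated condition;
    ``pair_priming`` holds the effective priming shift of each
    (line, fibroblast) pair, monoculture excluded (it is 0 by construction).
    """

    seed: int
    tissue_effects: dict[str, float]
    priming_shift: dict[str, float]
    pair_priming: pd.DataFrame
    drug_params: pd.DataFrame
    effective_params: pd.DataFrame
    dead_fraction: pd.DataFrame

    def pair_priming_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (r.line, r.fibroblast): r.p_pair
            for r in self.pair_priming.itertuples(index=False)
        }

    def priming_for(self, line: str, condition: str) -> float:
        if condition == MONOCULTURE:
            return 0.0
        match = self.pair_priming.loc[
            (self.pair_priming["line"] == line)
            & (self.pair_priming["fibroblast"] == condition),
            "p_pair",
        ]
        if match.empty:
            raise ScreenUsageError(f"unknown (line, condition): {(line, condition)}")
        return float(match.iloc[0])

    def summary_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "tissue_effects": self.tissue_effects,
                "priming_shift": self.priming_shift,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

def _draw_parameters(cfg: SimConfig, rng: np.random.Generator):
    """Draw the hierarchy in documented order; returns all parameter arrays."""
    n_fib, n_tis = cfg.n_fibroblasts, cfg.n_tissues
    lines = cfg.lines
    n_lines, n_drugs = len(lines), cfg.n_drugs

    # 1) tissue-level priming means
    if cfg.tissue_effects is not None:
        mu = np.asarray(cfg.tissue_effects, dtype=float)
    else:
        mu = rng.uniform(*cfg.tissue_effect_range, size=n_tis)
    # 2) per-fibroblast deviations
    eps = rng.normal(0.0, cfg.fibroblast_effect_sd, size=n_fib)
    tissue_idx = np.arange(n_fib) % n_tis
    p_fib = mu[tissue_idx] + eps
    # 3) per-(line, fibroblast) interaction noise
    pair_noise = rng.normal(0.0, cfg.pair_noise_sd, size=(n_lines, n_fib))
    p_pair = p_fib[None, :] + pair_noise

    # 4) per-(line, drug) pharmacology
    roster = cfg.drug_roster()
    emax = rng.uniform(*cfg.emax_range, size=(n_lines, n_drugs))
    emax[:, roster["inert"].to_numpy()] = cfg.inert_emax
    ec50 = 10.0 ** rng.uniform(*cfg.ec50_log10_range, size=(n_lines, n_drugs))
    hill = rng.uniform(*cfg.hill_range, size=(n_lines, n_drugs))
    delay = rng.uniform(*cfg.delay_range_h, size=(n_lines, n_drugs))
    rate = rng.uniform(*cfg.rate_range_per_h, size=(n_lines, n_drugs))

    # BL lines get a sensitivity boost restricted to conventional chemo classes
    logit_emax = logit(np.clip(emax, 1e-9, 1 - 1e-9))
    is_bl = np.array([cfg.subtype_map[ln] == "BL" for ln in lines])
    conv = roster["conventional"].to_numpy()
    logit_emax[np.ix_(is_bl, conv)] += cfg.subtype_sensitivity_shift

    return mu, p_fib, p_pair, roster, logit_emax, ec50, hill, delay, rate


def simulate_screen(cfg: SimConfig) -> tuple[ScreenTensor, PanelMetadata, GroundTruth]:
    """Generate a full-factorial synthetic screen plus metadata and ledger.

    Wells comprise every (line, condition, drug, dose, replicate) combination,
    the per-culture vehicle and alamethicin control wells, a time-0 baseline
    reading for every well, and the post-drug time grid.  With the defaults
    this yields the declared 312,120 post-drug drug-response measurements.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_SCREEN)
    lines, fibs, drugs = cfg.lines, cfg.fibroblasts, cfg.drugs
    conditions = [MONOCULTURE] + fibs
    doses = np.asarray(cfg.doses, dtype=float)
    post_t = np.asarray(cfg.post_times, dtype=float)
    reps = list(range(1, cfg.n_replicates + 1))
    L, C, G, Dd, T, R = (
        len(lines), len(conditions), len(drugs), len(doses), len(post_t), len(reps),
    )

    mu, p_fib, p_pair_fib, roster, logit_emax, ec50, hill, delay, rate = (
        _draw_parameters(cfg, rng)
    )

    # effective pharmacology per (line, condition, drug); monoculture has p = 0
    p_pair = np.zeros((L, C))
    p_pair[:, 1:] = p_pair_fib
    logit_eff = logit_emax[:, None, :] + p_pair[:, :, None]
    ec50_eff = ec50[:, None, :] * np.exp(-cfg.priming_ec50_gamma * p_pair[:, :, None])
    if cfg.drug_specific_shifts:
        for (fib, drug), dp in cfg.drug_specific_shifts.items():
            ci, gi = conditions.index(fib), drugs.index(drug)
            logit_eff[:, ci, gi] += dp
            ec50_eff[:, ci, gi] *= np.exp(-cfg.priming_ec50_gamma * dp)
    emax_eff = expit(logit_eff)

    # noise-free dead fraction D(line, condition, drug, dose, time)
    h = hill[:, None, :, None]
    with np.errstate(over="ignore"):
        dose_term = 1.0 / (1.0 + (ec50_eff[:, :, :, None] / doses) ** h)
    kin = np.clip(
        1.0 - np.exp(-rate[:, None, :, None, None]
                     * (post_t - delay[:, None, :, None, None])),
        0.0,
        None,
    )  # (L, 1, G, 1, T)
    dead = emax_eff[:, :, :, None, None] * dose_term[:, :, :, :, None] * kin

    bg, f0, cv = cfg.background_frac, cfg.baseline_fluorescence, cfg.measurement_cv
    signal = (1.0 - dead) * (1.0 - bg) + bg

    # 5) measurement noise, drawn in documented block order
    z_drug_post = rng.standard_normal((L, C, G, Dd, T, R))
    z_drug_base = rng.standard_normal((L, C, G, Dd, R))
    z_ctrl_post = rng.standard_normal((L, C, 2, T, R))
    z_ctrl_base = rng.standard_normal((L, C, 2, R))

    def _block(index_levels, names, values):
        idx = pd.MultiIndex.from_product(index_levels, names=names)
        return pd.DataFrame({"fluorescence": values.ravel()}, index=idx).reset_index()

    drug_post = _block(
        [lines, conditions, drugs, doses, post_t, reps],
        ["line", "condition", "drug", "dose_uM", "time_h", "replicate"],
        f0 * signal[..., None] * (1.0 + cv * z_drug_post),
    )
    drug_base = _block(
        [lines, conditions, drugs, doses, [0.0], reps],
        ["line", "condition", "drug", "dose_uM", "time_h", "replicate"],
        f0 * (1.0 + cv * z_drug_base),
    )
    ctrl_levels = [VEHICLE, ALAMETHICIN]
    ctrl_signal = np.empty((L, C, 2, T, R))
    ctrl_signal[:, :, 0] = 1.0  # vehicle: no death, no drift
    ctrl_signal[:, :, 1] = bg  # alamethicin: background floor
    ctrl_post = _block(
        [lines, conditions, ctrl_levels, [0.0], post_t, reps],
        ["line", "condition", "drug", "dose_uM", "time_h", "replicate"],
        f0 * ctrl_signal * (1.0 + cv * z_ctrl_post),
    )
    ctrl_base = _block(
        [lines, conditions, ctrl_levels, [0.0], [0.0], reps],
        ["line", "condition", "drug", "dose_uM", "time_h", "replicate"],
        f0 * (1.0 + cv * z_ctrl_base),
    )

    df = pd.concat([drug_post, drug_base, ctrl_post, ctrl_base], ignore_index=True)
    df["fluorescence"] = df["fluorescence"].clip(lower=0.0)
    df["subtype"] = df["line"].map(cfg.subtype_map)
    tissue_map = cfg.tissue_map
    df["tissue"] = df["condition"].map(lambda c: tissue_map.get(c, ""))
    class_map = cfg.class_map
    df["drug_class"] = df["drug"].map(lambda d: class_map.get(d, ""))

    design = {
        "n_lines": L,
        "n_conditions": C,
        "n_drugs": G,
        "n_doses": Dd,
        "n_post_times": T,
        "n_replicates": R,
        "declared_post_drug_count": cfg.declared_post_drug_count,
    }
    tensor = ScreenTensor.from_frame(df, design=design, validate=True)
    meta = PanelMetadata(
        subtype_map=cfg.subtype_map, tissue_map=tissue_map, class_map=class_map
    )

    tissues = cfg.tissues
    truth = GroundTruth(
        seed=cfg.seed,
        tissue_effects={tissues[i]: float(mu[i]) for i in range(cfg.n_tissues)},
        priming_shift={fibs[i]: float(p_fib[i]) for i in range(len(fibs))},
        pair_priming=pd.DataFrame(
            {
                "line": np.repeat(lines, len(fibs)),
                "fibroblast": np.tile(fibs, L),
                "p_pair": p_pair[:, 1:].ravel(),
            }
        ),
        drug_params=pd.DataFrame(
            {
                "line": np.repeat(lines, G),
                "drug": np.tile(drugs, L),
                "drug_class": np.tile(roster["drug_class"].to_numpy(), L),
                "conventional": np.tile(roster["conventional"].to_numpy(), L),
                "inert": np.tile(roster["inert"].to_numpy(), L),
                "emax": expit(logit_emax).ravel(),
                "ec50_uM": ec50.ravel(),
                "hill": hill.ravel(),
                "delay_h": delay.ravel(),
                "rate_per_h": rate.ravel(),
            }
        ),
        effective_params=(
            pd.MultiIndex.from_product(
                [lines, conditions, drugs], names=["line", "condition", "drug"]
            )
            .to_frame(index=False)
            .assign(emax_eff=emax_eff.ravel(), ec50_eff_uM=ec50_eff.ravel())
        ),
        dead_fraction=(
            pd.MultiIndex.from_product(
                [lines, conditions, drugs, doses, post_t],
                names=["line", "condition", "drug", "dose_uM", "time_h"],
            )
            .to_frame(index=False)
            .assign(dead_fraction=dead.ravel())
        ),
    )
    return tensor, meta, truth


# ---------------------------------------------------------------------------
# BH3 profiles
# ---------------------------------------------------------------------------

def simulate_bh3_profiles(
    cfg: SimConfig,
    conditions: Sequence[tuple[str, str]],
    truth: GroundTruth,
) -> list[BH3Profile]:
    """BH3-profiling dose series for the requested (line, condition) pairs.

    Expected cytochrome c retention follows a descending logistic in log BIM
    dose whose midpoint decreases with the condition's priming shift p
    (ln midpoint = ln(bh3_midpoint_uM) - p), so more-primed conditions release
    cytochrome c at lower peptide dose.  Additive Gaussian noise
    (``bh3_noise_sd_pct``) is clipped to [0, 100].
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_BH3)
    doses = np.asarray(cfg.bim_doses_uM, dtype=float)
    profiles = []
    for line, condition in conditions:
        p = truth.priming_for(line, condition)
        midpoint = cfg.bh3_midpoint_uM * np.exp(-p)
        release = 1.0 / (1.0 + (midpoint / doses) ** cfg.bh3_slope)
        retention = 100.0 * (1.0 - release)
        noise = rng.normal(0.0, cfg.bh3_noise_sd_pct, size=doses.shape + (3,))
        retention = np.clip(retention + noise[..., 0], 0.0, 100.0)
        vehicle = float(np.clip(100.0 + noise[0, 1], 0.0, 100.0))
        ala = float(np.clip(0.0 + noise[0, 2], 0.0, 100.0))
        profiles.append(
            BH3Profile(
                line=line,
                condition=condition,
                bim_doses_uM=tuple(doses),
                retention_pct=tuple(retention),
                vehicle_pct=vehicle,
                alamethicin_pct=ala,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# γ-H2AX nucleus tables
# ---------------------------------------------------------------------------

def simulate_gamma_h2ax(
    cfg: SimConfig,
    conditions: Sequence[tuple[str, str]],
    drugs: Sequence[str],
    truth: GroundTruth,
    times: Sequence[float] = (8.0, 24.0, 48.0, 72.0),
) -> NucleusIntensityTable:
    """Per-nucleus γ-H2AX intensities for genotoxic-drug exposures.

    By default intensity is *independent* of the priming shift — identical
    drug/time means in mono- and coculture — reproducing the negative control
    for the drug-bioavailability mechanism; ``h2ax_coupling`` couples the
    coculture mean to p for power analyses.  Per-nucleus intensities are
    lognormal (shape ``h2ax_sigma``); nucleus counts are lognormal with the
    configured mean, truncated to the configured range.
    """
    cfg.validate()
    known = set(cfg.drugs)
    unknown = [d for d in drugs if d not in known]
    if unknown:
        raise ScreenUsageError(f"unknown drug(s): {unknown}")
    rng = _rng(cfg, _STREAM_H2AX)
    lo, hi = cfg.h2ax_nuclei_range
    # drug-level intensity means, drawn once per requested drug
    base_logmean = {d: rng.normal(np.log(500.0), 0.3) for d in drugs}
    rows = []
    for line, condition in conditions:
        p = truth.priming_for(line, condition)
        for drug in drugs:
            for t in times:
                logmean = base_logmean[drug] + 0.25 * np.log1p(t / 8.0)
                if condition != MONOCULTURE:
                    logmean += cfg.h2ax_coupling * p
                n = int(
                    np.clip(
                        round(
                            float(
                                rng.lognormal(
                                    np.log(cfg.h2ax_nuclei_mean) - 0.45**2 / 2, 0.45
                                )
                            )
                        ),
                        lo,
                        hi,
                    )
                )
                intensities = np.exp(logmean + cfg.h2ax_sigma * rng.standard_normal(n))
                rows.append(
                    pd.DataFrame(
                        {
                            "line": line,
                            "condition": condition,
                            "drug": drug,
                            "time_h": t,
                            "intensity": intensities,
                        }
                    )
                )
    return NucleusIntensityTable(data=pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Combination grids
# ---------------------------------------------------------------------------

def simulate_combination_grid(
    cfg: SimConfig,
    pair: tuple[str, str],
    interaction: str = "bliss_independent",
    priming_shift: float = 0.0,
    margin: float | None = None,
    noise_cv: float | None = None,
    truth: GroundTruth | None = None,
    line: str | None = None,
) -> CombinationGrid:
    """Observed-viability grid for a two-drug combination.

    Monotherapy effects follow each drug's Hill curve (taken from the ledger
    when ``truth`` and ``line`` are given, else drawn deterministically from
    the combination stream).  Under ``bliss_independent`` the joint effect is
    exactly A + B - A*B plus measurement noise; under ``priming_shifted`` it
    exceeds (priming_shift > 0) or falls below (priming_shift < 0) the Bliss
    expectation by the configured multiplicative ``margin``.
    """
    cfg.validate()
    if interaction not in {"bliss_independent", "priming_shifted"}:
        raise ScreenUsageError(f"unknown interaction model {interaction!r}")
    rng = _rng(cfg, _STREAM_COMBO)
    margin = cfg.interaction_margin if margin is None else margin
    noise_cv = cfg.measurement_cv if noise_cv is None else noise_cv

    params: dict[str, tuple[float, float, float]] = {}
    for drug in pair:
        if truth is not None and line is not None:
            row = truth.drug_params.loc[
                (truth.drug_params["line"] == line)
                & (truth.drug_params["drug"] == drug)
            ]
            if row.empty:
                raise ScreenUsageError(f"no simulated parameters for {(line, drug)}")
            params[drug] = (
                float(row["emax"].iloc[0]),
                float(row["ec50_uM"].iloc[0]),
                float(row["hill"].iloc[0]),
            )
        else:
            params[drug] = (
                float(rng.uniform(0.5, 0.9)),
                float(10.0 ** rng.uniform(-0.5, 0.5)),
                float(rng.uniform(1.0, 2.0)),
            )

    dose_axis = np.concatenate([[0.0], np.sort(np.asarray(cfg.combo_doses_uM))])

    def _effect(drug: str, d: np.ndarray) -> np.ndarray:
        emax, ec50, h = params[drug]
        out = np.zeros_like(d)
        pos = d > 0
        out[pos] = emax / (1.0 + (ec50 / d[pos]) ** h)
        return out

    fa = _effect(pair[0], dose_axis)
    fb = _effect(pair[1], dose_axis)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    observed = expected.copy()
    if interaction == "priming_shifted" and priming_shift != 0.0:
        # the priming shift needs both drugs on board: monotherapy margins
        # keep their Hill effects, only true combination cells deviate
        factor = 1.0 + margin if priming_shift > 0 else 1.0 - margin
        both = (dose_axis[:, None] > 0) & (dose_axis[None, :] > 0)
        observed[both] = np.clip(expected[both] * factor, 0.0, 1.0)
    viability = 1.0 - observed
    if noise_cv > 0:
        viability = viability * (1.0 + noise_cv * rng.standard_normal(viability.shape))
    viability = np.clip(viability, 0.0, None)
    return CombinationGrid(
        drug_a=pair[0],
        drug_b=pair[1],
        doses_a=dose_axis,
        doses_b=dose_axis.copy(),
        viability=viability,
    )


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurveSet:
    """Kinetic growth fluorescence per (line, condition, replicate)."""

    data: pd.DataFrame  # columns: line, condition, time_h, replicate, fluorescence

    def curve(self, line: str, condition: str, replicate: int) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data.loc[
            (self.data["line"] == line)
            & (self.data["condition"] == condition)
            & (self.data["replicate"] == replicate)
        ].sort_values("time_h")
        if sub.empty:
            raise ScreenUsageError(f"no growth curve for {(line, condition, replicate)}")
        return sub["time_h"].to_numpy(), sub["fluorescence"].to_numpy()


def simulate_growth_curves(
    cfg: SimConfig,
    pairs: Sequence[tuple[str, str]],
    modifiers: Mapping[tuple[str, str], float] | None = None,
    n_replicates: int = 3,
) -> GrowthCurveSet:
    """Exponential growth traces with optional per-pair rate modifiers.

    A modifier of 0 (the default: fibroblasts do not change tumor fitness)
    gives coculture and monoculture identical expected trajectories; a
    negative modifier slows growth and lowers the AUC.
    """
    cfg.validate()
    rng = _rng(cfg, _STREAM_GROWTH)
    modifiers = dict(modifiers or {})
    times = np.asarray(cfg.growth_times_h, dtype=float)
    rows = []
    for line, condition in pairs:
        mod = modifiers.get((line, condition), 0.0)
        expected = cfg.baseline_fluorescence * np.exp(
            cfg.growth_rate_per_h * (1.0 + mod) * times
        )
        for rep in range(1, n_replicates + 1):
            noisy = expected * (
                1.0 + cfg.growth_noise_cv * rng.standard_normal(times.shape)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "line": line,
                        "condition": condition,
                        "time_h": times,
                        "replicate": rep,
                        "fluorescence": np.clip(noisy, 0.0, None),
                    }
                )
            )
    return GrowthCurveSet(data=pd.concat(rows, ignore_index=True))
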