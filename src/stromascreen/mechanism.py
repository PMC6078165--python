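"""Mechanism statistics: mitochondrial priming, Bliss synergy, randomization nulls.

Covers the downstream mechanistic readouts of a coculture screen:

* BH3-profiling dose series (% cytochrome c retention vs BIM peptide dose)
  summarized into a dimensionless priming score by integrating cytochrome c
  *release* over log10 dose;
* Pearson and permutation-null correlations linking priming shifts or
  γ-H2AX intensity shifts to screen-measured drug-sensitivity shifts;
* Bliss-independence expected effects and combination-index (CI) maps for
  two-drug dose grids.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import MONOCULTURE, ScreenUsageError

__all__ = [
    "BH3Profile",
    "CombinationGrid",
    "NucleusIntensityTable",
    "priming_auc",
    "priming_sensitivity_correlation",
    "permutation_correlation",
    "bliss_expected",
    "combination_index",
    "ci_map",
    "gamma_h2ax_ratio",
]

#: BIM peptide dose series used by the iBH3 assay, in μM.
DEFAULT_BIM_DOSES = (100.0, 33.0, 10.0, 3.3, 1.0, 0.33)


@dataclass
class BH3Profile:
    """Cytochrome c retention of one (line, condition) across a BIM dose series.

    ``retention_pct`` is aligned with ``bim_doses_uM``; values are percentages
    in [0, 100].  ``vehicle_pct`` / ``alamethicin_pct`` hold the DMSO and
    full-permeabilization control retentions (≈100 and ≈0 respectively).
    """

    line: str
    condition: str
    bim_doses_uM: tuple[float, ...] = DEFAULT_BIM_DOSES
    retention_pct: tuple[float, ...] = ()
    vehicle_pct: float = 100.0
    alamethicin_pct: float = 0.0

    def __post_init__(self) -> None:
        doses = np.asarray(self.bim_doses_uM, dtype=float)
        if (doses <= 0).any():
            raise ValueError("BIM doses must be strictly positive")
        if len(self.retention_pct) != len(self.bim_doses_uM):
            raise ValueError("retention series must align with the dose series")


@dataclass
class CombinationGrid:
    """Observed fractional viability over a dose x dose grid for two drugs.

    Dose vectors are ascending and include 0 (the monotherapy margins).
    ``viability[i, j]`` is the observed fractional viability at
    ``(doses_a[i], doses_b[j])``; ``effect_a``/``effect_b`` are the monotherapy
    fractional effects (1 - viability) used for the Bliss expectation, by
    default read off the grid's dose-0 margins.
    """

    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    effect_a: np.ndarray | None = None
    effect_b: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.viability.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("viability grid must be doses_a x doses_b")
        if self.effect_a is None:
            if self.doses_a[0] != 0 or self.doses_b[0] != 0:
                raise ValueError("dose-0 margins required to derive monotherapy effects")
            self.effect_a = 1.0 - self.viability[:, 0]
            self.effect_b = 1.0 - self.viability[0, :]
        self.effect_a = np.asarray(self.effect_a, dtype=float)
        self.effect_b = np.asarray(self.effect_b, dtype=float)

    def transpose(self) -> "CombinationGrid":
        """Swap drugs A and B (transposes the grid)."""
        return CombinationGrid(
            drug_a=self.drug_b,
            drug_b=self.drug_a,
            doses_a=self.doses_b.copy(),
            doses_b=self.doses_a.copy(),
            viability=self.viability.T.copy(),
            effect_a=self.effect_b.copy(),
            effect_b=self.effect_a.copy(),
        )


@dataclass
class NucleusIntensityTable:
    """Per-nucleus γ-H2AX intensities with (line, condition, drug, time) labels."""

    data: pd.DataFrame  # columns: line, condition, drug, time_h, intensity

    REQUIRED = ("line", "condition", "drug", "time_h", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"nucleus table missing column(s): {missing}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("nuclear intensities must be non-negative")

    def condition_means(self) -> pd.DataFrame:
        """Mean per-nucleus intensity per (line, condition, drug, time)."""
        return (
            self.data.groupby(["line", "condition", "drug", "time_h"])["intensity"]
            .mean()
            .reset_index()
        )


# ---------------------------------------------------------------------------
# Priming
# ---------------------------------------------------------------------------

def priming_auc(profile: BH3Profile) -> float:
    """Score mitochondrial priming as normalized AUC of cytochrome c release.

    Release fraction (1 - retention/100) is integrated by the trapezoid rule
    over log10 BIM dose and divided by the log10 dose span, so the score lives
    in [0, 1]: 0 = full retention at every dose (unprimed), 1 = complete
    release everywhere (maximally primed).
    """
    retention = np.asarray(profile.retention_pct, dtype=float)
    if len(retention) < 2:
        raise ScreenUsageError("priming score needs at least 2 BIM doses")
    if (retention < 0).any() or (retention > 100).any():
        raise ValueError("retention values must lie within [0, 100]")
    log_dose = np.log10(np.asarray(profile.bim_doses_uM, dtype=float))
    order = np.argsort(log_dose)
    x = log_dose[order]
    release = 1.0 - retention[order] / 100.0
    span = x[-1] - x[0]
    if span <= 0:
        raise ScreenUsageError("BIM doses must span more than one log10 value")
    return float(np.trapezoid(release, x) / span)


def priming_sensitivity_correlation(
    delta_priming: Sequence[float], delta_sensitivity: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided t-test p) between priming and sensitivity shifts.

    ``delta_priming`` is the coculture-minus-monoculture priming-score change
    per condition; ``delta_sensitivity`` the matching mean influence (log2
    coculture:monoculture viability ratio).  Returns ``(nan, nan)``-flagged
    result via ValueError when either vector is constant.
    """
    x = np.asarray(delta_priming, dtype=float)
    y = np.asarray(delta_sensitivity, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ScreenUsageError("need >= 3 paired conditions of equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def permutation_correlation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = None,
    max_exact: int = 50_000,
) -> tuple[float, float]:
    """Pearson correlation with a permutation-null two-sided p-value.

    The null is built by permuting ``y``.  When the total number of
    permutations n! is at most ``max_exact`` the null is enumerated
    exhaustively and the p-value is exact (#{|r_perm| >= |r_obs|} / n!,
    the identity permutation included); otherwise ``n_perm`` random
    permutations give p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ScreenUsageError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ScreenUsageError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in input")
    n = len(x)

    xc = x - x.mean()
    xs = xc / math.sqrt(float(xc @ xc))

    def _r(yvec: np.ndarray) -> float:
        yc = yvec - yvec.mean()
        denom = math.sqrt(float(yc @ yc))
        return float(xs @ yc / denom)

    r_obs = _r(y)
    if math.factorial(n) <= max_exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_r(y[list(perm)])) >= abs(r_obs) - 1e-12:
                count += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if abs(_r(rng.permutation(y))) >= abs(r_obs) - 1e-12:
            exceed += 1
    return r_obs, (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Bliss independence
# ---------------------------------------------------------------------------

def bliss_expected(f_a: float | np.ndarray, f_b: float | np.ndarray) -> float | np.ndarray:
    """Expected joint fractional effect of independent drugs: A + B - A*B."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if ((f_a < 0) | (f_a > 1) | (f_b < 0) | (f_b > 1)).any():
        raise ScreenUsageError("fractional effects must lie within [0, 1]")
    out = f_a + f_b - f_a * f_b
    return float(out) if out.ndim == 0 else out


def combination_index(observed_effect: float, f_a: float, f_b: float) -> float:
    """CI = observed fractional effect / Bliss-expected effect.

    CI > 1 denotes synergy (more killing than independence predicts), CI < 1
    antagonism.  NaN is returned (flagged, not raised) when the expectation is
    0, i.e. both monotherapies are ineffective.
    """
    expected = bliss_expected(f_a, f_b)
    if expected == 0:
        return float("nan")
    return float(observed_effect / expected)


def ci_map(grid: CombinationGrid) -> tuple[np.ndarray, np.ndarray]:
    """Combination-index matrix over a dose x dose grid, with undefined flags.

    The Bliss expectation in each cell uses the grid's monotherapy effect
    vectors (its dose-0 margins).  Returns ``(ci, defined)`` where ``ci`` has
    NaN and ``defined`` is False wherever the expectation is 0 — notably the
    dose-0 row/column against an ineffective partner.
    """
    if grid.effect_a is None or grid.effect_b is None:  # pragma: no cover
        raise ScreenUsageError("combination grid lacks monotherapy margins")
    fa = np.clip(grid.effect_a, 0.0, 1.0)
    fb = np.clip(grid.effect_b, 0.0, 1.0)
    expected = bliss_expected(fa[:, None], fb[None, :])
    observed = 1.0 - grid.viability
    defined = expected > 0
    ci = np.full(expected.shape, np.nan)
    np.divide(observed, expected, out=ci, where=defined)
    return ci, defined


# ---------------------------------------------------------------------------
# γ-H2AX
# ---------------------------------------------------------------------------

def gamma_h2ax_ratio(table: NucleusIntensityTable) -> pd.DataFrame:
    """log2 coculture:monoculture ratio of mean nuclear γ-H2AX intensity.

    Summarizes each (line, condition, drug, time) to its mean per-nucleus
    intensity, then pairs every fibroblast coculture with the matching
    monoculture of the same (line, drug, time).  Cocultures without a matched
    monoculture are reported masked (NaN ratio) with a reason column.
    """
    means = table.condition_means()
    mono = means.loc[means["condition"] == MONOCULTURE].rename(
        columns={"intensity": "intensity_mono"}
    )[["line", "drug", "time_h", "intensity_mono"]]
    co = means.loc[means["condition"] != MONOCULTURE].rename(
        columns={"condition": "fibroblast", "intensity": "intensity_co"}
    )
    merged = co.merge(mono, on=["line", "drug", "time_h"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["log2_ratio"] = np.log2(merged["intensity_co"] / merged["intensity_mono"])
    merged["mask_reason"] = ""
    missing = merged["intensity_mono"].isna()
    merged.loc[missing, "mask_reason"] = "no matched monoculture"
    nonpos = ~missing & (
        (merged["intensity_mono"] <= 0) | (merged["intensity_co"] <= 0)
    )
    merged.loc[nonpos, "mask_reason"] = "non-positive mean intensity"
    merged.loc[missing | nonpos, "log2_ratio"] = np.nan
    return merged[
        ["line", "fibroblast", "drug", "time_h", "intensity_co", "intensity_mono",
         "log2_ratio", "mask_reason"]
    ]
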