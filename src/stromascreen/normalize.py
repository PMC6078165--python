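"""Kinetic normalization: raw fluorescence -> per-well relative viability.

Each well's post-drug readings are divided by that same well's pre-drug
(time-0) baseline, optionally after subtracting the culture's alamethicin
background floor:

    v(t) = (F(t) - B) / (F0 - B)

where B is the mean post-drug fluorescence of the matching alamethicin wells
(or 0 when background subtraction is off).  Negative values are floored at 0
(dead cannot be deader) and floor events are counted.  The module also
summarizes monoculture dose-response (Hill fits for EC50 / maximal effect)
and computes trapezoidal growth AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, TransformerMixin

from .screen import (
    ALAMETHICIN,
    CONTROL_DRUGS,
    MONOCULTURE,
    IntegrityError,
    ScreenTensor,
    ScreenUsageError,
)

__all__ = [
    "DegenerateWellError",
    "ViabilityTensor",
    "BaselineNormalizer",
    "normalize_to_baseline",
    "DoseResponseFit",
    "HillCurveFitter",
    "fit_dose_response",
    "dose_response_table",
    "max_fractional_decrease",
    "GrowthCurve",
    "growth_auc",
    "growth_auc_table",
]

_WELL_KEY = ["line", "condition", "drug", "dose_uM", "replicate"]


class DegenerateWellError(ValueError):
    """A well's baseline does not exceed the background floor (F0 <= B)."""


@dataclass
class ViabilityTensor:
    """Relative viability per post-drug measurement, with provenance columns.

    ``data`` carries the screen's key and annotation columns plus
    ``viability``, the well baseline ``baseline`` and the background ``background``
    used.  ``n_floored`` counts values raised to the 0 floor.
    """

    data: pd.DataFrame
    background_mode: str = "none"
    n_floored: int = 0
    annotations: dict[str, Any] = field(default_factory=dict)

    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    def drug_rows(self) -> pd.DataFrame:
        """Rows for real drugs (controls excluded)."""
        return self.data.loc[~self.data["drug"].isin(CONTROL_DRUGS)]


class BaselineNormalizer(BaseEstimator, TransformerMixin):
    """Per-well baseline normalization with optional alamethicin background.

    Parameters
    ----------
    background : {"none", "alamethicin"}
        With ``"alamethicin"``, the mean post-drug fluorescence of the
        matching (line, condition) alamethicin wells is subtracted from both
        numerator and denominator; use ``"none"`` for tables whose
        normalization state is unknown, to avoid double-correction.

    Attributes
    ----------
    background_ : pandas.Series
        Fitted background per (line, condition).
    n_floored_ : int
        Count of negative viability values floored to 0 during transform.
    """

    def __init__(self, background: str = "none"):
        self.background = background

    def fit(self, tensor: ScreenTensor, y: None = None) -> "BaselineNormalizer":
        if self.background not in {"none", "alamethicin"}:
            raise ScreenUsageError(
                f"background must be 'none' or 'alamethicin', got {self.background!r}"
            )
        df = tensor.data
        cultures = df[["line", "condition"]].drop_duplicates()
        idx = pd.MultiIndex.from_frame(cultures)
        if self.background == "alamethicin":
            ala = df.loc[(df["drug"] == ALAMETHICIN) & (df["time_h"] > 0)]
            bg = ala.groupby(["line", "condition"])["fluorescence"].mean()
            missing = idx.difference(bg.index)
            if len(missing):
                raise IntegrityError(
                    "no alamethicin control wells for culture(s): "
                    f"{list(missing[:5])}"
                )
            self.background_ = bg
        else:
            self.background_ = pd.Series(0.0, index=idx, name="fluorescence")
        return self

    def transform(self, tensor: ScreenTensor) -> ViabilityTensor:
        df = tensor.data
        base = (
            df.loc[df["time_h"] == 0]
            .set_index(_WELL_KEY)["fluorescence"]
            .rename("baseline")
        )
        post = df.loc[df["time_h"] > 0].copy()
        post = post.join(base, on=_WELL_KEY)
        if post["baseline"].isna().any():
            bad = (
                post.loc[post["baseline"].isna(), _WELL_KEY]
                .drop_duplicates()
                .head(5)
                .to_dict("records")
            )
            raise IntegrityError(f"wells lacking a time-0 baseline reading: {bad}")
        post = post.join(self.background_.rename("background"), on=["line", "condition"])

        denom = post["baseline"] - post["background"]
        degenerate = denom <= 0
        if degenerate.any():
            bad = (
                post.loc[degenerate, _WELL_KEY].drop_duplicates().head(5).to_dict("records")
            )
            raise DegenerateWellError(
                f"baseline does not exceed background for well(s): {bad}"
            )
        v = (post["fluorescence"] - post["background"]) / denom
        n_floored = int((v < 0).sum())
        post["viability"] = v.clip(lower=0.0)
        self.n_floored_ = n_floored
        keep = [
            "line", "subtype", "condition", "tissue", "drug", "drug_class",
            "dose_uM", "time_h", "replicate", "viability", "baseline", "background",
        ]
        out = ViabilityTensor(
            data=post[keep].reset_index(drop=True),
            background_mode=self.background,
            n_floored=n_floored,
        )
        out.annotations["n_floored"] = n_floored
        return out


def normalize_to_baseline(tensor: ScreenTensor, background: str = "none") -> ViabilityTensor:
    """Functional wrapper over :class:`BaselineNormalizer`."""
    return BaselineNormalizer(background=background).fit(tensor).transform(tensor)


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Hill-curve summary of one viability-vs-dose series.

    ``emax_effect`` is the maximal fractional viability decrease in [0, 1];
    ``flag`` is ``"ok"``, ``"undetermined"`` (no >= 5% decline to fit) or
    ``"extrapolated"`` (EC50 outside [min dose / 10, max dose * 10]).
    """

    ec50_uM: float
    emax_effect: float
    hill: float
    residual: float
    flag: str = "ok"


def _hill_viability(doses: np.ndarray, emax: float, log10_ec50: float, h: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 - emax / (1.0 + (10.0 ** log10_ec50 / doses) ** h)


class HillCurveFitter(BaseEstimator):
    """Deterministic multi-start least-squares Hill fit of viability vs dose.

    The model is ``v(d) = 1 - Emax * d^h / (d^h + EC50^h)``.  Starts span the
    observed log10 dose grid crossed with Hill slopes {0.5, 1, 2, 4}; ties are
    broken by lowest residual, then lowest EC50, making the fit reproducible
    without randomness.

    Attributes (after ``fit``): ``ec50_uM_``, ``emax_effect_``, ``hill_``,
    ``residual_``, ``flag_``.
    """

    _START_SLOPES = (0.5, 1.0, 2.0, 4.0)

    def __init__(self, min_decline: float = 0.05):
        self.min_decline = min_decline

    def fit(self, doses: Sequence[float], viability: Sequence[float]) -> "HillCurveFitter":
        d = np.asarray(doses, dtype=float)
        v = np.asarray(viability, dtype=float)
        if d.shape != v.shape:
            raise ScreenUsageError("doses and viability must align")
        if len(np.unique(d)) < 4:
            raise ScreenUsageError("dose-response fitting needs >= 4 dose points")
        if (d <= 0).any():
            raise ScreenUsageError("doses must be positive")

        # mean viability per dose decides whether there is anything to fit
        per_dose = pd.Series(v).groupby(pd.Series(d)).mean()
        observed_decline = float(max(0.0, 1.0 - per_dose.min()))
        if observed_decline < self.min_decline:
            self.ec50_uM_ = float("nan")
            self.emax_effect_ = observed_decline
            self.hill_ = float("nan")
            self.residual_ = float(np.sum((v - 1.0) ** 2))
            self.flag_ = "undetermined"
            return self

        lo_d, hi_d = np.log10(d.min()), np.log10(d.max())
        bounds = ([0.0, lo_d - 1.0, 0.2], [1.0, hi_d + 1.0, 6.0])
        emax0 = min(observed_decline, 1.0)
        best: tuple[float, float, np.ndarray] | None = None
        for lec in np.unique(np.round(np.log10(d), 6)):
            for h0 in self._START_SLOPES:
                x0 = np.clip(
                    [emax0, lec, h0],
                    bounds[0],
                    bounds[1],
                )
                sol = least_squares(
                    lambda th: _hill_viability(d, *th) - v,
                    x0=x0,
                    bounds=bounds,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
                cost = float(np.sum(sol.fun**2))
                key = (round(cost, 12), round(float(sol.x[1]), 9))
                if best is None or key < (round(best[0], 12), round(best[1], 9)):
                    best = (cost, float(sol.x[1]), sol.x)
        assert best is not None
        cost, _, x = best
        ec50 = float(10.0 ** x[1])
        self.ec50_uM_ = ec50
        self.emax_effect_ = float(x[0])
        self.hill_ = float(x[2])
        self.residual_ = cost
        in_range = d.min() / 10.0 <= ec50 <= d.max() * 10.0
        self.flag_ = "ok" if in_range else "extrapolated"
        return self

    def result_(self) -> DoseResponseFit:
        return DoseResponseFit(
            ec50_uM=self.ec50_uM_,
            emax_effect=self.emax_effect_,
            hill=self.hill_,
            residual=self.residual_,
            flag=self.flag_,
        )


def fit_dose_response(doses: Sequence[float], viability: Sequence[float]) -> DoseResponseFit:
    """Functional wrapper over :class:`HillCurveFitter`."""
    return HillCurveFitter().fit(doses, viability).result_()


def dose_response_table(
    viab: ViabilityTensor,
    time_h: float,
    condition: str = MONOCULTURE,
) -> pd.DataFrame:
    """Per-(line, drug) Hill summaries at one timepoint and culture condition.

    Returns the CSV-facing schema
    ``line, drug, time_h, ec50_uM, emax_effect, hill, flag``.
    """
    df = viab.drug_rows()
    df = df.loc[(df["time_h"] == time_h) & (df["condition"] == condition)]
    if df.empty:
        raise ScreenUsageError(
            f"no measurements at time {time_h} h for condition {condition!r}"
        )
    rows = []
    for (line, drug), grp in df.groupby(["line", "drug"]):
        fit = fit_dose_response(grp["dose_uM"].to_numpy(), grp["viability"].to_numpy())
        rows.append(
            {
                "line": line,
                "drug": drug,
                "time_h": time_h,
                "ec50_uM": fit.ec50_uM,
                "emax_effect": fit.emax_effect,
                "hill": fit.hill,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows)


def max_fractional_decrease(
    viab: ViabilityTensor, line: str, condition: str, drug: str
) -> float:
    """Maximal fractional viability decrease over the (dose, time) grid.

    Replicates are averaged per (dose, time) before taking the maximum of
    ``1 - v``; this is the screen's summary of how completely a treatment
    killed one culture.
    """
    df = viab.data
    sel = df.loc[
        (df["line"] == line) & (df["condition"] == condition) & (df["drug"] == drug)
    ]
    if sel.empty:
        raise ScreenUsageError(f"no measurements for {(line, condition, drug)}")
    mean_v = sel.groupby(["dose_uM", "time_h"])["viability"].mean()
    return float(np.clip(1.0 - mean_v.min(), 0.0, None))


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    """A fluorescence growth trace on an ascending time grid (hours)."""

    times_h: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times_h.shape != self.fluorescence.shape:
            raise ScreenUsageError("growth curve times and values must align")


def growth_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under a growth trace, in fluorescence * hours."""
    t, y = curve.times_h, curve.fluorescence
    if len(t) < 2:
        raise ScreenUsageError("growth AUC needs >= 2 timepoints")
    if (np.diff(t) <= 0).any():
        raise ScreenUsageError("growth curve times must be strictly ascending")
    return float(np.trapezoid(y, t))


def growth_auc_table(curves: "pd.DataFrame | Any") -> pd.DataFrame:
    """Mean growth AUC per (line, condition) across replicates.

    Accepts a :class:`~stromascreen.simulate.GrowthCurveSet` or its underlying
    data frame (columns ``line, condition, time_h, replicate, fluorescence``).
    """
    data = getattr(curves, "data", curves)
    rows = []
    for (line, condition, rep), grp in data.groupby(["line", "condition", "replicate"]):
        grp = grp.sort_values("time_h")
        rows.append(
            {
                "line": line,
                "condition": condition,
                "replicate": rep,
                "auc": growth_auc(
                    GrowthCurve(grp["time_h"].to_numpy(), grp["fluorescence"].to_numpy())
                ),
            }
        )
    per_rep = pd.DataFrame(rows)
    return (
        per_rep.groupby(["line", "condition"])["auc"].mean().reset_index(name="auc")
    )
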