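"""Fibroblast influence ratios, hit calling, enrichment, tiles and divergence.

The influence of a fibroblast on a tumor line's drug response is the
replicate-matched log2 ratio of coculture to monoculture relative viability,

    r = log2( v_co / v_mono ),

computed per (line, fibroblast, drug, dose, time).  Negative r means the
fibroblast *sensitized* the tumor cells (lower viability in coculture).
A single pooled replicate-noise estimate sigma supports the fold-change hit
rule |r_bar| > k * sigma (k = 3 by default); the unstated convention behind
the published hit count is exposed through ``sigma_method`` flags.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .normalize import ViabilityTensor
from .screen import MONOCULTURE, ScreenUsageError

__all__ = [
    "InfluenceTensor",
    "HitTable",
    "InfluenceTile",
    "MeanInfluenceSummary",
    "DivergenceResult",
    "compute_influence",
    "HitCaller",
    "call_hits",
    "hit_enrichment",
    "influence_tile",
    "mean_influence",
    "tissue_divergence_test",
]

_COND_KEY = ["line", "fibroblast", "drug", "dose_uM", "time_h"]

#: Documented sigma conventions (see module docstring).
SIGMA_METHODS = ("half_diff", "paired_sqrt2", "pooled_replicate_sd")


@dataclass
class InfluenceTensor:
    """Coculture:monoculture log2 viability ratios plus a pooled noise estimate.

    ``data`` holds one row per (line, fibroblast, drug, dose, time) with the
    replicate-mean ratio ``r_mean``, the number of contributing replicate
    pairs and a mask reason where the ratio is undefined (either culture at 0
    viability).  ``replicate_ratios`` keeps the per-replicate ratios for tile
    assembly and noise estimation.  ``sigma`` is the pooled replicate-noise SD
    under the chosen convention.
    """

    data: pd.DataFrame
    replicate_ratios: pd.DataFrame
    sigma: float
    sigma_method: str
    n_masked: int
    doses: list[float] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    replicates: list[int] = field(default_factory=list)

    @property
    def fibroblasts(self) -> list[str]:
        return sorted(self.data["fibroblast"].unique())

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.data.loc[self.data["mask_reason"] == ""]

    def sigma_under(self, method: str) -> float:
        """Recompute the pooled noise estimate under another convention flag."""
        rr = self.replicate_ratios
        if len(self.replicates) < 2:
            raise ScreenUsageError("sigma needs >= 2 replicates")
        wide = (
            rr.loc[rr["mask_reason"] == ""]
            .pivot_table(index=_COND_KEY, columns="replicate", values="r")
            .dropna(subset=self.replicates[:2])
        )
        paired = wide.rename(
            columns={self.replicates[0]: "r_a", self.replicates[1]: "r_b"}
        )[["r_a", "r_b"]]
        return _pooled_sigma(paired, method)


def _pooled_sigma(paired: pd.DataFrame, method: str) -> float:
    """Replicate-noise SD from replicate-pair disagreements.

    half_diff (default): SD of (r1 - r2) / 2 — the noise SD of the
    2-replicate mean, so |r_bar| > 3 sigma has the 2*Phi(-3) null rate.
    paired_sqrt2: SD of (r1 - r2) / sqrt(2) — the single-replicate SD.
    pooled_replicate_sd: sqrt of the mean per-condition replicate variance.
    """
    if method not in SIGMA_METHODS:
        raise ScreenUsageError(
            f"sigma_method must be one of {SIGMA_METHODS}, got {method!r}"
        )
    if paired.empty:
        raise ScreenUsageError("no replicate pairs available to estimate sigma")
    diff = paired["r_a"] - paired["r_b"]
    if method == "half_diff":
        return float(np.std(diff / 2.0, ddof=1))
    if method == "paired_sqrt2":
        return float(np.std(diff / np.sqrt(2.0), ddof=1))
    return float(np.sqrt(np.mean(diff**2 / 2.0)))


def compute_influence(
    viab: ViabilityTensor, sigma_method: str = "half_diff"
) -> InfluenceTensor:
    """Replicate-matched influence ratios with a pooled noise estimate.

    Replicates are paired by index (coculture replicate i over monoculture
    replicate i).  Ratios where either viability is 0 are masked with a
    reason and excluded from sigma and from the hit universe.
    """
    df = viab.drug_rows()
    mono = df.loc[df["condition"] == MONOCULTURE]
    co = df.loc[df["condition"] != MONOCULTURE]
    missing = sorted(set(co["line"].unique()) - set(mono["line"].unique()))
    if missing:
        raise ScreenUsageError(f"line(s) without monoculture: {missing}")

    merge_key = ["line", "drug", "dose_uM", "time_h", "replicate"]
    merged = co.rename(columns={"condition": "fibroblast", "viability": "v_co"}).merge(
        mono[merge_key + ["viability"]].rename(columns={"viability": "v_mono"}),
        on=merge_key,
        how="inner",
    )
    valid = (merged["v_co"] > 0) & (merged["v_mono"] > 0)
    merged["r"] = np.nan
    merged.loc[valid, "r"] = np.log2(
        merged.loc[valid, "v_co"] / merged.loc[valid, "v_mono"]
    )
    merged["mask_reason"] = ""
    merged.loc[merged["v_mono"] <= 0, "mask_reason"] = "v_mono=0"
    merged.loc[(merged["v_mono"] > 0) & (merged["v_co"] <= 0), "mask_reason"] = "v_co=0"

    rep_cols = _COND_KEY + ["subtype", "tissue", "drug_class", "replicate", "r", "mask_reason"]
    replicate_ratios = merged[rep_cols].copy()

    grouped = merged.groupby(_COND_KEY + ["subtype", "tissue", "drug_class"], sort=False)
    summary = grouped.agg(
        r_mean=("r", "mean"), n_pairs=("r", "count"), n_reps=("r", "size")
    ).reset_index()
    summary["mask_reason"] = np.where(summary["n_pairs"] > 0, "", "all replicates masked")
    n_masked = int((summary["n_pairs"] == 0).sum())

    # sigma from conditions where two replicate ratios are defined
    reps = sorted(merged["replicate"].unique())
    paired = pd.DataFrame(columns=["r_a", "r_b"])
    if len(reps) >= 2:
        wide = (
            merged.loc[valid]
            .pivot_table(index=_COND_KEY, columns="replicate", values="r")
            .dropna(subset=reps[:2])
        )
        paired = wide.rename(columns={reps[0]: "r_a", reps[1]: "r_b"})[["r_a", "r_b"]]
    sigma = _pooled_sigma(paired, sigma_method)

    return InfluenceTensor(
        data=summary,
        replicate_ratios=replicate_ratios,
        sigma=sigma,
        sigma_method=sigma_method,
        n_masked=n_masked,
        doses=sorted(merged["dose_uM"].unique()),
        times=sorted(merged["time_h"].unique()),
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Conditions whose mean influence exceeds the k * sigma fold-change rule."""

    data: pd.DataFrame  # keys + r_mean + direction
    k: float
    sigma: float
    sigma_method: str
    n_universe: int

    @property
    def n_hits(self) -> int:
        return len(self.data)

    @property
    def hit_fraction(self) -> float:
        return self.n_hits / self.n_universe if self.n_universe else float("nan")

    @property
    def threshold(self) -> float:
        return self.k * self.sigma

    def summary(self) -> dict[str, Any]:
        return {
            "k": self.k,
            "sigma": self.sigma,
            "sigma_method": self.sigma_method,
            "threshold": self.threshold,
            "n_universe": self.n_universe,
            "n_hits": self.n_hits,
            "hit_fraction": self.hit_fraction,
            "n_sensitized": int((self.data["direction"] == "sensitized").sum()),
            "n_desensitized": int((self.data["direction"] == "desensitized").sum()),
        }


class HitCaller(BaseEstimator):
    """Flags |mean influence| > k * sigma, sigma pooled over the whole screen.

    Parameters
    ----------
    k : float
        Fold-change multiplier on the replicate-noise SD (default 3).

    Attributes
    ----------
    sigma_ : float
        Noise estimate taken from the influence tensor during ``fit``.
    threshold_ : float
        ``k * sigma_``.
    """

    def __init__(self, k: float = 3.0):
        self.k = k

    def fit(self, inf: InfluenceTensor, y: None = None) -> "HitCaller":
        if self.k <= 0 or not np.isfinite(self.k):
            # infinite k is legal (empty hit set) but k <= 0 is not
            if not (np.isinf(self.k) and self.k > 0):
                raise ScreenUsageError("hit multiplier k must be positive")
        self.sigma_ = inf.sigma
        self.threshold_ = self.k * inf.sigma
        return self

    def call(self, inf: InfluenceTensor) -> HitTable:
        universe = inf.unmasked
        hits = universe.loc[np.abs(universe["r_mean"]) > self.threshold_].copy()
        hits["direction"] = np.where(hits["r_mean"] < 0, "sensitized", "desensitized")
        hits["threshold"] = self.threshold_
        cols = _COND_KEY + ["drug_class", "r_mean", "direction", "threshold"]
        return HitTable(
            data=hits[cols].reset_index(drop=True),
            k=self.k,
            sigma=inf.sigma,
            sigma_method=inf.sigma_method,
            n_universe=len(universe),
        )


def call_hits(inf: InfluenceTensor, k: float = 3.0) -> HitTable:
    """Functional wrapper over :class:`HitCaller`."""
    return HitCaller(k=k).fit(inf).call(inf)


_FACTOR_COLUMNS = {"time": "time_h", "dose": "dose_uM", "drug_class": "drug_class"}


def hit_enrichment(
    hits: HitTable, universe: InfluenceTensor, factor: str
) -> pd.DataFrame:
    """Fisher's exact enrichment/depletion of hits per level of a design factor.

    For each level of ``factor`` (``time``, ``dose`` or ``drug_class``) the
    2x2 table (hit / non-hit) x (level / other levels) gives a two-sided
    Fisher exact p-value and sample odds ratio; direction is "enriched" when
    the level carries proportionally more hits than the rest of the screen.
    """
    if factor not in _FACTOR_COLUMNS:
        raise ScreenUsageError(
            f"factor must be one of {sorted(_FACTOR_COLUMNS)}, got {factor!r}"
        )
    col = _FACTOR_COLUMNS[factor]
    uni = universe.unmasked
    if uni.empty:
        raise ScreenUsageError("empty influence universe")
    hit_keys = set(map(tuple, hits.data[_COND_KEY].itertuples(index=False, name=None)))
    is_hit = [
        tuple(row) in hit_keys
        for row in uni[_COND_KEY].itertuples(index=False, name=None)
    ]
    uni = uni.assign(is_hit=is_hit)

    rows = []
    for level, grp in uni.groupby(col, sort=True):
        a = int(grp["is_hit"].sum())
        c = len(grp) - a
        b = int(uni["is_hit"].sum()) - a
        d = (len(uni) - len(grp)) - b
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "factor": factor,
                "level": level,
                "n_hit": a,
                "n_nonhit": c,
                "odds_ratio": float(odds),
                "p_value": float(p),
                "direction": "enriched" if odds > 1 else ("depleted" if odds < 1 else "flat"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tiles and summaries
# ---------------------------------------------------------------------------

@dataclass
class InfluenceTile:
    """One (line, fibroblast, drug) interaction arrayed dose x time x replicate.

    With the default design the tile has 4 doses x 9 timepoints x 2
    replicates = 72 entries; masked cells propagate as NaN without shrinking
    the tile.
    """

    line: str
    fibroblast: str
    drug: str
    doses: list[float]
    times: list[float]
    replicates: list[int]
    values: np.ndarray  # shape (n_doses, n_times, n_replicates)

    @property
    def size(self) -> int:
        return int(self.values.size)

    def mean(self) -> float:
        return float(np.nanmean(self.values))


def influence_tile(
    inf: InfluenceTensor, line: str, fibroblast: str, drug: str
) -> InfluenceTile:
    """Assemble the dose x time x replicate ratio tile for one interaction."""
    rr = inf.replicate_ratios
    sel = rr.loc[
        (rr["line"] == line) & (rr["fibroblast"] == fibroblast) & (rr["drug"] == drug)
    ]
    if sel.empty:
        raise ScreenUsageError(f"no influence data for {(line, fibroblast, drug)}")
    doses, times, reps = inf.doses, inf.times, inf.replicates
    values = np.full((len(doses), len(times), len(reps)), np.nan)
    d_idx = {d: i for i, d in enumerate(doses)}
    t_idx = {t: i for i, t in enumerate(times)}
    r_idx = {r: i for i, r in enumerate(reps)}
    for row in sel.itertuples(index=False):
        values[d_idx[row.dose_uM], t_idx[row.time_h], r_idx[row.replicate]] = row.r
    return InfluenceTile(
        line=line, fibroblast=fibroblast, drug=drug,
        doses=doses, times=times, replicates=reps, values=values,
    )


@dataclass
class MeanInfluenceSummary:
    """Mean influence per (fibroblast, drug) and grand mean per fibroblast."""

    group_by: str
    tables: dict[str, pd.DataFrame]  # group -> fibroblast x drug matrix
    grand_mean: dict[str, pd.Series]  # group -> per-fibroblast mean over drugs
    n_conditions: dict[str, pd.DataFrame]  # group -> contributing counts


def mean_influence(inf: InfluenceTensor, group_by: str = "all") -> MeanInfluenceSummary:
    """Average influence over tumor lines, optionally split by subtype.

    ``group_by="all"`` averages every line; ``"subtype"`` returns one
    fibroblast x drug matrix per subclass (BL, ML).  The grand mean per
    fibroblast additionally averages over drugs — the fibroblast's overall
    push on drug sensitivity.
    """
    if group_by not in {"all", "subtype"}:
        raise ScreenUsageError("group_by must be 'all' or 'subtype'")
    df = inf.unmasked
    groups = {"all": df} if group_by == "all" else dict(tuple(df.groupby("subtype")))
    tables, grand, counts = {}, {}, {}
    for name, grp in groups.items():
        mat = grp.pivot_table(
            index="fibroblast", columns="drug", values="r_mean", aggfunc="mean"
        )
        tables[name] = mat
        grand[name] = grp.groupby("fibroblast")["r_mean"].mean()
        counts[name] = grp.pivot_table(
            index="fibroblast", columns="drug", values="r_mean", aggfunc="count"
        )
    return MeanInfluenceSummary(
        group_by=group_by, tables=tables, grand_mean=grand, n_conditions=counts
    )


# ---------------------------------------------------------------------------
# Tissue-of-origin divergence
# ---------------------------------------------------------------------------

@dataclass
class DivergenceResult:
    """Within- vs between-tissue similarity of fibroblast influence profiles."""

    within: np.ndarray
    between: np.ndarray
    ks_statistic: float
    p_value: float
    pair_table: pd.DataFrame
    n_masked_pairs: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "within": [float(x) for x in self.within],
                "between": [float(x) for x in self.between],
                "ks_statistic": self.ks_statistic,
                "p_value": self.p_value,
                "n_masked_pairs": self.n_masked_pairs,
            },
            indent=2,
        )


def tissue_divergence_test(
    inf: InfluenceTensor,
    tissue_map: Mapping[str, str],
    min_overlap: float = 0.5,
) -> DivergenceResult:
    """Do same-tissue fibroblasts influence drug response more similarly?

    Each fibroblast's influence profile is its vector of mean ratios over
    (line, drug, dose, time).  Pearson correlations of all fibroblast pairs
    are split into within-tissue and between-tissue samples and compared with
    a two-sample Kolmogorov-Smirnov test (exact enumeration below 10 pairs
    per sample, asymptotic otherwise).

    Pairs sharing fewer than ``min_overlap`` of the profile entries are
    masked; a zero-variance profile correlates 1 with an equal profile and is
    otherwise masked.
    """
    fibs = inf.fibroblasts
    unknown = [f for f in fibs if f not in tissue_map]
    if unknown:
        raise ScreenUsageError(f"fibroblast(s) missing from tissue_map: {unknown}")
    tissues = {f: tissue_map[f] for f in fibs}
    if len(set(tissues.values())) < 2:
        raise ScreenUsageError("tissue divergence needs >= 2 tissues")
    by_tissue: dict[str, int] = {}
    for t in tissues.values():
        by_tissue[t] = by_tissue.get(t, 0) + 1
    if max(by_tissue.values()) < 2:
        raise ScreenUsageError("no tissue contributes >= 2 fibroblasts")

    profiles = inf.unmasked.pivot_table(
        index="fibroblast",
        columns=["line", "drug", "dose_uM", "time_h"],
        values="r_mean",
    ).reindex(fibs)
    n_features = profiles.shape[1]

    rows = []
    within, between = [], []
    n_masked = 0
    arr = profiles.to_numpy()
    for (i, fa), (j, fb) in itertools.combinations(enumerate(fibs), 2):
        x, y = arr[i], arr[j]
        common = ~(np.isnan(x) | np.isnan(y))
        r: float | None
        if common.sum() < max(2, min_overlap * n_features):
            r, reason = None, "insufficient overlap"
        else:
            xc, yc = x[common], y[common]
            if np.ptp(xc) == 0 or np.ptp(yc) == 0:
                if np.array_equal(xc, yc):
                    r, reason = 1.0, ""
                else:
                    r, reason = None, "zero-variance profile"
            else:
                r, reason = float(np.corrcoef(xc, yc)[0, 1]), ""
        same = tissues[fa] == tissues[fb]
        rows.append(
            {
                "fibroblast_a": fa, "fibroblast_b": fb,
                "tissue_a": tissues[fa], "tissue_b": tissues[fb],
                "same_tissue": same,
                "correlation": np.nan if r is None else r,
                "mask_reason": reason,
            }
        )
        if r is None:
            n_masked += 1
        elif same:
            within.append(r)
        else:
            between.append(r)

    if not within or not between:
        raise ScreenUsageError("need at least one within- and one between-tissue pair")
    within_a, between_a = np.asarray(within), np.asarray(between)
    method = "exact" if min(len(within_a), len(between_a)) < 10 else "asymp"
    if np.array_equal(np.unique(within_a), np.unique(between_a)) and (
        np.ptp(within_a) == 0 and np.ptp(between_a) == 0
    ):
        # degenerate identical samples: D = 0 by construction
        d_stat, p_val = 0.0, 1.0
    else:
        ks = stats.ks_2samp(within_a, between_a, method=method)
        d_stat, p_val = float(ks.statistic), float(ks.pvalue)
    return DivergenceResult(
        within=within_a,
        between=between_a,
        ks_statistic=d_stat,
        p_value=p_val,
        pair_table=pd.DataFrame(rows),
        n_masked_pairs=n_masked,
    )
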