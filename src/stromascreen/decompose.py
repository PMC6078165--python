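"""Unfolded response matrices, PCA, subtype/drug-class enrichment, UPGMA trees.

A screen's response tensor is unfolded into a sample x feature matrix — one
row per culture pair (tumor line x condition), one column per
(drug, dose, time) — z-scored per column, and decomposed by a deterministic
SVD-based PCA.  Per-component Fisher tests then ask which components separate
the basal-like from the mesenchymal-like lines (median-split of scores) and
which drug classes dominate a component's strongest loadings (top-quartile
membership).  UPGMA clustering of line x drug sensitivity summaries rounds
out the monoculture-style overview.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator

from .influence import InfluenceTensor
from .normalize import ViabilityTensor
from .screen import MONOCULTURE, ScreenUsageError

__all__ = [
    "ProfileMatrix",
    "PCAModel",
    "unfold_profiles",
    "ResponsePCA",
    "run_pca",
    "pc_subtype_association",
    "loading_class_enrichment",
    "ClusterResult",
    "cluster_sensitivity",
]


@dataclass
class ProfileMatrix:
    """Z-scored sample x feature response matrix with its scaling bookkeeping.

    Rows are samples (culture pairs or lines), columns a (drug, dose, time)
    MultiIndex.  Columns are centered to mean 0 / variance 1; zero-variance
    columns are dropped (``dropped_columns``) and imputed cells counted
    (``n_imputed``).  ``sample_meta`` carries line / condition / subtype per
    row for the association tests.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    col_means: pd.Series
    col_stds: pd.Series
    dropped_columns: list = field(default_factory=list)
    n_imputed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def unfold_profiles(
    source: InfluenceTensor | ViabilityTensor,
    value: str = "influence",
    conditions: str = "coculture",
    per_line: bool = False,
    max_missing: float = 0.2,
) -> ProfileMatrix:
    """Unfold a response tensor into a z-scored sample x feature matrix.

    Parameters
    ----------
    source, value
        An :class:`InfluenceTensor` with ``value="influence"`` (rows are
        line x fibroblast pairs) or a :class:`ViabilityTensor` with
        ``value="viability"`` (rows are line x condition pairs, restricted by
        ``conditions`` to ``"coculture"``, ``"monoculture"`` or ``"all"``).
    per_line
        Collapse conditions, leaving one row per tumor line (the alternative
        unfold used for monoculture-only overviews).
    max_missing
        Error threshold on the fraction of missing cells; below it, missing
        cells are imputed with the column mean before z-scoring.
    """
    if value == "influence":
        if not isinstance(source, InfluenceTensor):
            raise ScreenUsageError("value='influence' requires an InfluenceTensor")
        df = source.unmasked.rename(columns={"fibroblast": "condition", "r_mean": "y"})
    elif value == "viability":
        if not isinstance(source, ViabilityTensor):
            raise ScreenUsageError("value='viability' requires a ViabilityTensor")
        df = source.drug_rows().copy()
        if conditions == "coculture":
            df = df.loc[df["condition"] != MONOCULTURE]
        elif conditions == "monoculture":
            df = df.loc[df["condition"] == MONOCULTURE]
        elif conditions != "all":
            raise ScreenUsageError(
                "conditions must be 'coculture', 'monoculture' or 'all'"
            )
        df = (
            df.groupby(["line", "subtype", "condition", "drug", "dose_uM", "time_h"])[
                "viability"
            ]
            .mean()
            .reset_index()
            .rename(columns={"viability": "y"})
        )
    else:
        raise ScreenUsageError("value must be 'influence' or 'viability'")
    if df.empty:
        raise ScreenUsageError("nothing to unfold after selection")

    index_cols = ["line"] if per_line else ["line", "condition"]
    wide = df.pivot_table(
        index=index_cols,
        columns=["drug", "dose_uM", "time_h"],
        values="y",
        aggfunc="mean",
    )
    frac_missing = float(wide.isna().to_numpy().mean())
    if frac_missing > max_missing:
        raise ScreenUsageError(
            f"{frac_missing:.0%} of cells missing (> {max_missing:.0%}); "
            "subset the tensor before unfolding"
        )
    n_imputed = int(wide.isna().to_numpy().sum())
    wide = wide.fillna(wide.mean(axis=0))

    stds = wide.std(axis=0, ddof=0)
    dropped = list(wide.columns[stds == 0])
    wide = wide.loc[:, stds > 0]
    means = wide.mean(axis=0)
    stds = wide.std(axis=0, ddof=0)
    z = (wide - means) / stds

    subtype_map = df.drop_duplicates("line").set_index("line")["subtype"].to_dict()
    meta = wide.index.to_frame(index=False)
    if "condition" not in meta.columns:
        meta["condition"] = ""
    meta["subtype"] = meta["line"].map(subtype_map)
    return ProfileMatrix(
        values=z,
        sample_meta=meta,
        col_means=means,
        col_stds=stds,
        dropped_columns=dropped,
        n_imputed=n_imputed,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Scores, unit-norm loadings and explained-variance fractions.

    ``explained_fraction`` covers the retained components;
    ``full_spectrum_fraction`` the complete eigenvalue spectrum (sums to 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_fraction: np.ndarray
    full_spectrum_fraction: np.ndarray
    n_components: int
    sample_meta: pd.DataFrame

    def component(self, pc: int) -> str:
        if not 1 <= pc <= self.n_components:
            raise ScreenUsageError(
                f"PC{pc} not available; model holds PC1..PC{self.n_components}"
            )
        return f"PC{pc}"


class ResponsePCA(BaseEstimator):
    """Deterministic PCA of a z-scored profile matrix via full SVD.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so score plots reproduce across runs and platforms.
    Requesting more components than the matrix rank truncates with a warning.

    Attributes (after ``fit``): ``model_`` (:class:`PCAModel`),
    ``singular_values_``, ``n_components_``.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, matrix: ProfileMatrix, y: None = None) -> "ResponsePCA":
        X = matrix.values.to_numpy(dtype=float)
        X = X - X.mean(axis=0)  # columns are z-scored already; guard exactness
        u, s, vt = np.linalg.svd(X, full_matrices=False)
        tol = max(X.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
        rank = int((s > tol).sum())
        k = min(self.n_components, rank)
        if k < self.n_components:
            warnings.warn(
                f"requested {self.n_components} components but rank is {rank}; "
                f"returning {k}",
                RuntimeWarning,
                stacklevel=2,
            )
        # sign convention: dominant loading positive
        for j in range(k):
            lead = np.argmax(np.abs(vt[j]))
            if vt[j, lead] < 0:
                vt[j] *= -1.0
                u[:, j] *= -1.0
        var = s**2
        frac = var / var.sum()
        comp_names = [f"PC{i + 1}" for i in range(k)]
        scores = pd.DataFrame(
            u[:, :k] * s[:k], index=matrix.values.index, columns=comp_names
        )
        loadings = pd.DataFrame(
            vt[:k].T, index=matrix.values.columns, columns=comp_names
        )
        self.singular_values_ = s
        self.n_components_ = k
        self.model_ = PCAModel(
            scores=scores,
            loadings=loadings,
            explained_fraction=frac[:k],
            full_spectrum_fraction=frac,
            n_components=k,
            sample_meta=matrix.sample_meta,
        )
        return self

    def transform(self, matrix: ProfileMatrix) -> pd.DataFrame:
        load = self.model_.loadings
        cols = matrix.values.columns.intersection(load.index)
        return matrix.values[cols] @ load.loc[cols]


def run_pca(matrix: ProfileMatrix, n_components: int = 10) -> PCAModel:
    """Functional wrapper over :class:`ResponsePCA`."""
    return ResponsePCA(n_components=n_components).fit(matrix).model_


# ---------------------------------------------------------------------------
# Association and enrichment
# ---------------------------------------------------------------------------

def pc_subtype_association(
    model: PCAModel, subtype_map: Mapping[str, str]
) -> pd.DataFrame:
    """Fisher association between each PC's median-split scores and subtype.

    Samples are split at the component's median score (strictly above vs at
    or below); the 2x2 table against BL/ML membership yields a two-sided
    exact p-value.  Monotone transformations of the scores leave the result
    unchanged.
    """
    meta = model.sample_meta.copy()
    meta["subtype"] = meta["line"].map(subtype_map)
    if meta["subtype"].isna().any():
        missing = meta.loc[meta["subtype"].isna(), "line"].unique()
        raise ScreenUsageError(f"line(s) missing from subtype_map: {list(missing)}")
    levels = sorted(meta["subtype"].unique())
    if len(levels) < 2:
        raise ScreenUsageError("association needs both subtypes present")
    is_bl = (meta["subtype"] == "BL").to_numpy()
    rows = []
    for j, pc in enumerate(model.scores.columns):
        score = model.scores[pc].to_numpy()
        above = score > np.median(score)
        a = int((is_bl & above).sum())
        b = int((is_bl & ~above).sum())
        c = int((~is_bl & above).sum())
        d = int((~is_bl & ~above).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "pc": j + 1,
                "explained_fraction": float(model.explained_fraction[j]),
                "n_bl_above": a,
                "n_bl_below": b,
                "n_ml_above": c,
                "n_ml_below": d,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def loading_class_enrichment(
    model: PCAModel,
    class_map: Mapping[str, str],
    pc: int,
    tail: str = "positive",
    quantile: float = 0.25,
) -> pd.DataFrame:
    """Fisher enrichment of drug classes among a component's strongest loadings.

    Features inherit class membership from their drug.  They are ranked by
    loading on ``pc`` (descending for ``tail="positive"``, ascending for
    ``"negative"``, by magnitude for ``"both"``); the top ``quantile`` of the
    ranking is tested against the rest per class.
    """
    if tail not in {"positive", "negative", "both"}:
        raise ScreenUsageError("tail must be 'positive', 'negative' or 'both'")
    comp = model.component(pc)
    load = model.loadings[comp]
    drugs = load.index.get_level_values("drug")
    classes = pd.Series([class_map.get(d, "") for d in drugs], index=load.index)
    if (classes == "").any():
        missing = sorted(set(drugs[classes == ""]))
        raise ScreenUsageError(f"drug(s) missing from class_map: {missing}")

    key = {"positive": -load, "negative": load, "both": -load.abs()}[tail]
    order = key.argsort(kind="mergesort")  # stable -> deterministic ties
    n_top = max(1, int(np.ceil(quantile * len(load))))
    in_top = np.zeros(len(load), dtype=bool)
    in_top[order[:n_top]] = True

    rows = []
    for cls in sorted(classes.unique()):
        member = (classes == cls).to_numpy()
        a = int((member & in_top).sum())
        b = int(in_top.sum()) - a
        c = int(member.sum()) - a
        d = len(load) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "pc": pc,
                "tail": tail,
                "drug_class": cls,
                "n_in_top": a,
                "n_class": int(member.sum()),
                "odds_ratio": float(odds),
                "p_value": float(p),
                "direction": "enriched" if odds > 1 else ("depleted" if odds < 1 else "flat"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """UPGMA linkages and leaf orders for rows and columns of a summary matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str


def _newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def cluster_sensitivity(summary: pd.DataFrame) -> ClusterResult:
    """UPGMA (average-linkage, Euclidean) clustering of a line x drug summary.

    The input is a z-scored sensitivity matrix (e.g. EC50 or maximal effect
    per line and drug); missing cells are mean-imputed per column first.
    Deterministic: scipy's linkage breaks distance ties by lowest cluster
    index.
    """
    if summary.shape[0] < 2:
        raise ScreenUsageError("clustering needs >= 2 rows")
    mat = summary.astype(float)
    mat = mat.fillna(mat.mean(axis=0))
    X = mat.to_numpy()

    row_link = hierarchy.linkage(X, method="average", metric="euclidean")
    row_order = [mat.index[i] for i in hierarchy.leaves_list(row_link)]
    if summary.shape[1] >= 2:
        col_link = hierarchy.linkage(X.T, method="average", metric="euclidean")
        col_order = [mat.columns[i] for i in hierarchy.leaves_list(col_link)]
        col_newick = _newick(col_link, [str(c) for c in mat.columns])
    else:  # a single column cannot be clustered
        col_link = np.empty((0, 4))
        col_order = [str(c) for c in mat.columns]
        col_newick = f"({col_order[0]});" if col_order else ";"
    return ClusterResult(
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[str(r) for r in row_order],
        col_order=[str(c) for c in col_order],
        row_newick=_newick(row_link, [str(r) for r in mat.index]),
        col_newick=col_newick,
    )
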