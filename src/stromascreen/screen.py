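"""Domain types, validation and I/O for coculture screen measurement tables.

The canonical representation of a screen is a long ("tidy") table with one row
per well x timepoint, wrapped by :class:`ScreenTensor`.  A screen crosses tumor
lines with culture conditions (monoculture or one of a panel of fibroblasts),
drugs, doses, post-drug timepoints and replicates; the two control treatments
(vehicle and the membrane-permeabilizing peptide alamethicin, which defines the
fluorescence background floor) are encoded as reserved drug tokens so they flow
through counting and normalization like any other treatment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MONOCULTURE",
    "VEHICLE",
    "ALAMETHICIN",
    "CONTROL_DRUGS",
    "KEY_COLUMNS",
    "REQUIRED_COLUMNS",
    "SchemaError",
    "IntegrityError",
    "ScreenUsageError",
    "PanelMetadata",
    "ScreenTensor",
    "ValidationReport",
    "load_screen_table",
    "write_screen_table",
    "validate_screen",
    "subset",
]

#: Reserved condition token for cultures without fibroblasts.
MONOCULTURE = "monoculture"
#: Reserved drug tokens for the two per-culture controls.
VEHICLE = "vehicle"
ALAMETHICIN = "alamethicin"
CONTROL_DRUGS = frozenset({VEHICLE, ALAMETHICIN})

#: Columns that uniquely key one measurement (one well at one timepoint).
KEY_COLUMNS = ["line", "condition", "drug", "dose_uM", "time_h", "replicate"]
#: Header schema of the canonical CSV/TSV interchange format.
REQUIRED_COLUMNS = [
    "line",
    "subtype",
    "condition",
    "tissue",
    "drug",
    "drug_class",
    "dose_uM",
    "time_h",
    "replicate",
    "fluorescence",
]
OPTIONAL_COLUMNS = ["well"]


class SchemaError(ValueError):
    """An input table is missing a required column or has an unusable layout."""


class IntegrityError(ValueError):
    """An input table violates a structural invariant (e.g. duplicate keys)."""


class ScreenUsageError(ValueError):
    """An operation was called with arguments outside its contract."""


@dataclass(frozen=True)
class PanelMetadata:
    """Maps the panel's axis entries onto their biological annotations.

    Parameters
    ----------
    subtype_map
        Tumor line -> transcriptional subclass, ``"BL"`` (basal-like) or
        ``"ML"`` (mesenchymal-like).
    tissue_map
        Fibroblast identifier -> anatomical tissue of origin.
    class_map
        Drug identifier -> drug class label (control tokens excluded).
    """

    subtype_map: dict[str, str]
    tissue_map: dict[str, str]
    class_map: dict[str, str]

    @classmethod
    def from_tensor(cls, tensor: "ScreenTensor") -> "PanelMetadata":
        """Recover metadata from the annotation columns of a screen table."""
        df = tensor.data
        sub = (
            df.loc[df["subtype"].astype(str).str.len() > 0, ["line", "subtype"]]
            .drop_duplicates()
            .set_index("line")["subtype"]
            .to_dict()
        )
        fib = df.loc[df["condition"] != MONOCULTURE, ["condition", "tissue"]]
        tis = fib.drop_duplicates().set_index("condition")["tissue"].to_dict()
        drugs = df.loc[~df["drug"].isin(CONTROL_DRUGS), ["drug", "drug_class"]]
        cls_map = drugs.drop_duplicates().set_index("drug")["drug_class"].to_dict()
        return cls(subtype_map=sub, tissue_map=tis, class_map=cls_map)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class ScreenTensor:
    """A validated collection of screen measurements plus its axis registries.

    Thin wrapper around a long-format :class:`pandas.DataFrame` holding one row
    per well x timepoint.  Axis registries (lines, conditions, drugs, doses,
    times, replicates) are derived views of the table; ``design`` optionally
    records the declared full-factorial design for count bookkeeping.
    """

    data: pd.DataFrame
    design: dict[str, Any] | None = None
    annotations: dict[str, Any] = field(default_factory=dict)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        design: dict[str, Any] | None = None,
        validate: bool = True,
    ) -> "ScreenTensor":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["dose_uM"] = df["dose_uM"].astype(float)
        df["time_h"] = df["time_h"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["fluorescence"] = df["fluorescence"].astype(float)
        for col in ("line", "condition", "drug"):
            df[col] = df[col].astype(str)
        df["subtype"] = df["subtype"].fillna("").astype(str)
        df["tissue"] = df["tissue"].fillna("").astype(str)
        df["drug_class"] = df["drug_class"].fillna("").astype(str)
        if validate:
            cls._check_integrity(df)
        return cls(data=df.reset_index(drop=True), design=design)

    @staticmethod
    def _check_integrity(df: pd.DataFrame) -> None:
        if (df["fluorescence"] < 0).any():
            n = int((df["fluorescence"] < 0).sum())
            raise IntegrityError(f"{n} rows with negative fluorescence")
        if (df["time_h"] < 0).any():
            raise IntegrityError("negative time_h values present")
        if (df["replicate"] < 1).any():
            raise IntegrityError("replicate indices must be positive integers")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            first = df.loc[dup, KEY_COLUMNS].iloc[0].to_dict()
            raise IntegrityError(f"duplicate measurement key, first collision: {first}")
        is_control = df["drug"].isin(CONTROL_DRUGS)
        bad_ctrl = is_control & (df["dose_uM"] != 0.0)
        bad_drug = ~is_control & (df["dose_uM"] == 0.0)
        if bad_ctrl.any() or bad_drug.any():
            raise IntegrityError(
                "dose must be 0 exactly for control tokens (vehicle/alamethicin) "
                f"and nonzero otherwise: {int(bad_ctrl.sum())} control rows with "
                f"dose != 0, {int(bad_drug.sum())} drug rows with dose == 0"
            )

    # -- axis registries ---------------------------------------------------
    @property
    def lines(self) -> list[str]:
        return sorted(self.data["line"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.data["condition"].unique())

    @property
    def fibroblasts(self) -> list[str]:
        return [c for c in self.conditions if c != MONOCULTURE]

    @property
    def drugs(self) -> list[str]:
        """Non-control drug identifiers."""
        return sorted(set(self.data["drug"].unique()) - CONTROL_DRUGS)

    @property
    def doses(self) -> list[float]:
        d = self.data.loc[~self.data["drug"].isin(CONTROL_DRUGS), "dose_uM"]
        return sorted(d.unique())

    @property
    def times(self) -> list[float]:
        return sorted(self.data["time_h"].unique())

    @property
    def post_times(self) -> list[float]:
        return [t for t in self.times if t > 0]

    @property
    def replicates(self) -> list[int]:
        return sorted(self.data["replicate"].unique())

    # -- counts ------------------------------------------------------------
    @property
    def n_measurements(self) -> int:
        """Total rows, baselines included."""
        return len(self.data)

    @property
    def n_drug_response_measurements(self) -> int:
        """Post-drug (time > 0) measurements, the screen's headline count."""
        return int((self.data["time_h"] > 0).sum())

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"ScreenTensor({len(self.data)} rows: {len(self.lines)} lines x "
            f"{len(self.conditions)} conditions x {len(self.drugs)} drugs x "
            f"{len(self.doses)} doses x {len(self.times)} times x "
            f"{len(self.replicates)} replicates)"
        )


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_screen`; ``valid`` iff all defect lists empty."""

    baseline_missing: list[dict[str, Any]] = field(default_factory=list)
    unmapped: list[dict[str, str]] = field(default_factory=list)
    negative_values: list[dict[str, Any]] = field(default_factory=list)
    n_rows: int = 0

    @property
    def valid(self) -> bool:
        return not (self.baseline_missing or self.unmapped or self.negative_values)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["valid"] = self.valid
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "tsv", "xlsx"}:
        return suffix
    if suffix in {"txt", "tab"}:
        return "tsv"
    raise SchemaError(f"cannot infer table format from extension {path.suffix!r}")


def load_screen_table(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
    sheet: str | int = 0,
    validate: bool = True,
) -> ScreenTensor:
    """Read a screen measurement table into a validated :class:`ScreenTensor`.

    Parameters
    ----------
    path
        CSV/TSV file in the canonical header schema, or an XLSX workbook.
    format
        ``"csv"``, ``"tsv"`` or ``"xlsx"``; inferred from the extension when
        omitted.
    column_map
        For externally deposited workbooks whose headers differ from the
        canonical schema: mapping from *source* column name to canonical name,
        applied after reading.
    sheet
        Sheet name or index for XLSX input.

    Notes
    -----
    Rows with missing fluorescence are rejected (dropped) and their count kept
    in ``annotations["n_rows_rejected"]``; unknown columns are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        df = pd.read_csv(path, encoding="utf-8")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", encoding="utf-8")
    elif fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        raise SchemaError(f"unknown format {fmt!r}; expected csv, tsv or xlsx")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    n_bad = int(df["fluorescence"].isna().sum())
    if n_bad:
        df = df.loc[df["fluorescence"].notna()]
    tensor = ScreenTensor.from_frame(df, validate=validate)
    tensor.annotations["n_rows_rejected"] = n_bad
    tensor.annotations["source"] = str(path)
    return tensor


def write_screen_table(tensor: ScreenTensor, path: str | Path) -> Path:
    """Write a tensor back out in the canonical CSV/TSV schema (UTF-8, '.')."""
    path = Path(path)
    fmt = _infer_format(path)
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in tensor.data.columns]
    extra = [c for c in tensor.data.columns if c not in cols]
    out = tensor.data[cols + extra]
    sep = {"csv": ",", "tsv": "\t"}.get(fmt)
    if sep is None:
        raise SchemaError("write_screen_table emits csv or tsv only")
    out.to_csv(path, sep=sep, index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Validation and subsetting
# ---------------------------------------------------------------------------

def validate_screen(tensor: ScreenTensor, meta: PanelMetadata) -> ValidationReport:
    """Report structural defects: missing baselines, unmapped axes, negatives.

    Never raises; the ``valid`` flag on the returned report is true iff every
    defect list is empty.
    """
    df = tensor.data
    report = ValidationReport(n_rows=len(df))

    well_key = ["line", "condition", "drug", "dose_uM", "replicate"]
    has_t0 = df.groupby(well_key, sort=False)["time_h"].agg(lambda t: (t == 0).any())
    for key, ok in has_t0.items():
        if not ok:
            report.baseline_missing.append(dict(zip(well_key, key)))

    for line in tensor.lines:
        if line not in meta.subtype_map:
            report.unmapped.append({"axis": "line", "entry": line})
    for fib in tensor.fibroblasts:
        if fib not in meta.tissue_map:
            report.unmapped.append({"axis": "condition", "entry": fib})
    for drug in tensor.drugs:
        if drug not in meta.class_map:
            report.unmapped.append({"axis": "drug", "entry": drug})

    neg = df["fluorescence"] < 0
    for _, row in df.loc[neg].iterrows():  # pragma: no cover - barred upstream
        report.negative_values.append(
            {k: row[k] for k in KEY_COLUMNS} | {"fluorescence": row["fluorescence"]}
        )
    return report


_AXIS_COLUMNS = set(KEY_COLUMNS) | {"subtype", "tissue", "drug_class"}


def subset(tensor: ScreenTensor, **selector: Any) -> ScreenTensor:
    """Return the sub-tensor matching every per-axis predicate.

    Each keyword names an axis column (``line``, ``condition``, ``drug``,
    ``dose_uM``, ``time_h``, ``replicate``, or an annotation axis ``subtype``,
    ``tissue``, ``drug_class``) and takes a scalar, an iterable of allowed
    values, or a boolean predicate.  Conjunction across axes; an empty result
    is legal.
    """
    mask = pd.Series(True, index=tensor.data.index)
    for axis, pred in selector.items():
        if axis not in _AXIS_COLUMNS:
            raise ScreenUsageError(
                f"unknown axis {axis!r}; expected one of {sorted(_AXIS_COLUMNS)}"
            )
        col = tensor.data[axis]
        if callable(pred):
            mask &= col.map(pred).astype(bool)
        elif isinstance(pred, (list, tuple, set, frozenset, np.ndarray, pd.Series)):
            mask &= col.isin(list(pred))
        else:
            mask &= col == pred
    return ScreenTensor(
        data=tensor.data.loc[mask].reset_index(drop=True),
        design=None,
        annotations=dict(tensor.annotations),
    )
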