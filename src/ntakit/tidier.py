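"""Wide-to-long reshaping, sample-name parsing and dilution correction.

Measurement names in NTA exports encode the experimental factors, e.g.
``GD14.5_M1_500_a_1`` = gestational day 14.5, mouse 1, diluted 1:500,
injection a, technical replicate 1.  A :class:`SampleNameSchema` declares
the field names, the separator, and which field carries the fold
dilution ``d``.  Tidying melts the wide matrix to one row per
(bin, measurement), splits the name into factor columns, and
back-calculates the concentration in the undiluted sample:

    true_count = count * d

The dilution token must be the bare fold number (``500``), not a ratio
string (``1:500``).  Factor columns are pandas categoricals whose level
order is first appearance in measurement order, never alphabetical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DilutionError, FormatError, GridMismatchError, SchemaError
from .ntaio import AcquisitionMeta, WideExperimentTable

__all__ = ["SampleNameSchema", "tidy_table", "untidy_table", "save_tidy", "load_tidy"]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class SampleNameSchema:
    """How to split a measurement name into factor columns.

    Parameters
    ----------
    field_names : tuple of str
        One name per token, in order, e.g.
        ``("gest_age", "mouse", "dilution", "injection", "tech_rep")``.
    separator : str
        Single-character token separator, default ``"_"``.
    dilution_field : str
        Which field holds the numeric fold dilution, default ``"dilution"``.
    skip_leading_tokens : int
        Number of constant leading tokens (e.g. a ``Sample`` prefix) to
        drop before matching ``field_names``; default 0.
    """

    field_names: tuple[str, ...]
    separator: str = "_"
    dilution_field: str = "dilution"
    skip_leading_tokens: int = 0

    def __post_init__(self) -> None:
        names = tuple(self.field_names)
        object.__setattr__(self, "field_names", names)
        if not names or any(not n for n in names):
            raise SchemaError("field_names must be non-empty strings")
        if len(set(names)) != len(names):
            raise SchemaError(f"field_names must be unique, got {names}")
        if len(self.separator) != 1:
            raise SchemaError("separator must be a single character")
        if self.dilution_field not in names:
            raise SchemaError(
                f"dilution_field {self.dilution_field!r} not in field_names {names}"
            )
        if self.skip_leading_tokens < 0:
            raise SchemaError("skip_leading_tokens must be >= 0")

    def split(self, name: str) -> dict[str, str]:
        """Split one measurement name; raise on arity or dilution problems."""
        tokens = name.split(self.separator)[self.skip_leading_tokens:]
        if len(tokens) != len(self.field_names):
            raise SchemaError(
                f"measurement name {name!r} yields {len(tokens)} tokens after "
                f"skipping {self.skip_leading_tokens}; schema expects "
                f"{len(self.field_names)} ({self.field_names})"
            )
        return dict(zip(self.field_names, tokens))

    def join(self, fields: dict[str, str]) -> str:
        return self.separator.join(str(fields[f]) for f in self.field_names)


def _parse_dilution(token: str, name: str) -> float:
    try:
        d = float(token)
    except ValueError:
        raise DilutionError(
            f"dilution token {token!r} in measurement {name!r} is not a number "
            "(use the bare fold factor, e.g. 500, not '1:500')"
        )
    if not d > 0:
        raise DilutionError(f"dilution must be > 0, got {d} in measurement {name!r}")
    return d


def tidy_table(wide: WideExperimentTable, schema: SampleNameSchema) -> pd.DataFrame:
    """Melt a wide experiment into tidy long form with dilution correction.

    Returns a DataFrame with columns ``particle_size`` (bin centre, nm),
    one column per schema field (categorical except the numeric
    dilution), ``count`` (measured particles/mL) and ``true_count``
    (= count x dilution, the undiluted concentration).  Row count is
    exactly bins x measurements.
    """
    parsed = []
    for name in wide.measurement_names:
        fields = schema.split(name)
        fields[schema.dilution_field] = _parse_dilution(
            fields[schema.dilution_field], name
        )
        parsed.append(fields)

    long = wide.to_frame().reset_index().melt(
        id_vars="particle_size", var_name="_name", value_name="count"
    )
    meta = pd.DataFrame(parsed, index=list(wide.measurement_names))
    for col in meta.columns:
        long[col] = meta[col].reindex(long["_name"]).to_numpy()
    long = long.drop(columns="_name")

    for f in schema.field_names:
        if f == schema.dilution_field:
            long[f] = long[f].astype(float)
        else:
            levels = list(dict.fromkeys(m[f] for m in parsed))
            long[f] = pd.Categorical(long[f], categories=levels)
    long["true_count"] = long["count"] * long[schema.dilution_field]
    cols = ["particle_size", *schema.field_names, "count", "true_count"]
    return long[cols].reset_index(drop=True)


def untidy_table(
    tidy: pd.DataFrame,
    schema: SampleNameSchema,
    meta: AcquisitionMeta | None = None,
) -> WideExperimentTable:
    """Rebuild the wide layout from a tidy table (inverse of :func:`tidy_table`).

    Measurement names are rejoined by the separator (the dilution is
    rendered as an integer when it is one).  All measurements must share
    one bin grid or :class:`GridMismatchError` is raised.  When ``meta``
    is omitted a uniform grid is inferred from the bin centres.
    """
    required = {"particle_size", "count", *schema.field_names}
    missing = required - set(tidy.columns)
    if missing:
        raise SchemaError(f"tidy table lacks columns {sorted(missing)}")

    def render(v):
        f = float(v)
        return str(int(f)) if f == int(f) else str(f)

    keys = list(schema.field_names)
    name_of = {}
    order: list[str] = []
    for _, row in tidy[keys].drop_duplicates().iterrows():
        fields = {
            f: render(row[f]) if f == schema.dilution_field else str(row[f])
            for f in keys
        }
        name = schema.join(fields)
        name_of[tuple(row[f] for f in keys)] = name
        order.append(name)

    wide = tidy.assign(
        _name=[name_of[t] for t in zip(*(tidy[f] for f in keys))]
    ).pivot_table(
        index="particle_size", columns="_name", values="count",
        aggfunc="first", observed=True,
    )[order]
    if wide.isna().any().any():
        bad = wide.columns[wide.isna().any()].tolist()
        raise GridMismatchError(
            f"measurements {bad} do not cover the full bin grid"
        )
    n_expected = wide.shape[0] * wide.shape[1]
    if len(tidy) != n_expected:
        raise GridMismatchError(
            f"{len(tidy)} rows cannot form a complete "
            f"{wide.shape[0]}x{wide.shape[1]} grid"
        )

    centers = wide.index.to_numpy(dtype=float)
    if meta is None:
        if centers.size > 1:
            diffs = np.diff(centers)
            w = float(np.median(diffs))
            if not np.allclose(diffs, w, rtol=_REL_TOL, atol=_REL_TOL * w):
                raise GridMismatchError("bin centres are not uniformly spaced")
        else:
            w = 2 * centers[0] if centers[0] > 0 else 1.0
        meta = AcquisitionMeta(
            software_version="3.2",
            bin_width=w,
            size_min=max(0.0, float(centers[0]) - w / 2),
            size_max=float(centers[-1]) + w / 2,
        )
    return WideExperimentTable(
        meta=meta,
        bin_centers=centers,
        measurement_names=tuple(wide.columns),
        counts=wide.to_numpy(dtype=float),
    )


def save_tidy(tidy: pd.DataFrame, path) -> None:
    """Write a tidy table as CSV plus a ``<path>.schema.json`` sidecar.

    The sidecar records column order, dtypes, categorical level order
    and the row count, so :func:`load_tidy` restores the table exactly
    and can detect truncated files.
    """
    path = str(path)
    columns = {}
    for col in tidy.columns:
        s = tidy[col]
        if isinstance(s.dtype, pd.CategoricalDtype):
            columns[col] = {"kind": "categorical",
                            "levels": [str(v) for v in s.cat.categories]}
        elif pd.api.types.is_float_dtype(s) or pd.api.types.is_integer_dtype(s):
            columns[col] = {"kind": "float"}
        else:
            columns[col] = {"kind": "str"}
    sidecar = {"format": "ntakit-tidy-v1", "n_rows": int(len(tidy)),
               "columns": columns}
    tidy.to_csv(path, index=False, float_format="%.17g")
    with open(path + ".schema.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def load_tidy(path) -> pd.DataFrame:
    """Read a tidy table written by :func:`save_tidy`, restoring dtypes."""
    path = str(path)
    try:
        with open(path + ".schema.json", "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read sidecar for {path}: {exc}")
    if sidecar.get("format") != "ntakit-tidy-v1":
        raise FormatError(f"{path}: unrecognised tidy format {sidecar.get('format')!r}")
    cols = sidecar["columns"]
    df = pd.read_csv(path, dtype={c: str for c in cols})
    if list(df.columns) != list(cols):
        raise FormatError(
            f"{path}: columns {list(df.columns)} do not match sidecar "
            f"{list(cols)}"
        )
    if len(df) != sidecar["n_rows"]:
        raise FormatError(
            f"{path}: {len(df)} rows on disk but sidecar records "
            f"{sidecar['n_rows']} (truncated file?)"
        )
    for col, info in cols.items():
        if info["kind"] == "categorical":
            df[col] = pd.Categorical(df[col], categories=info["levels"])
            if df[col].isna().any() and sidecar["n_rows"] > 0:
                raise FormatError(f"{path}: value outside recorded levels in {col!r}")
        elif info["kind"] == "float":
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value in column {col!r}: {exc}")
    return df
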