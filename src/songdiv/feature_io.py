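"""Song-feature data model: measurement codes, feature tables, validation.

Acoustic measurements are keyed by short codes: a mandatory quantity digit
(1-9), an optional syllable letter (a-h) and an optional note digit. ``1``
is the duration of the whole song, ``1b`` the duration of syllable b and
``1b1`` the duration of note 1 of syllable b. Quantity 8 (slur direction,
up- or down-slurred) is the single categorical measurement; everything else
is numeric (seconds, hertz, counts, or a percentage).
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementCodeError",
    "FeatureTableError",
    "MeasurementDescriptor",
    "FeatureTable",
    "ValidationReport",
    "parse_measurement_code",
    "read_feature_table",
    "write_feature_table",
    "validate_feature_table",
]


class MeasurementCodeError(ValueError):
    """A string does not conform to the measurement-code grammar."""


class FeatureTableError(ValueError):
    """A feature table violates a structural contract."""


#: quantity digit -> (name, dtype)
QUANTITIES: dict[int, tuple[str, str]] = {
    1: ("duration_s", "numeric"),
    2: ("peak_freq_hz", "numeric"),
    3: ("min_freq_hz", "numeric"),
    4: ("max_freq_hz", "numeric"),
    5: ("n_repeats", "numeric"),
    6: ("n_notes", "numeric"),
    7: ("n_syllables", "numeric"),
    8: ("slur", "categorical"),
    9: ("proportion_pct", "numeric"),
}

COUNT_QUANTITIES = {"n_repeats", "n_notes", "n_syllables"}
FREQ_QUANTITIES = {"peak_freq_hz", "min_freq_hz", "max_freq_hz"}
SLUR_LEVELS = ("U", "D")

_CODE_RE = re.compile(r"^([1-9])([a-hA-H])?([1-9][0-9]*)?$")


@dataclass(frozen=True)
class MeasurementDescriptor:
    """Parsed measurement code.

    ``scope`` is ``song`` for a bare quantity digit, ``syllable`` when a
    syllable letter is present and ``note`` when a note index is also
    present.
    """

    code: str
    quantity: str
    scope: str
    syllable: str | None = None
    note_index: int | None = None
    dtype: str = "numeric"

    def __post_init__(self) -> None:
        if self.note_index is not None and self.syllable is None:
            raise MeasurementCodeError(
                f"code {self.code!r}: note index requires a syllable letter"
            )


def parse_measurement_code(code: str) -> MeasurementDescriptor:
    """Parse a measurement code such as ``"1"``, ``"8a"`` or ``"1b1"``.

    The syllable letter is case-insensitive and stored lower-case.

    Raises
    ------
    MeasurementCodeError
        If ``code`` does not match the grammar
        ``<quantity 1-9>[<syllable a-h>[<note digit>]]``.
    """
    if not isinstance(code, str):
        raise MeasurementCodeError(f"measurement code must be a string, got {code!r}")
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise MeasurementCodeError(
            f"malformed measurement code {code!r}: expected "
            "<quantity digit 1-9>[<syllable letter a-h>[<note digit>]]"
        )
    qdigit, letter, note = m.groups()
    quantity, dtype = QUANTITIES[int(qdigit)]
    syllable = letter.lower() if letter else None
    note_index = int(note) if note else None
    if note_index is not None:
        scope = "note"
    elif syllable is not None:
        scope = "syllable"
    else:
        scope = "song"
    canonical = f"{qdigit}{syllable or ''}{note or ''}"
    return MeasurementDescriptor(
        code=canonical,
        quantity=quantity,
        scope=scope,
        syllable=syllable,
        note_index=note_index,
        dtype=dtype,
    )


@dataclass
class FeatureTable:
    """Individuals x mixed-type song features, with per-individual metadata.

    ``values`` has record ids as the index and measurement codes as
    columns; numeric columns are float (NaN marks a missing cell) and the
    categorical slur columns hold ``"U"``/``"D"`` tokens (NaN missing).
    ``meta`` is index-aligned and carries at least a taxon label column
    (named ``taxon``) plus optional ``latitude``/``longitude`` in decimal
    degrees.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    descriptors: tuple[MeasurementDescriptor, ...] = ()
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.descriptors:
            self.descriptors = tuple(
                parse_measurement_code(str(c)) for c in self.values.columns
            )
        if len(self.descriptors) != self.values.shape[1]:
            raise FeatureTableError("descriptor count does not match column count")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate record ids: {dups}")
        if not self.values.index.equals(self.meta.index):
            raise FeatureTableError("values and meta must share the same index")
        # normalise column names to canonical parsed codes
        self.values = self.values.copy()
        self.values.columns = [d.code for d in self.descriptors]
        for d in self.descriptors:
            col = self.values[d.code]
            if d.dtype == "numeric":
                try:
                    self.values[d.code] = pd.to_numeric(col)
                except (ValueError, TypeError) as exc:
                    raise FeatureTableError(
                        f"non-numeric content in numeric column {d.code!r}: {exc}"
                    ) from exc
            else:
                self.values[d.code] = col.astype("object").where(col.notna(), np.nan)

    # -- basic views ---------------------------------------------------
    @property
    def ids(self) -> list:
        return list(self.values.index)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def codes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def numeric_codes(self) -> list[str]:
        return [d.code for d in self.descriptors if d.dtype == "numeric"]

    @property
    def categorical_codes(self) -> list[str]:
        return [d.code for d in self.descriptors if d.dtype == "categorical"]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def taxon_labels(self) -> pd.Series:
        if "taxon" not in self.meta.columns:
            raise FeatureTableError("metadata has no 'taxon' column")
        return self.meta["taxon"]

    def has_coordinates(self) -> bool:
        return (
            {"latitude", "longitude"} <= set(self.meta.columns)
            and self.meta["latitude"].notna().all()
            and self.meta["longitude"].notna().all()
        )

    # -- manipulation --------------------------------------------------
    def subset_features(self, codes: Sequence[str]) -> "FeatureTable":
        keep = [c for c in self.codes if c in set(codes)]
        desc = tuple(d for d in self.descriptors if d.code in set(keep))
        return FeatureTable(self.values[keep].copy(), self.meta.copy(), desc,
                            dict(self.attrs))

    def subset_individuals(self, ids: Sequence) -> "FeatureTable":
        return FeatureTable(
            self.values.loc[list(ids)].copy(),
            self.meta.loc[list(ids)].copy(),
            self.descriptors,
            dict(self.attrs),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.values.copy(), self.meta.copy(), self.descriptors, dict(self.attrs)
        )

    @staticmethod
    def concat(tables: Sequence["FeatureTable"]) -> "FeatureTable":
        """Row-concatenate tables sharing one feature schema."""
        codes = tables[0].codes
        for t in tables[1:]:
            if t.codes != codes:
                raise FeatureTableError("cannot concatenate tables with different schemas")
        values = pd.concat([t.values for t in tables], axis=0)
        meta = pd.concat([t.meta for t in tables], axis=0)
        return FeatureTable(values, meta, tables[0].descriptors)


def write_feature_table(table: FeatureTable, path_or_buf) -> None:
    """Write a feature table to CSV (id, metadata columns, then codes)."""
    out = table.meta.copy()
    for code in table.codes:
        out[code] = table.values[code]
    out.index.name = out.index.name or "id"
    out.to_csv(path_or_buf, na_rep="NA")


def read_feature_table(
    path_or_buf,
    taxon_column: str = "taxon",
    meta_columns: Sequence[str] = ("latitude", "longitude"),
    id_column: str = "id",
) -> FeatureTable:
    """Read a CSV feature table.

    The header holds measurement codes plus the id/metadata columns; empty
    cells and ``NA`` are read as missing (never silently zero). Any header
    entry that is not the id column, the taxon column or a listed metadata
    column must parse as a measurement code.
    """
    df = pd.read_csv(
        path_or_buf,
        keep_default_na=False,
        na_values=["", "NA"],
        dtype=str,
    )
    if id_column not in df.columns:
        raise FeatureTableError(f"missing id column {id_column!r}")
    if df[id_column].duplicated().any():
        dups = df.loc[df[id_column].duplicated(), id_column].tolist()
        raise FeatureTableError(f"duplicate record ids: {dups}")
    df = df.set_index(id_column)

    meta_cols = [c for c in [taxon_column, *meta_columns] if c in df.columns]
    feature_cols = [c for c in df.columns if c not in meta_cols]
    descriptors = tuple(parse_measurement_code(c) for c in feature_cols)

    meta = df[meta_cols].copy()
    if taxon_column in meta.columns and taxon_column != "taxon":
        meta = meta.rename(columns={taxon_column: "taxon"})
    for c in ("latitude", "longitude"):
        if c in meta.columns:
            meta[c] = pd.to_numeric(meta[c])
    if "variant_flag" in meta.columns:
        meta["variant_flag"] = meta["variant_flag"].map(
            {"True": True, "False": False}
        ).fillna(False)

    values = df[feature_cols].copy()
    for d in descriptors:
        if d.dtype == "numeric":
            try:
                values[d.code] = pd.to_numeric(values[d.code])
            except (ValueError, TypeError) as exc:
                raise FeatureTableError(
                    f"non-numeric content in numeric column {d.code!r}: {exc}"
                ) from exc
    return FeatureTable(values, meta, descriptors)


@dataclass
class ValidationReport:
    """Report-only summary of a feature table; never raises."""

    n_individuals: int
    features: dict[str, dict]
    problems: list[str]

    @property
    def ok(self) -> bool:
        return not self.problems

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "n_individuals": self.n_individuals,
                "features": self.features,
                "problems": self.problems,
                "ok": self.ok,
            },
            **kw,
        )


def validate_feature_table(table: FeatureTable) -> ValidationReport:
    """Summarise per-feature missingness, dtype and range; flag anomalies.

    Flags ``all_missing`` and ``constant`` columns, and records range
    violations (negative durations or frequencies, non-integer or negative
    counts, proportions outside [0, 100], slur tokens outside {U, D},
    non-finite numeric cells) as problems.
    """
    features: dict[str, dict] = {}
    problems: list[str] = []
    for d in table.descriptors:
        col = table.values[d.code]
        obs = col.dropna()
        entry: dict = {
            "dtype": d.dtype,
            "quantity": d.quantity,
            "missing_fraction": float(col.isna().mean()) if len(col) else 1.0,
            "flags": [],
        }
        if obs.empty:
            entry["flags"].append("all_missing")
        elif d.dtype == "numeric":
            arr = obs.to_numpy(dtype=float)
            if not np.all(np.isfinite(arr)):
                problems.append(f"{d.code}: non-finite numeric values")
                arr = arr[np.isfinite(arr)]
            if arr.size:
                entry["min"] = float(arr.min())
                entry["max"] = float(arr.max())
                if arr.min() == arr.max():
                    entry["flags"].append("constant")
                if d.quantity in ("duration_s", *FREQ_QUANTITIES) and arr.min() < 0:
                    problems.append(f"{d.code}: negative {d.quantity}")
                if d.quantity in COUNT_QUANTITIES and (
                    arr.min() < 0 or not np.allclose(arr, np.round(arr))
                ):
                    problems.append(f"{d.code}: counts must be non-negative integers")
                if d.quantity == "proportion_pct" and (
                    arr.min() < 0 or arr.max() > 100
                ):
                    problems.append(f"{d.code}: proportion outside [0, 100]")
        else:
            levels = sorted(set(obs))
            entry["levels"] = levels
            if len(levels) == 1:
                entry["flags"].append("constant")
            bad = set(levels) - set(SLUR_LEVELS)
            if bad:
                problems.append(f"{d.code}: slur values outside {{U, D}}: {sorted(bad)}")
        features[d.code] = entry
    return ValidationReport(table.n_individuals, features, problems)


def read_divergence_table(path_or_buf) -> pd.DataFrame:
    """Read a per-pair divergence table (pair_id, delta_p,
    mtdna_relative_time) and validate it: one row per pair, scores and
    relative times finite and non-negative."""
    df = pd.read_csv(path_or_buf)
    required = {"pair_id", "delta_p", "mtdna_relative_time"}
    missing = required - set(df.columns)
    if missing:
        raise FeatureTableError(f"divergence table missing columns: {sorted(missing)}")
    if df["pair_id"].duplicated().any():
        raise FeatureTableError("duplicate pair_id in divergence table")
    for col in ("delta_p", "mtdna_relative_time"):
        vals = pd.to_numeric(df[col])
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise FeatureTableError(f"{col} must be finite and non-negative")
        df[col] = vals
    return df


def require_min_group_sizes(table: FeatureTable, minimum: int = 2) -> None:
    """Fail fast unless every taxon label has at least ``minimum`` members."""
    counts = table.taxon_labels.value_counts()
    small = counts[counts < minimum]
    if len(small):
        raise FeatureTableError(
            f"taxa with fewer than {minimum} individuals: {dict(small)}"
        )
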