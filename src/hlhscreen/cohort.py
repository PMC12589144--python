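"""Patient records, cohorts and delimited-text I/O.

A cohort is an ordered collection of :class:`PatientRecord` — one row per
patient, carrying clinical flags (fever, organomegaly, immunosuppression,
haemophagocytosis) and laboratory values. Serum ferritin is special: the
assay has an upper quantification limit (16,500 ug/L in the study this
package replicates), so ferritin is held as a :class:`CensoredValue` that
remembers whether the reported number is a true measurement or the assay
ceiling. Any other field may simply be missing (``None``) — retrospective
cohorts routinely lack triglycerides, fibrinogen and AST because the tests
were never requested — and missingness is deliberately distinct from a
recorded "no"/normal value; the scoring engines decide how to treat it.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

__all__ = [
    "CensoredValue",
    "PatientRecord",
    "Cohort",
    "CohortReadError",
    "FERRITIN_ASSAY_CEILING",
    "FERRITIN_INCLUSION_THRESHOLD",
    "read_cohort",
    "write_cohort",
    "select_peak_presentation",
    "numeric_ferritin",
]

#: Upper quantification limit of the study's ferritin assay (ug/L).
FERRITIN_ASSAY_CEILING = 16_500.0

#: Cohort inclusion rule: peak serum ferritin strictly above this (ug/L).
FERRITIN_INCLUSION_THRESHOLD = 5_000.0


@dataclass(frozen=True)
class CensoredValue:
    """A lab value that may be right-censored at the assay ceiling.

    When ``censored`` is true the stored ``value`` *is* the ceiling — the
    true value is only known to be at or above it.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"lab value must be finite and >= 0, got {self.value}")

    def __str__(self) -> str:
        num = f"{self.value:g}"
        return f">{num}" if self.censored else num


# Policies for turning a CensoredValue into a plain number.
_CENSORING_POLICIES = ("ceiling", "exclude")

#: Sentinel returned by :func:`numeric_ferritin` under the "exclude" policy.
EXCLUDED = None


def numeric_ferritin(v: CensoredValue, policy: str = "ceiling") -> float | None:
    """Numeric ferritin under a censoring policy.

    ``"ceiling"`` (default) uses the stored value — the assay ceiling when
    censored; this is the convention under which the study's printed group
    mean is reproducible. ``"exclude"`` returns ``None`` for censored
    values so callers can drop them.
    """
    if policy not in _CENSORING_POLICIES:
        raise ValueError(
            f"unknown censoring policy {policy!r}; expected one of {_CENSORING_POLICIES}"
        )
    if policy == "exclude" and v.censored:
        return EXCLUDED
    return v.value


@dataclass
class PatientRecord:
    """One patient's clinical flags and labs at (peak-ferritin) presentation.

    Boolean clinical flags are ``True``/``False``/``None`` — ``None`` means
    the feature was never assessed, which is not the same as absent.
    """

    patient_id: str
    ferritin_ugL: CensoredValue
    age_years: int | None = None
    fever_documented: bool | None = None
    temperature_celsius: float | None = None
    hepatomegaly: bool | None = None
    splenomegaly: bool | None = None
    immunosuppressed: bool | None = None  # HIV+ or long-term immunosuppressive therapy
    haemoglobin_gL: float | None = None
    platelets_1e9L: float | None = None
    neutrophils_1e9L: float | None = None
    triglycerides_mmolL: float | None = None
    fibrinogen_gL: float | None = None
    ast_UL: float | None = None
    alt_UL: float | None = None
    haemophagocytosis: bool | None = None
    nk_activity_low: bool | None = None
    scd25_UmL: float | None = None
    clinician_hlh_diagnosis: bool = False
    conditions: list[str] = field(default_factory=list)

    _NUMERIC_FIELDS = (
        "temperature_celsius",
        "haemoglobin_gL",
        "platelets_1e9L",
        "neutrophils_1e9L",
        "triglycerides_mmolL",
        "fibrinogen_gL",
        "ast_UL",
        "alt_UL",
        "scd25_UmL",
    )
    _BOOL_FIELDS = (
        "fever_documented",
        "hepatomegaly",
        "splenomegaly",
        "immunosuppressed",
        "haemophagocytosis",
        "nk_activity_low",
    )

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        for name in self._NUMERIC_FIELDS:
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {val}")

    def has_fever(self) -> bool | None:
        """Fever present? Uses the documented flag, falling back to an
        exact temperature (>= 38.5 C) when only that is recorded."""
        if self.fever_documented is not None:
            return self.fever_documented
        if self.temperature_celsius is not None:
            return self.temperature_celsius >= 38.5
        return None


class CohortReadError(ValueError):
    """Malformed cohort file; carries per-cell error locations."""

    def __init__(self, message: str, cell_errors: list[tuple[int, str, str]] | None = None):
        super().__init__(message)
        self.cell_errors = cell_errors or []


@dataclass
class Cohort:
    """Ordered collection of patient records with unique ids."""

    patients: list[PatientRecord]
    provenance: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.patients[i]

    def ferritin_values(self, policy: str = "ceiling") -> list[float]:
        """Numeric ferritins under the given censoring policy (excluded
        values dropped)."""
        vals = (numeric_ferritin(p.ferritin_ugL, policy) for p in self.patients)
        return [v for v in vals if v is not None]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {f.name: getattr(p, f.name) for f in fields(p)}
            row["ferritin_ugL"] = str(p.ferritin_ugL)
            row["conditions"] = "; ".join(p.conditions)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_TRUE_STRINGS = {"true", "yes", "y", "1"}
_FALSE_STRINGS = {"false", "no", "n", "0"}


def _parse_bool(cell: str) -> bool:
    low = cell.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise ValueError(f"not a boolean: {cell!r}")


def _parse_number(cell: str) -> float:
    return float(cell.strip().replace(",", ""))


def parse_ferritin(cell: str, ceiling: float = FERRITIN_ASSAY_CEILING) -> CensoredValue:
    """Parse a ferritin cell; a ``>`` prefix, or equality with the assay
    ceiling, marks the value censored (mirrors the ">16,500" notation)."""
    text = cell.strip()
    if text.startswith(">"):
        val = _parse_number(text[1:])
        return CensoredValue(val, censored=True)
    val = _parse_number(text)
    return CensoredValue(val, censored=(val == ceiling))


def _load_schema(schema_config) -> dict[str, str]:
    """Column mapping {field_name: column_name}; accepts a dict or a YAML path."""
    if schema_config is None:
        return {}
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise CohortReadError(f"schema config {schema_config} must be a mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    return dict(schema_config)


def read_cohort(
    path: str | Path,
    schema_config: dict[str, str] | str | Path | None = None,
    sep: str | None = None,
    ceiling: float = FERRITIN_ASSAY_CEILING,
) -> Cohort:
    """Read a cohort from a delimited text file (CSV/TSV autodetected).

    ``schema_config`` maps record field names to column names for files
    whose headers differ from the canonical ones. Empty cells become
    missing fields; ferritin cells with a ``>`` prefix (or equal to the
    ceiling) become censored. Malformed numeric cells are collected and
    reported together with their row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = _load_schema(schema_config)
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python", keep_default_na=False)

    def col(field_name: str) -> str:
        return mapping.get(field_name, field_name)

    for required in ("patient_id", "ferritin_ugL"):
        if col(required) not in df.columns:
            raise CohortReadError(
                f"required column {col(required)!r} (field {required!r}) missing from {path}"
            )

    bool_fields = set(PatientRecord._BOOL_FIELDS) | {"clinician_hlh_diagnosis"}
    numeric_fields = set(PatientRecord._NUMERIC_FIELDS) | {"age_years"}

    patients: list[PatientRecord] = []
    cell_errors: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        kwargs: dict = {"patient_id": str(row[col("patient_id")]).strip()}
        ferr_cell = str(row[col("ferritin_ugL")]).strip()
        try:
            kwargs["ferritin_ugL"] = parse_ferritin(ferr_cell, ceiling)
        except ValueError:
            cell_errors.append((int(idx) + 2, col("ferritin_ugL"), ferr_cell))
            continue
        for f in fields(PatientRecord):
            if f.name in ("patient_id", "ferritin_ugL", "conditions"):
                continue
            column = col(f.name)
            if column not in df.columns:
                continue
            cell = str(row[column]).strip()
            if cell == "":
                continue
            try:
                if f.name in bool_fields:
                    kwargs[f.name] = _parse_bool(cell)
                elif f.name in numeric_fields:
                    val = _parse_number(cell)
                    kwargs[f.name] = int(val) if f.name == "age_years" else val
                else:
                    kwargs[f.name] = cell
            except ValueError:
                # header row is line 1, hence +2 for a 1-based file line
                cell_errors.append((int(idx) + 2, column, cell))
        cond_col = col("conditions")
        if cond_col in df.columns:
            cell = str(row[cond_col]).strip()
            kwargs["conditions"] = [c.strip() for c in cell.split(";") if c.strip()]
        try:
            patients.append(PatientRecord(**kwargs))
        except ValueError as exc:
            cell_errors.append((int(idx) + 2, "<record>", str(exc)))
    if cell_errors:
        detail = "; ".join(f"line {ln}, column {c}: {v!r}" for ln, c, v in cell_errors)
        raise CohortReadError(f"malformed cells in {path}: {detail}", cell_errors)
    return Cohort(patients, provenance=str(path))


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort as delimited text; round-trips every field and the
    ferritin censoring flag exactly (censored values get a ``>`` prefix)."""
    path = Path(path)
    cols = [f.name for f in fields(PatientRecord)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(cols)
        for p in cohort:
            row = []
            for name in cols:
                val = getattr(p, name)
                if name == "ferritin_ugL":
                    row.append(str(val))
                elif name == "conditions":
                    row.append("; ".join(val))
                elif val is None:
                    row.append("")
                elif isinstance(val, bool):
                    row.append("true" if val else "false")
                elif isinstance(val, float):
                    row.append(repr(val))
                else:
                    row.append(str(val))
            writer.writerow(row)


def select_peak_presentation(records: Sequence[PatientRecord]) -> PatientRecord:
    """From serial presentations of one patient, pick the one at peak
    ferritin (censored compares as the ceiling; ties broken by earliest
    record order)."""
    records = list(records)
    if not records:
        raise ValueError("select_peak_presentation: empty record collection")
    ids = {r.patient_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple patients: {sorted(ids)}")
    best = records[0]
    for r in records[1:]:
        if r.ferritin_ugL.value > best.ferritin_ugL.value:
            best = r
    return best
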