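"""Cohort data model, derived clinical quantities, and CSV/JSON round-tripping.

A cohort is a per-patient table of biomarker/clinical features plus outcome
fields.  Feature semantics (category, units, measurement-scale transform) live
in a schema of :class:`FeatureSpec` entries serialized as a JSON sidecar next
to the cohort CSV.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "PatientRecord",
    "CohortTable",
    "LipidPanel",
    "friedewald_ldl",
    "adjudicate_outcome",
    "read_cohort",
    "write_cohort",
    "OUTCOME_LABELS",
    "DISPOSITIONS",
    "OUTCOME_COLUMNS",
]

FEATURE_CATEGORIES = frozenset(
    {"lipid", "endothelial", "inflammatory", "sofa_component", "vital_sign",
     "clinical", "severity_score"}
)
OUTCOME_LABELS = ("rapid_recovery", "cci", "early_death")
DISPOSITIONS = frozenset(
    {"home", "rehab", "skilled_nursing", "ltac", "other_hospital", "hospice", "died"}
)
#: outcome/admin columns following the feature block in a cohort CSV
OUTCOME_COLUMNS = (
    "icu_days", "organ_dysfunction_at_day14", "death_day", "disposition",
    "mortality_28d", "mortality_1y", "outcome",
)

# Dispositions that qualify a short ICU stay as chronic critical illness
_CCI_DISPOSITIONS = frozenset({"ltac", "other_hospital", "hospice"})


class SchemaError(ValueError):
    """A column or feature name that the schema does not define."""


class AdjudicationError(ValueError):
    """A record that cannot be adjudicated without guessing."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one measured variable.

    Parameters
    ----------
    name : str
        Unique identifier within a schema (e.g. ``"hdl_c"``).
    category : str
        One of lipid, endothelial, inflammatory, sofa_component, vital_sign,
        clinical, severity_score.
    units : str
        Free-text units (mg/dL, pg/mL, nmol/min/ml, score points, ...).
    transform : str
        ``"log"`` for right-skewed strictly positive measurements modelled on
        the log scale, else ``"none"``.
    required : bool
        Whether the feature must be present for a patient to be analysable.
    """

    name: str
    category: str
    units: str = ""
    transform: str = "none"
    required: bool = False

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")


def _validate_schema(schema: Iterable[FeatureSpec]) -> list[FeatureSpec]:
    schema = list(schema)
    names = [s.name for s in schema]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise SchemaError(f"duplicate feature names in schema: {dupes}")
    return schema


@dataclass
class PatientRecord:
    """One patient's features and outcome fields.

    ``death_day`` is 1-based days from sepsis onset for in-hospital deaths;
    "within 2 weeks" means ``death_day <= 14``.
    """

    patient_id: str
    features: dict[str, float] = field(default_factory=dict)
    icu_days: Optional[int] = None
    organ_dysfunction_at_day14: Optional[bool] = None
    death_day: Optional[int] = None
    disposition: Optional[str] = None
    mortality_28d: Optional[bool] = None
    mortality_1y: Optional[bool] = None
    outcome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.icu_days is not None and self.icu_days < 0:
            raise ValueError(f"{self.patient_id}: icu_days must be >= 0")
        if self.death_day is not None:
            if self.death_day < 1:
                raise ValueError(f"{self.patient_id}: death_day must be >= 1")
            if self.disposition is not None and self.disposition != "died":
                raise ValueError(
                    f"{self.patient_id}: death_day present but disposition is "
                    f"{self.disposition!r}, not 'died'"
                )
        if self.disposition is not None and self.disposition not in DISPOSITIONS:
            raise ValueError(f"{self.patient_id}: unknown disposition {self.disposition!r}")
        if self.outcome is not None and self.outcome not in OUTCOME_LABELS:
            raise ValueError(f"{self.patient_id}: unknown outcome {self.outcome!r}")


class CohortTable:
    """Ordered collection of patients sharing a feature schema.

    The universal currency of the pipeline: downstream stages operate on the
    pandas view returned by :meth:`to_frame` and on the outcome columns.
    """

    def __init__(self, cohort_id: str, schema: Iterable[FeatureSpec],
                 patients: Iterable[PatientRecord]):
        self.cohort_id = cohort_id
        self.schema = _validate_schema(schema)
        self.patients = list(patients)
        names = set(self.feature_names)
        for p in self.patients:
            extra = set(p.features) - names
            if extra:
                raise SchemaError(
                    f"patient {p.patient_id}: features not in schema: {sorted(extra)}"
                )

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.schema]

    def __len__(self) -> int:
        return len(self.patients)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise SchemaError(f"feature {name!r} not in schema")

    def to_frame(self) -> pd.DataFrame:
        """Feature matrix (patients x features) with NaN for missing cells."""
        data = {
            name: [p.features.get(name, math.nan) for p in self.patients]
            for name in self.feature_names
        }
        return pd.DataFrame(data, index=[p.patient_id for p in self.patients], dtype=float)

    def outcome_frame(self) -> pd.DataFrame:
        """Outcome/admin columns, indexed by patient id."""
        rows = {
            col: [getattr(p, col) for p in self.patients] for col in OUTCOME_COLUMNS
        }
        return pd.DataFrame(rows, index=[p.patient_id for p in self.patients])

    def adjudicate(self, cci_icu_threshold: int = 14) -> "CohortTable":
        """Fill the ``outcome`` field of every patient in place; returns self."""
        for p in self.patients:
            p.outcome = adjudicate_outcome(p, cci_icu_threshold=cci_icu_threshold)
        return self


@dataclass
class LipidPanel:
    """Enrollment lipid panel in mg/dL; ``ldl_derived`` marks Friedewald LDL-C."""

    tc: float
    hdl: float
    tg: float
    ldl: Optional[float] = None
    ldl_derived: bool = False

    def __post_init__(self) -> None:
        for label, v in (("tc", self.tc), ("hdl", self.hdl), ("tg", self.tg)):
            if v < 0:
                raise ValueError(f"{label} must be non-negative, got {v}")

    def with_derived_ldl(self, tg_bound: Optional[float] = 400.0) -> "LipidPanel":
        ldl = friedewald_ldl(self.tc, self.hdl, self.tg, tg_bound=tg_bound)
        return LipidPanel(self.tc, self.hdl, self.tg, ldl=ldl, ldl_derived=True)


def friedewald_ldl(tc: float, hdl: float, tg: float,
                   tg_bound: Optional[float] = 400.0) -> float:
    """Estimate LDL-C (mg/dL) from a fasting lipid panel: TC − HDL-C − TG/5.

    The estimate assumes VLDL cholesterol ≈ TG/5, which breaks down at high
    triglycerides; by default the standard validity bound TG < 400 mg/dL is
    enforced.  Pass ``tg_bound=None`` to disable the bound.
    """
    for label, v in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{label} must be a non-negative finite number, got {v}")
    if tg_bound is not None and tg >= tg_bound:
        raise ValueError(
            f"triglycerides {tg} mg/dL >= {tg_bound}: Friedewald estimate invalid"
        )
    return tc - hdl - tg / 5.0


def adjudicate_outcome(record: PatientRecord, cci_icu_threshold: int = 14) -> str:
    """Assign the primary outcome label for one patient.

    early_death
        in-hospital death within 14 days of sepsis onset.
    cci (chronic critical illness)
        ICU stay > 14 days with continued organ dysfunction at day 14, or a
        shorter ICU stay ending in discharge to long-term acute care, another
        hospital, or hospice.
    rapid_recovery
        everything else.

    Raises
    ------
    AdjudicationError
        If the ICU stay exceeds the threshold but day-14 organ-dysfunction
        status is missing (we refuse to default it silently), or if required
        fields are absent.
    """
    if record.death_day is not None and record.death_day <= 14:
        return "early_death"
    if record.icu_days is None:
        raise AdjudicationError(f"{record.patient_id}: icu_days missing")
    if record.disposition is None:
        raise AdjudicationError(f"{record.patient_id}: disposition missing")
    if record.icu_days > cci_icu_threshold:
        if record.organ_dysfunction_at_day14 is None:
            raise AdjudicationError(
                f"{record.patient_id}: ICU stay {record.icu_days} d > "
                f"{cci_icu_threshold} but organ_dysfunction_at_day14 is missing"
            )
        if record.organ_dysfunction_at_day14:
            return "cci"
    if record.icu_days <= cci_icu_threshold and record.disposition in _CCI_DISPOSITIONS:
        return "cci"
    return "rapid_recovery"


# ---------------------------------------------------------------------------
# CSV / JSON plumbing
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA"}


def _schema_to_json(schema: list[FeatureSpec]) -> list[dict]:
    return [
        {"name": s.name, "category": s.category, "units": s.units,
         "transform": s.transform, "required": s.required}
        for s in schema
    ]


def schema_from_json(obj: list[dict]) -> list[FeatureSpec]:
    return _validate_schema(FeatureSpec(**d) for d in obj)


def _fmt(value, integer: bool = False) -> str:
    if value is None:
        return ""
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, float) and math.isnan(value):
        return ""
    if integer:
        return str(int(value))
    # repr keeps round-trips bit-stable for <= 17 significant digits
    return repr(float(value)) if isinstance(value, float) else str(value)


def _parse_bool(tok: str, ctx: str):
    if tok in _MISSING_TOKENS:
        return None
    if tok.lower() in ("true", "1"):
        return True
    if tok.lower() in ("false", "0"):
        return False
    raise ValueError(f"{ctx}: cannot parse boolean {tok!r}")


def write_cohort(table: CohortTable, path: str | Path,
                 schema_path: str | Path | None = None) -> None:
    """Write a cohort CSV (+ JSON schema sidecar).

    Layout: ``patient_id`` first, feature columns in schema order, then the
    outcome columns.  Missing cells are written empty.
    """
    path = Path(path)
    names = table.feature_names
    lines = [",".join(["patient_id", *names, *OUTCOME_COLUMNS])]
    for p in table.patients:
        cells = [p.patient_id]
        cells += [_fmt(p.features.get(n, math.nan)) for n in names]
        cells.append(_fmt(p.icu_days, integer=True))
        cells.append(_fmt(p.organ_dysfunction_at_day14))
        cells.append(_fmt(p.death_day, integer=True))
        cells.append(p.disposition or "")
        cells.append(_fmt(p.mortality_28d))
        cells.append(_fmt(p.mortality_1y))
        cells.append(p.outcome or "")
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    if schema_path is None:
        schema_path = path.with_suffix(".schema.json")
    Path(schema_path).write_text(
        json.dumps({"cohort_id": table.cohort_id,
                    "schema": _schema_to_json(table.schema)}, indent=2) + "\n"
    )


def read_cohort(path: str | Path, schema: Iterable[FeatureSpec] | str | Path,
                cohort_id: str | None = None) -> CohortTable:
    """Read a cohort CSV against a schema (list of FeatureSpec or sidecar path).

    Empty cells and the token ``NA`` denote missing.  Unknown columns raise
    :class:`SchemaError`; non-numeric feature cells raise ``ValueError`` with
    row/column context.
    """
    path = Path(path)
    if isinstance(schema, (str, Path)):
        side = json.loads(Path(schema).read_text())
        if cohort_id is None:
            cohort_id = side.get("cohort_id")
        schema = schema_from_json(side["schema"])
    schema = _validate_schema(schema)
    names = [s.name for s in schema]

    raw = path.read_text().splitlines()
    header = raw[0].split(",")
    expected = {"patient_id", *names, *OUTCOME_COLUMNS}
    unknown = [c for c in header if c not in expected]
    if unknown:
        raise SchemaError(f"{path.name}: columns not in schema: {unknown}")
    if header[0] != "patient_id":
        raise SchemaError(f"{path.name}: first column must be patient_id")
    col = {c: i for i, c in enumerate(header)}

    def get(cells: list[str], name: str) -> str:
        i = col.get(name)
        return cells[i] if i is not None and i < len(cells) else ""

    patients = []
    for rownum, line in enumerate(raw[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(",")
        pid = cells[col["patient_id"]]
        feats: dict[str, float] = {}
        for n in names:
            tok = get(cells, n)
            if tok in _MISSING_TOKENS:
                continue
            try:
                feats[n] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path.name} row {rownum}, column {n!r}: "
                    f"non-numeric feature cell {tok!r}"
                ) from None
        icu = get(cells, "icu_days")
        dday = get(cells, "death_day")
        dispo = get(cells, "disposition")
        outc = get(cells, "outcome")
        patients.append(PatientRecord(
            patient_id=pid,
            features=feats,
            icu_days=None if icu in _MISSING_TOKENS else int(float(icu)),
            organ_dysfunction_at_day14=_parse_bool(
                get(cells, "organ_dysfunction_at_day14"), f"row {rownum}"),
            death_day=None if dday in _MISSING_TOKENS else int(float(dday)),
            disposition=dispo if dispo not in _MISSING_TOKENS else None,
            mortality_28d=_parse_bool(get(cells, "mortality_28d"), f"row {rownum}"),
            mortality_1y=_parse_bool(get(cells, "mortality_1y"), f"row {rownum}"),
            outcome=outc if outc not in _MISSING_TOKENS else None,
        ))
    return CohortTable(cohort_id or path.stem, schema, patients)
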