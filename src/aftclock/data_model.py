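"""Domain types, long-format table I/O, validation, and study inclusion filters.

The cohort is stored in tidy (long) format: one row per biomarker
measurement, because markers have very unequal visit counts (roughly half
the cohort has a single amyloid scan while a third has three or more FLAIR
MRIs, and 40% have no tau scan at all).  Participant-level covariates live
in a separate table keyed by participant id.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is missing or a value cannot be parsed."""


class LinkageError(ValueError):
    """Observations reference participants without covariate records."""


class Marker(str, enum.Enum):
    """Imaging biomarkers handled by the pipeline.

    ``AMYLOID_PET`` and ``TAU_PET`` are meta-ROI SUVRs, ``WMH_PCT`` is white
    matter hyperintensity volume as a percent of total intracranial volume,
    ``FA_GCC`` is fractional anisotropy in the genu of the corpus callosum,
    and ``HVA`` is head-size-adjusted hippocampal volume.
    """

    AMYLOID_PET = "amyloid_pet"
    TAU_PET = "tau_pet"
    WMH_PCT = "wmh_pct"
    FA_GCC = "fa_gcc"
    HVA = "hva"

    @classmethod
    def parse(cls, name: str) -> "Marker":
        """Canonicalize a marker name: strip whitespace, case-insensitive,
        tolerate missing underscores (``"amyloidPET "`` -> ``AMYLOID_PET``).
        Unknown names are errors, never silently skipped."""
        key = "".join(str(name).split()).lower().replace("-", "_")
        aliases = {m.value.replace("_", ""): m for m in cls}
        aliases.update({m.value: m for m in cls})
        if key in aliases:
            return aliases[key]
        raise SchemaError(f"unknown marker name: {name!r}")


class Apoe4(str, enum.Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNKNOWN = "unknown"


#: Markers that count as PET for the inclusion filter.
PET_MARKERS = frozenset({Marker.AMYLOID_PET, Marker.TAU_PET})
#: Markers that count as MRI for the inclusion filter.
MRI_MARKERS = frozenset({Marker.WMH_PCT, Marker.FA_GCC, Marker.HVA})

VISITS_COLUMNS = ["participant_id", "marker", "age", "raw_value", "scanner"]
COVARIATES_COLUMNS = ["participant_id", "apoe4", "female", "education", "referral"]


@dataclass(frozen=True)
class BiomarkerObservation:
    """One measurement of one marker at one visit age.

    ``raw_value`` is in marker-native units (SUVR, % of TIV, unitless FA);
    ``transformed_value`` is on the modeling scale and may be absent until
    transforms are applied.  ``scanner`` is an optional manufacturer label
    ("A"/"B") used by harmonization.
    """

    participant_id: str
    marker: Marker
    age: float
    raw_value: float
    transformed_value: float | None = None
    scanner: str | None = None

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise SchemaError(f"age must be positive, got {self.age}")
        if not np.isfinite(self.raw_value):
            raise SchemaError(f"raw_value must be finite, got {self.raw_value}")
        if self.marker is Marker.WMH_PCT and self.raw_value < 0:
            raise SchemaError("WMH% raw value must be >= 0")
        if self.marker is Marker.FA_GCC and not (0.0 < self.raw_value < 1.0):
            raise SchemaError("FA raw value must lie in (0, 1)")


@dataclass(frozen=True)
class ParticipantCovariates:
    """Per-person time-shift predictors."""

    participant_id: str
    apoe4: Apoe4
    female: bool
    education: float
    referral: bool

    def __post_init__(self) -> None:
        if self.education < 0:
            raise SchemaError("education must be >= 0 years")


@dataclass
class CohortDataset:
    """A validated cohort: observations plus one covariate record per person."""

    observations: list[BiomarkerObservation]
    covariates: list[ParticipantCovariates]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cov_ids = [c.participant_id for c in self.covariates]
        if len(set(cov_ids)) != len(cov_ids):
            dupes = sorted({i for i in cov_ids if cov_ids.count(i) > 1})
            raise LinkageError(f"duplicate covariate records for: {dupes}")
        obs_ids = {o.participant_id for o in self.observations}
        missing = sorted(obs_ids - set(cov_ids))
        if missing:
            raise LinkageError(
                f"observed participants lack covariate records: {missing}"
            )
        keys = [(o.participant_id, o.marker, o.age) for o in self.observations]
        if len(set(keys)) != len(keys):
            seen, dupes = set(), set()
            for k in keys:
                (dupes if k in seen else seen).add(k)
            raise SchemaError(
                f"duplicate (participant, marker, age) observations: {sorted(dupes)[:5]}"
            )

    @property
    def participant_ids(self) -> list[str]:
        return [c.participant_id for c in self.covariates]

    def observed_participants(self) -> set[str]:
        return {o.participant_id for o in self.observations}

    def markers_by_participant(self) -> dict[str, set[Marker]]:
        out: dict[str, set[Marker]] = {pid: set() for pid in self.participant_ids}
        for o in self.observations:
            out[o.participant_id].add(o.marker)
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        visits = pd.DataFrame(
            {
                "participant_id": [o.participant_id for o in self.observations],
                "marker": [o.marker.value for o in self.observations],
                "age": [o.age for o in self.observations],
                "raw_value": [o.raw_value for o in self.observations],
                "scanner": [o.scanner if o.scanner is not None else "" for o in self.observations],
            }
        )
        cov = pd.DataFrame(
            {
                "participant_id": [c.participant_id for c in self.covariates],
                "apoe4": [c.apoe4.value for c in self.covariates],
                "female": [int(c.female) for c in self.covariates],
                "education": [c.education for c in self.covariates],
                "referral": [int(c.referral) for c in self.covariates],
            }
        )
        return visits, cov


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {missing}")


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n"}:
        return False
    raise SchemaError(f"cannot parse boolean value: {value!r}")


def read_long_table(visits_path: str | Path, covariates_path: str | Path) -> CohortDataset:
    """Read a visits CSV and a covariates CSV into a validated cohort.

    The visits schema is ``participant_id,marker,age,raw_value,scanner``
    (scanner may be empty); the covariates schema is
    ``participant_id,apoe4,female,education,referral``.  Unknown APOE levels
    are preserved as the explicit ``unknown`` category, not dropped.
    """
    visits_path, covariates_path = Path(visits_path), Path(covariates_path)
    for p in (visits_path, covariates_path):
        if not p.exists():
            raise FileNotFoundError(p)
    visits = pd.read_csv(visits_path, dtype={"participant_id": str, "scanner": str})
    cov = pd.read_csv(covariates_path, dtype={"participant_id": str})
    _require_columns(visits, [c for c in VISITS_COLUMNS if c != "scanner"], "visits")
    _require_columns(cov, COVARIATES_COLUMNS, "covariates")

    observations = []
    has_scanner = "scanner" in visits.columns
    for row in visits.itertuples(index=False):
        scanner = getattr(row, "scanner", None) if has_scanner else None
        if scanner is not None and (pd.isna(scanner) or str(scanner).strip() == ""):
            scanner = None
        observations.append(
            BiomarkerObservation(
                participant_id=str(row.participant_id),
                marker=Marker.parse(row.marker),
                age=float(row.age),
                raw_value=float(row.raw_value),
                scanner=str(scanner).strip() if scanner is not None else None,
            )
        )
    covariates = [
        ParticipantCovariates(
            participant_id=str(r.participant_id),
            apoe4=Apoe4(str(r.apoe4).strip().lower()),
            female=_parse_bool(r.female),
            education=float(r.education),
            referral=_parse_bool(r.referral),
        )
        for r in cov.itertuples(index=False)
    ]
    return CohortDataset(observations=observations, covariates=covariates)


def write_long_table(
    dataset: CohortDataset, visits_path: str | Path, covariates_path: str | Path
) -> None:
    """Write the cohort back to the two-CSV schema (round-trip safe)."""
    visits, cov = dataset.to_frames()
    visits.to_csv(visits_path, index=False)
    cov.to_csv(covariates_path, index=False)


# Exclusion reasons are assigned in a fixed priority order so that the
# report is deterministic: age first, then missing PET, then missing MRI.
EXCLUSION_PRIORITY = ("age", "no_pet", "no_mri")


def apply_inclusion_filters(
    dataset: CohortDataset,
    min_age: float = 50.0,
    require_pet: bool = True,
    require_mri: bool = True,
) -> tuple[CohortDataset, dict]:
    """Apply participant-level study inclusion criteria.

    A participant is retained when they have at least one PET observation
    (amyloid or tau) at ``min_age`` or older (the age criterion is evaluated
    at PET when PET is required, otherwise at any observation), at least one
    PET if ``require_pet``, and at least one MRI if ``require_mri``.
    Returns the filtered cohort and a JSON-serializable exclusion report.
    """
    if min_age < 0:
        raise ValueError("min_age must be nonnegative")

    by_pid: dict[str, list[BiomarkerObservation]] = {}
    for o in dataset.observations:
        by_pid.setdefault(o.participant_id, []).append(o)

    retained_ids: set[str] = set()
    exclusions: dict[str, int] = {r: 0 for r in EXCLUSION_PRIORITY}
    for c in dataset.covariates:
        obs = by_pid.get(c.participant_id, [])
        pet_ages = [o.age for o in obs if o.marker in PET_MARKERS]
        has_mri = any(o.marker in MRI_MARKERS for o in obs)
        # The age criterion is "min_age or older at the time of PET"; when a
        # participant has no PET the missing-PET reason applies instead (or,
        # with PET not required, age is assessed on whatever visits exist).
        age_basis = pet_ages if pet_ages else ([] if require_pet else [o.age for o in obs])
        reason = None
        if age_basis and max(age_basis) < min_age:
            reason = "age"
        elif not age_basis and not pet_ages and min_age > 0 and not obs:
            reason = "age"
        elif require_pet and not pet_ages:
            reason = "no_pet"
        elif require_mri and not has_mri:
            reason = "no_mri"
        if reason is None:
            retained_ids.add(c.participant_id)
        else:
            exclusions[reason] += 1

    filtered = CohortDataset(
        observations=[o for o in dataset.observations if o.participant_id in retained_ids],
        covariates=[c for c in dataset.covariates if c.participant_id in retained_ids],
    )
    report = {
        "input_participants": len(dataset.covariates),
        "retained": len(retained_ids),
        "exclusions": {k: v for k, v in exclusions.items()},
        "empty_result": len(retained_ids) == 0,
        "criteria": {
            "min_age": min_age,
            "require_pet": require_pet,
            "require_mri": require_mri,
        },
    }
    return filtered, report


def write_exclusion_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
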