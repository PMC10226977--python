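"""Biomarker derivation formulas and modeling-scale transforms.

Every marker is mapped onto a scale where an *increase* means disease
progression: PET SUVRs are natural-log transformed (to tame right skew),
fractional anisotropy is modeled as 1 - FA (integrity loss increases), WMH
volume is expressed as a percent of total intracranial volume, and
hippocampal volume is head-size adjusted via fixed sex-specific regressions
on TIV.  A separate rescaling set is provided for validation-cohort style
inputs (centiloid amyloid, precomputed WMH%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import Marker


class TransformDomainError(ValueError):
    """Input outside the domain of the requested transform."""


@dataclass(frozen=True)
class MarkerSpec:
    """How one marker enters the model.

    ``transform`` is one of ``log``, ``one_minus``, ``identity`` or
    ``linear_rescale`` (with coefficients ``a + b*x``); all are strictly
    monotone on their domains.  ``increasing`` records whether the
    *transformed* value increases with progression (always true for the
    shipped defaults).
    """

    marker: Marker
    transform: str = "identity"
    a: float = 0.0
    b: float = 1.0
    increasing: bool = True

    def __post_init__(self) -> None:
        if self.transform not in {"log", "one_minus", "identity", "linear_rescale"}:
            raise ValueError(f"unknown transform: {self.transform}")
        if self.transform == "linear_rescale" and self.b == 0:
            raise ValueError("linear_rescale slope must be nonzero")

    def forward(self, x):
        x = np.asarray(x, dtype=float)
        if self.transform == "log":
            if np.any(x <= 0):
                raise TransformDomainError(f"log transform requires positive values ({self.marker.value})")
            out = np.log(x)
        elif self.transform == "one_minus":
            if np.any((x < 0) | (x > 1)):
                raise TransformDomainError(f"one_minus transform requires values in [0, 1] ({self.marker.value})")
            out = 1.0 - x
        elif self.transform == "identity":
            out = x.copy()
        else:
            out = self.a + self.b * x
        return out if out.ndim else float(out)

    def inverse(self, y):
        y = np.asarray(y, dtype=float)
        if self.transform == "log":
            out = np.exp(y)
        elif self.transform == "one_minus":
            out = 1.0 - y
        elif self.transform == "identity":
            out = y.copy()
        else:
            out = (y - self.a) / self.b
        return out if out.ndim else float(out)


#: Primary-cohort modeling transforms.
DEFAULT_MARKER_SPECS: dict[Marker, MarkerSpec] = {
    Marker.AMYLOID_PET: MarkerSpec(Marker.AMYLOID_PET, "log"),
    Marker.TAU_PET: MarkerSpec(Marker.TAU_PET, "log"),
    Marker.WMH_PCT: MarkerSpec(Marker.WMH_PCT, "identity"),
    Marker.FA_GCC: MarkerSpec(Marker.FA_GCC, "one_minus"),
    Marker.HVA: MarkerSpec(Marker.HVA, "identity"),
}


def apply_marker_transform(spec: MarkerSpec, raw_value):
    """Map a raw marker value onto the modeling scale."""
    return spec.forward(raw_value)


def wmh_percent(wmh_volume: float, tiv: float) -> float:
    """White matter hyperintensity volume as a percent of TIV.

    Head sizes differ; expressing WMH volume relative to total intracranial
    volume (both in cm^3) removes that source of variation.
    """
    if tiv <= 0:
        raise TransformDomainError("TIV must be positive")
    if wmh_volume < 0:
        raise TransformDomainError("WMH volume must be nonnegative")
    return 100.0 * wmh_volume / tiv


@dataclass(frozen=True)
class RegionMeasurement:
    """Median tracer uptake in one atlas region plus its voxel count."""

    region_name: str
    median_uptake: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if self.median_uptake <= 0:
            raise ValueError("median_uptake must be positive")


#: Default composite-ROI region lists (configuration data, atlas-specific;
#: override freely).  The amyloid global meta-ROI and the tau temporal
#: meta-ROI follow the standard composites; the three tau stage composites
#: group regions from early (entorhinal) to late (widespread neocortical)
#: involvement.
AMYLOID_META_ROI_REGIONS = (
    "prefrontal", "orbitofrontal", "parietal", "temporal",
    "anterior_cingulate", "posterior_cingulate", "precuneus",
)
TAU_TEMPORAL_META_ROI_REGIONS = (
    "amygdala", "fusiform", "middle_inferior_temporal", "entorhinal",
    "parahippocampal",
)
TAU_STAGE_REGIONS = {
    "stage_1_2": ("entorhinal",),
    "stage_3_4": (
        "parahippocampal", "fusiform", "lingual", "amygdala", "insula",
        "inferior_temporal", "superior_temporal_pole", "middle_temporal_pole",
        "middle_temporal", "posterior_cingulate", "retrosplenial",
        "anterior_cingulate", "mid_cingulate",
    ),
    "stage_5_6": (
        "inferior_parietal", "angular", "middle_orbitofrontal",
        "inferior_orbitofrontal", "superior_orbitofrontal",
        "medial_orbitofrontal", "rectus", "olfactory", "superior_temporal",
        "heschl", "inferior_frontal_operculum", "inferior_frontal_triangularis",
        "supramarginal", "superior_occipital", "middle_occipital",
        "inferior_occipital", "precuneus", "superior_parietal",
        "superior_frontal", "superior_medial_frontal",
        "supplementary_motor_area", "middle_frontal", "paracentral_lobule",
        "postcentral", "precentral", "calcarine", "cuneus",
        "rolandic_operculum",
    ),
}


def read_region_table(path) -> list[RegionMeasurement]:
    """Read a regional-uptake CSV (region_name, median_uptake, voxel_count)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["region_name", "median_uptake", "voxel_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing column(s): {missing}")
    return [
        RegionMeasurement(str(r.region_name), float(r.median_uptake), int(r.voxel_count))
        for r in df.itertuples(index=False)
    ]


def meta_roi_weighted_average(regions: Sequence[RegionMeasurement]) -> float:
    """Voxel-number-weighted average of regional median uptakes.

    This is how composite (meta-ROI) SUVRs are formed from regional values:
    each region contributes proportionally to its size, so the result is a
    convex combination bounded by the smallest and largest regional uptake.
    """
    if len(regions) == 0:
        raise TransformDomainError("meta-ROI requires at least one region")
    w = np.array([r.voxel_count for r in regions], dtype=float)
    u = np.array([r.median_uptake for r in regions], dtype=float)
    return float(np.sum(w * u) / np.sum(w))


# Fixed head-size adjustment for hippocampal volume: the residual from a
# sex-specific linear regression of HV (cm^3) on TIV (cm^3), centered at
# TIV = 1500 cm^3.  Coefficients are fixed, not refit.
_HVA_COEF = {False: (7.58, 0.00441), True: (7.88, 0.00476)}  # keyed by female


def adjusted_hippocampal_volume(hv: float, tiv: float, female: bool) -> float:
    """Head-size-adjusted hippocampal volume (HVa), in cm^3.

    HVa = HV - (intercept + slope * (TIV - 1500)) with intercept/slope of
    7.58/0.00441 for males and 7.88/0.00476 for females.
    """
    if hv <= 0 or tiv <= 0:
        raise TransformDomainError("HV and TIV must be positive")
    intercept, slope = _HVA_COEF[bool(female)]
    return hv - (intercept + slope * (tiv - 1500.0))


def refit_hva_coefficients(
    hv: Sequence[float], tiv: Sequence[float], female: Sequence[bool]
) -> dict[bool, tuple[float, float]]:
    """Sex-stratified refit of the HV-on-TIV adjustment (for synthetic data).

    Returns ``{female: (intercept_at_tiv_1500, slope)}`` from ordinary least
    squares of HV on (TIV - 1500) within each sex.
    """
    hv = np.asarray(hv, float)
    tiv = np.asarray(tiv, float)
    female = np.asarray(female, bool)
    out: dict[bool, tuple[float, float]] = {}
    for sex in (False, True):
        m = female == sex
        if m.sum() < 2:
            raise ValueError("need at least 2 participants per sex to refit")
        x = tiv[m] - 1500.0
        slope, intercept = np.polyfit(x, hv[m], 1)
        out[sex] = (float(intercept), float(slope))
    return out


def adni_rescale(marker: Marker, value):
    """Validation-cohort rescalings onto the modeling scale.

    Amyloid arrives in centiloid and is divided by 200; WMH% is divided by
    5; tau SUVR is natural-log transformed; FA is modeled as 1 - FA.
    """
    value = np.asarray(value, dtype=float)
    if marker is Marker.AMYLOID_PET:
        out = value / 200.0
    elif marker is Marker.WMH_PCT:
        out = value / 5.0
    elif marker is Marker.TAU_PET:
        if np.any(value <= 0):
            raise TransformDomainError("tau SUVR must be positive for log rescale")
        out = np.log(value)
    elif marker is Marker.FA_GCC:
        out = 1.0 - value
    else:
        raise KeyError(f"no validation-cohort rescaling defined for {marker.value}")
    return out if out.ndim else float(out)


def transform_dataset(dataset, specs: dict[Marker, MarkerSpec] | None = None):
    """Return a copy of the cohort with ``transformed_value`` filled in."""
    from dataclasses import replace

    from .data_model import CohortDataset

    specs = specs or DEFAULT_MARKER_SPECS
    obs = [
        replace(o, transformed_value=float(specs[o.marker].forward(o.raw_value)))
        for o in dataset.observations
    ]
    return CohortDataset(observations=obs, covariates=list(dataset.covariates))
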