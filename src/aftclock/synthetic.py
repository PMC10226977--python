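"""Synthetic longitudinal cohorts drawn from the latent time-shift model.

The real study populations (population-based and clinic-referred aging
cohorts) are restricted-access, so this module generates cohorts with the
same structure and known ground truth: per-marker visit-count margins
matching the published cohort description (about half the participants
with a single amyloid scan, 40% with no tau scan at all, etc.), realistic
covariate prevalences, sigmoid-like common curves for amyloid/tau/WMH and
a linear trend for 1-FA, covariate effects in years, and correlated
per-person onset adjustments with a block structure: strong amyloid-tau,
moderate WMH-FA, near-zero across the blocks.

Values are generated on the transformed (modeling) scale — so the
generative model is exactly the model being fit — then inverse-transformed
to native units, with FA clipped into (0.01, 0.99).

Per-participant random substreams are spawned from one root seed, so the
first m participants of a size-n cohort are identical for any n >= m.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .data_model import (
    Apoe4,
    BiomarkerObservation,
    CohortDataset,
    Marker,
    ParticipantCovariates,
)
from .harmonization import PUBLISHED_MAPS, DemingFit, invert_map
from .transforms import DEFAULT_MARKER_SPECS


# ---------------------------------------------------------------------------
# true common curves


@dataclass(frozen=True)
class SigmoidCurve:
    """Generalized-logistic curve on the transformed scale: slow early rise,
    an inflection point, then rapid increase toward a plateau."""

    low: float
    high: float
    midpoint: float   # adjusted age of the inflection, years
    scale: float      # years; smaller = steeper

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.low + (self.high - self.low) / (1.0 + np.exp(-(t - self.midpoint) / self.scale))
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"kind": "sigmoid", **asdict(self)}


@dataclass(frozen=True)
class LinearCurve:
    """Linear trend on the transformed scale (the FA-like pattern)."""

    value_at_70: float
    slope: float      # transformed units per year

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.value_at_70 + self.slope * (t - 70.0)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        return {"kind": "linear", **asdict(self)}


def curve_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    return {"sigmoid": SigmoidCurve, "linear": LinearCurve}[kind](**d)


#: Default truth curves, on the transformed scale, tuned so native-scale
#: ranges match the published cohort summaries (amyloid SUVR ~1.3-2.8, tau
#: SUVR ~1.1-2.6, WMH% ~0-5, FA ~0.52-0.68).
DEFAULT_CURVES: dict[Marker, object] = {
    Marker.AMYLOID_PET: SigmoidCurve(low=math.log(1.3), high=math.log(2.8), midpoint=80.0, scale=8.0),
    Marker.TAU_PET: SigmoidCurve(low=math.log(1.1), high=math.log(2.6), midpoint=90.0, scale=6.0),
    Marker.WMH_PCT: SigmoidCurve(low=0.2, high=5.0, midpoint=85.0, scale=7.0),
    Marker.FA_GCC: LinearCurve(value_at_70=0.3886, slope=0.16 / 70.0),
}

DEFAULT_MARKER_ORDER = (Marker.AMYLOID_PET, Marker.TAU_PET, Marker.WMH_PCT, Marker.FA_GCC)

#: Visit-count probabilities for 0, 1, 2, 3+ scans per marker, matching the
#: published per-marker margins (amyloid/tau PET, FLAIR MRI for WMH, DTI
#: for FA).
DEFAULT_VISIT_PROBS: dict[Marker, tuple[float, ...]] = {
    Marker.AMYLOID_PET: (0.0, 0.49, 0.24, 0.27),
    Marker.TAU_PET: (0.40, 0.36, 0.16, 0.08),
    Marker.WMH_PCT: (0.01, 0.39, 0.26, 0.34),
    Marker.FA_GCC: (0.17, 0.40, 0.25, 0.18),
}

#: True covariate effects (years, positive = earlier onset) per marker, in
#: the order (APOE e4 carrier, APOE unknown, female, education/yr,
#: referral); values follow the published covariate-effect table, with
#: small ad-hoc effects for the unknown-APOE level.
DEFAULT_BETA = np.array(
    [
        [9.0, 4.0, 2.1, 0.2, 19.0],    # amyloid PET
        [6.1, 3.0, 2.6, 0.8, 29.4],    # tau PET
        [-0.9, 0.0, 2.3, -0.1, 10.4],  # WMH%
        [-0.5, 0.0, 4.1, -0.1, 13.3],  # FA GCC
    ]
)

#: Onset-adjustment correlation: strong amyloid-tau, moderate WMH-FA,
#: near-zero cross-block.
DEFAULT_R = np.array(
    [
        [1.00, 0.60, 0.05, 0.05],
        [0.60, 1.00, 0.05, 0.05],
        [0.05, 0.05, 1.00, 0.45],
        [0.05, 0.05, 0.45, 1.00],
    ]
)


@dataclass
class TwoScannerConfig:
    """Optional scanner-switch artifact for MRI-derived markers.

    Each participant gets a calendar entry year; visits before
    ``switch_year`` are labeled scanner "A" and their raw values are pushed
    through the *inverse* of the reference harmonization map plus extra
    noise, so downstream harmonization is exercised end-to-end.
    """

    switch_year: float = 2018.0
    entry_year_low: float = 2010.0
    entry_year_high: float = 2020.0
    markers: tuple[str, ...] = ("wmh_pct", "fa_gcc")
    extra_noise_sd: dict = field(
        default_factory=lambda: {"wmh_pct": 0.05, "fa_gcc": 0.005}
    )
    maps: dict = field(default_factory=lambda: dict(PUBLISHED_MAPS))


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_participants: int = 300
    seed: int = 0
    markers: tuple[Marker, ...] = DEFAULT_MARKER_ORDER
    entry_age_mean: float = 70.0
    entry_age_sd: float = 10.0
    entry_age_min: float = 50.0
    entry_age_max: float = 95.0
    visit_probs: dict = field(default_factory=lambda: dict(DEFAULT_VISIT_PROBS))
    extra_visits_rate: float = 0.8    # Poisson mean added on top of 3 for "3+"
    gap_mean: float = 2.5             # years between visits
    gap_sd: float = 0.5
    gap_min: float = 0.5
    apoe_carrier_frac: float = 0.31
    apoe_unknown_frac: float = 0.06
    female_frac: float = 0.48
    education_mean: float = 15.0
    education_sd: float = 3.0
    education_min: float = 6.0
    referral_frac: float = 0.11
    beta: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    tau: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 10.0, 10.0]))
    R: np.ndarray = field(default_factory=lambda: DEFAULT_R.copy())
    sigma: np.ndarray = field(default_factory=lambda: np.array([0.08, 0.08, 0.25, 0.015]))
    curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))
    scanner: TwoScannerConfig | None = None
    #: optional marker -> group label; markers sharing a label share one
    #: drawn visit schedule (e.g. stage composites read off the same scan)
    schedule_groups: dict | None = None

    def validate(self) -> None:
        K = len(self.markers)
        R = np.asarray(self.R, float)
        if R.shape != (K, K) or not np.allclose(R, R.T):
            raise ValueError("R must be a symmetric KxK matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("R must have unit diagonal")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as e:
            raise ValueError("R is not positive definite") from e
        for m in self.markers:
            probs = np.asarray(self.visit_probs[m], float)
            if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"visit probabilities for {m.value} must sum to 1")
        if np.any(np.asarray(self.tau, float) <= 0) or np.any(np.asarray(self.sigma, float) <= 0):
            raise ValueError("tau and sigma must be positive")
        if np.asarray(self.beta, float).shape != (K, 5):
            raise ValueError("beta must be (K, 5)")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated cohort, for recovery tests."""

    markers: tuple[Marker, ...]
    beta: np.ndarray              # (K, 5) years
    tau: np.ndarray               # (K,)
    R: np.ndarray                 # (K, K)
    sigma: np.ndarray             # (K,)
    curves: dict                  # marker -> curve object
    u: np.ndarray                 # (n, K) realized shifts, years
    covariate_shift: np.ndarray   # (n, K) x_i' beta_k, years
    participant_ids: list[str]
    education_center: float

    def total_shift(self) -> np.ndarray:
        return self.u + self.covariate_shift

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": [m.value for m in self.markers],
                "beta": np.asarray(self.beta).tolist(),
                "tau": np.asarray(self.tau).tolist(),
                "R": np.asarray(self.R).tolist(),
                "sigma": np.asarray(self.sigma).tolist(),
                "curves": {m.value: self.curves[m].to_dict() for m in self.markers},
                "u": np.asarray(self.u).tolist(),
                "covariate_shift": np.asarray(self.covariate_shift).tolist(),
                "participant_ids": list(self.participant_ids),
                "education_center": self.education_center,
            },
            indent=1,
        )


def sample_visit_schedule(
    config: CohortConfig,
    rng: np.random.Generator,
    entry_age: float | None = None,
) -> dict[Marker, np.ndarray]:
    """Draw per-marker visit ages for one participant.

    The visit count is categorical over 0/1/2/3+ per marker ("3+" adds a
    Poisson tail); ages start at the participant's entry age and advance by
    truncated-normal gaps, drawn independently per marker.
    """
    if entry_age is None:
        a, b = config.entry_age_min, config.entry_age_max
        entry_age = float(np.clip(
            rng.normal(config.entry_age_mean, config.entry_age_sd), a, b))
    out: dict[Marker, np.ndarray] = {}
    group_cache: dict[str, np.ndarray] = {}
    for m in config.markers:
        group = (config.schedule_groups or {}).get(m)
        if group is not None and group in group_cache:
            out[m] = group_cache[group].copy()
            continue
        probs = np.asarray(config.visit_probs[m], float)
        count = int(rng.choice(len(probs), p=probs))
        if count == len(probs) - 1 and count >= 3:
            count += int(rng.poisson(config.extra_visits_rate))
        if count == 0:
            ages = np.empty(0)
        else:
            gaps = np.maximum(
                rng.normal(config.gap_mean, config.gap_sd, size=count - 1),
                config.gap_min,
            )
            ages = entry_age + np.concatenate([[0.0], np.cumsum(gaps)])
        out[m] = ages
        if group is not None:
            group_cache[group] = ages
    return out


def generate_cohort(
    config: CohortConfig, seed: int | None = None
) -> tuple[CohortDataset, SyntheticTruth]:
    """Generate one cohort plus its ground truth.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    K = len(config.markers)
    tau = np.asarray(config.tau, float)
    sigma = np.asarray(config.sigma, float)
    beta = np.asarray(config.beta, float)
    Lt = np.linalg.cholesky(np.asarray(config.R, float))
    specs = DEFAULT_MARKER_SPECS

    root = np.random.SeedSequence(seed)
    streams = root.spawn(config.n_participants)

    observations: list[BiomarkerObservation] = []
    covariates: list[ParticipantCovariates] = []
    u_all = np.empty((config.n_participants, K))
    xshift_all = np.empty((config.n_participants, K))

    width = max(4, len(str(config.n_participants)))
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"S{i:0{width}d}"

        roll = rng.uniform()
        apoe = (
            Apoe4.CARRIER
            if roll < config.apoe_carrier_frac
            else Apoe4.UNKNOWN
            if roll < config.apoe_carrier_frac + config.apoe_unknown_frac
            else Apoe4.NONCARRIER
        )
        female = bool(rng.uniform() < config.female_frac)
        education = float(
            max(config.education_min,
                rng.normal(config.education_mean, config.education_sd))
        )
        referral = bool(rng.uniform() < config.referral_frac)
        covariates.append(ParticipantCovariates(pid, apoe, female, education, referral))

        x = np.array(
            [
                1.0 if apoe is Apoe4.CARRIER else 0.0,
                1.0 if apoe is Apoe4.UNKNOWN else 0.0,
                1.0 if female else 0.0,
                education - config.education_mean,
                1.0 if referral else 0.0,
            ]
        )
        u = tau * (Lt @ rng.standard_normal(K))
        u_all[i] = u
        xshift = beta @ x
        xshift_all[i] = xshift

        entry_cal = (
            rng.uniform(config.scanner.entry_year_low, config.scanner.entry_year_high)
            if config.scanner is not None
            else None
        )
        schedule = sample_visit_schedule(config, rng)
        entry_age = min(
            (ages[0] for ages in schedule.values() if ages.size), default=None
        )
        for k, m in enumerate(config.markers):
            curve = config.curves[m]
            spec = specs[m]
            for age in schedule[m]:
                t = age + xshift[k] + u[k]
                value = float(curve(t) + sigma[k] * rng.standard_normal())
                scanner = None
                if m is Marker.FA_GCC:
                    value = float(np.clip(value, 0.01, 0.99))
                if m is Marker.WMH_PCT:
                    value = max(value, 0.0)
                raw = float(spec.inverse(value))
                if config.scanner is not None and m.value in config.scanner.markers:
                    cal = entry_cal + (age - entry_age)
                    if cal < config.scanner.switch_year:
                        fit = config.scanner.maps[m.value]
                        noise = config.scanner.extra_noise_sd.get(m.value, 0.0)
                        raw = float(
                            invert_map(raw, fit) + noise * rng.standard_normal()
                        )
                        if m is Marker.WMH_PCT:
                            raw = max(raw, 0.0)
                        if m is Marker.FA_GCC:
                            raw = float(np.clip(raw, 0.01, 0.99))
                        scanner = "A"
                    else:
                        scanner = "B"
                observations.append(
                    BiomarkerObservation(
                        participant_id=pid,
                        marker=m,
                        age=float(age),
                        raw_value=raw,
                        transformed_value=None if config.scanner is not None else value,
                        scanner=scanner,
                    )
                )

    dataset = CohortDataset(observations=observations, covariates=covariates)
    truth = SyntheticTruth(
        markers=tuple(config.markers),
        beta=beta,
        tau=tau,
        R=np.asarray(config.R, float),
        sigma=sigma,
        curves=dict(config.curves),
        u=u_all,
        covariate_shift=xshift_all,
        participant_ids=[c.participant_id for c in covariates],
        education_center=config.education_mean,
    )
    return dataset, truth


def generate_crossover_pairs(
    n_pairs: int,
    true_map: DemingFit,
    rng: np.random.Generator,
    latent_mean: float = 1.0,
    latent_sd: float = 1.0,
    noise_sd_x: float = 0.1,
    noise_sd_y: float = 0.1,
) -> np.ndarray:
    """Paired same-participant measurements on two scanners.

    A latent true value v is measured as x = v + eps_x on the source
    scanner and y = (intercept + slope*v) + eps_y on the reference scanner;
    used to exercise the Deming fit.
    """
    v = rng.normal(latent_mean, latent_sd, size=n_pairs)
    x = v + rng.normal(0.0, noise_sd_x, size=n_pairs)
    y = true_map.intercept + true_map.slope * v + rng.normal(0.0, noise_sd_y, size=n_pairs)
    return np.column_stack([x, y])


def config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a cohort configuration from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> CohortConfig:
    kwargs = {}
    simple = {
        "n_participants", "seed", "entry_age_mean", "entry_age_sd",
        "entry_age_min", "entry_age_max", "extra_visits_rate", "gap_mean",
        "gap_sd", "gap_min", "apoe_carrier_frac", "apoe_unknown_frac",
        "female_frac", "education_mean", "education_sd", "education_min",
        "referral_frac",
    }
    for k, v in raw.items():
        if k in simple:
            kwargs[k] = v
        elif k == "markers":
            kwargs["markers"] = tuple(Marker.parse(m) for m in v)
        elif k in {"beta", "tau", "R", "sigma"}:
            kwargs[k] = np.asarray(v, float)
        elif k == "visit_probs":
            kwargs["visit_probs"] = {Marker.parse(m): tuple(p) for m, p in v.items()}
        elif k == "curves":
            kwargs["curves"] = {Marker.parse(m): curve_from_dict(d) for m, d in v.items()}
        elif k == "scanner":
            kwargs["scanner"] = TwoScannerConfig(**v) if v else None
        elif k == "schedule_groups":
            kwargs["schedule_groups"] = {Marker.parse(m): g for m, g in v.items()}
        else:
            raise KeyError(f"unknown cohort config key: {k}")
    return CohortConfig(**kwargs)
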