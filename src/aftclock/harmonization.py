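"""Crossover-based scanner harmonization via Deming regression.

When a study replaces its MRI scanner mid-stream, measurements from the two
systems differ systematically.  A crossover sample — the same participants
imaged on both scanners within days — supports an errors-in-variables
(Deming) regression that maps one scanner's scale onto the other's.  Both
axes are noisy measurements of the same underlying quantity, so ordinary
least squares (which attenuates the slope) is not appropriate; the Deming
estimator is parameterized by lambda, the ratio of error variances
var(y-error)/var(x-error).

An optional floor guards against extrapolation: mapped values below the
smallest value ever observed on the reference scanner are clamped to it
(the study's white matter hyperintensity map uses a floor of 0.01 %TIV).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np


class DemingFitError(ValueError):
    """Degenerate crossover sample (e.g. no variance in x)."""


@dataclass(frozen=True)
class DemingFit:
    """A fitted source->reference scanner map: reference = intercept + slope*source."""

    slope: float
    intercept: float
    lam: float = 1.0
    n_pairs: int = 0
    floor: float | None = None
    marker: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and self.slope != 0.0):
            raise ValueError("slope must be finite and nonzero")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DemingFit":
        return cls(**json.loads(text))


#: Printed crossover maps from the study (source scanner "A" = GE onto
#: reference scanner "B" = Siemens).  Only WMH% carries a floor: 0.01 was
#: the minimum WMH% observed on the reference scanner.
PUBLISHED_MAPS: dict[str, DemingFit] = {
    "wmh_pct": DemingFit(slope=0.9276, intercept=-0.0357, lam=1.0, n_pairs=111,
                         floor=0.01, marker="wmh_pct"),
    "fa_gcc": DemingFit(slope=0.5988, intercept=0.2644, lam=1.0, n_pairs=81,
                        floor=None, marker="fa_gcc"),
}


def fit_deming(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    lam: float = 1.0,
    floor: float | None = None,
    marker: str | None = None,
) -> DemingFit:
    """Fit a Deming regression to paired (source, reference) measurements.

    Uses the closed-form estimator: with s_xx, s_yy, s_xy the sample
    (co)variances,

        slope = (s_yy - lam*s_xx + sqrt((s_yy - lam*s_xx)^2 + 4*lam*s_xy^2))
                / (2*s_xy)
        intercept = ybar - slope * xbar

    ``lam`` is the ratio of error variances var(eps_y)/var(eps_x); lam = 1
    gives orthogonal regression, and lam -> infinity recovers the OLS slope
    of y on x.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DemingFitError("need at least 3 (x, y) pairs")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    x, y = arr[:, 0], arr[:, 1]
    xbar, ybar = x.mean(), y.mean()
    sxx = np.mean((x - xbar) ** 2)
    syy = np.mean((y - ybar) ** 2)
    sxy = np.mean((x - xbar) * (y - ybar))
    if sxx <= 0:
        raise DemingFitError("all x values identical; cannot fit")
    if sxy == 0.0:
        # no linear association: orthogonal slope is 0 or undefined; treat
        # as degenerate rather than returning slope 0 (which the map forbids)
        raise DemingFitError("zero covariance between scanners; cannot fit")
    d = syy - lam * sxx
    slope = (d + math.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = ybar - slope * xbar
    return DemingFit(slope=slope, intercept=intercept, lam=lam,
                     n_pairs=arr.shape[0], floor=floor, marker=marker)


def apply_harmonization(value, fit: DemingFit):
    """Map source-scanner value(s) onto the reference scale, flooring if set.

    Returns ``intercept + slope * value``; when the fit carries a floor,
    results below it are clamped up to the floor (anti-extrapolation rule).
    """
    v = np.asarray(value, dtype=float)
    out = fit.intercept + fit.slope * v
    if fit.floor is not None:
        out = np.maximum(out, fit.floor)
    return out if out.ndim else float(out)


def invert_map(value, fit: DemingFit):
    """Reference -> source inverse of the linear map (no floor applied)."""
    v = np.asarray(value, dtype=float)
    out = (v - fit.intercept) / fit.slope
    return out if out.ndim else float(out)


def harmonize_dataset(dataset, maps: dict[str, DemingFit] | None = None,
                      source_scanner: str = "A"):
    """Apply per-marker source->reference maps to raw values in a cohort.

    Observations whose ``scanner`` equals ``source_scanner`` and whose
    marker has a map are remapped; all others pass through unchanged.  The
    returned observations carry the reference scanner label with a ``*``
    suffix marking provenance.
    """
    from dataclasses import replace

    from .data_model import CohortDataset

    maps = PUBLISHED_MAPS if maps is None else maps
    obs = []
    for o in dataset.observations:
        m = maps.get(o.marker.value)
        if m is not None and o.scanner == source_scanner:
            obs.append(replace(o, raw_value=float(apply_harmonization(o.raw_value, m)),
                               scanner="B*"))
        else:
            obs.append(o)
    return CohortDataset(observations=obs, covariates=list(dataset.covariates))


def save_fits(fits: dict[str, DemingFit], path: str | Path) -> None:
    Path(path).write_text(json.dumps({k: asdict(v) for k, v in fits.items()}, indent=2))


def load_fits(path: str | Path) -> dict[str, DemingFit]:
    raw = json.loads(Path(path).read_text())
    return {k: DemingFit(**v) for k, v in raw.items()}
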