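"""Publication-style outputs: adjusted-age curve overlays, pairwise
adjustment scatter data with 80% coverage ellipses and percent-variance
annotations, covariate-effect forest tables, and the end-to-end pipeline
that chains simulate -> harmonize -> fit -> report.

Figures are emitted as data tables plus rendered images, so tests can
assert on numbers rather than pixels.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortDataset, write_exclusion_report
from .aft_model import (
    AFTPosterior,
    MCMCConfig,
    adjustment_correlation,
    build_covariate_matrix,
    extract_adjustments,
    fit_aft,
    percent_variance_explained,
)
from .transforms import DEFAULT_MARKER_SPECS, transform_dataset
from . import harmonization


@dataclass(frozen=True)
class EllipseSpec:
    """A coverage ellipse for a bivariate normal cloud of adjustments.

    ``semi_axes`` are in years along the eigenvector directions; ``angle``
    is the rotation of the first axis from the x-axis, in radians.  A near
    circle means the two adjustments are unrelated; a thin tilted ellipse
    means knowing one tells you the other.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    coverage: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse."""
        pts = np.asarray(points, float) - np.asarray(self.center)
        ca, sa = math.cos(self.angle), math.sin(self.angle)
        rot = np.array([[ca, sa], [-sa, ca]])
        q = pts @ rot.T
        a, b = self.semi_axes
        return (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 <= 1.0


def coverage_ellipse(
    cov: np.ndarray, coverage: float = 0.80, center=(0.0, 0.0)
) -> EllipseSpec:
    """Ellipse containing the given probability mass of a bivariate normal.

    Axes follow the covariance eigenvectors; semi-axis lengths are
    sqrt(eigenvalue * q) with q the ``coverage`` quantile of a chi-square
    with 2 degrees of freedom.
    """
    cov = np.asarray(cov, float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric 2x2")
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0:
        raise ValueError("covariance must be positive definite")
    q = stats.chi2.ppf(coverage, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = math.atan2(evecs[1, 0], evecs[0, 0])
    return EllipseSpec(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(np.sqrt(evals[0] * q)), float(np.sqrt(evals[1] * q))),
        angle=float(angle),
        coverage=float(coverage),
    )


def adjusted_age_dataset(
    dataset: CohortDataset, posterior: AFTPosterior, n_curve_points: int = 200
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables behind the age vs adjusted-age panels.

    Returns ``(points, curves)``: each observation with its adjusted age
    (chronological age plus covariate and random-effect shifts, at the
    posterior-mean parameters) and transformed value, and the common curve
    sampled densely over its support.  Participants appear only in panels
    for markers they contributed.
    """
    params = posterior.mean_parameters()
    X, ids, _ = build_covariate_matrix(dataset, params.education_center)
    pid_index = {pid: i for i, pid in enumerate(ids)}
    mk_index = {m: k for k, m in enumerate(posterior.markers)}
    specs = DEFAULT_MARKER_SPECS
    rows = []
    for o in dataset.observations:
        if o.marker not in mk_index:
            continue
        k = mk_index[o.marker]
        i = pid_index[o.participant_id]
        tv = (
            o.transformed_value
            if o.transformed_value is not None
            else float(specs[o.marker].forward(o.raw_value))
        )
        adj = float(o.age + X[i] @ params.beta[k] + params.u[i, k])
        rows.append(
            {
                "participant_id": o.participant_id,
                "marker": o.marker.value,
                "age": o.age,
                "adjusted_age": adj,
                "transformed_value": tv,
            }
        )
    points = pd.DataFrame(rows)
    grid = np.linspace(posterior.basis.lo, posterior.basis.hi, n_curve_points)
    curve_rows = []
    for m in posterior.markers:
        vals = params.curves[m].evaluate(grid)
        for t, v in zip(grid, vals):
            curve_rows.append({"marker": m.value, "adjusted_age": t, "value": v})
    return points, pd.DataFrame(curve_rows)


def adjustment_pairs_table(
    posterior: AFTPosterior, flip_axes: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise adjustment scatter data plus ellipse/correlation annotations.

    ``flip_axes`` negates both coordinates so earlier onset plots toward
    the lower left, matching the publication convention for adjustment
    panels.  The percent-variance annotation is the squared posterior-mean
    correlation times 100.
    """
    adj = extract_adjustments(posterior)
    wide = adj.pivot(index="participant_id", columns="marker", values="mean")
    corr = adjustment_correlation(posterior)
    sign = -1.0 if flip_axes else 1.0
    scatter_rows, annot_rows = [], []
    for _, row in corr.iterrows():
        m1, m2 = row.marker_1, row.marker_2
        if m1 not in wide.columns or m2 not in wide.columns:
            continue
        sub = wide[[m1, m2]].dropna()
        for pid, (x, y) in sub.iterrows():
            scatter_rows.append(
                {"pair": f"{m1}|{m2}", "participant_id": pid,
                 "x": sign * x, "y": sign * y}
            )
        if len(sub) >= 3:
            cov = np.cov(sub[m1], sub[m2])
            ell = coverage_ellipse(cov, 0.80, center=(sign * sub[m1].mean(),
                                                      sign * sub[m2].mean()))
        else:
            ell = None
        annot_rows.append(
            {
                "pair": f"{m1}|{m2}",
                "marker_x": m1,
                "marker_y": m2,
                "R_mean": row["mean"],
                "R_ci_low": row.ci_low,
                "R_ci_high": row.ci_high,
                "pct_variance_explained": percent_variance_explained(row["mean"]),
                "n": len(sub),
                **(
                    {
                        "ellipse_a": ell.semi_axes[0],
                        "ellipse_b": ell.semi_axes[1],
                        "ellipse_angle": ell.angle,
                    }
                    if ell is not None
                    else {}
                ),
            }
        )
    return pd.DataFrame(scatter_rows), pd.DataFrame(annot_rows)


def forest_table(posterior: AFTPosterior) -> pd.DataFrame:
    """Covariate-effect rows (years, mean and 95% CI) covering the full
    covariate-by-marker grid — the data behind a forest plot."""
    return posterior.beta_summary()


def render_figures(points, curves, scatter, annots, out_dir: Path) -> list[Path]:
    """Render the standard panels as PNGs; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    markers = curves["marker"].unique()
    fig, axes = plt.subplots(len(markers), 2, figsize=(9, 2.6 * len(markers)))
    axes = np.atleast_2d(axes)
    for r, m in enumerate(markers):
        pm = points[points.marker == m]
        cm = curves[curves.marker == m]
        axes[r, 0].scatter(pm.age, pm.transformed_value, s=4, alpha=0.4)
        axes[r, 0].set_ylabel(m)
        axes[r, 1].scatter(pm.adjusted_age, pm.transformed_value, s=4, alpha=0.4)
        axes[r, 1].plot(cm.adjusted_age, cm.value, color="red", lw=1.5)
        if r == len(markers) - 1:
            axes[r, 0].set_xlabel("age (years)")
            axes[r, 1].set_xlabel("adjusted age (years)")
    fig.tight_layout()
    p = out_dir / "trajectories.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    out.append(p)

    pairs = annots["pair"].tolist()
    ncol = 2
    nrow = (len(pairs) + 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(8, 3.2 * nrow))
    axes = np.ravel(np.atleast_1d(axes))
    for ax, pair in zip(axes, pairs):
        sp = scatter[scatter.pair == pair]
        an = annots[annots.pair == pair].iloc[0]
        ax.scatter(sp.x, sp.y, s=5, alpha=0.4)
        if "ellipse_a" in an and not pd.isna(an.get("ellipse_a", np.nan)):
            th = np.linspace(0, 2 * np.pi, 200)
            a, b, ang = an.ellipse_a, an.ellipse_b, an.ellipse_angle
            ex = a * np.cos(th) * math.cos(ang) - b * np.sin(th) * math.sin(ang)
            ey = a * np.cos(th) * math.sin(ang) + b * np.sin(th) * math.cos(ang)
            ax.plot(sp.x.mean() + ex, sp.y.mean() + ey, color="black", lw=1)
        ax.set_title(
            f"{pair}  R={an.R_mean:.2f}  ({an.pct_variance_explained:.1f}%)",
            fontsize=9,
        )
    for ax in axes[len(pairs):]:
        ax.axis("off")
    fig.tight_layout()
    p = out_dir / "adjustment_pairs.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    out.append(p)
    return out


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run simulate -> harmonize -> fit -> report and write an artifact
    bundle (CSV tables, JSON manifest, PNG figures) under ``out_dir``.

    ``config`` mirrors the YAML schema: a ``cohort`` section for the
    generator (or ``visits``/``covariates`` paths for user data), optional
    ``filters``, ``harmonize`` and ``mcmc`` sections, and a ``seed``.
    Outputs are deterministic for a fixed config.  Any stage failure
    raises a stage-named error; artifacts from earlier stages remain.
    """
    from .synthetic import config_from_dict, generate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_text = json.dumps(config, sort_keys=True, default=str)
    manifest: dict = {
        "config_hash": hashlib.sha256(config_text.encode()).hexdigest()[:16],
        "seed": int(config.get("seed", 0)),
        "stages": [],
    }
    seed = int(config.get("seed", 0))

    # --- simulate or load -------------------------------------------------
    truth = None
    try:
        if "cohort" in config:
            cc = config_from_dict(config["cohort"])
            dataset, truth = generate_cohort(cc, seed=seed)
            (out_dir / "truth.json").write_text(truth.to_json())
        else:
            from .data_model import read_long_table

            dataset = read_long_table(config["visits"], config["covariates"])
    except Exception as e:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError("simulate", e) from e
    manifest["stages"].append("simulate")
    manifest["n_participants"] = len(dataset.covariates)
    manifest["n_observations"] = len(dataset.observations)

    # --- filters ----------------------------------------------------------
    try:
        f = config.get("filters")
        if f:
            from .data_model import apply_inclusion_filters

            dataset, report = apply_inclusion_filters(
                dataset,
                min_age=f.get("min_age", 50.0),
                require_pet=f.get("require_pet", True),
                require_mri=f.get("require_mri", True),
            )
            write_exclusion_report(report, out_dir / "exclusions.json")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filter", e) from e

    # --- harmonize --------------------------------------------------------
    try:
        h = config.get("harmonize", {})
        if h.get("enabled", True):
            maps = None
            if "fits" in h:
                maps = harmonization.load_fits(h["fits"])
            dataset = harmonization.harmonize_dataset(
                dataset, maps=maps, source_scanner=h.get("source_scanner", "A")
            )
        dataset = transform_dataset(dataset)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("harmonize", e) from e
    manifest["stages"].append("harmonize")

    # --- fit ----------------------------------------------------------------
    try:
        mc = config.get("mcmc", {})
        mcfg = MCMCConfig(
            chains=mc.get("chains", 4),
            warmup=mc.get("warmup", 1000),
            draws=mc.get("draws", 1000),
            max_depth=mc.get("max_depth", 8),
            target_accept=mc.get("target_accept", 0.8),
        )
        posterior = fit_aft(dataset, mcmc_config=mcfg, seed=seed + 1)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("fit", e) from e
    manifest["stages"].append("fit")
    manifest["converged"] = bool(posterior.converged)
    manifest["divergences"] = int(posterior.divergences)
    manifest["max_rhat"] = float(max(posterior.rhat.values()))

    # --- report -------------------------------------------------------------
    try:
        forest_table(posterior).to_csv(out_dir / "covariate_effects.csv", index=False)
        adjustment_correlation(posterior).to_csv(
            out_dir / "adjustment_correlations.csv", index=False
        )
        extract_adjustments(posterior).to_csv(
            out_dir / "adjustments.csv", index=False
        )
        points, curvetab = adjusted_age_dataset(dataset, posterior)
        points.to_csv(out_dir / "adjusted_age_points.csv", index=False)
        curvetab.to_csv(out_dir / "common_curves.csv", index=False)
        scatter, annots = adjustment_pairs_table(posterior)
        scatter.to_csv(out_dir / "adjustment_scatter.csv", index=False)
        annots.to_csv(out_dir / "adjustment_annotations.csv", index=False)
        if config.get("figures", True):
            render_figures(points, curvetab, scatter, annots, out_dir)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", e) from e
    manifest["stages"].append("report")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
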