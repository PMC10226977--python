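"""Multivariate latent time-shift (accelerated failure time) model.

Each biomarker k has one common nondecreasing progression curve g_k on an
"adjusted age" axis.  Person i's observation of marker k at chronological
age a has mean

    g_k(a + x_i' beta_k + u_ik)

where x_i are covariates (APOE e4 carriership with an explicit unknown
level, sex, centered education, clinic referral), beta_k are covariate
effects *in years* (positive = earlier onset), and u_ik is a per-person
per-marker onset adjustment in years with

    u_i ~ N(0, diag(tau) . R . diag(tau)).

The correlation matrix R of these adjustments across markers is the
estimand of primary scientific interest: it measures whether a person who
progresses early on one marker also progresses early on another.

Inference is Bayesian via Hamiltonian Monte Carlo with analytic gradients.
Curves use a monotone I-spline basis with nonnegative weights; u is given
a non-centered parameterization (standard normals times the Cholesky
factor of the covariance) to avoid funnel pathologies; R uses a
tanh/canonical-partial-correlation Cholesky transform with an LKJ prior.
Participants missing a marker entirely still carry a u draw for it (a draw
from the conditional prior) but are masked out of posterior summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Apoe4, CohortDataset, Marker
from .splines import MonotoneBasis
from .transforms import DEFAULT_MARKER_SPECS, MarkerSpec
from . import hmc, _kernels

DEFAULT_MARKERS = (Marker.AMYLOID_PET, Marker.TAU_PET, Marker.WMH_PCT, Marker.FA_GCC)
COVARIATE_NAMES = ("apoe4_carrier", "apoe4_unknown", "female", "education", "referral")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class ProgressionCurve:
    """Monotone common curve for one marker: intercept + I-spline mixture."""

    marker: Marker
    basis: MonotoneBasis
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.basis.n_basis,):
            raise ValueError(
                f"expected {self.basis.n_basis} weights, got {w.shape}"
            )

    def evaluate(self, t):
        """Curve value at adjusted age(s) t (flat beyond the support)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = self.intercept + self.basis.design(t_arr) @ self.weights
        return out if np.ndim(t) else float(out[0])

    def derivative(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = self.basis.deriv_design(t_arr) @ self.weights
        return out if np.ndim(t) else float(out[0])


def evaluate_curve(curve: ProgressionCurve, t):
    return curve.evaluate(t)


def shifted_age(age, x, beta_k, u_ik):
    """Adjusted age = chronological age + x'beta_k + u_ik (years).

    Positive shifts mean the person is 'older' with respect to that
    marker's process, i.e. earlier onset.
    """
    x = np.asarray(x, dtype=float)
    beta_k = np.asarray(beta_k, dtype=float)
    return np.asarray(age, dtype=float) + float(x @ beta_k) + u_ik


@dataclass
class AFTParameters:
    """One full parameter configuration of the model."""

    curves: dict[Marker, ProgressionCurve]
    beta: np.ndarray            # (K, P) years
    u: np.ndarray               # (n, K) years
    tau: np.ndarray             # (K,) years
    R: np.ndarray               # (K, K) correlation
    sigma: np.ndarray           # (K,) transformed units
    markers: tuple[Marker, ...] = DEFAULT_MARKERS
    covariate_names: tuple[str, ...] = COVARIATE_NAMES
    participant_ids: tuple[str, ...] = ()
    education_center: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.u = np.asarray(self.u, float)
        self.tau = np.asarray(self.tau, float)
        self.R = np.asarray(self.R, float)
        self.sigma = np.asarray(self.sigma, float)
        K = len(self.markers)
        if self.R.shape != (K, K) or not np.allclose(self.R, self.R.T):
            raise ValueError("R must be a symmetric KxK matrix")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have unit diagonal")
        np.linalg.cholesky(self.R)  # raises if not positive definite
        if np.any(self.tau <= 0) or np.any(self.sigma <= 0):
            raise ValueError("tau and sigma must be positive")


# ---------------------------------------------------------------------------
# design matrices


def build_covariate_matrix(
    dataset: CohortDataset, education_center: float | None = None
) -> tuple[np.ndarray, list[str], float]:
    """Participant covariate design matrix in COVARIATE_NAMES order.

    Education is centered (default: at the cohort mean) so the common curve
    describes the reference person: male, APOE e4 noncarrier, average
    education, population-based recruitment.
    """
    ids = [c.participant_id for c in dataset.covariates]
    edu = np.array([c.education for c in dataset.covariates], float)
    center = float(edu.mean()) if education_center is None else float(education_center)
    X = np.column_stack(
        [
            [1.0 if c.apoe4 is Apoe4.CARRIER else 0.0 for c in dataset.covariates],
            [1.0 if c.apoe4 is Apoe4.UNKNOWN else 0.0 for c in dataset.covariates],
            [1.0 if c.female else 0.0 for c in dataset.covariates],
            edu - center,
            [1.0 if c.referral else 0.0 for c in dataset.covariates],
        ]
    )
    return X, ids, center


@dataclass
class _ModelData:
    """Flat observation arrays for vectorized likelihood work."""

    y: np.ndarray               # (N,) transformed values
    age: np.ndarray             # (N,)
    part: np.ndarray            # (N,) participant index
    mk: np.ndarray              # (N,) marker index
    X: np.ndarray               # (n, P)
    participant_ids: list[str]
    markers: tuple[Marker, ...]
    education_center: float
    idx_by_marker: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.idx_by_marker = [
            np.nonzero(self.mk == k)[0] for k in range(len(self.markers))
        ]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def availability(self) -> np.ndarray:
        avail = np.zeros((self.n, len(self.markers)), dtype=bool)
        avail[self.part, self.mk] = True
        return avail


def _prepare_data(
    dataset: CohortDataset,
    markers: tuple[Marker, ...],
    specs: dict[Marker, MarkerSpec] | None = None,
) -> _ModelData:
    specs = specs or DEFAULT_MARKER_SPECS
    X, ids, center = build_covariate_matrix(dataset)
    pid_index = {pid: i for i, pid in enumerate(ids)}
    mk_index = {m: k for k, m in enumerate(markers)}
    rows = [(o, mk_index[o.marker]) for o in dataset.observations if o.marker in mk_index]
    y = np.array(
        [
            o.transformed_value
            if o.transformed_value is not None
            else float(specs[o.marker].forward(o.raw_value))
            for o, _ in rows
        ]
    )
    return _ModelData(
        y=y,
        age=np.array([o.age for o, _ in rows]),
        part=np.array([pid_index[o.participant_id] for o, _ in rows], dtype=int),
        mk=np.array([k for _, k in rows], dtype=int),
        X=X,
        participant_ids=ids,
        markers=markers,
        education_center=center,
    )


# ---------------------------------------------------------------------------
# likelihood (public, parameter-container based)

_LOG_2PI = math.log(2.0 * math.pi)


def log_likelihood(dataset: CohortDataset, params: AFTParameters) -> float:
    """Joint Gaussian log likelihood of the transformed observations.

    Sum over observations of the normal log density at mean
    g_k(shifted_age) with SD sigma_k.  Raises if any single contribution is
    non-finite, naming the offending observation.
    """
    X, ids, _ = build_covariate_matrix(dataset, params.education_center)
    pid_index = {pid: i for i, pid in enumerate(ids)}
    mk_index = {m: k for k, m in enumerate(params.markers)}
    specs = DEFAULT_MARKER_SPECS
    total = 0.0
    for o in dataset.observations:
        if o.marker not in mk_index:
            continue
        k = mk_index[o.marker]
        i = pid_index[o.participant_id]
        yv = (
            o.transformed_value
            if o.transformed_value is not None
            else float(specs[o.marker].forward(o.raw_value))
        )
        t = shifted_age(o.age, X[i], params.beta[k], params.u[i, k])
        mu = params.curves[o.marker].evaluate(float(t))
        s = params.sigma[k]
        contrib = -0.5 * _LOG_2PI - math.log(s) - 0.5 * ((yv - mu) / s) ** 2
        if not np.isfinite(contrib):
            raise ValueError(
                f"non-finite log-likelihood contribution for observation "
                f"(participant={o.participant_id}, marker={o.marker.value}, age={o.age})"
            )
        total += contrib
    return total


# ---------------------------------------------------------------------------
# correlation-matrix transform (tanh CPC Cholesky, LKJ prior)


def _corr_forward(y_vec: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained vector -> (L, z) with L the Cholesky factor of R."""
    z = np.tanh(y_vec)
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, K):
        q = 1.0
        for j in range(i):
            L[i, j] = z[pos] * math.sqrt(q)
            q -= L[i, j] ** 2
            pos += 1
        L[i, i] = math.sqrt(max(q, 1e-300))
    return L, z


def _corr_logp_grad(
    y_vec: np.ndarray, K: int, dL_lik: np.ndarray, eta: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """LKJ(eta) log prior + transform Jacobian, and gradient wrt y.

    ``dL_lik`` carries the likelihood gradient with respect to the entries
    of L; the returned gradient combines it with the prior/Jacobian terms.
    Also returns L for reuse.
    """
    z = np.tanh(y_vec)
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    logp = 0.0
    dy = np.zeros_like(y_vec)
    pos0 = 0
    for i in range(1, K):
        # forward pass for row i, caching q_j = prod_{m<j} (1 - z_im^2)
        qs = np.empty(i + 1)
        qs[0] = 1.0
        zrow = z[pos0 : pos0 + i]
        for j in range(i):
            L[i, j] = zrow[j] * math.sqrt(qs[j])
            qs[j + 1] = qs[j] - L[i, j] ** 2
        qs = np.maximum(qs, 1e-300)
        L[i, i] = math.sqrt(qs[i])
        expo = (K - 1 - i) + 2.0 * (eta - 1.0)
        logp += 0.5 * expo * math.log(qs[i])                 # LKJ density on L_ii
        logp += 0.5 * np.sum(np.log(qs[1:i])) if i > 1 else 0.0  # z -> L Jacobian
        logp += np.sum(np.log1p(-zrow * zrow))               # y -> z Jacobian

        # backward pass: accumulate gradients wrt q_j and z_ij
        gq = np.zeros(i + 1)
        gq[i] = dL_lik[i, i] * 0.5 / math.sqrt(qs[i]) + 0.5 * expo / qs[i]
        for j in range(i - 1, -1, -1):
            tot = dL_lik[i, j] - 2.0 * L[i, j] * gq[j + 1]
            gz = tot * math.sqrt(qs[j])
            dy[pos0 + j] = gz * (1.0 - zrow[j] ** 2) - 2.0 * zrow[j]
            if j > 0:
                gq[j] = gq[j + 1] + tot * zrow[j] * 0.5 / math.sqrt(qs[j]) + 0.5 / qs[j]
        pos0 += i
    return logp, dy, L


# ---------------------------------------------------------------------------
# model spec / sampler config


@dataclass
class PriorConfig:
    """Weakly informative defaults; all scales overridable."""

    beta_sd: float = 10.0        # years
    tau_sd: float = 10.0         # years (half-normal)
    sigma_sd: float = 1.0        # transformed units (half-normal)
    weight_sd: float = 1.0       # curve increment scale (half-normal)
    intercept_sd: float = 5.0    # transformed units
    lkj_eta: float = 1.0


@dataclass
class ModelSpec:
    markers: tuple[Marker, ...] = DEFAULT_MARKERS
    basis: MonotoneBasis = field(default_factory=MonotoneBasis)
    priors: PriorConfig = field(default_factory=PriorConfig)
    min_participants_per_marker: int = 20


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.8
    max_depth: int = 8
    rhat_threshold: float = 1.05
    max_divergence_frac: float = 0.02


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class AFTPosterior:
    """Posterior draws with chain structure plus diagnostics.

    Draw arrays have shape (chains, draws_per_chain, ...).  ``availability``
    flags which (participant, marker) adjustments are informed by data;
    prior-only entries are excluded from every summary.
    """

    markers: tuple[Marker, ...]
    covariate_names: tuple[str, ...]
    participant_ids: list[str]
    basis: MonotoneBasis
    education_center: float
    availability: np.ndarray          # (n, K) bool
    intercept: np.ndarray             # (C, S, K)
    weights: np.ndarray               # (C, S, K, nb)
    beta: np.ndarray                  # (C, S, K, P)
    tau: np.ndarray                   # (C, S, K)
    sigma: np.ndarray                 # (C, S, K)
    R: np.ndarray                     # (C, S, K, K)
    u: np.ndarray                     # (C, S, n, K)
    divergences: int = 0
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool = True
    step_sizes: tuple = ()

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_summary(self) -> pd.DataFrame:
        """Covariate effects in years: posterior mean and 95% CI."""
        b = self._flat(self.beta)
        rows = []
        for k, m in enumerate(self.markers):
            for p, cname in enumerate(self.covariate_names):
                lo, hi = np.percentile(b[:, k, p], [2.5, 97.5])
                rows.append(
                    {
                        "marker": m.value,
                        "covariate": cname,
                        "mean": b[:, k, p].mean(),
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
        return pd.DataFrame(rows)

    def mean_parameters(self) -> AFTParameters:
        """Posterior-mean plug-in parameter set."""
        curves = {
            m: ProgressionCurve(
                m,
                self.basis,
                self._flat(self.weights)[:, k].mean(axis=0),
                float(self._flat(self.intercept)[:, k].mean()),
            )
            for k, m in enumerate(self.markers)
        }
        Rm = self._flat(self.R).mean(axis=0)
        # mean of correlation draws is symmetric PD for any sane posterior,
        # but renormalize the diagonal defensively
        d = np.sqrt(np.diag(Rm))
        Rm = Rm / np.outer(d, d)
        return AFTParameters(
            curves=curves,
            beta=self._flat(self.beta).mean(axis=0),
            u=self._flat(self.u).mean(axis=0),
            tau=self._flat(self.tau).mean(axis=0),
            R=Rm,
            sigma=self._flat(self.sigma).mean(axis=0),
            markers=self.markers,
            covariate_names=self.covariate_names,
            participant_ids=tuple(self.participant_ids),
            education_center=self.education_center,
        )


# ---------------------------------------------------------------------------
# the log posterior and its gradient


class _Posterior:
    """Packs/unpacks the unconstrained parameter vector and evaluates
    the joint log density with analytic gradients."""

    def __init__(self, data: _ModelData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.K = len(spec.markers)
        # Standardize the response per marker so every marker's likelihood
        # has comparable curvature (residual SDs differ by an order of
        # magnitude across markers on their native transformed scales).
        # Curve intercepts/weights and sigma are mapped back at unpacking.
        self.y_center = np.zeros(self.K)
        self.y_scale = np.ones(self.K)
        for k, idx in enumerate(data.idx_by_marker):
            if idx.size:
                self.y_center[k] = data.y[idx].mean()
                self.y_scale[k] = max(float(data.y[idx].std()), 1e-8)
        self.y_std = (data.y - self.y_center[data.mk]) / self.y_scale[data.mk]
        self.n_obs_per_marker = np.array(
            [idx.size for idx in data.idx_by_marker], dtype=float
        )
        self._mk = np.ascontiguousarray(data.mk, dtype=np.int64)
        self._part = np.ascontiguousarray(data.part, dtype=np.int64)
        self._knots = np.ascontiguousarray(spec.basis.knots, dtype=float)
        self.P = data.X.shape[1]
        self.nb = spec.basis.n_basis
        self.n = data.n
        self.T = self.K * (self.K - 1) // 2
        sizes = [
            self.K,                  # intercepts c
            self.K * self.nb,        # log weights a
            self.K * self.P,         # beta
            self.K,                  # log tau
            self.K,                  # log sigma
            self.T,                  # correlation unconstrained
            self.n * self.K,         # z (non-centered u)
        ]
        self.offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.dim = int(self.offsets[-1])

    def split(self, theta: np.ndarray):
        o = self.offsets
        c = theta[o[0] : o[1]]
        a = theta[o[1] : o[2]].reshape(self.K, self.nb)
        beta = theta[o[2] : o[3]].reshape(self.K, self.P)
        log_tau = theta[o[3] : o[4]]
        log_sigma = theta[o[4] : o[5]]
        y_corr = theta[o[5] : o[6]]
        z = theta[o[6] : o[7]].reshape(self.n, self.K)
        return c, a, beta, log_tau, log_sigma, y_corr, z

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            return self._logp_grad(theta)

    def _logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d, pri = self.data, self.spec.priors
        c, a, beta, log_tau, log_sigma, y_corr, z = self.split(theta)
        w = np.exp(a)
        tau = np.exp(log_tau)
        sigma = np.exp(log_sigma)
        L, _ = _corr_forward(y_corr, self.K)

        zL = z @ L.T                       # (n, K)
        u = zL * tau
        shift = d.X @ beta.T + u           # (n, K)
        t = d.age + shift[d.part, d.mk]

        dc = np.zeros(self.K)
        dW = np.zeros((self.K, self.nb))
        G = np.zeros((self.n, self.K))
        rss = np.zeros(self.K)
        logp = float(
            _kernels.likelihood_accumulate(
                t, self.y_std, self._mk, self._part,
                self._knots, self.spec.basis.degree,
                self.spec.basis.lo, self.spec.basis.hi,
                w, c, sigma, dc, dW, G, rss,
            )
        )
        if not np.isfinite(logp):
            grad = np.zeros(self.dim)
            return -np.inf, grad
        dsig = -self.n_obs_per_marker / sigma + rss / sigma**3

        dbeta = G.T @ d.X
        Gt = G * tau
        dz = Gt @ L
        dtau = np.einsum("ik,ik->k", G, zL)
        dL_lik = Gt.T @ z                   # (K, K); lower triangle is used

        # priors and transform Jacobians
        logp += float(np.sum(-0.5 * (c / pri.intercept_sd) ** 2))
        dc += -c / pri.intercept_sd**2
        logp += float(np.sum(-0.5 * (w / pri.weight_sd) ** 2 + a))
        da = dW * w + (-(w**2) / pri.weight_sd**2 + 1.0)
        logp += float(np.sum(-0.5 * (beta / pri.beta_sd) ** 2))
        dbeta += -beta / pri.beta_sd**2
        logp += float(np.sum(-0.5 * (tau / pri.tau_sd) ** 2 + log_tau))
        dlog_tau = dtau * tau + (-(tau**2) / pri.tau_sd**2 + 1.0)
        logp += float(np.sum(-0.5 * (sigma / pri.sigma_sd) ** 2 + log_sigma))
        dlog_sigma = dsig * sigma + (-(sigma**2) / pri.sigma_sd**2 + 1.0)
        logp += float(np.sum(-0.5 * z * z))
        dz += -z
        corr_logp, dy_corr, _ = _corr_logp_grad(y_corr, self.K, dL_lik, pri.lkj_eta)
        logp += corr_logp

        grad = np.concatenate(
            [dc, da.ravel(), dbeta.ravel(), dlog_tau, dlog_sigma, dy_corr, dz.ravel()]
        )
        return logp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        """Data-driven start: flat-ish curves anchored at each marker's low
        quantile, unit-scale everything else, small jitter."""
        d = self.data
        c0 = np.zeros(self.K)
        a0 = np.full((self.K, self.nb), -2.5)
        s0 = np.zeros(self.K)
        for k, idx in enumerate(d.idx_by_marker):
            yk = self.y_std[idx]
            c0[k] = np.quantile(yk, 0.05) if idx.size else 0.0
            rng_k = (np.quantile(yk, 0.95) - c0[k]) if idx.size else 1.0
            a0[k] = np.log(max(rng_k, 1e-2) / self.nb)
            s0[k] = np.log(max(yk.std() * 0.5, 1e-2)) if idx.size else 0.0
        theta = np.concatenate(
            [
                c0,
                a0.ravel(),
                np.zeros(self.K * self.P),
                np.full(self.K, np.log(5.0)),
                s0,
                np.zeros(self.T),
                np.zeros(self.n * self.K),
            ]
        )
        jitter = 0.05 * rng.standard_normal(self.dim)
        return theta + jitter


# ---------------------------------------------------------------------------
# fitting


class ConvergenceWarning(UserWarning):
    pass


def fit_aft(
    dataset: CohortDataset,
    model_spec: ModelSpec | None = None,
    mcmc_config: MCMCConfig | None = None,
    seed: int = 0,
) -> AFTPosterior:
    """Fit the latent time-shift model by HMC and return the posterior.

    The dataset must carry transformed values (or raw values for markers
    whose default transform applies).  Draws are deterministic given
    ``seed``.  If split-R-hat on any headline estimand exceeds the
    threshold, or divergences exceed the allowed fraction, the posterior is
    returned with ``converged=False`` rather than raising.
    """
    spec = model_spec or ModelSpec()
    cfg = mcmc_config or MCMCConfig()
    if len(spec.markers) < 2:
        raise ValueError("need at least 2 markers")
    data = _prepare_data(dataset, spec.markers)
    avail = data.availability
    n_per_marker = avail.sum(axis=0)
    for k, m in enumerate(spec.markers):
        if n_per_marker[k] < spec.min_participants_per_marker:
            raise ValueError(
                f"marker {m.value} observed in only {n_per_marker[k]} participants "
                f"(minimum {spec.min_participants_per_marker})"
            )

    post = _Posterior(data, spec)
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(cfg.chains)
    K, P, nb, n = post.K, post.P, post.nb, post.n

    results = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        x0 = post.initial_point(rng)
        results.append(
            hmc.sample_chain(
                post.logp_grad,
                x0,
                rng,
                n_warmup=cfg.warmup,
                n_draws=cfg.draws,
                target_accept=cfg.target_accept,
                max_depth=cfg.max_depth,
            )
        )

    C, S = cfg.chains, cfg.draws
    intercept = np.empty((C, S, K))
    weights = np.empty((C, S, K, nb))
    beta = np.empty((C, S, K, P))
    tau = np.empty((C, S, K))
    sigma = np.empty((C, S, K))
    Rd = np.empty((C, S, K, K))
    u = np.empty((C, S, n, K))
    scale, center = post.y_scale, post.y_center
    for ci, res in enumerate(results):
        for si in range(S):
            c_, a_, b_, lt_, ls_, yc_, z_ = post.split(res.draws[si])
            L, _ = _corr_forward(yc_, K)
            # undo the internal per-marker response standardization
            intercept[ci, si] = c_ * scale + center
            weights[ci, si] = np.exp(a_) * scale[:, None]
            beta[ci, si] = b_
            tau[ci, si] = np.exp(lt_)
            sigma[ci, si] = np.exp(ls_) * scale
            Rd[ci, si] = L @ L.T
            u[ci, si] = (z_ @ L.T) * np.exp(lt_)

    divergences = sum(r.divergences for r in results)
    rhat, ess = _diagnostics(beta, tau, sigma, Rd, intercept)
    worst_rhat = max(rhat.values()) if rhat else 1.0
    converged = (
        worst_rhat <= cfg.rhat_threshold
        and divergences <= cfg.max_divergence_frac * C * S
    )
    return AFTPosterior(
        markers=spec.markers,
        covariate_names=COVARIATE_NAMES,
        participant_ids=data.participant_ids,
        basis=spec.basis,
        education_center=data.education_center,
        availability=avail,
        intercept=intercept,
        weights=weights,
        beta=beta,
        tau=tau,
        sigma=sigma,
        R=Rd,
        u=u,
        divergences=divergences,
        rhat=rhat,
        ess=ess,
        converged=converged,
        step_sizes=tuple(r.step_size for r in results),
    )


def _diagnostics(beta, tau, sigma, Rd, intercept) -> tuple[dict, dict]:
    """Split-R-hat and bulk ESS for the headline estimands via arviz."""
    import arviz as az

    K = tau.shape[2]
    P = beta.shape[3]
    named = {}
    for k in range(K):
        named[f"tau_{k}"] = tau[:, :, k]
        named[f"sigma_{k}"] = sigma[:, :, k]
        named[f"intercept_{k}"] = intercept[:, :, k]
        for p in range(P):
            named[f"beta_{k}_{p}"] = beta[:, :, k, p]
        for j in range(k):
            named[f"R_{k}_{j}"] = Rd[:, :, k, j]
    rhat, ess = {}, {}
    for name, arr in named.items():
        if arr.shape[0] >= 2:
            rhat[name] = float(az.rhat(arr.astype(float)))
            ess[name] = float(az.ess(arr.astype(float)))
        else:
            rhat[name] = 1.0
            ess[name] = float(az.ess(arr.astype(float)))
    return rhat, ess


# ---------------------------------------------------------------------------
# estimand extraction


def percent_variance_explained(r: float) -> float:
    """Percent of one adjustment's variance explained by another: 100*r^2."""
    if abs(r) > 1.0:
        raise ValueError("correlation must lie in [-1, 1]")
    return 100.0 * r * r


def adjustment_correlation(posterior: AFTPosterior) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% CI of each R entry.

    Summaries are taken over draws of the model-level correlation
    parameter, not the empirical correlation of point estimates.
    """
    Rd = posterior._flat(posterior.R)
    rows = []
    K = len(posterior.markers)
    for i in range(K):
        for j in range(i + 1, K):
            draws = Rd[:, i, j]
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "marker_1": posterior.markers[i].value,
                    "marker_2": posterior.markers[j].value,
                    "mean": float(draws.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "pct_variance_explained": percent_variance_explained(
                        float(draws.mean())
                    ),
                }
            )
    return pd.DataFrame(rows)


def extract_adjustments(posterior: AFTPosterior) -> pd.DataFrame:
    """Per-participant onset adjustments in years (positive = earlier).

    Participants with no observations of a marker are excluded for that
    marker (their u draws are prior-only).  FA GCC adjustments keep the
    positive-= -earlier-onset convention after restoring native scaling,
    so no sign flip is applied.
    """
    ud = posterior._flat(posterior.u)     # (draws, n, K)
    rows = []
    for i, pid in enumerate(posterior.participant_ids):
        for k, m in enumerate(posterior.markers):
            if not posterior.availability[i, k]:
                continue
            draws = ud[:, i, k]
            lo, hi = np.percentile(draws, [2.5, 97.5])
            rows.append(
                {
                    "participant_id": pid,
                    "marker": m.value,
                    "mean": float(draws.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)
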