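"""Hierarchical Bayesian estimation of cortical currents from EEG.

Observation model (per time sample): ``E = G J + xi`` with sensor noise
precision ``beta`` and a conditionally Gaussian prior on the currents,

    P(J | alpha, beta) ~ exp(-beta/2 * J' A J),   A = diag(alpha),

so ``alpha_i`` is the current precision of source i *relative to* the noise
precision.  An automatic-relevance-determination (ARD) hierarchy places a
Gamma prior on each ``alpha_i`` with mean ``alpha0_i = 1/v0_i`` and degree
of freedom ``r0``; a Jeffreys prior ``P(beta) = 1/beta`` completes the
model.  Functional-MRI information enters through the prior variances

    v0_i = vbase + (m0 - 1) * vbase * t_i^2,

with ``t_i`` the normalized T-value on vertex i, ``vbase`` a baseline
variance estimated from pre-movement data by Bayesian minimum-norm, and
``m0`` the task/baseline variance magnification (default 100; prior
confidence ``r0`` defaults to 10).

Inference is variational Bayes: coordinate ascent on the free energy under
the factorization q(J) q(alpha) q(beta), with conjugate updates (Gaussian
for J, Gamma for alpha and beta).  The free energy is evaluated exactly at
every iteration; it is non-decreasing, which the test suite asserts.

The converged posterior defines the linear inverse filter

    L = S G' (G S G' + beta^-1 I_M)^-1,        S = diag(current variance),

applied as ``J(t) = L E(t)`` to (preprocessed) EEG.  Artifact dipole
columns (heart, eyes, ...) are carried in the lead field and absorbed by
the same machinery but never exported in cortical ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from cortexlimb.exceptions import (
    EstimationError,
    InvalidInputError,
    InvalidPriorError,
    InvalidRoiError,
    NumericalError,
)

DEFAULT_M0 = 100.0
DEFAULT_R0 = 10.0

#: condition-number threshold beyond which the sensor-space system is jittered
CONDITION_GUARD = 1e12
JITTER_SCALE = 1e-10


@dataclass
class LeadField:
    """Sensors x sources gain matrix with source bookkeeping.

    Columns ``0..n_cortex-1`` are cortical vertexes; ``artifact_idx`` lists
    extra artifact-dipole columns (heart, shoulder, wrist, eyeballs,
    carotids).  ``roi_m1`` indexes the primary-motor-cortex subset used for
    EMG decoding; ``regions`` may carry further labeled vertex groups.
    """

    G: np.ndarray
    n_cortex: int
    roi_m1: np.ndarray
    artifact_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    sensor_names: tuple | None = None
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        self.roi_m1 = np.asarray(self.roi_m1, dtype=int)
        self.artifact_idx = np.asarray(self.artifact_idx, dtype=int)
        if self.G.ndim != 2:
            raise InvalidInputError("G must be 2-D (sensors x sources)")
        if not np.all(np.isfinite(self.G)):
            raise InvalidInputError("lead field contains non-finite entries")
        if np.any(np.all(self.G == 0, axis=1)):
            raise InvalidInputError("lead field has an all-zero sensor row")
        if self.n_cortex + len(self.artifact_idx) != self.G.shape[1]:
            raise InvalidInputError(
                "n_cortex + artifact columns must equal the number of G columns"
            )
        if self.roi_m1.size and (
            self.roi_m1.min() < 0 or self.roi_m1.max() >= self.n_cortex
        ):
            raise InvalidInputError("roi_m1 indices must lie in the cortical range")

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G.shape[1]


@dataclass
class FMRIPrior:
    """Normalized per-vertex T-values, in [0, 1] with max 1 when active."""

    t_hat: np.ndarray

    def __post_init__(self):
        self.t_hat = np.asarray(self.t_hat, dtype=float)
        if np.any(self.t_hat < 0) or np.any(self.t_hat > 1):
            raise InvalidPriorError("normalized T-values must lie in [0, 1]")


@dataclass
class VariancePrior:
    """Per-source prior current variances and ARD hyperparameters.

    ``v0`` is in absolute (squared current) units; internally the VB
    machinery works with variances relative to the sensor-noise variance.
    """

    v0: np.ndarray
    vbase: float
    m0: float = DEFAULT_M0
    r0: float = DEFAULT_R0

    def __post_init__(self):
        self.v0 = np.asarray(self.v0, dtype=float)
        if self.vbase <= 0:
            raise InvalidPriorError("vbase must be positive")
        if self.m0 < 1:
            raise InvalidPriorError("m0 must be >= 1")
        if self.r0 <= 0:
            raise InvalidPriorError("r0 must be positive")
        if np.any(self.v0 < self.vbase * (1 - 1e-12)):
            raise InvalidPriorError("v0 must be >= vbase elementwise")


@dataclass
class PosteriorState:
    """Converged (or last-iterate) VB posterior summaries.

    ``alpha_inv`` is the posterior mean current variance *relative to the
    noise variance* (the ``alpha^-1`` of the hierarchical model); ``beta``
    is the posterior mean noise precision in 1/uV^2.  Their product
    ``current_variance = alpha_inv / beta`` is the absolute per-source
    variance entering the inverse filter.
    """

    alpha_inv: np.ndarray
    beta: float
    free_energy_trace: np.ndarray
    iterations: int
    converged: bool
    noise_var0: float = np.nan

    @property
    def current_variance(self) -> np.ndarray:
        return self.alpha_inv / self.beta


@dataclass
class InverseFilter:
    """Precomputed N x M source-reconstruction matrix, J(t) = L E(t)."""

    L: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class SourceEstimate:
    """Per-vertex current time series (N, T) at ``rate`` Hz."""

    J: np.ndarray
    rate: float
    t_start: float = 0.0
    indices: np.ndarray | None = None  # source indices represented by the rows

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2:
            raise InvalidInputError("J must be (sources, T)")
        if not np.all(np.isfinite(self.J)):
            raise InvalidInputError("source estimate contains non-finite values")


# ---------------------------------------------------------------------------
# Priors


def prior_variance_from_fmri(
    prior: FMRIPrior,
    vbase: float,
    m0: float = DEFAULT_M0,
    r0: float = DEFAULT_R0,
    n_artifact: int = 0,
) -> VariancePrior:
    """Map normalized T-values to prior current variances.

    ``v0_i = vbase + (m0 - 1) * vbase * t_i^2``: inactive vertexes keep the
    baseline variance, fully active ones are magnified by ``m0``.  Artifact
    dipole columns (appended last) get the unconstrained magnified variance
    ``m0 * vbase``.
    """
    if vbase <= 0:
        raise InvalidPriorError("vbase must be positive")
    v0_cortex = vbase + (m0 - 1.0) * vbase * prior.t_hat**2
    v0 = np.concatenate([v0_cortex, np.full(n_artifact, m0 * vbase)])
    return VariancePrior(v0=v0, vbase=vbase, m0=m0, r0=r0)


@dataclass
class BaselineEstimate:
    """Uniform source-variance scale and sensor-noise variance of a baseline."""

    vbase: float
    noise_variance: float

    def __float__(self):
        return float(self.vbase)


def estimate_baseline_variance(
    pre_movement_eeg: np.ndarray, G: np.ndarray
) -> BaselineEstimate:
    """Fit a uniform-prior (minimum-norm) model to baseline sensor data.

    The baseline sensor covariance is modeled as ``C = v G G' + s I`` and
    the Gaussian evidence is maximized over the uniform source variance
    ``v`` and noise variance ``s``.  Only ``v`` (vbase) feeds the fMRI
    prior; ``s`` anchors the relative units of the VB model.
    """
    E = np.atleast_2d(np.asarray(pre_movement_eeg, dtype=float))
    if E.shape[1] == 0 or not np.any(E):
        raise EstimationError("degenerate (empty or all-zero) baseline segment")
    G = np.asarray(G, dtype=float)
    M, T = E.shape
    lam, U = np.linalg.eigh(G @ G.T)
    lam = np.clip(lam, 0.0, None)
    p = np.sum((U.T @ E) ** 2, axis=1)  # per-eigendirection data power

    def nll(logparams):
        v, s = np.exp(logparams)
        c = v * lam + s
        return T * np.sum(np.log(c)) + np.sum(p / c)

    power = p.sum() / (M * T)
    lam_scale = max(lam.mean(), 1e-300)
    # two starts: source-dominant and noise-dominant.  When G G' is close
    # to a multiple of the identity the (v, s) split is unidentifiable and
    # the likelihood has a flat ridge; the tie-break below prefers the
    # noise explanation, so source variance is only claimed on evidence.
    starts = [
        np.log([max(0.9 * power / lam_scale, 1e-12), max(0.1 * power, 1e-12)]),
        np.log([max(1e-3 * power / lam_scale, 1e-15), max(power, 1e-12)]),
    ]
    fits = [
        optimize.minimize(nll, x0, method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 2000})
        for x0 in starts
    ]
    best = min(f.fun for f in fits)
    tied = [f for f in fits if f.fun <= best + 1e-6 * abs(best)]
    res = min(tied, key=lambda f: f.x[0])
    v, s = np.exp(res.x)
    return BaselineEstimate(vbase=float(v), noise_variance=float(s))


# ---------------------------------------------------------------------------
# Variational Bayes


def _vb_posterior_moments(E, G, alpha_bar, beta_bar):
    """Gaussian q(J) moments via the Woodbury identity (M x M solves only)."""
    Ainv = 1.0 / alpha_bar
    GA = G * Ainv  # (M, N) = G @ diag(Ainv)
    C = GA @ G.T  # G A^-1 G'
    K = np.eye(G.shape[0]) + C
    Kinv_GA = np.linalg.solve(K, GA)
    mu = GA.T @ np.linalg.solve(K, E)  # (N, T)
    # diag of (G'G + A)^-1 = A^-1 - A^-1 G' K^-1 G A^-1
    diag_inner = Ainv - np.einsum("mn,mn->n", GA, Kinv_GA)
    tr_CKinv = np.trace(np.linalg.solve(K, C))
    logdet_inner = np.sum(np.log(alpha_bar)) + np.linalg.slogdet(K)[1]
    resid_mean = float(np.sum((E - G @ mu) ** 2))
    return mu, diag_inner, tr_CKinv, logdet_inner, resid_mean


def vb_estimate(
    E: np.ndarray,
    G: np.ndarray | LeadField,
    prior: VariancePrior,
    noise_var: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> PosteriorState:
    """Estimate source current variances by variational Bayes.

    Parameters
    ----------
    E : (M, T) preprocessed EEG samples (one or more concatenated epochs).
    G : lead field matrix or :class:`LeadField`.
    prior : per-source prior variances (absolute units) and (m0, r0).
    noise_var : sensor-noise variance anchoring the relative units of the
        model (typically the baseline estimate).  When omitted, half the
        mean sensor power is used as a crude anchor.
    """
    if isinstance(G, LeadField):
        G = G.G
    E = np.atleast_2d(np.asarray(E, dtype=float))
    G = np.asarray(G, dtype=float)
    M, T = E.shape
    N = G.shape[1]
    if G.shape[0] != M:
        raise InvalidInputError("E and G disagree on the number of sensors")
    if prior.v0.shape != (N,):
        raise InvalidInputError("prior v0 length must match the number of sources")
    if noise_var is None:
        noise_var = 0.5 * float(np.mean(E**2))
    if noise_var <= 0:
        raise InvalidInputError("noise_var must be positive")

    r0 = prior.r0
    alpha0 = noise_var / prior.v0  # prior mean of the relative precisions
    alpha_bar = alpha0.copy()
    beta_bar = 1.0 / noise_var

    a_shape = r0 + T / 2.0
    c_shape = (M + N) * T / 2.0
    lgam_r0 = special.gammaln(r0)

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # --- q(J)
        mu, diag_inner, tr_CKinv, logdet_inner, resid_mean = _vb_posterior_moments(
            E, G, alpha_bar, beta_bar
        )
        S = np.sum(mu**2, axis=1) + T * diag_inner / beta_bar
        resid = resid_mean + T * tr_CKinv / beta_bar

        # --- q(alpha): Gamma(a_shape, b)
        b_rate = r0 / alpha0 + beta_bar * S / 2.0
        alpha_bar = a_shape / b_rate
        ln_alpha = special.digamma(a_shape) - np.log(b_rate)

        # --- q(beta): Gamma(c_shape, d)
        d_rate = resid / 2.0 + float(alpha_bar @ S) / 2.0
        beta_new = c_shape / d_rate
        ln_beta = special.digamma(c_shape) - np.log(d_rate)

        # --- free energy (exact, with q(J) moments from this iteration)
        F = (
            (M * T / 2.0) * (ln_beta - np.log(2 * np.pi))
            - beta_new * resid / 2.0
            + (N * T / 2.0) * (ln_beta - np.log(2 * np.pi))
            + (T / 2.0) * np.sum(ln_alpha)
            - beta_new * float(alpha_bar @ S) / 2.0
            + np.sum(
                r0 * np.log(r0 / alpha0)
                - lgam_r0
                + (r0 - 1.0) * ln_alpha
                - (r0 / alpha0) * alpha_bar
            )
            - ln_beta
            # entropy of q(J): T/2 * ln det(2 pi e Sigma_J), Sigma_J from step 1
            + (T / 2.0) * (N * np.log(2 * np.pi * np.e) - N * np.log(beta_bar) - logdet_inner)
            # entropies of the Gamma factors
            + np.sum(a_shape - np.log(b_rate) + special.gammaln(a_shape)
                     + (1 - a_shape) * special.digamma(a_shape))
            + c_shape - np.log(d_rate) + special.gammaln(c_shape)
            + (1 - c_shape) * special.digamma(c_shape)
        )
        beta_bar = float(beta_new)
        if not np.isfinite(F):
            raise NumericalError(f"free energy became non-finite at iteration {it}")
        trace.append(float(F))
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / max(abs(trace[-2]), 1e-300)
            if rel < tol:
                converged = True
                break

    if not converged:
        warnings.warn(
            f"VB did not converge within {max_iter} iterations "
            f"(returning the last iterate)",
            RuntimeWarning,
        )
    return PosteriorState(
        alpha_inv=1.0 / alpha_bar,
        beta=beta_bar,
        free_energy_trace=np.asarray(trace),
        iterations=it,
        converged=converged,
        noise_var0=float(noise_var),
    )


# ---------------------------------------------------------------------------
# Inverse filter


def build_inverse_filter(
    state, G: np.ndarray | LeadField, beta: float | None = None
) -> InverseFilter:
    """Assemble ``L = S G' (G S G' + beta^-1 I)^-1`` from a posterior.

    ``state`` may be a :class:`PosteriorState` (its absolute per-source
    variance and noise precision are used) or a per-source variance array
    with an explicit ``beta``.  If the M x M sensor-space system is
    ill-conditioned beyond 1e12 a trace-scaled jitter is added.
    """
    if isinstance(G, LeadField):
        G = G.G
    G = np.asarray(G, dtype=float)
    if isinstance(state, PosteriorState):
        variance = state.current_variance
        beta = state.beta
    else:
        variance = np.asarray(state, dtype=float)
        if beta is None:
            raise InvalidInputError("beta is required with an explicit variance array")
    if variance.shape != (G.shape[1],):
        raise InvalidInputError("variance length must match the number of sources")

    SGt = (G * variance).T  # S G'
    K = G @ SGt + (1.0 / beta) * np.eye(G.shape[0])
    cond = np.linalg.cond(K)
    if not np.isfinite(cond):
        raise NumericalError("singular sensor-space system")
    if cond > CONDITION_GUARD:
        K = K + JITTER_SCALE * (np.trace(K) / K.shape[0]) * np.eye(K.shape[0])
    L = np.linalg.solve(K, SGt.T).T  # (S G') K^-1, K symmetric
    return InverseFilter(L=L, provenance={"beta": float(beta)})


def apply_inverse(
    L: InverseFilter | np.ndarray, E, rate: float | None = None, t_start: float = 0.0
) -> SourceEstimate:
    """Apply the inverse filter per time sample: ``J = L E``."""
    Lm = L.L if isinstance(L, InverseFilter) else np.asarray(L, dtype=float)
    from cortexlimb.signal_preprocessing import EEGRecording  # local: avoid cycle

    if isinstance(E, EEGRecording):
        samples, rate, t_start = E.samples, E.rate, E.t_start
    else:
        samples = np.atleast_2d(np.asarray(E, dtype=float))
        if rate is None:
            rate = 256.0
    if samples.shape[0] != Lm.shape[1]:
        raise InvalidInputError(
            f"filter expects {Lm.shape[1]} sensors, got {samples.shape[0]}"
        )
    return SourceEstimate(J=Lm @ samples, rate=rate, t_start=t_start)


def select_roi(
    estimate: SourceEstimate,
    roi: np.ndarray | None = None,
    lead_field: LeadField | None = None,
) -> SourceEstimate:
    """Restrict a source estimate to a cortical ROI (stable index order).

    Defaults to the lead field's primary-motor-cortex subset.  Artifact
    dipole columns are never valid ROI members.
    """
    if roi is None:
        if lead_field is None:
            raise InvalidRoiError("need an explicit roi or a lead field with roi_m1")
        roi = lead_field.roi_m1
    roi = np.asarray(roi, dtype=int)
    if roi.size == 0:
        raise InvalidRoiError("empty ROI")
    n_rows = estimate.J.shape[0]
    if lead_field is not None:
        if np.any(np.isin(roi, lead_field.artifact_idx)):
            raise InvalidRoiError("ROI contains artifact-dipole indices")
        if roi.min() < 0 or roi.max() >= lead_field.n_cortex:
            raise InvalidRoiError("ROI index outside the cortical range")
    if roi.min() < 0 or roi.max() >= n_rows:
        raise InvalidRoiError("ROI index out of range for this estimate")
    return SourceEstimate(
        J=estimate.J[roi], rate=estimate.rate, t_start=estimate.t_start, indices=roi
    )
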