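"""Mixture-of-experts decoder from filtered EMG to four joint angles.

Two feed-forward expert networks (by convention one specializes in posture,
the other in movement) each map the 9 filtered-EMG channels to the 4 joint
angles; a gating network driven by the scalar summed-squared joint-angle
velocity assigns softmax weights ``g_i`` to the experts, and the decoder
output is the convex combination ``theta = sum_i g_i * theta_hat_i``.

Training maximizes the mixture log likelihood

    lnL = ln sum_i g_i exp(-||theta - theta_hat_i||^2 / (2 sigma_i^2))

by full-batch gradient ascent (backpropagation), using the analytic
gradients ``d lnL / d x_i = h_i - g_i`` for the gate pre-activations and
``d lnL / d theta_hat_i = h_i (theta - theta_hat_i) / sigma_i^2`` for the
expert outputs, where ``h_i`` is the posterior responsibility of expert i.
Separating posture (near-zero velocity, low muscle tension) from movement
(high velocity, high tension) prevents the movement regime's large errors
from swamping the posture regime during training.

The true summed-squared velocity exists only for training data; at test
time a linear proxy estimates it from the filtered EMG itself
(:func:`fit_velocity_proxy`), clipped at zero.

Training supports a kick-out-style restart: on loss plateaus the weights
receive a small seeded random perturbation and the best checkpoint is
retained — a documented surrogate for the cited kick-out procedure whose
published details are unavailable; it preserves the stated purpose
(escaping local optima) and can be disabled.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from cortexlimb.arm_kinematics import JointAngleTrajectory, summed_squared_velocity
from cortexlimb.exceptions import (
    InvalidInputError,
    ModelStateError,
    TrainingError,
)

N_ANGLES = 4
N_EMG = 9


# ---------------------------------------------------------------------------
# Mixture mathematics (pure functions, array in / array out)


def softmax_gate(x: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with max-subtraction for stability.

    ``g_j = exp(x_j) / sum_i exp(x_i)``; the outputs sum to 1 for any
    finite scores, including extreme ones.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("gate scores must be finite")
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def combine_experts(g: np.ndarray, expert_outputs: np.ndarray) -> np.ndarray:
    """Convex combination ``theta = sum_i g_i theta_hat_i``.

    ``g`` is (..., N); ``expert_outputs`` is (N, ..., 4).
    """
    g = np.asarray(g, dtype=float)
    outs = np.asarray(expert_outputs, dtype=float)
    if g.shape[-1] != outs.shape[0]:
        raise InvalidInputError(
            f"{g.shape[-1]} gate outputs for {outs.shape[0]} experts"
        )
    return np.einsum("...i,i...d->...d", g, outs)


def mixture_loglik(
    gate_scores: np.ndarray,
    expert_outputs: np.ndarray,
    targets: np.ndarray,
    sigma: np.ndarray,
    normalized: bool = False,
):
    """Per-sample mixture log likelihood and expert responsibilities.

    Computed via log-sum-exp, so extreme scores or large residuals never
    produce NaN.  Responsibilities sum to 1 over experts.

    With ``normalized=False`` (default) the mixture kernel is the bare
    ``exp(-||theta - theta_hat_i||^2 / (2 sigma_i^2))``, so a perfect fit
    under a unit gate weight gives lnL = 0.  ``normalized=True`` restores
    the Gaussian normalizer ``(2 pi sigma_i^2)^(-d/2)``; with per-expert
    scales this matters for training, because an unnormalized kernel lets
    a large-sigma expert approach kernel 1 everywhere and absorb all
    responsibilities.

    Parameters
    ----------
    gate_scores : (T, N) pre-activation gate scores x_i.
    expert_outputs : (N, T, 4) per-expert angle predictions theta_hat_i.
    targets : (T, 4) target angles.
    sigma : (N,) per-expert residual scales, all > 0.

    Returns
    -------
    lnL : (T,) per-sample log likelihood.
    resp : (T, N) posterior responsibilities h_i.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise InvalidInputError("sigma must be positive")
    g = softmax_gate(gate_scores)
    sq = np.sum((targets[None, :, :] - expert_outputs) ** 2, axis=-1).T  # (T, N)
    log_kernel = -sq / (2.0 * sigma**2)
    if normalized:
        d = targets.shape[-1]
        log_kernel = log_kernel - d * np.log(sigma) - 0.5 * d * np.log(2 * np.pi)
    log_terms = np.log(np.clip(g, 1e-300, None)) + log_kernel
    m = log_terms.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.sum(np.exp(log_terms - m), axis=1))
    resp = np.exp(log_terms - lse[:, None])
    return lse, resp


def mixture_gradients(
    gate_scores: np.ndarray,
    expert_outputs: np.ndarray,
    targets: np.ndarray,
    sigma: np.ndarray,
    normalized: bool = False,
):
    """Analytic gradients of the summed lnL w.r.t. gate scores and outputs.

    ``d lnL / d x_i = h_i - g_i`` (so the gradient sums to zero over
    experts) and ``d lnL / d theta_hat_i = h_i (theta - theta_hat_i) /
    sigma_i^2``.

    Returns
    -------
    d_scores : (T, N)
    d_outputs : (N, T, 4)
    """
    sigma = np.asarray(sigma, dtype=float)
    g = softmax_gate(gate_scores)
    _, resp = mixture_loglik(gate_scores, expert_outputs, targets, sigma,
                             normalized=normalized)
    d_scores = resp - g
    diff = targets[None, :, :] - expert_outputs  # (N, T, 4)
    d_outputs = resp.T[:, :, None] * diff / (sigma**2)[:, None, None]
    return d_scores, d_outputs


# ---------------------------------------------------------------------------
# Networks


@dataclass
class ExpertNetwork:
    """One-hidden-layer tanh network, EMG (9) -> hidden -> angles (4)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, n_in: int, n_hidden: int, rng, scale: float = 0.1):
        return cls(
            W1=scale * rng.standard_normal((n_in, n_hidden)),
            b1=np.zeros(n_hidden),
            W2=scale * rng.standard_normal((n_hidden, N_ANGLES)),
            b2=np.zeros(N_ANGLES),
        )

    def forward(self, X: np.ndarray):
        H = np.tanh(X @ self.W1 + self.b1)
        return H @ self.W2 + self.b2, H

    def backward(self, X, H, d_out):
        """Gradients of sum(d_out * output) w.r.t. the weights."""
        dW2 = H.T @ d_out
        db2 = d_out.sum(axis=0)
        dH = (d_out @ self.W2.T) * (1.0 - H**2)
        dW1 = X.T @ dH
        db1 = dH.sum(axis=0)
        return dW1, db1, dW2, db2

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


@dataclass
class GatingNetwork:
    """Linear map from the scalar gate feature to N expert scores."""

    w: np.ndarray  # (N,)
    b: np.ndarray  # (N,)

    @classmethod
    def init(cls, n_experts: int, rng, scale: float = 0.1):
        """Seeded init with deterministic symmetry breaking.

        The base slopes spread from -1 to +1 over the experts so that the
        first expert is favored at low gate-feature values (posture) and
        the last at high values (movement); without this the experts start
        interchangeable, responsibilities stay uniform and neither
        specializes.
        """
        base = np.linspace(-1.0, 1.0, n_experts) if n_experts > 1 else np.zeros(1)
        return cls(
            w=base + scale * rng.standard_normal(n_experts),
            b=-base + scale * rng.standard_normal(n_experts),
        )

    def forward(self, feature: np.ndarray) -> np.ndarray:
        return feature[:, None] * self.w + self.b

    def params(self):
        return [self.w, self.b]


@dataclass
class VelocityProxy:
    """Linear map from filtered EMG to summed-squared velocity, clipped at 0."""

    w: np.ndarray
    b: float

    def __call__(self, femg: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(femg) @ self.w + self.b, 0.0, None)


@dataclass
class TrainConfig:
    """Training hyperparameters (all exposed; defaults are the package's)."""

    n_experts: int = 2
    n_hidden: int = 20
    epochs: int = 2000
    learning_rate: float = 0.05
    init_scale: float = 0.1
    seed: int = 0
    kickout: bool = True
    kickout_patience: int = 50
    kickout_scale: float = 0.01
    sigma_floor: float = 0.05
    #: train on the normalized Gaussian mixture likelihood (recommended with
    #: per-expert sigma; see mixture_loglik)
    normalized_kernels: bool = True
    #: epochs during which responsibilities follow the gate prior (not the
    #: posterior), committing each expert to its velocity regime before
    #: joint refinement; prevents one expert from absorbing all data early
    warmup_epochs: int = 200


@dataclass
class MixtureModel:
    """Trained mixture-of-experts decoder with standardization metadata."""

    experts: list
    gate: GatingNetwork
    sigma: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    f_scale: float  # gate-feature scale
    config: TrainConfig = field(default_factory=TrainConfig)
    loss_trace: np.ndarray | None = None
    trained: bool = False

    def _forward_std(self, Xs: np.ndarray, feature: np.ndarray):
        scores = self.gate.forward(feature / self.f_scale)
        g = softmax_gate(scores)
        outs = np.stack([e.forward(Xs)[0] for e in self.experts])
        return scores, g, outs

    def predict_standardized(self, femg: np.ndarray, feature: np.ndarray):
        """Combined output plus gate weights, on raw (unstandardized) scales."""
        Xs = (np.asarray(femg) - self.x_mean) / self.x_std
        _, g, outs = self._forward_std(Xs, np.asarray(feature, dtype=float))
        theta_s = combine_experts(g, outs)
        return theta_s * self.y_std + self.y_mean, g


# ---------------------------------------------------------------------------
# Training


def _flat_params(experts, gate):
    return np.concatenate(
        [p.ravel() for e in experts for p in e.params()] + [p.ravel() for p in gate.params()]
    )


def train_mixture(
    femg: np.ndarray,
    angles: JointAngleTrajectory,
    config: TrainConfig | None = None,
    gate_feature: np.ndarray | None = None,
) -> MixtureModel:
    """Train the mixture-of-experts decoder on aligned EMG/angle data.

    ``femg`` is (T, 9) filtered EMG; ``angles`` supplies the (T,) gating
    feature (summed-squared joint-angle velocity) unless ``gate_feature``
    overrides it.  Training is deterministic for a fixed seed.
    """
    cfg = config or TrainConfig()
    X = np.asarray(femg, dtype=float)
    Y = np.asarray(angles.theta, dtype=float).T
    if X.shape[0] != Y.shape[0]:
        raise InvalidInputError("EMG and angles must be time-aligned (same T)")
    if gate_feature is None:
        gate_feature = summed_squared_velocity(angles)
    f = np.asarray(gate_feature, dtype=float)

    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean, y_std = Y.mean(axis=0), Y.std(axis=0)
    y_std[y_std < 1e-12] = 1.0
    f_scale = float(max(np.mean(f), 1e-12))
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std
    fs = f / f_scale
    T = X.shape[0]

    rng = np.random.default_rng(cfg.seed)
    experts = [
        ExpertNetwork.init(X.shape[1], cfg.n_hidden, rng, cfg.init_scale)
        for _ in range(cfg.n_experts)
    ]
    gate = GatingNetwork.init(cfg.n_experts, rng, cfg.init_scale)
    sigma = np.ones(cfg.n_experts)

    lr = cfg.learning_rate
    trace = np.empty(cfg.epochs)
    best = (-np.inf, None)
    since_best = 0
    last_good = None
    for epoch in range(cfg.epochs):
        scores = gate.forward(fs)
        outs = np.stack([e.forward(Xs)[0] for e in experts])
        lnL, resp = mixture_loglik(scores, outs, Ys, sigma,
                                   normalized=cfg.normalized_kernels)
        if epoch < cfg.warmup_epochs:
            # commit each sample to its gate-preferred expert (gate frozen)
            gp = softmax_gate(scores)
            resp = np.zeros_like(gp)
            resp[np.arange(len(gp)), np.argmax(gp, axis=1)] = 1.0
        mean_lnL = float(np.mean(lnL))
        if not np.isfinite(mean_lnL):
            raise TrainingError(
                f"training diverged (non-finite loss) at epoch {epoch}",
                checkpoint=last_good,
            )
        trace[epoch] = mean_lnL

        if epoch < cfg.warmup_epochs:
            g = softmax_gate(scores)
            d_scores = np.zeros_like(scores)
            d_outs = resp.T[:, :, None] * (Ys[None] - outs) / (sigma**2)[:, None, None]
        else:
            d_scores, d_outs = mixture_gradients(scores, outs, Ys, sigma,
                                                 normalized=cfg.normalized_kernels)
        d_scores /= T
        d_outs /= T
        # precondition each expert's step by sigma_i^2 (a positive multiple
        # of the same ascent direction): the raw gradient carries a 1/sigma^2
        # factor whose growth as an expert tightens destabilizes fixed-step
        # ascent; the scaled step is the responsibility-weighted LS gradient
        d_outs = d_outs * (sigma**2)[:, None, None]
        for i, e in enumerate(experts):
            _, H = e.forward(Xs)
            dW1, db1, dW2, db2 = e.backward(Xs, H, d_outs[i])
            e.W1 += lr * dW1
            e.b1 += lr * db1
            e.W2 += lr * dW2
            e.b2 += lr * db2
        gate.w += lr * (d_scores * fs[:, None]).sum(axis=0)
        gate.b += lr * d_scores.sum(axis=0)

        # responsibility-weighted RMS residual per expert (dimension-aware)
        sq = np.sum((Ys[None] - outs) ** 2, axis=-1).T  # (T, N)
        wsum = resp.sum(axis=0)
        sigma = np.sqrt(
            (resp * sq).sum(axis=0) / np.maximum(wsum * Ys.shape[1], 1e-12)
        )
        sigma = np.maximum(sigma, cfg.sigma_floor)

        if mean_lnL > best[0] + 1e-9:
            best = (mean_lnL, (copy.deepcopy(experts), copy.deepcopy(gate), sigma.copy()))
            since_best = 0
        else:
            since_best += 1
        last_good = best[1]
        if cfg.kickout and since_best >= cfg.kickout_patience:
            # kick-out surrogate: seeded perturbation, keep best checkpoint
            for e in experts:
                for p in e.params():
                    p += cfg.kickout_scale * np.linalg.norm(p) * rng.standard_normal(
                        p.shape
                    ) / max(np.sqrt(p.size), 1.0)
            for p in gate.params():
                p += cfg.kickout_scale * max(np.linalg.norm(p), 1e-3) * (
                    rng.standard_normal(p.shape) / max(np.sqrt(p.size), 1.0)
                )
            since_best = 0

    experts_f, gate_f, sigma_f = best[1] if best[1] is not None else (
        experts, gate, sigma
    )
    return MixtureModel(
        experts=experts_f,
        gate=gate_f,
        sigma=sigma_f,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        f_scale=f_scale,
        config=cfg,
        loss_trace=trace,
        trained=True,
    )


def fit_velocity_proxy(femg: np.ndarray, ssv: np.ndarray) -> VelocityProxy:
    """Least-squares linear map from filtered EMG to summed-squared velocity.

    The true velocity is unavailable at test time, so this proxy supplies
    the gate input when decoding.  Output is clipped at zero.
    """
    X = np.asarray(femg, dtype=float)
    y = np.asarray(ssv, dtype=float)
    A = np.column_stack([X, np.ones(len(X))])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "EMG design is rank-deficient; velocity proxy may be degenerate",
            RuntimeWarning,
        )
    return VelocityProxy(w=coef[:-1], b=float(coef[-1]))


def apply_velocity_proxy(proxy: VelocityProxy, femg: np.ndarray) -> np.ndarray:
    return proxy(np.asarray(femg, dtype=float))


def predict_angles(
    model: MixtureModel,
    proxy: VelocityProxy,
    femg: np.ndarray,
    rate: float,
    t_start: float = 0.0,
) -> JointAngleTrajectory:
    """Decode joint angles from filtered EMG via the trained mixture.

    The gate feature is estimated from the EMG by the velocity proxy;
    experts consume the EMG directly; outputs are combined per the softmax
    gate.  Output is at the EMG rate.
    """
    if not model.trained:
        raise ModelStateError("mixture model is not trained")
    X = np.asarray(femg, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.x_mean):
        raise InvalidInputError(
            f"femg must be (T, {len(model.x_mean)}), got {X.shape}"
        )
    feature = apply_velocity_proxy(proxy, X)
    theta, _ = model.predict_standardized(X, feature)
    return JointAngleTrajectory(theta=theta.T, rate=rate, t_start=t_start)


# ---------------------------------------------------------------------------
# Monolithic baseline (architecture comparison)


@dataclass
class MonolithicNetwork:
    """Single MLP of matched parameter count, trained on mean-squared error.

    Baseline for quantifying the benefit of the modular architecture; it
    receives the same information as the full mixture system (EMG channels
    plus the scalar gate feature).
    """

    net: ExpertNetwork
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    loss_trace: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X) - self.x_mean) / self.x_std
        out, _ = self.net.forward(Xs)
        return out * self.y_std + self.y_mean


def matched_hidden_size(n_in_mix: int, cfg: TrainConfig, n_in_mono: int) -> int:
    """Hidden size for a monolithic net matching the mixture's parameters."""
    per_expert = n_in_mix * cfg.n_hidden + cfg.n_hidden + cfg.n_hidden * N_ANGLES + N_ANGLES
    total = cfg.n_experts * per_expert + 2 * cfg.n_experts  # + gate w, b
    return max(1, int(round((total - N_ANGLES) / (n_in_mono + 1 + N_ANGLES))))


def train_monolithic(
    X: np.ndarray,
    Y: np.ndarray,
    n_hidden: int,
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    seed: int = 0,
    init_scale: float = 0.1,
) -> MonolithicNetwork:
    """Train the matched single network by full-batch gradient descent on MSE."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x_mean, x_std = X.mean(axis=0), X.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean, y_std = Y.mean(axis=0), Y.std(axis=0)
    y_std[y_std < 1e-12] = 1.0
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_mean) / y_std
    rng = np.random.default_rng(seed)
    net = ExpertNetwork.init(X.shape[1], n_hidden, rng, init_scale)
    T = X.shape[0]
    trace = np.empty(epochs)
    for epoch in range(epochs):
        out, H = net.forward(Xs)
        err = Ys - out
        trace[epoch] = float(np.mean(err**2))
        d_out = err / T  # gradient of -0.5*MSE, ascent == descent on MSE
        dW1, db1, dW2, db2 = net.backward(Xs, H, d_out)
        net.W1 += learning_rate * dW1
        net.b1 += learning_rate * db1
        net.W2 += learning_rate * dW2
        net.b2 += learning_rate * db2
    return MonolithicNetwork(
        net=net, x_mean=x_mean, x_std=x_std, y_mean=y_mean, y_std=y_std,
        loss_trace=trace,
    )
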