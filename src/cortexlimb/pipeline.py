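"""End-to-end decoding pipeline: metrics, training, cross-validation.

Evaluation metrics are the Pearson correlation coefficient (CC) and the
range-normalized root-mean-square error

    nRMSE = sqrt( sum_i (y_pred_i - y_actual_i)^2 / n )
            / (max(y_actual) - min(y_actual)).

The evaluation protocol is set-level leave-one-out: with seven recording
sets, each fold trains every stage (baseline variance, VB source variances,
inverse filter, sparse EMG decoder, velocity proxy, mixture network) on six
sets and decodes the held-out set.  Per-fold metrics are aggregated per
task sequence as mean (SD) across held-out trials, then averaged across
folds.  An audit record of the trial ids consumed by each training stage
guards against data leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cortexlimb import emg_processing, modular_ann, source_inverse, sparse_regression
from cortexlimb.arm_kinematics import (
    JointAngleTrajectory,
    inverse_kinematics,
    resample_trajectory,
    summed_squared_velocity,
)
from cortexlimb.exceptions import (
    ConfigurationError,
    ProtocolError,
    UndefinedMetricError,
)
from cortexlimb.signal_preprocessing import (
    SOURCE_RATE,
    SessionContainer,
    preprocess_eeg,
)
from cortexlimb.synthetic_data import SEQUENCES, SimulationConfig

TASKS = tuple(SEQUENCES)


# ---------------------------------------------------------------------------
# Metrics


def corrcoef(pred, actual) -> float:
    """Pearson correlation coefficient between two equal-length series."""
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape or len(pred) < 2:
        raise UndefinedMetricError("need two equal-length series of >= 2 samples")
    if np.ptp(actual) == 0 or np.ptp(pred) == 0:
        raise UndefinedMetricError("correlation undefined for a constant series")
    return float(np.corrcoef(pred, actual)[0, 1])


def nrmse(pred, actual) -> float:
    """Root-mean-square error normalized by the actual signal's range."""
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if pred.shape != actual.shape:
        raise UndefinedMetricError("series lengths differ")
    rng = np.max(actual) - np.min(actual)
    if rng == 0:
        raise UndefinedMetricError("nRMSE undefined for a constant actual series")
    return float(np.sqrt(np.mean((pred - actual) ** 2)) / rng)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Hyperparameters of a full decoding run (archived with its outputs)."""

    band: tuple = (None, 30.0)  # synthetic drive is low-frequency; see methods
    m0: float = 100.0
    r0: float = 10.0
    delay_ms: float = 17.0
    vb_max_iter: int = 300
    vb_tol: float = 1e-6
    vb_max_samples: int = 4000
    ann: modular_ann.TrainConfig = field(default_factory=lambda: modular_ann.TrainConfig(epochs=1500))
    ann_train_rate: float = 50.0
    eval_rate: float = 1000.0
    seed: int = 0


@dataclass
class DecoderBundle:
    """Everything fitted on the training sets of one fold."""

    baseline: source_inverse.BaselineEstimate
    posterior: source_inverse.PosteriorState
    inverse_filter: source_inverse.InverseFilter
    emg_weights: sparse_regression.SparseWeights
    emg_norm: np.ndarray  # per-channel training maxima of measured fEMG
    mixture: modular_ann.MixtureModel
    proxy: modular_ann.VelocityProxy
    config: RunConfig
    consumed_trial_ids: tuple


# ---------------------------------------------------------------------------
# Per-trial feature extraction


def _measured_femg(trial):
    """Quasi-tension EMG measured from the trial's raw EMG (unnormalized)."""
    return emg_processing.filter_emg(trial.emg)


def _task_window(samples, rate, t_start, lo=0.0, hi=None):
    """Columns of a (C, T) array with times in [lo, hi)."""
    t = t_start + np.arange(samples.shape[1]) / rate
    mask = t >= lo - 1e-9
    if hi is not None:
        mask &= t < hi - 1e-9
    return samples[:, mask]


def _preprocessed_sources(trial, bundle_or_L, config):
    """Preprocess one trial's EEG and apply the inverse filter."""
    pre = preprocess_eeg(trial.eeg, band=config.band)
    L = (
        bundle_or_L.inverse_filter
        if isinstance(bundle_or_L, DecoderBundle)
        else bundle_or_L
    )
    return source_inverse.apply_inverse(L, pre)


def _ik_angles(trial, eval_rate):
    """Joint angles from the 120-Hz markers, resampled for evaluation."""
    ang = inverse_kinematics(trial.markers)
    theta = resample_trajectory(ang.theta, ang.rate, eval_rate)
    return JointAngleTrajectory(theta=theta, rate=eval_rate, t_start=ang.t_start)


def train_decoder(
    session: SessionContainer, train_sets, config: RunConfig | None = None
) -> DecoderBundle:
    """Fit the complete decoding chain on the given training sets."""
    config = config or RunConfig()
    lf = session.lead_field
    if lf is None:
        raise ConfigurationError("session has no lead field")
    trials = session.trials_in_sets(train_sets)
    if not trials:
        raise ProtocolError("no trials in the requested training sets")
    consumed = tuple(tr.trial_id for tr in trials)

    # 1. preprocess EEG; collect pre-movement baseline (-1.0 .. -0.5 s)
    pre_eeg = [preprocess_eeg(tr.eeg, band=config.band) for tr in trials]
    base = np.concatenate(
        [_task_window(p.samples, p.rate, p.t_start, -1.0, -0.5) for p in pre_eeg],
        axis=1,
    )
    baseline = source_inverse.estimate_baseline_variance(base, lf.G[:, : lf.n_cortex])

    # 2. fMRI-informed prior and VB variance estimation on task segments
    prior = source_inverse.prior_variance_from_fmri(
        session.fmri_prior,
        vbase=baseline.vbase,
        m0=config.m0,
        r0=config.r0,
        n_artifact=len(lf.artifact_idx),
    )
    task_eeg = np.concatenate(
        [_task_window(p.samples, p.rate, p.t_start, 0.0) for p in pre_eeg], axis=1
    )
    if task_eeg.shape[1] > config.vb_max_samples:
        step = task_eeg.shape[1] // config.vb_max_samples + 1
        task_eeg = task_eeg[:, ::step]
    posterior = source_inverse.vb_estimate(
        task_eeg,
        lf.G,
        prior,
        noise_var=baseline.noise_variance,
        max_iter=config.vb_max_iter,
        tol=config.vb_tol,
    )
    inv = source_inverse.build_inverse_filter(posterior, lf.G)

    # 3. sparse EMG decoder on (J_roi(t), fEMG(t+dt)) pairs at the source rate
    delay = sparse_regression.DelayConfig(config.delay_ms, SOURCE_RATE)
    X_parts, Y_parts = [], []
    femg_train = [_measured_femg(tr) for tr in trials]
    emg_norm = np.max(
        [f.samples.max(axis=1) for f in femg_train], axis=0
    )
    emg_norm = np.maximum(emg_norm, 1e-12)
    J_tasks = []
    for tr, pre, femg in zip(trials, pre_eeg, femg_train):
        est = source_inverse.apply_inverse(inv, pre)
        roi = source_inverse.select_roi(est, lead_field=lf)
        J_task = _task_window(roi.J, roi.rate, roi.t_start, 0.0)
        J_tasks.append(J_task)
        f256 = resample_trajectory(
            femg.samples / emg_norm[:, None], femg.rate, SOURCE_RATE
        )
        f_task = _task_window(f256, SOURCE_RATE, femg.t_start, 0.0)
        n = min(J_task.shape[1], f_task.shape[1])
        X, Y = sparse_regression.build_lagged_design(
            J_task[:, :n], f_task[:, :n], delay
        )
        X_parts.append(X)
        Y_parts.append(Y)
    weights = sparse_regression.fit_sparse_ard(
        np.concatenate(X_parts), np.concatenate(Y_parts), delay=delay
    )

    # 4. mixture network on fEMG vs marker-derived angles.  Training pairs
    # include both the measured and the cortically decoded fEMG of the
    # training trials: at test time the network only ever sees decoded
    # signals, so matching that input distribution (while keeping the
    # clean measured pairs) makes the angle stage robust to decoding error.
    f_parts, a_parts, s_parts = [], [], []
    for tr, femg, J_task in zip(trials, femg_train, J_tasks):
        ang = _ik_angles(tr, config.ann_train_rate)
        a_task = _task_window(ang.theta, ang.rate, ang.t_start, 0.0)
        ssv = summed_squared_velocity(ang)[None, :]
        s_task = _task_window(ssv, config.ann_train_rate, ang.t_start, 0.0)

        f_lo = resample_trajectory(
            femg.samples / emg_norm[:, None], femg.rate, config.ann_train_rate
        )
        f_task = _task_window(f_lo, config.ann_train_rate, femg.t_start, 0.0)
        n = min(f_task.shape[1], a_task.shape[1])
        f_parts.append(f_task[:, :n])
        a_parts.append(a_task[:, :n])
        s_parts.append(s_task[:, :n])

        pred256 = sparse_regression.predict_emg(
            weights, source_inverse.SourceEstimate(J=J_task, rate=SOURCE_RATE)
        )
        f_dec = resample_trajectory(
            pred256.samples, SOURCE_RATE, config.ann_train_rate
        )
        n = min(f_dec.shape[1], a_task.shape[1])
        f_parts.append(f_dec[:, :n])
        a_parts.append(a_task[:, :n])
        s_parts.append(s_task[:, :n])
    F = np.concatenate(f_parts, axis=1).T  # (T, 9)
    A = np.concatenate(a_parts, axis=1)  # (4, T)
    S = np.concatenate(s_parts, axis=1).ravel()
    ann_cfg = replace(config.ann, seed=config.seed)
    mixture = modular_ann.train_mixture(
        F,
        JointAngleTrajectory(theta=A, rate=config.ann_train_rate),
        ann_cfg,
        gate_feature=S,
    )
    proxy = modular_ann.fit_velocity_proxy(F, S)

    return DecoderBundle(
        baseline=baseline,
        posterior=posterior,
        inverse_filter=inv,
        emg_weights=weights,
        emg_norm=emg_norm,
        mixture=mixture,
        proxy=proxy,
        config=config,
        consumed_trial_ids=consumed,
    )


def decode_trial(bundle: DecoderBundle, trial, lead_field):
    """Decode one trial: EEG -> ROI currents -> fEMG -> joint angles.

    Returns ``(femg_pred, angles_pred)`` on the evaluation rate (1 kHz),
    restricted to the task window [0, trial end).
    """
    config = bundle.config
    est = _preprocessed_sources(trial, bundle, config)
    roi = source_inverse.select_roi(est, lead_field=lead_field)
    J_task = _task_window(roi.J, roi.rate, roi.t_start, 0.0)
    pred256 = sparse_regression.predict_emg(
        bundle.emg_weights,
        source_inverse.SourceEstimate(J=J_task, rate=SOURCE_RATE),
    )
    femg_pred = resample_trajectory(pred256.samples, SOURCE_RATE, config.eval_rate)
    ang_pred = modular_ann.predict_angles(
        bundle.mixture, bundle.proxy, femg_pred.T, rate=config.eval_rate
    )
    return femg_pred, ang_pred


def _trial_metrics(femg_pred, ang_pred, trial, bundle, config):
    """Per-muscle and per-joint CC / nRMSE against the trial's references."""
    femg_ref = _measured_femg(trial)
    ref = _task_window(
        femg_ref.samples / bundle.emg_norm[:, None],
        femg_ref.rate,
        femg_ref.t_start,
        0.0,
    )
    n = min(ref.shape[1], femg_pred.shape[1])
    emg_cc = [corrcoef(femg_pred[m, :n], ref[m, :n]) for m in range(ref.shape[0])]
    emg_nr = [nrmse(femg_pred[m, :n], ref[m, :n]) for m in range(ref.shape[0])]

    ang_ref = _ik_angles(trial, config.eval_rate)
    ref_a = _task_window(ang_ref.theta, ang_ref.rate, ang_ref.t_start, 0.0)
    na = min(ref_a.shape[1], ang_pred.theta.shape[1])
    ang_cc = [corrcoef(ang_pred.theta[k, :na], ref_a[k, :na]) for k in range(4)]
    ang_nr = [nrmse(ang_pred.theta[k, :na], ref_a[k, :na]) for k in range(4)]
    return emg_cc, emg_nr, ang_cc, ang_nr


# ---------------------------------------------------------------------------
# Evaluation protocol


@dataclass
class EvaluationReport:
    """Tables mirroring the per-task CC/nRMSE layout, plus provenance.

    ``emg_table`` and ``angle_table`` are indexed by statistic (CC, nRMSE)
    with one column per task sequence; each cell is "mean (SD)" across
    held-out trials, averaged over folds.  Raw per-trial values live in
    ``details``; ``audit`` records consumed trial ids per fold.
    """

    emg_table: pd.DataFrame
    angle_table: pd.DataFrame
    details: pd.DataFrame
    audit: list
    seed: int | None = None

    @property
    def mean_emg_cc(self) -> float:
        return float(self.details["emg_cc"].mean())

    @property
    def mean_angle_cc(self) -> float:
        return float(self.details["angle_cc"].mean())

    @property
    def mean_emg_nrmse(self) -> float:
        return float(self.details["emg_nrmse"].mean())

    @property
    def mean_angle_nrmse(self) -> float:
        return float(self.details["angle_nrmse"].mean())

    def audit_leakage(self) -> bool:
        """True when no fold's training stages touched its held-out trials."""
        for fold in self.audit:
            if set(fold["consumed"]) & set(fold["held_out"]):
                return False
        return True


def _aggregate_table(details: pd.DataFrame, cc_col: str, nr_col: str) -> pd.DataFrame:
    rows = {}
    for stat, col in (("CC", cc_col), ("nRMSE", nr_col)):
        cells = {}
        for task in TASKS:
            sub = details[details["task"] == task]
            per_fold = sub.groupby("fold")[col].agg(["mean", "std"])
            m = per_fold["mean"].mean()
            s = per_fold["std"].mean()
            cells[task] = f"{m:.3f} ({0.0 if np.isnan(s) else s:.3f})"
        rows[stat] = cells
    return pd.DataFrame(rows).T[list(TASKS)]


def evaluate_fold(session, train_sets, test_set, config) -> tuple:
    """Train on ``train_sets``, decode ``test_set``; returns (rows, audit)."""
    bundle = train_decoder(session, train_sets, config)
    rows = []
    held = []
    for tr in session.trials_in_sets([test_set]):
        held.append(tr.trial_id)
        femg_pred, ang_pred = decode_trial(bundle, tr, session.lead_field)
        emg_cc, emg_nr, ang_cc, ang_nr = _trial_metrics(
            femg_pred, ang_pred, tr, bundle, config
        )
        rows.append(
            {
                "fold": test_set,
                "task": tr.task,
                "trial_id": tr.trial_id,
                "emg_cc": float(np.mean(emg_cc)),
                "emg_nrmse": float(np.mean(emg_nr)),
                "angle_cc": float(np.mean(ang_cc)),
                "angle_nrmse": float(np.mean(ang_nr)),
            }
        )
    audit = {
        "fold": test_set,
        "consumed": bundle.consumed_trial_ids,
        "held_out": tuple(held),
    }
    return rows, audit


def loocv_evaluate(
    session: SessionContainer, config: RunConfig | None = None
) -> EvaluationReport:
    """Set-level leave-one-out evaluation of the full decoding chain."""
    config = config or RunConfig()
    sets = session.set_indices
    if len(sets) < 2:
        raise ProtocolError("leave-one-out needs at least 2 sets")
    all_rows, audits = [], []
    for test_set in sets:
        train_sets = [s for s in sets if s != test_set]
        rows, audit = evaluate_fold(session, train_sets, test_set, config)
        all_rows.extend(rows)
        audits.append(audit)
    details = pd.DataFrame(all_rows)
    return EvaluationReport(
        emg_table=_aggregate_table(details, "emg_cc", "emg_nrmse"),
        angle_table=_aggregate_table(details, "angle_cc", "angle_nrmse"),
        details=details,
        audit=audits,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Region comparison


def region_comparison(
    session: SessionContainer,
    roi_sets: dict | None = None,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """EMG-reconstruction CC per cortical region (M1 / PMd / PP / All).

    The source inverse is trained once on the first available set(s); the
    sparse EMG decoder is then refit per region on the training trials and
    evaluated on the remaining set's trials.  On sessions whose muscles
    are driven from M1 only, M1 must rank first.
    """
    config = config or RunConfig()
    lf = session.lead_field
    roi_sets = roi_sets if roi_sets is not None else lf.regions
    if not roi_sets:
        raise ConfigurationError("no labeled ROI groups available")
    for name, idx in roi_sets.items():
        if len(np.atleast_1d(idx)) == 0:
            raise ConfigurationError(f"ROI {name!r} is empty")

    sets = session.set_indices
    if len(sets) < 2:
        raise ProtocolError("region comparison needs >= 2 sets")
    train_sets, test_set = sets[:-1], sets[-1]
    bundle = train_decoder(session, train_sets, config)
    delay = sparse_regression.DelayConfig(config.delay_ms, SOURCE_RATE)

    def trial_design(tr, roi):
        est = _preprocessed_sources(tr, bundle, config)
        sel = source_inverse.select_roi(est, roi=np.atleast_1d(roi), lead_field=lf)
        J_task = _task_window(sel.J, sel.rate, sel.t_start, 0.0)
        femg = _measured_femg(tr)
        f256 = resample_trajectory(
            femg.samples / bundle.emg_norm[:, None], femg.rate, SOURCE_RATE
        )
        f_task = _task_window(f256, SOURCE_RATE, femg.t_start, 0.0)
        n = min(J_task.shape[1], f_task.shape[1])
        return J_task[:, :n], f_task[:, :n]

    records = []
    for name, roi in roi_sets.items():
        Xp, Yp = [], []
        for tr in session.trials_in_sets(train_sets):
            J, F = trial_design(tr, roi)
            X, Y = sparse_regression.build_lagged_design(J, F, delay)
            Xp.append(X)
            Yp.append(Y)
        w = sparse_regression.fit_sparse_ard(
            np.concatenate(Xp), np.concatenate(Yp), delay=delay
        )
        ccs = []
        for tr in session.trials_in_sets([test_set]):
            J, F = trial_design(tr, roi)
            pred = sparse_regression.predict_emg(
                w, source_inverse.SourceEstimate(J=J, rate=SOURCE_RATE)
            )
            ccs.extend(
                corrcoef(pred.samples[m], F[m]) for m in range(F.shape[0])
            )
        records.append({"region": name, "cc": float(np.mean(ccs)),
                        "n_vertexes": len(np.atleast_1d(roi))})
    return (
        pd.DataFrame(records)
        .sort_values("cc", ascending=False)
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Printed-split accounting


def split_sample_counts(
    config: SimulationConfig | None = None,
    train_trials_per_task: int = 60,
    test_trials_per_task: int = 10,
) -> dict:
    """Training/test sample totals implied by the task arithmetic.

    One decoded trial contributes ``round(trial_s * emg_rate)`` samples;
    totals multiply by the trials per task and the four task sequences.
    """
    config = config or SimulationConfig()
    per_trial = config.trial_samples
    n_tasks = len(SEQUENCES)
    return {
        "samples_per_trial": per_trial,
        "training_samples": train_trials_per_task * per_trial * n_tasks,
        "test_samples": test_trials_per_task * per_trial * n_tasks,
    }
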