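"""Forward simulator: complete reaching-task sessions with stage-wise truth.

The simulator emulates the continuous button-reaching experiment — a
subject facing a panel with a hold button and four targets (A-D), pressing
them in one of four fixed sequences — and the full signal chain on top of
it, so that every decoding stage can be verified by parameter recovery:

* joint-angle trajectories: minimum-jerk point-to-point reaches in joint
  space between button postures, separated by 1-s stationary holds; the
  decoded trial window is 4.503 s (three reaches of 0.501 s each, three
  1-s holds), with movement onset at t = 0 and the initial hold supplying
  the pre-movement baseline,
* muscle activations: rectified joint-velocity and joint-excursion drives
  assigned per the muscle/DOF table (agonist/antagonist signs), plus a
  tonic co-contraction floor,
* surface EMG: a 20-450 Hz broadband carrier amplitude-modulated by the
  activation, plus additive sensor noise,
* cortical currents: each muscle's (delay-advanced) quasi-tension drive is
  mixed sparsely onto 2-4 dedicated primary-motor-cortex vertexes, so the
  instantaneous linear cortex-to-muscle model holds exactly by
  construction; remaining vertexes carry low-variance 8-30 Hz background,
* EEG: lead field times currents plus artifact-dipole activity (cardiac
  pulses, eye blinks, movement-locked shoulder/wrist sources, carotid
  pulses) and white sensor noise,
* lead field: a three-concentric-sphere analytic head model
  (brain/skull/scalp conductivities 1 : 0.0125 : 1) at full scale, or a
  seeded random matrix with controlled condition number at test scale,
* fMRI prior: normalized T-values high on the M1 subset, near zero
  elsewhere.

All randomness flows through one seeded generator; a session manifest
records the configuration hash and seed, and equal (config, seed) pairs
produce bitwise-identical sessions.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import signal as sps

from cortexlimb.arm_kinematics import (
    ArmGeometry,
    JointAngleTrajectory,
    forward_kinematics,
    summed_squared_velocity,
)
from cortexlimb.emg_processing import N_MUSCLES, RawEMG, filter_emg
from cortexlimb.exceptions import ConfigurationError
from cortexlimb.signal_preprocessing import EEGRecording, SessionContainer, Trial
from cortexlimb.source_inverse import FMRIPrior, LeadField

#: the four task sequences (initial hold + three target presses)
SEQUENCES = {
    "CAB": ("hold", "C", "A", "B"),
    "CDB": ("hold", "C", "D", "B"),
    "DBA": ("hold", "D", "B", "A"),
    "DCA": ("hold", "D", "C", "A"),
}

ARTIFACT_NAMES = (
    "heart",
    "right_shoulder",
    "right_wrist",
    "left_eye",
    "right_eye",
    "left_carotid",
    "right_carotid",
    "spare",
)

#: joint postures (theta1..theta4, rad) realizing the five buttons; all lie
#: in the restricted workspace and share theta4 near pi/2 so the buttons
#: sit on a frontal shell at roughly 70% of full arm extension
BUTTON_POSTURES = {
    "hold": np.array([0.00, 0.25, 0.00, 1.567]),
    "A": np.array([-0.45, 0.45, 0.15, 1.50]),
    "B": np.array([0.35, 0.55, -0.15, 1.62]),
    "C": np.array([-0.25, 0.10, 0.20, 1.75]),
    "D": np.array([0.40, 0.15, -0.20, 1.40]),
}

#: (muscle index, DOF index, direction sign) triples per the measurement
#: table; sign +1 means the muscle drives adduction (theta1), extension
#: (theta2), medial rotation (theta3) or elbow extension (theta4)
MUSCLE_DOF_ROLES = (
    # theta1 adduction (+): Pectoralis major, Teres major
    (2, 0, +1), (3, 0, +1),
    # theta1 abduction (-): Deltoid, Deltoideus
    (0, 0, -1), (1, 0, -1),
    # theta2 extension (+): Deltoid, Teres major, Triceps longus, Triceps lat.
    (0, 1, +1), (3, 1, +1), (7, 1, +1), (8, 1, +1),
    # theta2 flexion (-): Deltoid, Pectoralis major, Biceps, Deltoideus
    (0, 1, -1), (2, 1, -1), (5, 1, -1), (1, 1, -1),
    # theta3 medial (+): Deltoid, Pectoralis major, Teres major, Deltoideus
    (0, 2, +1), (2, 2, +1), (3, 2, +1), (1, 2, +1),
    # theta3 lateral (-): Deltoid, Infraspinatus, Deltoideus
    (0, 2, -1), (4, 2, -1), (1, 2, -1),
    # theta4 extension (+): Triceps longus, Triceps laterale
    (7, 3, +1), (8, 3, +1),
    # theta4 flexion (-): Biceps, Brachialis
    (5, 3, -1), (6, 3, -1),
)


@dataclass(frozen=True)
class TaskSpec:
    """Timing and geometry of the button-reaching task.

    The decoded window starts at movement onset (leaving the hold button)
    and spans ``trial_s = 3 * (reach_s + hold_s)`` seconds; each reach may
    start with a small uniform jitter that eats into the preceding hold.
    """

    hold_s: float = 1.0
    reach_s: float = 0.501
    trial_s: float = 4.503
    rest_s: tuple = (3.0, 4.0)
    jitter_s: float = 0.04

    def __post_init__(self):
        if abs(3 * (self.reach_s + self.hold_s) - self.trial_s) > 1e-9:
            raise ConfigurationError(
                "trial_s must equal 3 * (reach_s + hold_s); "
                f"got {self.trial_s} vs {3 * (self.reach_s + self.hold_s)}"
            )
        if self.jitter_s >= self.hold_s:
            raise ConfigurationError("jitter must be shorter than a hold")


@dataclass
class SimulationConfig:
    """All knobs of the forward simulator (defaults = study conditions)."""

    geometry: ArmGeometry = field(default_factory=lambda: ArmGeometry(0.30, 0.26))
    task: TaskSpec = field(default_factory=TaskSpec)
    n_cortex: int = 2240
    n_m1: int = 33
    n_sensors: int = 64
    eeg_rate: float = 1000.0
    emg_rate: float = 1000.0
    marker_rate: float = 120.0
    eeg_snr: float = 10.0
    emg_snr: float = 10.0
    delay_ms: float = 17.0
    n_sets: int = 7
    trials_per_sequence: int = 10
    pre_s: float = 1.2  # pre-onset margin carried with each trial (baseline)
    # muscle-activation model
    tonic_floor: float = 0.05
    velocity_gain: float = 0.35  # s/rad
    excursion_gain: float = 1.0  # 1/rad
    # EMG synthesis
    emg_noise_ref: float = 0.2  # reference activation scale for the noise floor
    carrier_band: tuple = (20.0, 450.0)
    # source synthesis
    j_amp: float = 1.0
    background_amp: float = 0.05
    background_band: tuple = (8.0, 30.0)
    vertices_per_muscle: int = 3
    # artifacts
    heart_amp: float = 1.0
    heart_rate_hz: float = 1.2
    blink_amp: float = 1.5
    blink_rate_hz: float = 0.15
    movement_artifact_amp: float = 0.3
    # lead field
    leadfield_kind: str = "auto"  # "sphere" | "random" | "auto"
    conductivities: tuple = (1.0, 0.0125, 1.0)
    leadfield_condition: float = 100.0

    def __post_init__(self):
        for name in ("eeg_rate", "emg_rate", "marker_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.eeg_snr <= 0 or self.emg_snr <= 0:
            raise ConfigurationError("SNR values must be positive")
        if self.n_sensors < 2 or self.n_cortex < self.n_sensors // 2:
            raise ConfigurationError("need >= 2 sensors and enough sources")
        if self.n_m1 > self.n_cortex:
            raise ConfigurationError("M1 subset cannot exceed the cortex size")
        if self.pre_s < 1.0:
            raise ConfigurationError("pre_s must cover the [-1, 0] s baseline")

    @classmethod
    def test_scale(cls, **overrides) -> "SimulationConfig":
        """Desk-scale configuration: 224 vertexes, 16 sensors, 2 sets x 8 trials."""
        defaults = dict(
            n_cortex=224,
            n_sensors=16,
            n_sets=2,
            trials_per_sequence=2,
            task=TaskSpec(rest_s=(1.5, 1.5)),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def trial_samples(self) -> int:
        """Samples in one decoded trial window at the EMG/EEG rate."""
        return int(round(self.task.trial_s * self.emg_rate))

    def manifest(self, seed: int) -> dict:
        blob = repr(sorted(asdict(self).items())).encode()
        return {
            "config_sha1": hashlib.sha1(blob).hexdigest(),
            "seed": int(seed),
        }


@dataclass
class GroundTruth:
    """Session-level generative parameters shared by all trials."""

    mixing: np.ndarray  # (n_m1, 9) muscle -> M1 vertex currents
    emg_noise_std: float
    eeg_noise_std: float
    delay_samples: int


# ---------------------------------------------------------------------------
# Task trajectories


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _segment_table(sequence: str, task: TaskSpec, rng) -> list:
    """[(t_start, t_end, theta_from, theta_to or None)]; None = hold."""
    names = SEQUENCES[sequence]
    segs = []
    t = 0.0
    current = BUTTON_POSTURES[names[0]]
    for target_name in names[1:]:
        target = BUTTON_POSTURES[target_name]
        jit = float(rng.uniform(0.0, task.jitter_s))
        if jit > 0:
            segs.append((t, t + jit, current, None))
        segs.append((t + jit, t + jit + task.reach_s, current, target))
        hold_end = t + task.reach_s + task.hold_s  # jitter eats the hold
        segs.append((t + jit + task.reach_s, hold_end, target, None))
        current = target
        t = hold_end
    return segs


def _angles_at(times: np.ndarray, segs: list, pre_posture: np.ndarray) -> np.ndarray:
    theta = np.empty((4, len(times)))
    theta[:] = pre_posture[:, None]
    for t0, t1, a, b in segs:
        mask = (times >= t0) & (times < t1)
        if not np.any(mask):
            continue
        if b is None:
            theta[:, mask] = a[:, None]
        else:
            s = _min_jerk((times[mask] - t0) / (t1 - t0))
            theta[:, mask] = a[:, None] + (b - a)[:, None] * s
    # after the final segment the arm rests on the last button
    last_t1, _, last_a, last_b = segs[-1][1], None, segs[-1][2], segs[-1][3]
    tail = times >= last_t1
    theta[:, tail] = (last_b if last_b is not None else last_a)[:, None]
    return theta


def generate_task_trajectory(
    sequence: str,
    config: SimulationConfig,
    rng,
) -> tuple:
    """One trial's joint angles (EEG rate) and markers (marker rate).

    The returned angle trajectory spans ``[-pre_s, trial_s)`` with
    stationary hold posture before movement onset at t = 0; reaches follow
    minimum-jerk profiles in joint space between the button postures.
    """
    if sequence not in SEQUENCES:
        raise ConfigurationError(f"unknown sequence {sequence!r}")
    segs = _segment_table(sequence, config.task, rng)
    rate = config.eeg_rate
    n_pre = int(round(config.pre_s * rate))
    n_task = int(round(config.task.trial_s * rate))
    times = (np.arange(n_pre + n_task) - n_pre) / rate
    theta = _angles_at(times, segs, BUTTON_POSTURES[SEQUENCES[sequence][0]])
    angles = JointAngleTrajectory(theta=theta, rate=rate, t_start=-config.pre_s)

    m_times = np.arange(
        -config.pre_s,
        config.task.trial_s - 1e-9,
        1.0 / config.marker_rate,
    )
    m_theta = _angles_at(m_times, segs, BUTTON_POSTURES[SEQUENCES[sequence][0]])
    m_angles = JointAngleTrajectory(
        theta=m_theta, rate=config.marker_rate, t_start=-config.pre_s
    )
    markers = forward_kinematics(m_angles, config.geometry)
    return angles, markers


# ---------------------------------------------------------------------------
# Muscles and EMG


def muscle_activations(
    angles: JointAngleTrajectory, config: SimulationConfig
) -> np.ndarray:
    """Map joint kinematics to 9 non-negative muscle activations.

    Each muscle sums rectified velocity and excursion drives over the
    DOF/direction roles it serves (agonists see positive, antagonists
    negative, half-wave rectified), on top of a tonic co-contraction
    floor.  Excursions are measured from the hold posture, so a static
    hold at the hold button yields exactly the tonic floor.
    """
    theta = angles.theta
    omega = np.gradient(theta, 1.0 / angles.rate, axis=1)
    ref = BUTTON_POSTURES["hold"]
    act = np.full((N_MUSCLES, theta.shape[1]), config.tonic_floor)
    for muscle, dof, sign in MUSCLE_DOF_ROLES:
        act[muscle] += config.velocity_gain * np.clip(sign * omega[dof], 0, None)
        act[muscle] += config.excursion_gain * np.clip(
            sign * (theta[dof] - ref[dof]), 0, None
        )
    return act


def synthesize_emg(
    activations: np.ndarray,
    rate: float,
    snr: float,
    rng,
    noise_ref: float = 0.2,
    carrier_band: tuple = (20.0, 450.0),
    t_start: float = 0.0,
) -> RawEMG:
    """Amplitude-modulated broadband surface-EMG model.

    Per channel: a band-limited (20-450 Hz) unit-variance noise carrier is
    multiplied by the activation envelope; white sensor noise with standard
    deviation ``noise_ref / sqrt(snr)`` is added (the noise floor is tied
    to a fixed reference activation scale so it does not vanish for quiet
    muscles).
    """
    if snr <= 0:
        raise ConfigurationError("snr must be positive")
    act = np.asarray(activations, dtype=float)
    high = min(carrier_band[1], 0.45 * rate)
    sos = sps.butter(4, [carrier_band[0], high], btype="band", fs=rate, output="sos")
    carrier = sps.sosfilt(sos, rng.standard_normal(act.shape), axis=-1)
    carrier /= np.maximum(carrier.std(axis=-1, keepdims=True), 1e-12)
    noise_std = noise_ref / np.sqrt(snr)
    noise = noise_std * rng.standard_normal(act.shape)
    return RawEMG(samples=carrier * act + noise, rate=rate, t_start=t_start)


def true_filtered_emg(activations: np.ndarray, rate: float) -> np.ndarray:
    """Ground-truth quasi-tension: the clean activation through the
    envelope low-pass and quasi-tension FIR (the same chain the measured
    EMG passes, minus the carrier/noise), divided by the FIR's DC gain so
    the drive stays on the activation scale (order 1) — the cortical
    currents mixed from it must be commensurate with the background."""
    from cortexlimb.emg_processing import quasi_tension_dc_gain

    raw = RawEMG(samples=np.asarray(activations, dtype=float), rate=rate)
    return filter_emg(raw).samples / quasi_tension_dc_gain(rate)


# ---------------------------------------------------------------------------
# Lead fields


def _legendre_terms(x: np.ndarray, nmax: int):
    """Yield (n, P_n(x), dP_n/dx) for n = 1..nmax via stable recurrences."""
    p_prev = np.ones_like(x)
    p = x.copy()
    for n in range(1, nmax + 1):
        # derivative from (1 - x^2) P_n' = n (P_{n-1} - x P_n)
        dp = n * (p_prev - x * p) / np.maximum(1.0 - x * x, 1e-12)
        yield n, p, dp
        p_prev, p = p, ((2 * n + 1) * x * p - n * p_prev) / (n + 1)


def three_sphere_lead_field(
    sensor_pos: np.ndarray,
    source_pos: np.ndarray,
    source_ori: np.ndarray,
    radii: tuple = (0.087, 0.092, 0.100),
    conductivities: tuple = (1.0, 0.0125, 1.0),
    n_terms: int = 60,
) -> np.ndarray:
    """Scalp potentials of dipoles in a 3-shell concentric-sphere head.

    For each spherical-harmonic order the two-point boundary problem
    (potential and radial-current continuity at the brain/skull and
    skull/scalp interfaces, zero radial current at the scalp surface) is
    solved as a small linear system, driven by the standard multipole
    expansion of the dipole's primary potential.  Sources must lie inside
    the innermost shell; sensors are radially projected onto the scalp.

    Returns the (n_sensors, n_sources) gain matrix in potential units per
    unit dipole moment.
    """
    R1, R2, R3 = radii
    s1, s2, s3 = conductivities
    sensor_pos = np.asarray(sensor_pos, dtype=float)
    source_pos = np.asarray(source_pos, dtype=float)
    source_ori = np.asarray(source_ori, dtype=float)
    if np.any(np.linalg.norm(source_pos, axis=1) >= R1):
        raise ConfigurationError("sources must lie strictly inside the brain shell")

    # scalp coefficient per unit source coefficient, for each order n:
    # unknowns [A1, A2, B2, A3, B3] with the source contributing B1 = 1
    c_scalp = np.empty(n_terms + 1)
    for n in range(1, n_terms + 1):
        rows = []
        rhs = []
        f = lambda r: r**n
        g = lambda r: r ** -(n + 1)
        fp = lambda r: n * r ** (n - 1)
        gp = lambda r: -(n + 1) * r ** -(n + 2)
        # continuity of V and sigma dV/dr at R1 (source term moves to rhs)
        rows.append([f(R1), -f(R1), -g(R1), 0, 0]);          rhs.append(-g(R1))
        rows.append([s1 * fp(R1), -s2 * fp(R1), -s2 * gp(R1), 0, 0])
        rhs.append(-s1 * gp(R1))
        # continuity at R2
        rows.append([0, f(R2), g(R2), -f(R2), -g(R2)]);      rhs.append(0.0)
        rows.append([0, s2 * fp(R2), s2 * gp(R2), -s3 * fp(R2), -s3 * gp(R2)])
        rhs.append(0.0)
        # zero radial current at the scalp
        rows.append([0, 0, 0, fp(R3), gp(R3)]);              rhs.append(0.0)
        sol = np.linalg.solve(np.array(rows), np.array(rhs))
        c_scalp[n] = sol[3] * f(R3) + sol[4] * g(R3)

    e_sensor = sensor_pos / np.linalg.norm(sensor_pos, axis=1, keepdims=True)
    b = np.linalg.norm(source_pos, axis=1)
    e_src = source_pos / b[:, None]
    m_r = np.sum(source_ori * e_src, axis=1)
    mt_vec = source_ori - m_r[:, None] * e_src
    mt = np.linalg.norm(mt_vec, axis=1)
    t_hat = np.divide(mt_vec, mt[:, None], out=np.zeros_like(mt_vec),
                      where=mt[:, None] > 1e-12)

    cosg = e_sensor @ e_src.T  # (M, S)
    sing = np.sqrt(np.clip(1.0 - cosg**2, 1e-12, None))
    cosphi = (e_sensor @ t_hat.T) / sing

    V = np.zeros(cosg.shape)
    for n, P, dP in _legendre_terms(cosg, n_terms):
        Pn1 = sing * dP  # sign fixed against the direct dipole potential
        radial = n * m_r * b ** (n - 1)
        tangential = mt * b ** (n - 1)
        V += c_scalp[n] * (radial * P + tangential * cosphi * Pn1)
    return V / (4 * np.pi * s1)


def _fibonacci_hemisphere(n: int, radius: float, z_min: float = 0.05) -> np.ndarray:
    """Quasi-uniform points on the upper spherical cap (EEG montage stand-in)."""
    k = np.arange(n)
    z = z_min + (1.0 - z_min) * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    return radius * np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def synth_lead_field(config: SimulationConfig, rng) -> LeadField:
    """Synthetic lead field with M1/PMd/PP-analog labels and artifact columns.

    ``leadfield_kind="sphere"`` builds the analytic three-shell model with
    sources on an upper-hemisphere cortical shell; ``"random"`` draws a
    seeded random matrix with controlled condition number (fast, for desk
    scale); ``"auto"`` picks by problem size.
    """
    kind = config.leadfield_kind
    if kind == "auto":
        kind = "sphere" if config.n_cortex >= 1000 else "random"
    M, N = config.n_sensors, config.n_cortex
    n_art = len(ARTIFACT_NAMES)

    if kind == "random":
        # G = U diag(s) Vt with log-spaced singular values
        A = rng.standard_normal((M, N))
        U, _, Vt = np.linalg.svd(A, full_matrices=False)
        svals = np.logspace(0, -np.log10(config.leadfield_condition), M)
        G_cortex = (U * svals) @ Vt
    elif kind == "sphere":
        r_cortex = 0.8 * 0.087
        src = _fibonacci_hemisphere(N, r_cortex, z_min=0.0)
        # jitter source positions a little so the grid is not too regular
        src += 0.002 * rng.standard_normal(src.shape)
        src *= (r_cortex / np.linalg.norm(src, axis=1))[:, None]
        ori = rng.standard_normal((N, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        sensors = _fibonacci_hemisphere(M, 0.100, z_min=0.05)
        G_cortex = three_sphere_lead_field(
            sensors, src, ori, conductivities=config.conductivities
        )
    else:
        raise ConfigurationError(f"unknown leadfield kind {kind!r}")

    col_scale = np.mean(np.linalg.norm(G_cortex, axis=0))
    G_art = rng.standard_normal((M, n_art))
    G_art *= 2.0 * col_scale / np.linalg.norm(G_art, axis=0)

    # labeled vertex groups: disjoint contiguous blocks (left-hemisphere
    # patches in the sphere model's index order)
    n_m1 = config.n_m1
    start = N // 5
    roi_m1 = np.arange(start, start + n_m1)
    regions = {
        "M1": roi_m1,
        "PMd": np.arange(start + n_m1, start + 2 * n_m1),
        "PP": np.arange(start + 2 * n_m1, start + 3 * n_m1),
        "All": np.arange(N),
    }
    return LeadField(
        G=np.concatenate([G_cortex, G_art], axis=1),
        n_cortex=N,
        roi_m1=roi_m1,
        artifact_idx=np.arange(N, N + n_art),
        sensor_names=tuple(f"EEG{k:03d}" for k in range(M)),
        regions=regions,
    )


def synth_fmri_prior(lead_field: LeadField, rng) -> FMRIPrior:
    """Normalized T-value map: high (0.7-1.0) on M1, near zero elsewhere."""
    t = np.abs(rng.normal(0.0, 0.03, lead_field.n_cortex))
    t[lead_field.roi_m1] = rng.uniform(0.7, 1.0, len(lead_field.roi_m1))
    t = np.clip(t, 0.0, None)
    t /= t.max()
    return FMRIPrior(t_hat=t)


# ---------------------------------------------------------------------------
# Sources, artifacts and EEG


def _band_noise(shape, band, rate, rng):
    high = min(band[1], 0.45 * rate)
    sos = sps.butter(4, [band[0], high], btype="band", fs=rate, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / np.maximum(x.std(axis=-1, keepdims=True), 1e-12)


def _pulse_train(times, rate_hz, width, rng, amp=1.0):
    """Periodic Gaussian pulses with a random phase (cardiac-like)."""
    phase = rng.uniform(0.0, 1.0 / rate_hz)
    t0 = times[0] - phase
    centers = np.arange(t0, times[-1] + 1.0 / rate_hz, 1.0 / rate_hz)
    out = np.zeros_like(times)
    for c in centers:
        out += np.exp(-0.5 * ((times - c) / width) ** 2)
    return amp * out


def artifact_sources(
    times: np.ndarray, ssv: np.ndarray, config: SimulationConfig, rng
) -> np.ndarray:
    """(8, T) artifact-dipole activities: heart, movement, eyes, carotids."""
    T = len(times)
    out = np.zeros((len(ARTIFACT_NAMES), T))
    heart = _pulse_train(times, config.heart_rate_hz, 0.03, rng, config.heart_amp)
    out[0] = heart
    # shoulder/wrist movement artifacts track the (normalized) joint velocity
    ssv_n = ssv / max(np.max(ssv), 1e-12)
    out[1] = config.movement_artifact_amp * ssv_n
    out[2] = config.movement_artifact_amp * ssv_n * 0.7
    # blinks: sparse smooth transients, shared between the two eyes
    n_blinks = rng.poisson(config.blink_rate_hz * (times[-1] - times[0]))
    blink = np.zeros(T)
    for c in rng.uniform(times[0], times[-1], n_blinks):
        blink += np.exp(-0.5 * ((times - c) / 0.1) ** 2)
    out[3] = config.blink_amp * blink
    out[4] = config.blink_amp * 0.9 * blink
    # carotid pulsation: attenuated delayed heart
    shift = max(int(round(0.05 * (len(times) / (times[-1] - times[0])))), 1)
    out[5, shift:] = 0.3 * heart[:-shift]
    out[6, shift:] = 0.3 * heart[:-shift]
    return out


def synthesize_sources_and_eeg(
    activations: np.ndarray,
    angles: JointAngleTrajectory,
    lead_field: LeadField,
    mixing: np.ndarray,
    config: SimulationConfig,
    rng,
) -> tuple:
    """Ground-truth currents and the resulting EEG for one trial.

    The M1 currents are the muscles' quasi-tension drives advanced by the
    cortico-muscular delay and mixed onto dedicated vertexes, so that
    ``J(t)`` linearly predicts ``fEMG(t + dt)`` exactly in the noise-free
    limit.  Non-driven cortical vertexes carry 8-30 Hz background,
    artifact dipoles their own activity, and white sensor noise is scaled
    to the configured SNR against the clean cortical EEG.

    Returns ``(J_m1, femg_true, J_artifact, EEGRecording)``.
    """
    rate = config.eeg_rate
    T = activations.shape[1]
    times = angles.t_start + np.arange(T) / rate

    femg = true_filtered_emg(activations, rate)
    d = int(round(config.delay_ms * rate / 1000.0))
    advanced = np.concatenate([femg[:, d:], np.repeat(femg[:, -1:], d, axis=1)], 1)
    J_m1 = mixing @ advanced  # (n_m1, T)

    G = lead_field.G
    G_m1 = G[:, lead_field.roi_m1]
    clean = G_m1 @ J_m1

    bg_idx = np.setdiff1d(np.arange(lead_field.n_cortex), lead_field.roi_m1)
    bg = config.background_amp * config.j_amp * _band_noise(
        (len(bg_idx), T), config.background_band, rate, rng
    )
    clean = clean + G[:, bg_idx] @ bg

    ssv = summed_squared_velocity(angles)
    J_art = artifact_sources(times, ssv, config, rng)
    art = G[:, lead_field.artifact_idx] @ J_art

    noise_std = float(np.sqrt(np.mean(clean**2) / config.eeg_snr))
    eeg = clean + art + noise_std * rng.standard_normal(clean.shape)
    rec = EEGRecording(samples=eeg, rate=rate, t_start=angles.t_start,
                       channel_names=lead_field.sensor_names)
    return J_m1, femg, J_art, rec


def make_mixing(config: SimulationConfig, rng) -> np.ndarray:
    """Sparse muscle-to-M1 mixing: each muscle drives its own vertex group."""
    k = config.vertices_per_muscle
    if N_MUSCLES * k > config.n_m1:
        raise ConfigurationError(
            f"{N_MUSCLES} muscles x {k} vertexes exceed the M1 subset"
        )
    P = np.zeros((config.n_m1, N_MUSCLES))
    order = rng.permutation(config.n_m1)
    for m in range(N_MUSCLES):
        rows = order[m * k: (m + 1) * k]
        P[rows, m] = config.j_amp * rng.uniform(0.5, 1.5, k)
    return P


def true_emg_weights(mixing: np.ndarray) -> np.ndarray:
    """The sparse ground-truth decoder implied by the mixing: W P = I."""
    W = np.zeros((mixing.shape[1], mixing.shape[0]))
    for m in range(mixing.shape[1]):
        rows = np.nonzero(mixing[:, m])[0]
        p = mixing[rows, m]
        W[m, rows] = p / (p @ p)
    return W


def generate_regime_switching_data(
    seed: int,
    n_samples: int = 3000,
    block_len: int = 250,
    rate: float = 100.0,
    noise: float = 0.01,
):
    """EMG-like inputs and angles whose map flips between two regimes.

    Alternating posture/movement blocks: inputs are rectified-Gaussian
    9-channel envelopes (amplified during movement); the EMG-to-angle map
    is a fixed random linear map in the posture regime and its negation in
    the movement regime — a caricature of the tension/velocity dependence
    that motivates the two-expert architecture.  The returned gate feature
    mimics the summed-squared velocity (near zero at rest, high during
    movement).

    Returns ``(inputs (T, 9), JointAngleTrajectory, gate_feature, regime)``.
    """
    rng = np.random.default_rng(seed)
    regime = (np.arange(n_samples) // block_len) % 2
    u = np.abs(rng.normal(0.4, 0.15, (n_samples, N_MUSCLES)))
    u *= 1.0 + 1.5 * regime[:, None]
    B = rng.normal(0.0, 0.6, (N_MUSCLES, 4))
    Y = np.where(regime[:, None] == 0, u @ B, -(u @ B))
    Y = Y + noise * rng.standard_normal(Y.shape)
    feature = regime * 4.0 + np.abs(rng.normal(0.0, 0.05, n_samples))
    angles = JointAngleTrajectory(theta=Y.T, rate=rate)
    return u, angles, feature, regime


# ---------------------------------------------------------------------------
# Sessions


def generate_session(config: SimulationConfig, seed: int) -> tuple:
    """Generate a full session: trials across sets with embedded truth.

    Returns ``(SessionContainer, GroundTruth)``.  The default
    configuration yields 7 sets x 40 trials (10 per sequence, shuffled
    within each set); all streams are time-aligned to movement onset and
    every observable is a deterministic function of (config, seed).
    """
    rng = np.random.default_rng(seed)
    lead_field = synth_lead_field(config, rng)
    prior = synth_fmri_prior(lead_field, rng)
    mixing = make_mixing(config, rng)
    delay_samples = int(round(config.delay_ms * config.eeg_rate / 1000.0))

    trials = []
    eeg_noise = []
    for set_index in range(1, config.n_sets + 1):
        labels = np.repeat(list(SEQUENCES), config.trials_per_sequence)
        rng.shuffle(labels)
        for trial_index, task in enumerate(labels):
            angles, markers = generate_task_trajectory(task, config, rng)
            act = muscle_activations(angles, config)
            emg = synthesize_emg(
                act, config.emg_rate, config.emg_snr, rng,
                noise_ref=config.emg_noise_ref,
                carrier_band=config.carrier_band,
                t_start=angles.t_start,
            )
            J_m1, femg, J_art, eeg = synthesize_sources_and_eeg(
                act, angles, lead_field, mixing, config, rng
            )
            eeg_noise.append(np.sqrt(np.mean((eeg.samples - eeg.samples.mean()) ** 2)))
            trials.append(Trial(
                eeg=eeg,
                emg=emg,
                markers=markers,
                angles=angles,
                task=str(task),
                set_index=set_index,
                trial_index=trial_index,
                truth={
                    "activations": act,
                    "femg": femg,
                    "j_m1": J_m1,
                    "j_artifact": J_art,
                },
            ))

    session = SessionContainer(
        trials=trials,
        lead_field=lead_field,
        fmri_prior=prior,
        config={"manifest": config.manifest(seed), "delay_ms": config.delay_ms},
        seed=seed,
    )
    truth = GroundTruth(
        mixing=mixing,
        emg_noise_std=config.emg_noise_ref / np.sqrt(config.emg_snr),
        eeg_noise_std=float(np.mean(eeg_noise)),
        delay_samples=delay_samples,
    )
    return session, truth
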