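"""EEG conditioning and session container I/O.

EEG epochs are baseline-corrected against the pre-movement second,
band-pass (or low-pass) filtered with a 5th-order Butterworth, and
polyphase-resampled to 256 Hz for source estimation.  Filtering is
zero-phase by default (training/evaluation); a causal mode exists for
simulated online use.

The session container is an HDF5 file holding time-aligned per-trial EEG,
raw EMG, marker and joint-angle streams plus (for synthetic sessions) the
ground truth of every stage, the lead field and the fMRI prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import h5py
import numpy as np
import yaml
from scipy import signal as sps

from cortexlimb.arm_kinematics import JointAngleTrajectory, MarkerTrajectory
from cortexlimb.emg_processing import MUSCLES, RawEMG
from cortexlimb.exceptions import FormatError, InvalidInputError
from cortexlimb.source_inverse import FMRIPrior, LeadField

SCHEMA_VERSION = 1

TASK_LABELS = ("CAB", "CDB", "DBA", "DCA")

#: default analysis band (Hz); low edge may be None for a pure low-pass
DEFAULT_BAND = (8.0, 30.0)
SOURCE_RATE = 256.0
BASELINE_WINDOW = (-1.0, 0.0)


@dataclass
class EEGRecording:
    """One EEG epoch: (n_channels, T) in microvolts at ``rate`` Hz.

    ``t_start`` is the time of the first sample relative to movement onset;
    epochs cut for decoding start at -1 s so the [-1, 0] s baseline is
    inside the recording.
    """

    samples: np.ndarray
    rate: float
    t_start: float = -1.0
    channel_names: tuple | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InvalidInputError("samples must be (channels, T)")
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.rate

    def segment(self, t0: float, t1: float) -> np.ndarray:
        """Samples with times in [t0, t1)."""
        t = self.times
        mask = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        return self.samples[:, mask]


def preprocess_eeg(
    eeg: EEGRecording,
    band: tuple = DEFAULT_BAND,
    out_rate: float = SOURCE_RATE,
    mode: str = "zero-phase",
) -> EEGRecording:
    """Baseline-correct, filter and downsample one EEG epoch.

    Per channel: subtract the mean over the [-1, 0] s pre-movement window,
    apply a 5th-order Butterworth band-pass (``band=(low, high)``; ``low``
    may be None for a low-pass), and polyphase-resample to ``out_rate``.
    The output is trimmed to ``floor(input_seconds * out_rate)`` samples.

    ``mode`` is ``"zero-phase"`` (forward-backward, no lag against the
    kinematics) or ``"causal"`` (forward-only, for simulated online use).
    """
    if eeg.rate < 2 * max(v for v in band if v is not None):
        raise InvalidInputError("sampling rate too low for the requested band")
    t = eeg.times
    base = (t >= BASELINE_WINDOW[0] - 1e-9) & (t < BASELINE_WINDOW[1] - 1e-9)
    if not np.any(base):
        raise InvalidInputError(
            "invalid epoch: baseline window [-1, 0] s not inside the recording"
        )
    x = eeg.samples - eeg.samples[:, base].mean(axis=1, keepdims=True)

    low, high = band
    if low is None:
        sos = sps.butter(5, high, btype="low", fs=eeg.rate, output="sos")
    else:
        sos = sps.butter(5, [low, high], btype="band", fs=eeg.rate, output="sos")
    if mode == "zero-phase":
        x = sps.sosfiltfilt(sos, x, axis=-1)
    elif mode == "causal":
        x = sps.sosfilt(sos, x, axis=-1)
    else:
        raise InvalidInputError(f"unknown filter mode {mode!r}")

    frac = Fraction(out_rate / eeg.rate).limit_denominator(10000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_out = int(np.floor(eeg.n_samples * out_rate / eeg.rate))
    y = y[:, :n_out]
    return EEGRecording(
        samples=y, rate=out_rate, t_start=eeg.t_start, channel_names=eeg.channel_names
    )


def read_eeg_edf(path) -> EEGRecording:
    """Import an EEG recording from EDF/BDF (via mne).

    Returns the full recording with ``t_start = 0``; epoching against task
    onsets is the caller's concern.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise FormatError("EDF/BDF import requires the optional 'mne' extra") from exc
    name = str(path)
    if name.endswith(".bdf"):
        raw = mne.io.read_raw_bdf(name, preload=True, verbose="ERROR")
    else:
        raw = mne.io.read_raw_edf(name, preload=True, verbose="ERROR")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        samples=data,
        rate=float(raw.info["sfreq"]),
        t_start=0.0,
        channel_names=tuple(raw.ch_names),
    )


# ---------------------------------------------------------------------------
# Session container


@dataclass
class Trial:
    """All time-aligned streams of one task trial."""

    eeg: EEGRecording
    emg: RawEMG
    markers: MarkerTrajectory
    angles: JointAngleTrajectory | None
    task: str
    set_index: int
    trial_index: int
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in TASK_LABELS:
            raise InvalidInputError(
                f"task must be one of {TASK_LABELS}, got {self.task!r}"
            )

    @property
    def trial_id(self) -> str:
        return f"set{self.set_index}_trial{self.trial_index}"


@dataclass
class SessionContainer:
    """A full recording session: trials + lead field + prior + provenance."""

    trials: list
    lead_field: LeadField | None = None
    fmri_prior: FMRIPrior | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def set_indices(self) -> list:
        return sorted({tr.set_index for tr in self.trials})

    def trials_in_sets(self, sets) -> list:
        sets = set(sets)
        return [tr for tr in self.trials if tr.set_index in sets]


def _write_series(grp, name, data, rate, t_start, **attrs):
    d = grp.create_dataset(name, data=np.asarray(data))
    d.attrs["rate"] = rate
    d.attrs["t_start"] = t_start
    for k, v in attrs.items():
        d.attrs[k] = v


def write_session(session: SessionContainer, path) -> str:
    """Serialize a session to HDF5 (lossless for all numeric payloads)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        f.attrs["config_yaml"] = yaml.safe_dump(session.config)
        trials = f.create_group("trials")
        for k, tr in enumerate(session.trials):
            g = trials.create_group(str(k))
            g.attrs["task"] = tr.task
            g.attrs["set"] = tr.set_index
            g.attrs["trial"] = tr.trial_index
            _write_series(g, "eeg", tr.eeg.samples, tr.eeg.rate, tr.eeg.t_start,
                          units="uV")
            _write_series(g, "emg", tr.emg.samples, tr.emg.rate, tr.emg.t_start,
                          units="au", channels=",".join(MUSCLES))
            mg = g.create_group("markers")
            mg.attrs["rate"] = tr.markers.rate
            mg.attrs["t_start"] = tr.markers.t_start
            for nm in ("shoulder", "elbow", "wrist"):
                mg.create_dataset(nm, data=getattr(tr.markers, nm))
            if tr.angles is not None:
                _write_series(g, "angles", tr.angles.theta, tr.angles.rate,
                              tr.angles.t_start, units="rad")
            if tr.truth:
                tg = g.create_group("truth")
                for key, val in tr.truth.items():
                    tg.create_dataset(key, data=np.asarray(val))
        if session.lead_field is not None:
            lf = session.lead_field
            g = f.create_group("leadfield")
            g.create_dataset("G", data=lf.G)
            g.create_dataset("roi_m1", data=np.asarray(lf.roi_m1, dtype=np.int64))
            g.create_dataset("artifact_idx",
                             data=np.asarray(lf.artifact_idx, dtype=np.int64))
            g.attrs["n_cortex"] = lf.n_cortex
            if lf.sensor_names is not None:
                g.attrs["sensor_names"] = ",".join(lf.sensor_names)
            if lf.regions:
                rg = g.create_group("regions")
                for name, idx in lf.regions.items():
                    rg.create_dataset(name, data=np.asarray(idx, dtype=np.int64))
        if session.fmri_prior is not None:
            f.create_dataset("prior/t_hat", data=session.fmri_prior.t_hat)
    return str(path)


def _require(grp, name, where):
    if name not in grp:
        raise FormatError(f"missing '{name}' block in {where}")
    return grp[name]


def read_session(path) -> SessionContainer:
    """Load a session container written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise FormatError("missing 'schema_version' attribute: not a session file")
        if version > SCHEMA_VERSION:
            raise FormatError(f"unsupported schema_version {version}")
        config = yaml.safe_load(f.attrs.get("config_yaml", "{}")) or {}
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None

        trials = []
        tgrp = _require(f, "trials", "session root")
        for k in sorted(tgrp, key=int):
            g = tgrp[k]
            eeg_d = _require(g, "eeg", f"trial {k}")
            emg_d = _require(g, "emg", f"trial {k}")
            mk = _require(g, "markers", f"trial {k}")
            eeg = EEGRecording(eeg_d[()], float(eeg_d.attrs["rate"]),
                               float(eeg_d.attrs["t_start"]))
            emg = RawEMG(emg_d[()], float(emg_d.attrs["rate"]),
                         t_start=float(emg_d.attrs["t_start"]))
            markers = MarkerTrajectory(
                shoulder=mk["shoulder"][()], elbow=mk["elbow"][()],
                wrist=mk["wrist"][()], rate=float(mk.attrs["rate"]),
                t_start=float(mk.attrs["t_start"]),
            )
            angles = None
            if "angles" in g:
                ad = g["angles"]
                angles = JointAngleTrajectory(ad[()], float(ad.attrs["rate"]),
                                              float(ad.attrs["t_start"]))
            truth = {key: g["truth"][key][()] for key in g["truth"]} if "truth" in g else {}
            trials.append(Trial(
                eeg=eeg, emg=emg, markers=markers, angles=angles,
                task=str(g.attrs["task"]), set_index=int(g.attrs["set"]),
                trial_index=int(g.attrs["trial"]), truth=truth,
            ))

        lead_field = None
        if "leadfield" in f:
            g = f["leadfield"]
            regions = {}
            if "regions" in g:
                regions = {name: g["regions"][name][()] for name in g["regions"]}
            sensor_names = None
            if "sensor_names" in g.attrs:
                sensor_names = tuple(str(g.attrs["sensor_names"]).split(","))
            lead_field = LeadField(
                G=g["G"][()], n_cortex=int(g.attrs["n_cortex"]),
                roi_m1=g["roi_m1"][()], artifact_idx=g["artifact_idx"][()],
                sensor_names=sensor_names, regions=regions,
            )
        prior = FMRIPrior(f["prior/t_hat"][()]) if "prior" in f else None

    return SessionContainer(trials=trials, lead_field=lead_field,
                            fmri_prior=prior, config=config, seed=seed)
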