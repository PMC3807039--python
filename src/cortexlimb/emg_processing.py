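"""Surface-EMG conditioning: rectified envelope and quasi-tension filtering.

Raw differential EMG is converted into a slowly varying "quasi-tension"
signal that approximates muscle tension: the signal is rectified, smoothed
by a 5-ms moving average, low-pass filtered at ~3 Hz (2nd-order
Butterworth), and finally convolved with a causal FIR whose impulse
response samples the second-order tension dynamics

    h(t) = 6.44 * (exp(-10.80 t) - exp(-16.52 t)),   t in seconds.

The linear low-pass view of muscle tension ignores length/velocity
nonlinearities and degrades at very fast contractions, but is a standard,
well-behaved approximation for slow reaching movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from cortexlimb.exceptions import DegenerateChannelError, InvalidInputError

#: canonical muscle order for the 9 recorded channels
MUSCLES = (
    "Deltoid",
    "Deltoideus",
    "Pectoralis major",
    "Teres major",
    "Infraspinatus",
    "Biceps Brachii",
    "Brachialis",
    "Triceps Brachii Caput Longus",
    "Triceps Brachii Caput Laterale",
)

N_MUSCLES = len(MUSCLES)

# quasi-tension impulse-response constants (1/s and dimensionless scale)
QT_DECAY_SLOW = 10.80
QT_DECAY_FAST = 16.52
QT_SCALE = 6.44

#: FIR truncation: keep taps until h falls below this fraction of its peak
QT_TRUNCATION = 1e-3

ENVELOPE_WINDOW_S = 0.005
ENVELOPE_LOWPASS_HZ = 3.0


@dataclass
class RawEMG:
    """Raw 9-channel surface EMG, (9, T) in amplifier units at ``rate`` Hz."""

    samples: np.ndarray
    rate: float = 1000.0
    channels: tuple = MUSCLES
    t_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_MUSCLES:
            raise InvalidInputError(
                f"samples must be ({N_MUSCLES}, T), got {self.samples.shape}"
            )
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")
        if tuple(self.channels) != MUSCLES:
            raise InvalidInputError("channels must follow the canonical muscle order")


@dataclass
class FilteredEMG:
    """Quasi-tension (filtered) EMG, (9, T), dimensionless after normalization."""

    samples: np.ndarray
    rate: float
    t_start: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_MUSCLES:
            raise InvalidInputError(
                f"samples must be ({N_MUSCLES}, T), got {self.samples.shape}"
            )
        if self.rate <= 0:
            raise InvalidInputError("rate must be positive")


def emg_envelope(raw: RawEMG | np.ndarray, rate: float | None = None) -> np.ndarray:
    """Rectified, smoothed EMG envelope.

    Per channel: absolute value, moving average over a 5-ms window (rounded
    to the nearest odd sample count), then a causal 2nd-order Butterworth
    low-pass at 3 Hz.  Both smoothing stages have unit DC gain, so a
    constant input reaches the same constant in steady state.
    """
    if isinstance(raw, RawEMG):
        x, rate = raw.samples, raw.rate
    else:
        x = np.atleast_2d(np.asarray(raw, dtype=float))
        if rate is None:
            raise InvalidInputError("rate is required for array input")
    if x.shape[-1] == 0:
        raise InvalidInputError("empty EMG signal")
    if rate < 200:
        raise InvalidInputError("rate must be >= 200 Hz for 5-ms averaging")

    rect = np.abs(x)
    win = int(round(ENVELOPE_WINDOW_S * rate))
    win = max(1, win + (1 - win % 2))  # nearest odd count, at least 1
    kernel = np.ones(win) / win
    # symmetric moving average with edge padding so short signals stay sane
    padded = np.pad(rect, [(0, 0)] * (rect.ndim - 1) + [(win // 2, win // 2)], mode="edge")
    smoothed = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="valid"), -1, padded
    )
    sos = sps.butter(2, ENVELOPE_LOWPASS_HZ, btype="low", fs=rate, output="sos")
    return sps.sosfilt(sos, smoothed, axis=-1)


def quasi_tension_impulse_response(t: np.ndarray) -> np.ndarray:
    """Evaluate h(t) = 6.44 (exp(-10.80 t) - exp(-16.52 t)); zero at t=0."""
    t = np.asarray(t, dtype=float)
    return QT_SCALE * (np.exp(-QT_DECAY_SLOW * t) - np.exp(-QT_DECAY_FAST * t))


def quasi_tension_peak_time() -> float:
    """Analytic argmax of h(t): ln(a2/a1) / (a2 - a1)."""
    return float(np.log(QT_DECAY_FAST / QT_DECAY_SLOW) / (QT_DECAY_FAST - QT_DECAY_SLOW))


def quasi_tension_kernel(rate: float) -> np.ndarray:
    """Sampled FIR taps ``h_j = h((j-1)/rate)``, truncated where h decays.

    The FIR is cut at the smallest tap count n for which
    ``h((n-1)/rate) < 1e-3 * max h`` past the peak (roughly 0.6 s of taps).
    """
    if rate <= 0:
        raise InvalidInputError("rate must be positive")
    # generous grid: h decays below 0.1% of peak well before 2 s
    t = np.arange(int(np.ceil(2.0 * rate)) + 1) / rate
    h = quasi_tension_impulse_response(t)
    peak = h.max()
    below = np.nonzero((h < QT_TRUNCATION * peak) & (t > quasi_tension_peak_time()))[0]
    n = int(below[0]) if below.size else len(h)
    return h[:n]


def quasi_tension_filter(
    envelope: np.ndarray, rate: float, t_start: float = 0.0
) -> FilteredEMG:
    """Causal FIR convolution of the envelope with the sampled h(t).

    Implements ``fEMG(t) = sum_j h_j * EMG(t - j + 1)``; the unit-impulse
    response of the output equals the sampled tap sequence exactly.
    """
    env = np.atleast_2d(np.asarray(envelope, dtype=float))
    if env.shape[-1] == 0:
        raise InvalidInputError("empty envelope")
    h = quasi_tension_kernel(rate)
    out = sps.lfilter(h, [1.0], env, axis=-1)
    if out.shape[0] == N_MUSCLES:
        return FilteredEMG(samples=out, rate=rate, t_start=t_start)
    # non-canonical channel counts (single-channel tests): return raw array
    return out


def quasi_tension_dc_gain(rate: float) -> float:
    """Measured DC gain of the truncated FIR (sum of taps).

    The continuous-time integral of h is 6.44*(1/10.80 - 1/16.52); sampling
    at ``rate`` scales the discrete sum by the rate.  The gain is reported,
    not rescaled away: downstream normalization makes the scale immaterial.
    """
    return float(quasi_tension_kernel(rate).sum())


def filter_emg(raw: RawEMG) -> FilteredEMG:
    """Full chain: rectify -> 5-ms average -> 3-Hz low-pass -> quasi-tension FIR."""
    env = emg_envelope(raw)
    h = quasi_tension_kernel(raw.rate)
    out = sps.lfilter(h, [1.0], env, axis=-1)
    return FilteredEMG(samples=out, rate=raw.rate, t_start=raw.t_start)


def normalize_emg(
    filtered: FilteredEMG, reference: FilteredEMG | None = None
) -> FilteredEMG:
    """Divide each channel by its reference (training-set) maximum.

    With ``reference=None`` the signal is self-normalized.  Test-set values
    may exceed 1 when the test maximum exceeds the training maximum; no
    clipping is applied here.
    """
    ref = filtered if reference is None else reference
    maxima = ref.samples.max(axis=1)
    if np.any(maxima <= 0):
        bad = [MUSCLES[i] for i in np.nonzero(maxima <= 0)[0]]
        raise DegenerateChannelError(
            f"reference maximum is not positive for channel(s): {bad}"
        )
    return FilteredEMG(
        samples=filtered.samples / maxima[:, None],
        rate=filtered.rate,
        t_start=filtered.t_start,
    )
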