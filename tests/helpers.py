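"""Test-only helpers: independent oracles and fixture writers."""

import numpy as np


# ---------------------------------------------------------------------------
# Independent forward-kinematics oracle: explicit homogeneous-matrix chain


def _hx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0, 0], [0, c, -s, 0], [0, s, c, 0], [0, 0, 0, 1.0]])


def _hy(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s, 0], [0, 1, 0, 0], [-s, 0, c, 0], [0, 0, 0, 1.0]])


def _hz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0, 0], [s, c, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])


def _lz(length):
    T = np.eye(4)
    T[2, 3] = -length
    return T


def fk_matrix_oracle(theta, l1, l2):
    """Elbow and wrist positions by explicit 4x4 rotation/translation products.

    Chain: Ax(t1) Ay(t2) Az(t3) Lz(l1) Ax(pi - t4) Lz(l2); the elbow is the
    translation part after Lz(l1), the wrist after the full chain.
    """
    t1, t2, t3, t4 = theta
    A_elbow = _hx(t1) @ _hy(t2) @ _hz(t3) @ _lz(l1)
    A_wrist = A_elbow @ _hx(np.pi - t4) @ _lz(l2)
    return A_elbow[:3, 3], A_wrist[:3, 3]


# ---------------------------------------------------------------------------
# Minimal EDF writer (independent of the package's EDF *reader*)


def _field(value, width):
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data_uv, rate, channel_names):
    """Write a minimal valid EDF file with int16 records.

    ``data_uv`` is (n_channels, T) in microvolts at integer rate; the
    duration must be a whole number of seconds.  Quantization is 0.1 uV.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    ns, T = data_uv.shape
    rate = int(rate)
    assert T % rate == 0, "duration must be whole seconds"
    n_records = T // rate

    header = b""
    header += _field("0", 8)
    header += _field("X X X X", 80)
    header += _field("Startdate 01-JAN-2020 X X X", 80)
    header += _field("01.01.20", 8)
    header += _field("00.00.00", 8)
    header += _field(256 * (ns + 1), 8)
    header += _field("", 44)
    header += _field(n_records, 8)
    header += _field(1, 8)
    header += _field(ns, 4)
    header += b"".join(_field(nm, 16) for nm in channel_names)
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field("uV", 8) for _ in range(ns))
    header += b"".join(_field(-3276.8, 8) for _ in range(ns))
    header += b"".join(_field(3276.7, 8) for _ in range(ns))
    header += b"".join(_field(-32768, 8) for _ in range(ns))
    header += b"".join(_field(32767, 8) for _ in range(ns))
    header += b"".join(_field("", 80) for _ in range(ns))
    header += b"".join(_field(rate, 8) for _ in range(ns))
    header += b"".join(_field("", 32) for _ in range(ns))
    assert len(header) == 256 * (ns + 1)

    digital = np.clip(np.round(data_uv / 0.1), -32768, 32767).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            block = digital[:, r * rate: (r + 1) * rate]
            f.write(block.tobytes())  # channel-major within the record
    return path
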