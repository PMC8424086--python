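"""Gravity removal: 0.05 Hz high-pass filtering of synchronized recordings.

A resting accelerometer measures ~9.81 m/s² of gravity whose projection on
the sensor axes drifts slowly with posture. Movement energy of infant general
movements lives well above 0.05 Hz, so a high-pass at that cutoff removes the
gravitational/postural component while leaving the movement band untouched.

The filter family is a 4th-order Butterworth applied forward-backward
(zero-phase): maximally flat in the passband, and zero phase distortion so
the relative timing of jerk events across limbs — which the inter-limb
cross-correlation depends on — is preserved. Edges are padded by odd
reflection over three filter time constants (3/cutoff seconds) to suppress
startup transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import ConfigError, NotSynchronizedError
from .recording import SubjectRecording

#: relative tolerance for deciding a time grid is uniform
_GRID_RTOL = 1e-6


@dataclass(frozen=True)
class FilterSpec:
    """High-pass filter parameters.

    cutoff_hz : corner frequency in Hz (0.05 by default, i.e. a 20 s
        time constant); must lie in (0, Nyquist).
    order : Butterworth order (4 by default).
    zero_phase : apply forward-backward (True, default) or single-pass.
    """

    cutoff_hz: float = 0.05
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if not self.cutoff_hz > 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.order < 1:
            raise ConfigError("order must be >= 1")


def _check_uniform(rec: SubjectRecording) -> float:
    if not rec.synchronized or rec.rate is None:
        raise NotSynchronizedError("highpass requires a synchronized recording")
    t = rec.limbs["LW"].timestamps
    dt = np.diff(t)
    if dt.size == 0:
        raise NotSynchronizedError("recording has fewer than 2 samples")
    period = 1.0 / rec.rate
    if np.abs(dt - period).max() > _GRID_RTOL * period:
        raise NotSynchronizedError("time grid is not uniform")
    return float(rec.rate)


def highpass(rec: SubjectRecording, spec: FilterSpec | None = None) -> SubjectRecording:
    """High-pass filter every axis of every limb identically.

    Returns a new recording with the gravitational (DC and slow drift)
    component removed; each output axis has mean ≈ 0.

    Raises
    ------
    NotSynchronizedError
        If the recording is not on a uniform common grid.
    """
    if spec is None:
        spec = FilterSpec()
    fs = _check_uniform(rec)
    if not spec.cutoff_hz < fs / 2:
        raise ConfigError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    duration = rec.duration
    if duration < 3.0 / spec.cutoff_hz:
        warnings.warn(
            f"recording of {duration:.0f} s is shorter than 3/cutoff "
            f"({3.0 / spec.cutoff_hz:.0f} s); high-pass edge effects may be large",
            stacklevel=2,
        )

    sos = signal.butter(spec.order, spec.cutoff_hz, btype="highpass", fs=fs, output="sos")
    n = rec.limbs["LW"].n_samples
    padlen = min(n - 1, int(round(3.0 * fs / spec.cutoff_hz)))

    limbs = {}
    for limb_id, limb in rec.limbs.items():
        if spec.zero_phase:
            filtered = signal.sosfiltfilt(sos, limb.accel, axis=0, padtype="odd", padlen=padlen)
        else:
            filtered = signal.sosfilt(sos, limb.accel, axis=0)
        limbs[limb_id] = replace(limb, accel=np.ascontiguousarray(filtered))
    return replace(rec, limbs=limbs)
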