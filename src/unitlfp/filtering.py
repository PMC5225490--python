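"""Fourier-domain band-pass filtering and LFP decimation.

The band-pass filter has unit response inside the pass-band, zero in the
stop-band, and Gaussian roll-offs at the corner frequencies to avoid ringing.
It is applied multiplicatively in the Fourier domain, per channel, over the
whole recording.  The response at DC is exactly zero: a band-pass filter must
reject a constant offset, and downstream covariance estimation relies on the
filtered signal being mean-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError

__all__ = ["BandpassSpec", "bandpass_response", "bandpass_filter", "decimate_lfp"]


@dataclass(frozen=True)
class BandpassSpec:
    """Pass-band corners and Gaussian roll-off width (all Hz).

    ``roll_width_hz`` is the standard deviation of the Gaussian profile the
    response follows outside [low_hz, high_hz].
    """

    low_hz: float = 15.0
    high_hz: float = 300.0
    roll_width_hz: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.roll_width_hz <= 0:
            raise ParameterError("roll_width_hz must be > 0")


def bandpass_response(n_samples: int, fs_hz: float, spec: BandpassSpec) -> np.ndarray:
    """Filter response over the FFT frequency grid of an n-sample signal.

    Response is 1 on [low, high], follows exp(-(f - f_corner)^2 / (2 w^2))
    outside, is exactly 0 at DC, and is symmetric in frequency so that the
    filtered signal stays real.
    """
    if n_samples < 2:
        raise ParameterError("need at least 2 samples")
    if spec.high_hz >= fs_hz / 2:
        raise ParameterError(
            f"high corner {spec.high_hz} Hz is not below Nyquist ({fs_hz / 2} Hz)"
        )
    f = np.abs(np.fft.fftfreq(n_samples, d=1.0 / fs_hz))
    resp = np.ones_like(f)
    low = f < spec.low_hz
    high = f > spec.high_hz
    w2 = 2.0 * spec.roll_width_hz**2
    resp[low] = np.exp(-((spec.low_hz - f[low]) ** 2) / w2)
    resp[high] = np.exp(-((f[high] - spec.high_hz) ** 2) / w2)
    resp[f == 0.0] = 0.0
    return resp


def bandpass_filter(
    signal_arr: np.ndarray, fs_hz: float, spec: BandpassSpec
) -> np.ndarray:
    """Band-pass a (channels x samples) array in the Fourier domain.

    Length-preserving and linear; the output is real by construction.
    """
    x = np.asarray(signal_arr, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("input contains NaN or Inf")
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    resp = bandpass_response(x.shape[1], fs_hz, spec)
    y = np.fft.ifft(np.fft.fft(x, axis=1) * resp[None, :], axis=1).real
    return y[0] if squeeze else y


def decimate_lfp(
    signal_arr: np.ndarray, fs_hz: float, target_fs_hz: float
) -> tuple[np.ndarray, float]:
    """Anti-alias low-pass then subsample to ``target_fs_hz``.

    The rate ratio must be an integer (e.g. 30 kHz -> 1250 Hz keeps every 24th
    sample).  Uses a zero-phase FIR anti-aliasing filter with cutoff at
    0.4 x target_fs (0.8 x the output Nyquist).
    """
    ratio = fs_hz / target_fs_hz
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ParameterError(
            f"fs ratio {fs_hz}/{target_fs_hz} = {ratio} is not a positive integer"
        )
    x = np.asarray(signal_arr, dtype=float)
    if q == 1:
        return x.copy(), target_fs_hz
    y = signal.decimate(x, q, ftype="fir", zero_phase=True, axis=-1)
    return y, target_fs_hz
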