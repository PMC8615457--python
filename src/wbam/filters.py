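"""Zero-phase Butterworth smoothing for kinematic and force signals."""

from __future__ import annotations

import numpy as np
from scipy import signal as _signal


class FilterError(ValueError):
    """Invalid cutoff or input too short for the filter."""


def butterworth_lowpass(x: np.ndarray, fs: float, fc: float, order: int = 4) -> np.ndarray:
    """Bidirectional (zero-phase) Butterworth low-pass filter.

    A filter of the given order is applied forward and backward
    (``scipy.signal.filtfilt``), giving zero phase lag and squaring the
    magnitude response: the gain at the cutoff frequency is 0.5 rather
    than the single-pass 1/sqrt(2).

    Parameters
    ----------
    x:
        Uniformly sampled signal; filtering runs along the first axis,
        so multi-column arrays (e.g. xyz trajectories) are supported.
    fs:
        Sampling rate, Hz.
    fc:
        Cutoff frequency, Hz.  Must satisfy ``0 < fc < fs / 2``.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise FilterError("sampling rate must be positive")
    if not 0 < fc < fs / 2:
        raise FilterError(f"cutoff {fc} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    sos = _signal.butter(order, fc, btype="low", fs=fs, output="sos")
    # filtfilt's default padding needs ~3x the impulse-response settle length
    padlen = 3 * (2 * order + 1)
    if x.shape[0] <= padlen:
        raise FilterError(
            f"series of length {x.shape[0]} too short for order-{order} "
            f"bidirectional filtering (needs > {padlen} samples)"
        )
    return _signal.sosfiltfilt(sos, x, axis=0)
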