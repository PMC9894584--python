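"""Hemodynamic response functions and event-to-BOLD convolution.

Both the simulator and the GLM design-matrix builder discretize events on the
same fine time grid (default 0.1 s, an integer divisor of the 1.5 s TR) and
convolve with the same unit-peak kernels, so noiseless simulated data are
reproduced exactly by the matching linear model.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import gammaln

DT = 0.1               # fine simulation/design grid, s
KERNEL_LENGTH = 30.0   # HRF support, s

PEAK_DELAY = 6.0       # gamma-density peak-delay parameter (shape 6, scale 1)
UNDERSHOOT_DELAY = 16.0
UNDERSHOOT_RATIO = 1.0 / 6.0


def _gamma_density(t: np.ndarray, shape: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - gammaln(shape))
    return out


@lru_cache(maxsize=8)
def _peak_value(kind: str) -> float:
    t = np.arange(0.0, KERNEL_LENGTH, 0.001)
    return float(np.max(_raw_hrf(t, kind)))


def _raw_hrf(t: np.ndarray, kind: str) -> np.ndarray:
    if kind == "single":
        return _gamma_density(t, PEAK_DELAY)
    if kind == "double":
        return (_gamma_density(t, PEAK_DELAY)
                - UNDERSHOOT_RATIO * _gamma_density(t, UNDERSHOOT_DELAY))
    raise ValueError(f"unknown HRF kind {kind!r}")


def canonical_hrf(t, kind: str = "double") -> np.ndarray:
    """Unit-peak HRF at times ``t`` (s); double gamma peaks near 5 s."""
    t = np.atleast_1d(np.asarray(t, float))
    return _raw_hrf(t, kind) / _peak_value(kind)


def hrf_peak_time(kind: str = "double", dt: float = 0.001) -> float:
    """Argmax of the unit-peak HRF on a dense grid."""
    t = np.arange(0.0, KERNEL_LENGTH, dt)
    return float(t[np.argmax(canonical_hrf(t, kind))])


@lru_cache(maxsize=8)
def hrf_kernel(dt: float = DT, kind: str = "double") -> np.ndarray:
    t = np.arange(0.0, KERNEL_LENGTH, dt)
    return canonical_hrf(t, kind)


def event_signal(onsets, amplitudes, durations, total_time: float,
                 dt: float = DT, kind: str = "double") -> np.ndarray:
    """Fine-grid BOLD signal for a set of events.

    Zero-duration events are impulses contributing ``amp * hrf(t - onset)``;
    positive durations are boxcars whose convolution is scaled by ``dt``
    (integral approximation), so a sustained block plateaus near
    ``amp * integral(hrf)``.
    """
    n = int(round(total_time / dt))
    impulses = np.zeros(n)
    boxcar = np.zeros(n)
    for onset, amp, dur in zip(onsets, amplitudes, durations):
        i = int(round(onset / dt))
        if i >= n:
            raise ValueError(f"event at {onset} s beyond run end {total_time} s")
        if dur <= 0:
            impulses[i] += amp
        else:
            j = min(n, i + int(round(dur / dt)))
            boxcar[i:j] += amp
    kernel = hrf_kernel(dt, kind)
    signal = np.zeros(n)
    if np.any(impulses):
        signal += np.convolve(impulses, kernel)[:n]
    if np.any(boxcar):
        signal += np.convolve(boxcar, kernel)[:n] * dt
    return signal


def sample_at_volumes(signal_fine: np.ndarray, n_volumes: int, tr: float,
                      dt: float = DT) -> np.ndarray:
    """Sample a fine-grid signal at volume acquisition times k * TR."""
    step = tr / dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("TR must be an integer multiple of the fine grid step")
    idx = (np.arange(n_volumes) * int(round(step)))
    if idx[-1] >= signal_fine.size:
        raise ValueError("fine-grid signal shorter than the volume grid")
    return signal_fine[idx]
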