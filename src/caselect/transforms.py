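"""The four neural datatypes, temporal binning, and the inclusion filter.

Datatypes:

``events``
    discrete calcium-event amplitudes per frame (mostly zero);
``conv2s`` / ``conv4s``
    the event train convolved with a causal exponential-decay kernel of time
    constant 2 s or 4 s, mimicking fast/slow indicator kinetics;
``traces``
    the continuous trace with its slow drift removed (zero-phase low-pass
    subtraction) and negative values rectified to zero.

Per-frame activity averages (area under the curve per unit time) are the
activity metric everywhere, which keeps matched and nonmatched comparisons
duration-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

#: kernel truncation in units of tau (< 1% residual mass)
KERNEL_SUPPORT_TAUS = 5.0
#: drift low-pass: 2nd-order Butterworth, zero phase
DRIFT_CUTOFF_HZ = 0.01
DRIFT_ORDER = 2


@dataclass(frozen=True)
class Kernel:
    tau: float  # seconds
    support: float | None = None  # truncation length, seconds

    def values(self, rate_hz: float) -> np.ndarray:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        support = KERNEL_SUPPORT_TAUS * self.tau if self.support is None else self.support
        n = int(round(support * rate_hz))
        return np.exp(-np.arange(n) / (self.tau * rate_hz))


def convolve_events(events: np.ndarray, rate_hz: float, tau: float) -> np.ndarray:
    """Causal convolution with exp(-t/tau); output length equals input length."""
    kernel = Kernel(tau).values(rate_hz)
    events = np.asarray(events, dtype=float)
    return np.convolve(events, kernel)[: events.size]


def preprocess_trace(raw: np.ndarray, rate_hz: float) -> np.ndarray:
    """Low-pass-subtracted rectified trace.

    The drift estimate is a forward-backward (zero-phase) Butterworth
    low-pass of the raw trace; the output is max(raw - drift, 0).  Accepts a
    single trace or a (neurons, frames) matrix (last axis = time).  Generous
    reflect padding (three cutoff periods) keeps edge transients of the
    zero-phase filter below the filter's pass-band leakage.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0 or not np.all(np.isfinite(raw)):
        raise ValueError("trace must be finite and non-empty")
    sos = butter(DRIFT_ORDER, DRIFT_CUTOFF_HZ, btype="low", fs=rate_hz, output="sos")
    padlen = min(raw.shape[-1] - 1, int(3 * rate_hz / DRIFT_CUTOFF_HZ))
    drift = sosfiltfilt(sos, raw, axis=-1, padlen=padlen)
    return np.maximum(raw - drift, 0.0)


def one_second_window(rate_hz: float) -> int:
    return int(round(rate_hz))


def bin_signal(values: np.ndarray, rate_hz: float, bin_width: str) -> np.ndarray:
    """Centered moving-average binning; ``native`` is the identity.

    The 1 s window spans round(rate) frames centered on each frame (for even
    windows the extra frame falls on the earlier side); windows are clipped
    and renormalized at the edges, so a constant signal stays constant.
    """
    values = np.asarray(values, dtype=float)
    if bin_width == "native":
        return values.copy()
    if bin_width != "one_second":
        raise ValueError(f"unknown bin width {bin_width!r}")
    w = one_second_window(rate_hz)
    T = values.size
    cs = np.concatenate(([0.0], np.cumsum(values)))
    t = np.arange(T)
    lo = np.maximum(t - w // 2, 0)
    hi = np.minimum(t + (w - w // 2), T)
    return (cs[hi] - cs[lo]) / (hi - lo)


def filter_neurons(event_trains) -> np.ndarray:
    """Ids of neurons with strictly more than 10 calcium events.

    Accepts either dense per-frame amplitude vectors (events are the nonzero
    frames) or event-index arrays.
    """
    keep = []
    for i, tr in enumerate(event_trains):
        arr = np.asarray(tr)
        n = int(np.count_nonzero(arr)) if arr.dtype.kind == "f" else int(arr.size)
        if n > 10:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def state_activity(
    signal: np.ndarray,
    is_oa: np.ndarray,
    valid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Mean per-frame activity in each state over the valid frames."""
    signal = np.asarray(signal, dtype=float)
    is_oa = np.asarray(is_oa, dtype=bool)
    valid = np.ones_like(is_oa) if valid is None else np.asarray(valid, dtype=bool)
    oa_mask = is_oa & valid
    ca_mask = ~is_oa & valid
    if not oa_mask.any() or not ca_mask.any():
        raise ValueError("state unobserved")
    return float(signal[oa_mask].mean()), float(signal[ca_mask].mean())
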