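"""Force-event detection, zero-lag filtering, and numerical differentiation.

Event detection runs on the RAW summed vertical ground-reaction force before
any filtering, with the conventional 10 N threshold; marker and force
channels are then low-pass filtered with a zero-lag Butterworth filter
(second order per pass, applied forward and backward for a net fourth-order
response) at 15 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

DEFAULT_THRESHOLD_N = 10.0
DEFAULT_CUTOFF_HZ = 15.0
DEFAULT_ORDER = 4          # net order after the dual pass
DEFAULT_DEBOUNCE_S = 0.020
MIN_CONTACT_S = 0.100


class SignalError(ValueError):
    pass


class NoContactError(SignalError):
    pass


@dataclass(frozen=True)
class Events:
    """Landing events for the analyzed contact, at both stream rates.

    ``idx_*`` are kinematic-rate frame indices; ``idx_*_force`` the raw
    force-rate sample indices from which they were derived.  The contact
    interval is half-open: ``idx_takeoff_force`` is the first sample at or
    below threshold after contact.
    """

    idx_ic: int
    idx_peak_knee: int
    idx_takeoff: int
    idx_ic_force: int
    idx_takeoff_force: int

    def __post_init__(self):
        if not (self.idx_ic < self.idx_peak_knee < self.idx_takeoff):
            raise SignalError(
                f"event order must be ic < peak knee < takeoff, got "
                f"{self.idx_ic}, {self.idx_peak_knee}, {self.idx_takeoff}")


def detect_contact_events(raw_vertical_grf, rate: float,
                          threshold: float = DEFAULT_THRESHOLD_N,
                          debounce: float = DEFAULT_DEBOUNCE_S):
    """Maximal above-threshold intervals of the raw vertical GRF.

    Returns a list of half-open ``(start, end)`` force-sample index pairs:
    start is the first sample strictly above ``threshold``, end the first
    subsequent sample at or below it.  Sub-debounce gaps between intervals
    are merged and sub-debounce intervals discarded, which makes detection
    immune to threshold chatter from plate noise of a few newtons.
    """
    f = np.asarray(raw_vertical_grf, dtype=float)
    if f.size < 2:
        raise SignalError("force series must have at least 2 samples")
    above = f > threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(f.size)
    intervals = list(zip(starts, ends))
    win = max(1, int(round(debounce * rate)))
    merged = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < win:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    return [iv for iv in merged if iv[1] - iv[0] >= win]


def select_landing_contact(intervals, rate: float,
                           min_duration: float = MIN_CONTACT_S):
    """First contact interval at least ``min_duration`` long (the landing)."""
    for start, end in intervals:
        if (end - start) / rate >= min_duration:
            return start, end
    raise NoContactError(
        f"no contact of >= {min_duration * 1e3:.0f} ms detected")


def butterworth_lowpass(series, rate: float,
                        cutoff: float = DEFAULT_CUTOFF_HZ,
                        order: int = DEFAULT_ORDER,
                        dual_pass: bool = True, axis: int = -1):
    """Zero-lag low-pass filter.

    ``order`` is the net order: with ``dual_pass`` (default) a Butterworth
    of order ``order // 2`` is applied forward and backward, doubling the
    attenuation and cancelling the phase, so the gain at the cutoff is
    (1/sqrt(2))^2 = 0.5.  Edges are handled by odd reflective padding.
    """
    x = np.asarray(series, dtype=float)
    if rate <= 2 * cutoff:
        raise SignalError(f"rate {rate} Hz must exceed twice the cutoff {cutoff} Hz")
    per_pass = order // 2 if dual_pass else order
    if per_pass < 1 or (dual_pass and order % 2):
        raise SignalError(f"net order {order} incompatible with dual-pass filtering")
    b, a = butter(per_pass, cutoff, btype="low", fs=rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[axis] <= padlen:
        raise SignalError(
            f"series of length {x.shape[axis]} too short for the "
            f"{padlen}-sample filter padding")
    return filtfilt(b, a, x, axis=axis, padtype="odd")


def downsample_force_to_kin(force_series, rate_force: float, rate_kin: float,
                            cutoff: float = DEFAULT_CUTOFF_HZ,
                            order: int = DEFAULT_ORDER, axis: int = 0):
    """Low-pass at the analysis cutoff, then decimate to the kinematic rate.

    The series is filtered first, so plain every-k-th-sample decimation
    (starting at index 0) cannot alias.
    """
    ratio = rate_force / rate_kin
    if abs(ratio - round(ratio)) > 1e-9:
        raise SignalError(f"rate ratio {ratio:.6g} is not an integer")
    k = int(round(ratio))
    filt = butterworth_lowpass(force_series, rate_force, cutoff, order, axis=axis)
    sl = [slice(None)] * filt.ndim
    sl[axis] = slice(0, None, k)
    return filt[tuple(sl)]


def derivative(series, rate: float, order: int = 1, axis: int = -1):
    """Central-difference derivative (one-sided at the edges), same length."""
    x = np.asarray(series, dtype=float)
    if x.shape[axis] < 3:
        raise SignalError("need at least 3 samples to differentiate")
    if order not in (1, 2):
        raise SignalError(f"derivative order must be 1 or 2, got {order}")
    dt = 1.0 / rate
    d = np.gradient(x, dt, axis=axis)
    if order == 2:
        d = np.gradient(d, dt, axis=axis)
    return d
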