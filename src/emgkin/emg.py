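"""Time-domain EMG feature extraction.

Pipeline per trial: band-pass filter (2nd-order Butterworth, 20-500 Hz,
zero-phase by default) -> crop the middle 3 s of the hold -> slide a 250 ms
window stepping by 200 ms (the literal "50 ms overlap") -> compute five
time-domain features per channel per window:

* MAV  = (1/N) sum |x_i|                       (contraction level)
* ZC   = #{i : x_i x_{i+1} < 0 and |x_i - x_{i+1}| > thr}   (coarse frequency)
* SSC  = #{i : (x_i - x_{i-1})(x_i - x_{i+1}) > thr}        (local extrema)
* DAMV = (1/N) sum_{i=1}^{N-1} |x_{i+1} - x_i| (oscillation)
* VAR  = (1/(N-1)) sum x_i^2                   (power; uncentered)

VAR is deliberately uncentered and DAMV divides by N over N-1 terms: these
are the printed definitions this pipeline implements; a centered variance is
available via ``centered_var=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from .data import (
    TD_FEATURE_NAMES,
    EMGRecording,
    FeatureMatrix,
    WindowingConfig,
)

#: Default analysis band (Hz) and Butterworth order.
DEFAULT_BAND_HZ: tuple[float, float] = (20.0, 500.0)
DEFAULT_FILTER_ORDER: int = 2

# fraction of Nyquist the upper band edge is clipped to when it would
# otherwise reach or exceed fs/2 (e.g. 500 Hz at fs = 2000 Hz is fine,
# but 500 Hz at fs = 1000 Hz is not designable)
_NYQUIST_CLIP = 0.99


def design_bandpass(low: float, high: float, fs: float,
                    order: int = DEFAULT_FILTER_ORDER) -> np.ndarray:
    """Second-order-section Butterworth band-pass; clips high to < Nyquist."""
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"invalid band ({low}, {high})")
    if low >= nyq:
        raise ValueError(f"low edge {low} Hz >= Nyquist {nyq} Hz")
    high = min(high, _NYQUIST_CLIP * nyq)
    if high <= low:
        raise ValueError(f"band collapsed after Nyquist clipping: ({low}, {high})")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(
    rec: EMGRecording,
    low: float = DEFAULT_BAND_HZ[0],
    high: float = DEFAULT_BAND_HZ[1],
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = True,
) -> EMGRecording:
    """Band-pass filter every channel.

    Zero-phase (forward-backward) by default so the filter introduces no
    group delay that would desynchronize EMG windows from kinematic windows;
    note this squares the magnitude response.
    """
    sos = design_bandpass(low, high, rec.fs, order)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    else:
        filtered = signal.sosfilt(sos, rec.samples, axis=1)
    return rec.with_samples(filtered)


def crop_middle(rec: EMGRecording, span_s: float = 3.0) -> EMGRecording:
    """Centered crop of ``span_s`` seconds (left-biased by <= 1 sample)."""
    n_span = int(round(span_s * rec.fs))
    if n_span > rec.n_samples:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than span {span_s} s"
        )
    start = (rec.n_samples - n_span) // 2
    return rec.with_samples(rec.samples[:, start:start + n_span])


def segment(rec: EMGRecording, cfg: WindowingConfig = WindowingConfig()) -> np.ndarray:
    """Contiguous sliding windows, shape (n_windows, n_channels, W).

    n_windows = floor((T - W) / S) + 1; any trailing remainder is dropped.
    """
    w = cfg.window_samples(rec.fs)
    s = cfg.step_samples(rec.fs)
    t = rec.n_samples
    if w > t:
        raise ValueError(f"window of {w} samples exceeds signal length {t}")
    n_win = (t - w) // s + 1
    return np.stack([rec.samples[:, i * s:i * s + w] for i in range(n_win)])


@dataclass(frozen=True)
class TDFeatureSet:
    """The five time-domain features of one window of one channel."""

    mav: float
    zc: int
    ssc: int
    damv: float
    var: float
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0

    def as_array(self) -> np.ndarray:
        # order matches TD_FEATURE_NAMES: MAV, ZC, SSC, DAMV, VAR
        return np.array([self.mav, self.zc, self.ssc, self.damv, self.var])


def td_features(
    window: np.ndarray,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
) -> TDFeatureSet:
    """Compute the five time-domain features of a 1-D window (N >= 3)."""
    x = np.asarray(window, dtype=float).ravel()
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"window must have at least 3 samples, got {n}")
    mav = float(np.abs(x).mean())
    diffs = np.diff(x)
    damv = float(np.abs(diffs).sum() / n)
    var = float(np.square(x).sum() / (n - 1))
    zc = int(np.count_nonzero(
        (x[:-1] * x[1:] < 0) & (np.abs(diffs) > zc_threshold)
    ))
    ssc = int(np.count_nonzero(
        (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > ssc_threshold
    ))
    return TDFeatureSet(mav=mav, zc=zc, ssc=ssc, damv=damv, var=var,
                        zc_threshold=zc_threshold, ssc_threshold=ssc_threshold)


def td_feature_block(
    windows: np.ndarray,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    centered_var: bool = False,
) -> np.ndarray:
    """Vectorized features for stacked windows (..., N) -> (..., 5)."""
    x = np.asarray(windows, dtype=float)
    n = x.shape[-1]
    if n < 3:
        raise ValueError("windows must have at least 3 samples")
    mav = np.abs(x).mean(axis=-1)
    diffs = np.diff(x, axis=-1)
    damv = np.abs(diffs).sum(axis=-1) / n
    if centered_var:
        var = x.var(axis=-1, ddof=1)
    else:
        var = np.square(x).sum(axis=-1) / (n - 1)
    zc = np.count_nonzero(
        (x[..., :-1] * x[..., 1:] < 0) & (np.abs(diffs) > zc_threshold),
        axis=-1,
    )
    ssc = np.count_nonzero(
        (x[..., 1:-1] - x[..., :-2]) * (x[..., 1:-1] - x[..., 2:]) > ssc_threshold,
        axis=-1,
    )
    return np.stack([mav, zc, ssc, damv, var], axis=-1)


def emg_column_names(channels: Sequence[int]) -> tuple[str, ...]:
    return tuple(
        f"ch{c + 1}_{feat}" for c in channels for feat in TD_FEATURE_NAMES
    )


def extract_emg_features(
    rec: EMGRecording,
    cfg: WindowingConfig = WindowingConfig(),
    channels: Sequence[int] | None = None,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
    band: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    centered_var: bool = False,
    label: str | None = None,
    subject: str = "",
    trial: str = "",
) -> FeatureMatrix:
    """Full per-trial EMG feature pipeline: filter -> crop -> segment -> features.

    Rows are windows; columns are channel-major blocks of the five features
    (ch1_MAV ... ch1_VAR, ch2_MAV, ...).  ``channels`` selects a subset of
    0-based channel indices (default: all).
    """
    if channels is None:
        channels = list(range(rec.n_channels))
    channels = list(channels)
    if len(channels) == 0:
        raise ValueError("channel subset must be nonempty")
    if any(c < 0 or c >= rec.n_channels for c in channels):
        raise ValueError(f"channel index out of range: {channels}")
    filtered = bandpass(rec, band[0], band[1], order)
    cropped = crop_middle(filtered, cfg.analysis_span_s)
    windows = segment(cropped, cfg)                  # (n_win, C, W)
    feats = td_feature_block(windows[:, channels, :], zc_threshold,
                             ssc_threshold, centered_var)  # (n_win, |sub|, 5)
    n_win = feats.shape[0]
    rows = feats.reshape(n_win, -1)
    lab = "" if label is None else label
    return FeatureMatrix(
        X=rows,
        labels=np.array([lab] * n_win),
        subjects=np.array([subject] * n_win),
        trials=np.array([trial] * n_win),
        columns=emg_column_names(channels),
    )
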