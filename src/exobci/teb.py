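"""Triple-eye-blink (TEB) brain switch.

The mean of FP1/FP2 is bandpassed to 2-15 Hz, enhanced by an undecimated
biorthogonal (bior1.5) wavelet decomposition restricted to ~2-8 Hz detail
scales, rectified, and smoothed.  A 1.6 s window sliding by 0.4 s counts
supra-threshold peaks; exactly three peaks in one window signal a TEB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .filterbank import bandpass
from .recording import EEGRecording
from .wavelets import band_detail_reconstruction

MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian noise


@dataclass(frozen=True)
class BlinkDetectorConfig:
    """Preprocessing and window geometry of the blink switch."""

    band: tuple = (2.0, 15.0)
    filter_order: int = 4
    wavelet_band: tuple = (2.0, 8.0)  # pseudo-frequency range of detail scales
    smooth_s: float = 0.34            # envelope moving-average length
    window_s: float = 1.6
    shift_s: float = 0.4
    min_gap_s: float = 0.3            # minimum inter-peak separation
    refractory_s: float = 2.0
    threshold_sigmas: float = 10.0    # calibration multiplier on robust sigma
    context_s: float = 1.2            # padding used for per-window preprocessing

    def __post_init__(self):
        if self.window_s <= 3 * self.min_gap_s:
            raise ValueError("window must exceed 3x the minimum inter-peak gap")
        if self.threshold_sigmas <= 0:
            raise ValueError("threshold multiplier must be positive")


@dataclass(frozen=True)
class TEBEvent:
    """One detected triple blink."""

    time_s: float                 # detection time (end of the detecting window)
    peak_times: tuple             # three peak times, seconds
    peak_amplitudes: tuple

    def __post_init__(self):
        if len(self.peak_times) != 3:
            raise ValueError("a TEB event has exactly 3 peaks")


def _frontal_mean(recording: EEGRecording) -> np.ndarray:
    names = recording.montage.channel_names
    for ch in ("FP1", "FP2"):
        if ch not in names:
            raise ValueError(f"recording lacks required channel {ch}")
    return 0.5 * (recording.channel("FP1") + recording.channel("FP2"))


def _envelope(x: np.ndarray, fs: float, cfg: BlinkDetectorConfig) -> np.ndarray:
    if not np.any(x):
        return np.zeros_like(x)
    filtered = bandpass(x, cfg.band, fs, cfg.filter_order)
    enhanced = band_detail_reconstruction(filtered, fs, *cfg.wavelet_band)
    env = np.maximum(enhanced, 0.0)  # blink pulses are frontal-positive
    n = max(1, int(round(cfg.smooth_s * fs)))
    kernel = np.ones(n) / n
    return np.convolve(env, kernel, mode="same")


def frontal_preprocess(recording: EEGRecording,
                       cfg: BlinkDetectorConfig | None = None) -> np.ndarray:
    """Blink-enhanced scalar envelope of the frontal channels (full length)."""
    cfg = cfg or BlinkDetectorConfig()
    return _envelope(_frontal_mean(recording), recording.sfreq, cfg)


def count_peaks(window_signal: np.ndarray, threshold: float, fs: float,
                min_gap_s: float = 0.3) -> int:
    """Local maxima above threshold, separated by at least the minimum gap."""
    peaks, _ = sps.find_peaks(np.asarray(window_signal, float),
                              height=threshold,
                              distance=max(1, int(round(min_gap_s * fs))))
    return int(peaks.size)


def calibrate_threshold(baseline: EEGRecording,
                        cfg: BlinkDetectorConfig | None = None) -> float:
    """Robust threshold from a blink-free baseline: median + s * 1.4826 * MAD."""
    cfg = cfg or BlinkDetectorConfig()
    if baseline.duration < 30.0:
        raise ValueError("threshold calibration needs >= 30 s of baseline")
    env = frontal_preprocess(baseline, cfg)
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    return med + cfg.threshold_sigmas * MAD_SCALE * mad


def _window_peaks(frontal: np.ndarray, fs: float, start: int, stop: int,
                  threshold: float, cfg: BlinkDetectorConfig):
    """Peaks inside [start, stop), preprocessing a padded context segment so
    streaming and offline runs are sample-identical."""
    pad = int(round(cfg.context_s * fs))
    c0 = max(0, start - pad)
    c1 = min(frontal.size, stop + pad)
    env = _envelope(frontal[c0:c1], fs, cfg)
    seg = env[start - c0:stop - c0]
    idx, props = sps.find_peaks(seg, height=threshold,
                                distance=max(1, int(round(cfg.min_gap_s * fs))))
    times = (start + idx) / fs
    return times, props.get("peak_heights", np.array([]))


def detect_teb(recording: EEGRecording, threshold: float,
               cfg: BlinkDetectorConfig | None = None) -> list:
    """Slide the detection window over the recording and emit TEB events.

    A window with exactly three supra-threshold peaks raises an event; a
    refractory period then suppresses re-detections of the same burst.
    """
    cfg = cfg or BlinkDetectorConfig()
    if threshold is None or threshold <= 0:
        raise ValueError("detector threshold must be calibrated and positive")
    fs = recording.sfreq
    frontal = _frontal_mean(recording)
    wlen = int(round(cfg.window_s * fs))
    shift = int(round(cfg.shift_s * fs))
    events = []
    suppress_until = -np.inf
    start = 0
    while start + wlen <= frontal.size:
        t_end = (start + wlen) / fs
        if t_end > suppress_until:
            times, amps = _window_peaks(frontal, fs, start, start + wlen,
                                        threshold, cfg)
            if times.size == 3:
                events.append(TEBEvent(time_s=t_end,
                                       peak_times=tuple(times),
                                       peak_amplitudes=tuple(float(a) for a in amps)))
                suppress_until = t_end + cfg.refractory_s
        start += shift
    return events


class StreamingTEBDetector:
    """Incremental wrapper producing the same events as :func:`detect_teb`.

    Samples are appended chunk-by-chunk; completed windows are evaluated with
    the identical padded-context computation, so results match the offline
    path bit-for-bit once the same samples have been seen.
    """

    def __init__(self, threshold: float, fs: float,
                 cfg: BlinkDetectorConfig | None = None):
        self.cfg = cfg or BlinkDetectorConfig()
        if threshold is None or threshold <= 0:
            raise ValueError("detector threshold must be calibrated and positive")
        self.threshold = threshold
        self.fs = fs
        self._frontal = np.empty(0)
        self._next_start = 0
        self._suppress_until = -np.inf
        self.events = []

    def push(self, fp1: np.ndarray, fp2: np.ndarray) -> list:
        """Append frontal samples; return any newly detected events."""
        self._frontal = np.concatenate([self._frontal, 0.5 * (np.asarray(fp1, float)
                                                              + np.asarray(fp2, float))])
        cfg, fs = self.cfg, self.fs
        wlen = int(round(cfg.window_s * fs))
        shift = int(round(cfg.shift_s * fs))
        pad = int(round(cfg.context_s * fs))
        new = []
        # Evaluate a window only once its trailing context has arrived.
        while self._next_start + wlen + pad <= self._frontal.size:
            start = self._next_start
            t_end = (start + wlen) / fs
            if t_end > self._suppress_until:
                times, amps = _window_peaks(self._frontal, fs, start, start + wlen,
                                            self.threshold, cfg)
                if times.size == 3:
                    ev = TEBEvent(time_s=t_end, peak_times=tuple(times),
                                  peak_amplitudes=tuple(float(a) for a in amps))
                    new.append(ev)
                    self._suppress_until = t_end + cfg.refractory_s
            self._next_start += shift
        self.events.extend(new)
        return new

    def finalize(self) -> list:
        """Flush remaining windows at end-of-stream (clamped trailing context,
        matching the offline path)."""
        cfg, fs = self.cfg, self.fs
        wlen = int(round(cfg.window_s * fs))
        shift = int(round(cfg.shift_s * fs))
        new = []
        while self._next_start + wlen <= self._frontal.size:
            start = self._next_start
            t_end = (start + wlen) / fs
            if t_end > self._suppress_until:
                times, amps = _window_peaks(self._frontal, fs, start, start + wlen,
                                            self.threshold, cfg)
                if times.size == 3:
                    ev = TEBEvent(time_s=t_end, peak_times=tuple(times),
                                  peak_amplitudes=tuple(float(a) for a in amps))
                    new.append(ev)
                    self._suppress_until = t_end + cfg.refractory_s
            self._next_start += shift
        self.events.extend(new)
        return new
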