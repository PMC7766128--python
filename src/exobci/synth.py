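"""Seeded synthetic EEG: training sessions, scenario streams, blink injection.

Background activity is per-channel pink (1/f) noise plus a small common-mode
60 Hz line component.  Sensorimotor rhythms are narrow-band oscillators over
motor-strip electrodes whose amplitude is multiplicatively attenuated (ERD)
while the corresponding imagery class is active.  Eye blinks are additive
biphasic pulses dominant at FP1/FP2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import MontageSpec
from .recording import EEGRecording, EVENT_COLUMNS

# Ground-truth interval labels.
GAIT_MI = "GAIT_MI"
SIT_MI = "SIT_MI"
NOTHING = "NOTHING"
TEB = "TEB"
SINGLE_BLINK = "SINGLE_BLINK"
DOUBLE_BLINK = "DOUBLE_BLINK"

MI_LABELS = (GAIT_MI, SIT_MI, NOTHING)
BLINK_LABELS = (TEB, SINGLE_BLINK, DOUBLE_BLINK)
ALL_LABELS = MI_LABELS + BLINK_LABELS


@dataclass(frozen=True)
class IntentTimeline:
    """Ground-truth labelled intervals (start_s, end_s, label)."""

    intervals: tuple = ()

    def __post_init__(self):
        ivs = tuple((float(a), float(b), str(lab)) for a, b, lab in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        for a, b, lab in ivs:
            if not a < b:
                raise ValueError(f"interval start must precede end: ({a}, {b}, {lab})")
            if lab not in ALL_LABELS:
                raise ValueError(f"unknown label {lab!r}")
        # No overlap within a label family (MI intents vs blink events).
        for family in (MI_LABELS, BLINK_LABELS):
            spans = sorted((a, b) for a, b, lab in ivs if lab in family)
            for (a0, b0), (a1, _) in zip(spans, spans[1:]):
                if a1 < b0:
                    raise ValueError(f"overlapping intervals in family {family}")

    def for_label(self, label: str) -> list:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    @property
    def end(self) -> float:
        return max((b for _, b, _ in self.intervals), default=0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b - a, lab) for a, b, lab in self.intervals], columns=list(EVENT_COLUMNS)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntentTimeline":
        return cls(tuple(
            (r.onset_s, r.onset_s + r.duration_s, r.label) for r in df.itertuples()
        ))


@dataclass(frozen=True)
class Oscillator:
    """One band-limited rhythm source attenuated during a class's MI."""

    channel_weights: dict          # channel label -> weight >= 0
    band: tuple = (10.0, 15.0)      # Hz
    amplitude: float = 20.0         # resting RMS in uV at a weight-1 channel
    erd_depth: float = 0.75         # fractional attenuation in [0, 1]
    onset_lag: float = 0.0          # s after cue before ERD begins

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        lo, hi = self.band
        if not (7.0 <= lo < hi <= 34.0):
            raise ValueError("oscillator band must lie inside 7-34 Hz")
        if any(w < 0 for w in self.channel_weights.values()):
            raise ValueError("channel weights must be non-negative")


@dataclass(frozen=True)
class ErdParams:
    """Per-class oscillator sets plus background-noise settings.

    Each oscillator runs continuously at its resting amplitude and is
    attenuated (with a linear onset ramp) during intervals of the class it
    is keyed under.
    """

    oscillators: dict = field(default_factory=dict)  # class -> tuple[Oscillator]
    ramp_s: float = 0.5
    background_rms: float = 10.0    # uV per channel
    line_freq: float = 60.0
    line_amp: float = 2.0           # uV common-mode

    @classmethod
    def default(cls) -> "ErdParams":
        gait = (
            Oscillator({"Cz": 1.0, "C1": 0.85, "C2": 0.85, "FC1": 0.5, "FC2": 0.5},
                       band=(10.0, 15.0), amplitude=20.0, erd_depth=0.8),
        )
        sit = (
            Oscillator({"C3": 1.0, "C4": 1.0, "CP3": 0.8, "CP4": 0.8,
                        "CP1": 0.6, "CP2": 0.6, "CP5": 0.4, "CP6": 0.4},
                       band=(10.0, 15.0), amplitude=20.0, erd_depth=0.8),
            Oscillator({"C3": 0.7, "C4": 0.7, "CP3": 0.6, "CP4": 0.6},
                       band=(21.0, 25.0), amplitude=12.0, erd_depth=0.7),
        )
        return cls(oscillators={GAIT_MI: gait, SIT_MI: sit})


@dataclass(frozen=True)
class BlinkParams:
    """Stereotyped eye-blink pulse shape and spatial spread."""

    duration: float = 0.3           # s, support of one pulse
    peak_amplitude: float = 80.0    # uV at FP1/FP2
    falloff: float = 0.4            # scaling of spread beyond FP1/FP2; 0 => frontal only
    triple_gap: float = 0.45        # s between successive blinks of a triple

    def __post_init__(self):
        if self.triple_span > 1.6:
            raise ValueError("triple-blink span exceeds the 1.6 s detection window")
        if self.peak_amplitude <= 0 or self.duration <= 0:
            raise ValueError("duration and peak_amplitude must be positive")

    @property
    def triple_span(self) -> float:
        return 2 * self.triple_gap + self.duration


# ---------------------------------------------------------------------------
# primitive generators


def pink_noise(n_samples: int, n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms


def _narrowband(n_samples: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (randomized phase by construction)."""
    x = rng.standard_normal(n_samples)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / np.sqrt(np.mean(y**2))


def _erd_envelope(n_samples: int, fs: float, intervals, depth: float,
                  lag: float, ramp: float) -> np.ndarray:
    """Multiplicative amplitude envelope: 1 at rest, 1-depth during MI."""
    env = np.ones(n_samples)
    t = np.arange(n_samples) / fs
    for start, end in intervals:
        on = start + lag
        lo = 1.0 - depth
        env = np.where((t >= on + ramp) & (t < end), np.minimum(env, lo), env)
        in_ramp = (t >= on) & (t < on + ramp)
        ramp_val = 1.0 - depth * (t - on) / ramp
        env = np.where(in_ramp, np.minimum(env, ramp_val), env)
        after = (t >= end) & (t < end + ramp)
        rec_val = lo + depth * (t - end) / ramp
        env = np.where(after, np.minimum(env, rec_val), env)
    return env


def blink_template(fs: float, params: BlinkParams) -> np.ndarray:
    """Biphasic difference-of-Gaussians pulse, peak-normalized to 1."""
    n = max(3, int(round(params.duration * fs)))
    t = np.linspace(0.0, params.duration, n)
    c = params.duration / 2.0
    sig = params.duration / 7.0
    shape = (np.exp(-0.5 * ((t - c) / sig) ** 2)
             - 0.35 * np.exp(-0.5 * ((t - c) / (1.8 * sig)) ** 2))
    return shape / shape.max()


def _blink_gains(montage: MontageSpec, params: BlinkParams) -> np.ndarray:
    """Per-channel amplitude gain: 1 at FP1/FP2, exponential falloff elsewhere."""
    pos = montage.position_array()
    front = 0.5 * (pos[montage.index("FP1")] + pos[montage.index("FP2")])
    dist = np.linalg.norm(pos - front, axis=1)
    gains = params.falloff * np.exp(-2.5 * dist)
    gains[montage.index("FP1")] = 1.0
    gains[montage.index("FP2")] = 1.0
    return gains


# ---------------------------------------------------------------------------
# public operations


def _background(montage: MontageSpec, erd: ErdParams, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    fs = montage.sampling_rate
    data = erd.background_rms * pink_noise(n_samples, montage.n_channels, rng)
    if erd.line_amp > 0:
        t = np.arange(n_samples) / fs
        data += erd.line_amp * np.sin(2 * np.pi * erd.line_freq * t)[None, :]
    return data


def _add_oscillators(data: np.ndarray, montage: MontageSpec, erd: ErdParams,
                     timeline: IntentTimeline, rng: np.random.Generator) -> None:
    """Add each rhythm source, attenuated during its class's intervals."""
    fs = montage.sampling_rate
    n = data.shape[1]
    for cls, oscs in erd.oscillators.items():
        intervals = timeline.for_label(cls)
        for osc in oscs:
            carrier = _narrowband(n, fs, osc.band, rng) * osc.amplitude
            env = _erd_envelope(n, fs, intervals, osc.erd_depth, osc.onset_lag, erd.ramp_s)
            wave = carrier * env
            for ch, w in osc.channel_weights.items():
                data[montage.index(ch)] += w * wave


def generate_training_session(
    montage: MontageSpec | None = None,
    erd: ErdParams | None = None,
    n_per_class: int = 30,
    seed: int = 0,
    mi_duration: float = 8.0,
    nothing_duration: float = 4.0,
    inter_trial_gap: float = 2.0,
):
    """Simulate one cued training session.

    Trials of the three tasks are randomly interleaved; each trial is a
    3-5 s fixation followed by the cue and the task interval (8 s for the
    two imagery tasks, 4 s for do-nothing).

    Returns
    -------
    (EEGRecording, pd.DataFrame)
        The recording and a trial table with columns
        (onset_s, duration_s, label) where onset_s is the cue time.
    """
    montage = montage or MontageSpec()
    erd = erd or ErdParams.default()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)

    labels = np.array([GAIT_MI] * n_per_class + [SIT_MI] * n_per_class
                      + [NOTHING] * n_per_class)
    order = rng.permutation(labels.size)
    labels = labels[order]

    rows = []
    t = 0.0
    for lab in labels:
        t += rng.uniform(3.0, 5.0)                       # pre-cue fixation
        dur = nothing_duration if lab == NOTHING else mi_duration
        rows.append((t, dur, lab))
        t += dur + inter_trial_gap
    trials = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))

    fs = montage.sampling_rate
    n_samples = int(np.ceil(t * fs))
    timeline = IntentTimeline(tuple(
        (r.onset_s, r.onset_s + r.duration_s, r.label) for r in trials.itertuples()
    ))
    data = _background(montage, erd, n_samples, rng)
    _add_oscillators(data, montage, erd, timeline, rng)
    rec = EEGRecording(data, montage, trials.copy())
    return rec, trials


def inject_blinks(recording: EEGRecording, event_times, params: BlinkParams) -> EEGRecording:
    """Return a copy of ``recording`` with additive blink pulses at ``event_times``.

    Pulses are maximal at FP1/FP2 and attenuated elsewhere according to the
    spatial falloff; overlapping pulses sum.
    """
    fs = recording.sfreq
    template = blink_template(fs, params) * params.peak_amplitude
    gains = _blink_gains(recording.montage, params)
    out = recording.copy()
    for t0 in event_times:
        i0 = int(round(t0 * fs))
        i1 = i0 + template.size
        if i0 < 0 or i1 > recording.n_samples:
            raise ValueError(f"blink at t={t0} s falls outside the recording")
        out.data[:, i0:i1] += gains[:, None] * template[None, :]
    return out


def _blink_times_for_interval(label: str, start: float, end: float,
                              params: BlinkParams) -> list:
    if label == TEB:
        if end - start < params.triple_span:
            raise ValueError(
                f"TEB interval [{start}, {end}) shorter than the triple-blink "
                f"span {params.triple_span:.2f} s")
        return [start + i * params.triple_gap for i in range(3)]
    if label == DOUBLE_BLINK:
        return [start, start + params.triple_gap]
    if label == SINGLE_BLINK:
        return [start]
    return []


def generate_scenario_stream(
    montage: MontageSpec | None = None,
    erd: ErdParams | None = None,
    blinks: BlinkParams | None = None,
    script: IntentTimeline = IntentTimeline(),
    seed: int = 0,
    duration: float | None = None,
    pad_s: float = 2.0,
):
    """Simulate a continuous stream following a scripted intent timeline.

    MI intervals carry per-class ERD; TEB intervals carry three blink
    pulses; single/double blink intervals carry distractor pulses.

    Returns (EEGRecording, IntentTimeline) where the timeline is the
    realized ground truth (equal to the script).
    """
    montage = montage or MontageSpec()
    erd = erd or ErdParams.default()
    blinks = blinks or BlinkParams()
    rng = np.random.default_rng(seed)

    total = duration if duration is not None else script.end + pad_s
    if script.end > total:
        raise ValueError("script extends past the requested duration")
    fs = montage.sampling_rate
    n_samples = int(np.ceil(total * fs))

    data = _background(montage, erd, n_samples, rng)
    _add_oscillators(data, montage, erd, script, rng)
    rec = EEGRecording(data, montage, script.to_frame())

    blink_times = []
    for a, b, lab in script.intervals:
        blink_times.extend(_blink_times_for_interval(lab, a, b, blinks))
    if blink_times:
        rec = inject_blinks(rec, blink_times, blinks)
    return rec, script


def default_scenario_script(start: float = 5.0) -> IntentTimeline:
    """Scripted stand-up / gait / pause / resume / stop / sit-down intents.

    Four MI engagement intervals and four deliberate triple-blinks, mirroring
    the sit-to-sit walk scenario.
    """
    ivs = []
    t = start
    def teb(t):
        ivs.append((t, t + 1.6, TEB)); return t + 4.0
    def mi(t, lab, dur=12.0):
        ivs.append((t, t + dur, lab)); return t + dur + 4.0
    t = teb(t)          # switch decoder on (sit state)
    t = mi(t, GAIT_MI)  # fill sit-to-stand
    t = teb(t)          # decoder on (standing)
    t = mi(t, GAIT_MI)  # start gait
    t = teb(t)          # stop gait
    t = teb(t)          # decoder on again
    t = mi(t, GAIT_MI)  # resume gait
    t = teb(t)          # stop gait
    t = teb(t)          # decoder on
    t = mi(t, SIT_MI)   # sit down
    return IntentTimeline(tuple(ivs))


def make_blink_script(
    n_teb: int,
    n_single: int,
    n_double: int,
    rng: np.random.Generator,
    spacing: float = 4.0,
    jitter: float = 1.0,
    start: float = 65.0,
) -> IntentTimeline:
    """Randomly ordered blink events with a minimum spacing between groups.

    The default start leaves a blink-free baseline for threshold calibration.
    """
    labels = [TEB] * n_teb + [SINGLE_BLINK] * n_single + [DOUBLE_BLINK] * n_double
    rng.shuffle(labels)
    ivs = []
    t = start
    for lab in labels:
        t += rng.uniform(0.0, jitter)
        span = 1.6 if lab == TEB else 1.0
        ivs.append((t, t + span, lab))
        t += span + spacing
    return IntentTimeline(tuple(ivs))
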