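"""Binary MI decoders and the real-time sliding-window command stream.

Two linear classifiers are trained on MIBIF-selected FBCSP features:
Gait-vs-Nothing ("gvn") and Gait-vs-Sit ("gvs").  Online, a 2 s window is
re-classified every 0.5 s (1000 samples / 250-sample shift at 500 Hz).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from . import synth
from .filterbank import (FilterBank, FBCSPModel, CSPModel, band_covariances,
                         features_from_covariances, fit_fbcsp_from_covariances)
from .mibif import MIRanking, SelectionK, rank_features, select_features
from .recording import EEGRecording

log = logging.getLogger(__name__)

PAIRS = {
    "gvn": (synth.GAIT_MI, synth.NOTHING),
    "gvs": (synth.GAIT_MI, synth.SIT_MI),
}

#: Command vocabulary emitted by the decoders.
GAIT, SIT, NOTHING_CMD = "GAIT", "SIT", "NOTHING"

_LABEL_TO_COMMAND = {synth.GAIT_MI: GAIT, synth.SIT_MI: SIT, synth.NOTHING: NOTHING_CMD}

WINDOW_SAMPLES = 1000
SHIFT_SAMPLES = 250

# Analysis spans (seconds post-cue) for cutting training windows.
MI_SPAN = (1.0, 9.0)
NOTHING_SPAN = (1.0, 5.0)


@dataclass(frozen=True)
class CommandLabel:
    """One decoder output: command, emission time (window end), and source."""

    label: str
    time_s: float
    source: str  # "gvn" or "gvs"

    def __post_init__(self):
        pair = PAIRS[self.source]
        if _LABEL_TO_COMMAND[pair[0]] != self.label and \
           _LABEL_TO_COMMAND[pair[1]] != self.label:
            raise ValueError(f"label {self.label!r} not producible by {self.source!r}")


@dataclass(frozen=True)
class StreamPacket:
    """One acquisition packet: (n_channels x 10) samples with a sequence number."""

    data: np.ndarray
    seq: int


@dataclass
class DecoderModel:
    """Trained FBCSP + MIBIF + linear classifier for one class pair."""

    fbcsp: FBCSPModel
    ranking: MIRanking
    selection: SelectionK
    weights: np.ndarray
    bias: float
    pair_name: str
    window_samples: int = WINDOW_SAMPLES
    shift_samples: int = SHIFT_SAMPLES
    training_accuracy: float | None = None

    @property
    def pair(self) -> tuple:
        return PAIRS[self.pair_name]

    def decision_value(self, features: np.ndarray) -> float:
        return float(self.weights @ features[list(self.selection.indices)] + self.bias)

    def decide(self, features: np.ndarray) -> str:
        """Positive decision -> Gait command; ties go to the non-Gait class."""
        gait, other = self.pair
        label = gait if self.decision_value(features) > 0 else other
        return _LABEL_TO_COMMAND[label]


def epoch_training_windows(recording: EEGRecording, trials, pair: tuple,
                           window_s: float = 2.0, shift_s: float = 0.5):
    """Cut labelled sliding windows from each trial of the two classes.

    Imagery trials are windowed over 1-9 s post-cue, do-nothing over
    1-5 s; each window inherits its trial's label.  Returns
    (windows, labels, trial_ids).
    """
    fs = recording.sfreq
    wlen = int(round(window_s * fs))
    windows, labels, trial_ids = [], [], []
    for tid, row in enumerate(trials.itertuples()):
        if row.label not in pair:
            continue
        span = NOTHING_SPAN if row.label == synth.NOTHING else MI_SPAN
        start, end = row.onset_s + span[0], row.onset_s + span[1]
        end = min(end, recording.duration)
        if end - start < window_s:
            log.warning("trial %d interval shorter than the %.1f s window; skipped",
                        tid, window_s)
            continue
        t = start
        while t + window_s <= end + 1e-9:
            i0 = int(round(t * fs))
            windows.append(recording.data[:, i0:i0 + wlen])
            labels.append(row.label)
            trial_ids.append(tid)
            t += shift_s
    return windows, np.asarray(labels), np.asarray(trial_ids)


def _fit_linear(features: np.ndarray, labels, pair: tuple,
                C: float = 1.0, seed: int = 0):
    """Linear max-margin classifier; positive decision side = Gait class."""
    gait, _ = pair
    y = (np.asarray(labels) == gait).astype(int)
    clf = LinearSVC(C=C, class_weight="balanced", random_state=seed)
    clf.fit(features, y)
    # sklearn classes_ = [0, 1]; decision_function > 0 predicts class 1 (gait).
    return clf.coef_[0].copy(), float(clf.intercept_[0])


def train_decoder_from_covariances(covs: np.ndarray, labels, pair_name: str,
                                   bank: FilterBank, fs: float, k: int = 6,
                                   pair_completion: bool = True,
                                   shrinkage: float = 1e-4,
                                   C: float = 1.0, seed: int = 0) -> DecoderModel:
    pair = PAIRS[pair_name]
    labels = np.asarray(labels)
    counts = [np.sum(labels == c) for c in pair]
    if min(counts) < 10:
        raise ValueError(f"need >= 10 windows per class, got {counts}")
    fbcsp = fit_fbcsp_from_covariances(covs, labels, pair, bank, fs, shrinkage)
    feats = features_from_covariances(covs, fbcsp)
    ranking = rank_features(feats, labels, pair)
    selection = select_features(ranking, k, pair_completion)
    w, b = _fit_linear(feats[:, list(selection.indices)], labels, pair, C, seed)
    model = DecoderModel(fbcsp=fbcsp, ranking=ranking, selection=selection,
                         weights=w, bias=b, pair_name=pair_name)
    preds = [model.decide(f) for f in feats]
    truth = [_LABEL_TO_COMMAND[l] for l in labels]
    model.training_accuracy = float(np.mean(np.array(preds) == np.array(truth)))
    return model


def train_decoder(windows, labels, pair_name: str, k: int = 6,
                  pair_completion: bool = True, bank: FilterBank | None = None,
                  fs: float = 500.0, shrinkage: float = 1e-4,
                  C: float = 1.0, seed: int = 0) -> DecoderModel:
    """Full training pipeline: filter bank -> CSP -> features -> MIBIF -> SVM."""
    bank = bank or FilterBank()
    pair = PAIRS[pair_name]
    mask = np.isin(np.asarray(labels), pair)
    windows = [w for w, m in zip(windows, mask) if m]
    labels = np.asarray(labels)[mask]
    covs = band_covariances(windows, bank, fs)
    return train_decoder_from_covariances(covs, labels, pair_name, bank, fs, k,
                                          pair_completion, shrinkage, C, seed)


def classify_window(window: np.ndarray, model: DecoderModel) -> str:
    """Classify one exact-length window into a command label."""
    w = np.asarray(window, float)
    n = model.fbcsp.csp_models[0].n_channels
    if w.shape != (n, model.window_samples):
        raise ValueError(
            f"window shape {w.shape} != expected ({n}, {model.window_samples})")
    covs = band_covariances([w], model.fbcsp.bank, model.fbcsp.fs)
    feats = features_from_covariances(covs, model.fbcsp)[0]
    return model.decide(feats)


def stream_decode(packets, model: DecoderModel, fs: float = 500.0):
    """Run the online decoder over a contiguous packet sequence.

    A ring buffer accrues samples; once a full window (2 s) is available a
    command is emitted, then again every shift (0.5 s), time-stamped at the
    window end.  Gaps in packet sequence numbers raise.
    """
    buf = None
    n_seen = 0
    last_seq = None
    out = []
    next_emit = model.window_samples
    for pkt in packets:
        if last_seq is not None and pkt.seq != last_seq + 1:
            raise ValueError(f"packet gap: expected seq {last_seq + 1}, got {pkt.seq}")
        last_seq = pkt.seq
        d = np.asarray(pkt.data, float)
        buf = d if buf is None else np.concatenate([buf, d], axis=1)
        keep = model.window_samples + 64  # margin for emit offsets inside a packet
        if buf.shape[1] > keep:
            buf = buf[:, -keep:]
        n_seen += d.shape[1]
        while n_seen >= next_emit:
            # Window ends exactly at next_emit; buffer tail holds it.
            offset = n_seen - next_emit
            win = buf[:, buf.shape[1] - model.window_samples - offset:
                      buf.shape[1] - offset] if offset else buf[:, -model.window_samples:]
            label = classify_window(win, model)
            out.append(CommandLabel(label, next_emit / fs, model.pair_name))
            next_emit += model.shift_samples
    return out


def packets_from_recording(recording: EEGRecording, packet_samples: int = 10):
    """Replay a recording as a contiguous packet stream (drops any tail
    shorter than one packet)."""
    n = recording.n_samples // packet_samples
    for i in range(n):
        yield StreamPacket(recording.data[:, i * packet_samples:(i + 1) * packet_samples], i)


def decode_recording(recording: EEGRecording, model: DecoderModel):
    """Offline equivalent of ``stream_decode``: classify the same windows cut
    directly from the recording."""
    fs = recording.sfreq
    out = []
    end = model.window_samples
    usable = (recording.n_samples // 10) * 10  # packet-aligned span
    while end <= usable:
        win = recording.data[:, end - model.window_samples:end]
        out.append(CommandLabel(classify_window(win, model), end / fs, model.pair_name))
        end += model.shift_samples
    return out


# ---------------------------------------------------------------------------
# serialization (plain JSON; Python float repr round-trips exactly)


def model_to_dict(model: DecoderModel) -> dict:
    return {
        "format": "exobci-decoder-v1",
        "pair": model.pair_name,
        "window_samples": model.window_samples,
        "shift_samples": model.shift_samples,
        "fs": model.fbcsp.fs,
        "bank": {"bands": [list(b) for b in model.fbcsp.bank.bands],
                 "order": model.fbcsp.bank.order},
        "csp": [{"W": m.W.tolist(), "eigenvalues": m.eigenvalues.tolist(),
                 "selected_rows": list(m.selected_rows)} for m in model.fbcsp.csp_models],
        "ranking": {"mi": model.ranking.mi.tolist(), "order": list(model.ranking.order)},
        "selection": {"k": model.selection.k, "indices": list(model.selection.indices),
                      "pair_completion": model.selection.pair_completion},
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "training_accuracy": model.training_accuracy,
    }


def model_from_dict(d: dict) -> DecoderModel:
    if d.get("format") != "exobci-decoder-v1":
        raise ValueError("not a decoder model file")
    bank = FilterBank(tuple(tuple(b) for b in d["bank"]["bands"]), d["bank"]["order"])
    pair = PAIRS[d["pair"]]
    csp_models = [CSPModel(W=np.array(m["W"]), eigenvalues=np.array(m["eigenvalues"]),
                           selected_rows=tuple(m["selected_rows"]), classes=pair)
                  for m in d["csp"]]
    fbcsp = FBCSPModel(bank=bank, csp_models=csp_models, fs=d["fs"], classes=pair)
    ranking = MIRanking(mi=np.array(d["ranking"]["mi"]),
                        order=tuple(d["ranking"]["order"]), classes=pair)
    selection = SelectionK(k=d["selection"]["k"],
                           indices=tuple(d["selection"]["indices"]),
                           pair_completion=d["selection"]["pair_completion"])
    return DecoderModel(fbcsp=fbcsp, ranking=ranking, selection=selection,
                        weights=np.array(d["weights"]), bias=d["bias"],
                        pair_name=d["pair"],
                        window_samples=d["window_samples"],
                        shift_samples=d["shift_samples"],
                        training_accuracy=d.get("training_accuracy"))


def save_model(model: DecoderModel, path) -> None:
    with open(path, "w") as f:
        json.dump(model_to_dict(model), f)


def load_model(path) -> DecoderModel:
    with open(path) as f:
        return model_from_dict(json.load(f))
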