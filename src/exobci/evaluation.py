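"""Quantitative evaluation: confusion rates, bit rate / ITR, bootstrap
offline accuracy, Fisher-ratio topography, ERSP, and scenario timing."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoder import (PAIRS, epoch_training_windows,
                      train_decoder_from_covariances, _LABEL_TO_COMMAND)
from .filterbank import (FilterBank, band_covariances, bandpass,
                         features_from_covariances)
from .recording import EEGRecording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of one binary classifier."""

    nTP: int = 0
    nTN: int = 0
    nFP: int = 0
    nFN: int = 0

    def __post_init__(self):
        if min(self.nTP, self.nTN, self.nFP, self.nFN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.nTP + self.nTN + self.nFP + self.nFN


def count_confusions(predictions, truths, positive) -> ConfusionCounts:
    """Tally a prediction/truth sequence against a positive class."""
    tp = tn = fp = fn = 0
    for p, t in zip(predictions, truths, strict=True):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def compute_rates(counts: ConfusionCounts) -> dict:
    """TPR, FPR, ACC as exact ratios; undefined metrics are None."""
    tpr = counts.nTP / (counts.nTP + counts.nFN) if counts.nTP + counts.nFN else None
    fpr = counts.nFP / (counts.nTN + counts.nFP) if counts.nTN + counts.nFP else None
    acc = (counts.nTP + counts.nTN) / counts.total if counts.total else None
    return {"TPR": tpr, "FPR": fpr, "ACC": acc}


def bit_rate(p: float, n_tasks: int = 3) -> float:
    """Bits per trial: log2 N + p log2 p + (1-p) log2((1-p)/(N-1)).

    The p=1 limit is handled exactly; p below chance is allowed but flagged
    with a warning (the formula is not meaningful there).
    """
    if n_tasks < 2:
        raise ValueError("need at least 2 tasks")
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy p must be in [0, 1]")
    if p < 1.0 / n_tasks:
        warnings.warn(f"accuracy {p} below chance 1/{n_tasks}; bit rate unreliable",
                      stacklevel=2)
    out = np.log2(n_tasks)
    if p > 0:
        out += p * np.log2(p)
    if p < 1:
        out += (1 - p) * np.log2((1 - p) / (n_tasks - 1))
    return float(out)


def itr(p: float, n_tasks: int = 3, fd: float = 4.60) -> float:
    """Information transfer rate in bits/min: decision rate times bit rate."""
    if fd <= 0:
        raise ValueError("decision rate fd must be positive")
    return fd * bit_rate(p, n_tasks)


# Printed average decision rates (trials/min) usable as defaults.
FD_OFFLINE = 4.60
FD_ONLINE = 5.97


@dataclass
class MetricsReport:
    """Bundle of the online metrics for one classifier."""

    counts: ConfusionCounts
    TPR: float | None
    FPR: float | None
    ACC: float | None
    Id: float | None = None
    ITR: float | None = None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, n_tasks: int = 3,
                    fd: float | None = None) -> "MetricsReport":
        rates = compute_rates(counts)
        rep = cls(counts=counts, **rates)
        if rates["ACC"] is not None and rates["ACC"] >= 1.0 / n_tasks:
            rep.Id = bit_rate(rates["ACC"], n_tasks)
            if fd:
                rep.ITR = fd * rep.Id
        return rep


def online_decoder_accuracy(acc_gvn: float, acc_gvs: float) -> float:
    """Overall online score: the lower of the two classifier accuracies."""
    return min(acc_gvn, acc_gvs)


# ---------------------------------------------------------------------------
# bootstrap offline accuracy


def _majority_command(commands, pair) -> str:
    gait_cmd = _LABEL_TO_COMMAND[pair[0]]
    other_cmd = _LABEL_TO_COMMAND[pair[1]]
    n_gait = sum(1 for c in commands if c == gait_cmd)
    # Ties resolve to the non-gait class, like the per-window tie rule.
    return gait_cmd if n_gait * 2 > len(commands) else other_cmd


def bootstrap_offline_accuracy(
    recording: EEGRecording,
    trials: pd.DataFrame,
    pair_name: str,
    n_reps: int = 100,
    n_test: int = 10,
    k: int = 6,
    pair_completion: bool = True,
    bank: FilterBank | None = None,
    seed: int = 0,
    permute_labels: bool = False,
) -> dict:
    """Repeated train/test evaluation of one binary decoder.

    Per repetition: draw ``n_test`` stratified test trials; bootstrap-resample
    the remaining trials (with replacement) into the training set; train the
    full pipeline on the training trials' sliding windows; score each test
    trial by majority vote over its windows.  Returns mean/std accuracy (%)
    over repetitions.

    Band-filtered window covariances are precomputed once, which is exact:
    every downstream quantity (CSP, features) depends on the windows only
    through these covariances.
    """
    bank = bank or FilterBank()
    pair = PAIRS[pair_name]
    rng = np.random.default_rng(seed)

    windows, labels, trial_ids = epoch_training_windows(recording, trials, pair)
    covs = band_covariances(windows, bank, recording.sfreq)

    uniq_trials = np.unique(trial_ids)
    trial_label = {t: labels[trial_ids == t][0] for t in uniq_trials}
    by_class = {c: np.array([t for t in uniq_trials if trial_label[t] == c])
                for c in pair}
    if min(len(v) for v in by_class.values()) < n_test // 2 + 2:
        raise ValueError("too few trials per class for the bootstrap protocol")

    win_of_trial = {t: np.flatnonzero(trial_ids == t) for t in uniq_trials}
    accs = np.empty(n_reps)
    for rep in range(n_reps):
        labels_rep = dict(trial_label)
        if permute_labels:
            perm = rng.permutation([labels_rep[t] for t in uniq_trials])
            labels_rep = dict(zip(uniq_trials, perm))
        test = np.concatenate([
            rng.choice(by_class[c], size=n_test // 2, replace=False) for c in pair])
        rest = np.array([t for t in uniq_trials if t not in set(test)])
        train = rng.choice(rest, size=rest.size, replace=True)

        train_win = np.concatenate([win_of_trial[t] for t in train])
        train_lab = np.concatenate([
            np.repeat(labels_rep[t], win_of_trial[t].size) for t in train])
        model = train_decoder_from_covariances(
            covs[train_win], train_lab, pair_name, bank, recording.sfreq,
            k=k, pair_completion=pair_completion, seed=rep)

        correct = 0
        for t in test:
            feats = features_from_covariances(covs[win_of_trial[t]], model.fbcsp)
            cmds = [model.decide(f) for f in feats]
            if _majority_command(cmds, pair) == _LABEL_TO_COMMAND[labels_rep[t]]:
                correct += 1
        accs[rep] = 100.0 * correct / test.size
    return {"mean": float(accs.mean()), "std": float(accs.std(ddof=1)),
            "accuracies": accs, "n_reps": n_reps, "pair": pair_name}


# ---------------------------------------------------------------------------
# Fisher-ratio topography and ERSP


def fisher_ratio_map(trials_a, trials_b, bank: FilterBank | None = None,
                     fs: float = 500.0, normalize: bool = True) -> np.ndarray:
    """(channels x bands) Fisher ratio of log band power between two classes.

    FR = (mu1 - mu2)^2 / (s1^2 + s2^2) per cell; optionally scaled to [0, 1]
    over the map.  Cells with zero pooled variance are NaN.
    """
    bank = bank or FilterBank()
    if len(trials_a) < 2 or len(trials_b) < 2:
        raise ValueError("need >= 2 trials per class")

    def log_power(trials):
        # (n_trials, channels, bands)
        out = np.empty((len(trials), np.asarray(trials[0]).shape[0], bank.n_bands))
        for ti, tr in enumerate(trials):
            for bi, band in enumerate(bank.bands):
                f = bandpass(tr, band, fs, bank.order)
                out[ti, :, bi] = np.log(np.mean(f**2, axis=1))
        return out

    pa, pb = log_power(trials_a), log_power(trials_b)
    num = (pa.mean(axis=0) - pb.mean(axis=0)) ** 2
    den = pa.var(axis=0, ddof=1) + pb.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fr = np.where(den > 0, num / den, np.nan)
    if np.any(den <= 0):
        log.warning("zero pooled variance in %d Fisher-ratio cells", int((den <= 0).sum()))
    if normalize:
        finite = np.isfinite(fr)
        if finite.any() and np.nanmax(fr) > 0:
            fr = fr / np.nanmax(fr)
    return fr


def _morlet_kernel(freq: float, fs: float, n_cycles: float = 6.0) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(-5 * sigma_t, 5 * sigma_t + 1.0 / fs, 1.0 / fs)
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    return kernel / np.sqrt(np.sum(np.abs(kernel) ** 2))


def ersp(trials, fs: float = 500.0, freqs=None, n_cycles: float = 6.0) -> dict:
    """Event-related spectral perturbation of one channel's trials.

    Morlet-wavelet power, trial-averaged, in dB relative to the whole-epoch
    mean per frequency (cue at time 0).  ``trials`` is a list of equal-length
    1-D arrays time-locked to the cue.
    """
    if freqs is None:
        freqs = np.arange(4.0, 41.0, 1.0)
    lengths = {np.asarray(t).size for t in trials}
    if len(lengths) != 1:
        raise ValueError("all trials must have the same length")
    n = lengths.pop()
    power = np.zeros((len(freqs), n))
    for tr in trials:
        x = np.asarray(tr, float)
        for fi, f in enumerate(freqs):
            conv = np.convolve(x, _morlet_kernel(f, fs, n_cycles), mode="same")
            power[fi] += np.abs(conv) ** 2
    power /= len(trials)
    baseline = power.mean(axis=1, keepdims=True)  # whole-epoch mean per frequency
    db = 10.0 * np.log10(power / baseline)
    return {"power_db": db, "freqs": np.asarray(freqs), "times": np.arange(n) / fs}


# ---------------------------------------------------------------------------
# scenario timing


@dataclass(frozen=True)
class ScenarioResult:
    completed: bool
    completion_s: float | None
    time_ratio_pct: float | None


EXPECTED_ACTION_SEQUENCE = ("STAND_UP", "GAIT_START", "GAIT_STOP",
                            "GAIT_START", "GAIT_STOP", "SIT_DOWN")


def scenario_timing(actions, reference_s: float | None = None,
                    start_s: float = 0.0,
                    expected=EXPECTED_ACTION_SEQUENCE) -> ScenarioResult:
    """Completion time of the scripted walk scenario and the time ratio.

    ``actions`` is [(time_s, action)]; the scenario counts as completed when
    the expected action sequence appears in order.
    """
    seq = [getattr(a, "value", str(a)) for _, a in actions]
    it = iter(enumerate(seq))
    last_idx = None
    for want in expected:
        for i, got in it:
            if got == want:
                last_idx = i
                break
        else:
            return ScenarioResult(False, None, None)
    completion = actions[last_idx][0] - start_s
    ratio = 100.0 * completion / reference_s if reference_s else None
    return ScenarioResult(True, completion, ratio)
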