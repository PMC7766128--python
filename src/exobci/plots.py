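"""Diagnostic figures: buffer trace, Fisher-ratio topography, ERSP map."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .filterbank import DEFAULT_BANDS
from .fsm import BUFFERS
from .montage import MontageSpec


def plot_buffer_trace(trace, path) -> None:
    """Stair plot of the three buffer levels over time, with actions marked."""
    fig, ax = plt.subplots(figsize=(10, 3.2))
    for name, color in zip(BUFFERS, ("#bbbbbb", "#777777", "#333333")):
        ax.step(trace.time_s, trace[name], where="post", label=name, color=color)
    acts = trace[trace.action != ""]
    for _, row in acts.iterrows():
        ax.axvline(row.time_s, color="tab:red", ls="--", lw=0.8)
        ax.text(row.time_s, 10.3, row.action, rotation=90, fontsize=7,
                ha="right", va="bottom", color="tab:red")
    ax.set(xlabel="time (s)", ylabel="buffer level", ylim=(-0.5, 13))
    ax.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_fisher_map(fisher, path, montage: MontageSpec | None = None,
                    bands=DEFAULT_BANDS) -> None:
    """Channels x bands Fisher-ratio heat map."""
    montage = montage or MontageSpec()
    fig, ax = plt.subplots(figsize=(5, 8))
    im = ax.imshow(fisher, aspect="auto", cmap="viridis")
    ax.set_yticks(range(montage.n_channels), montage.channel_names, fontsize=6)
    ax.set_xticks(range(len(bands)), [f"{lo:g}-{hi:g}" for lo, hi in bands],
                  fontsize=7, rotation=45)
    ax.set(xlabel="band (Hz)", title="Fisher ratio")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ersp(ersp_result, path, cue_time_s: float = 0.0) -> None:
    """Time-frequency perturbation map (dB vs whole-epoch baseline)."""
    db, freqs, times = (ersp_result["power_db"], ersp_result["freqs"],
                        ersp_result["times"])
    vmax = np.nanmax(np.abs(db))
    fig, ax = plt.subplots(figsize=(7, 3.5))
    im = ax.pcolormesh(times - cue_time_s, freqs, db, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="auto")
    ax.axvline(0.0, color="b", lw=1)
    ax.set(xlabel="time from cue (s)", ylabel="frequency (Hz)")
    fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
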