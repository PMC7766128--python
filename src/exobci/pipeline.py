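"""End-to-end hybrid control: route decoder commands and TEB events into the
FSM and score the scenario."""

from __future__ import annotations

import pandas as pd

from .decoder import CommandLabel, DecoderModel, decode_recording
from .fsm import BUFFERS, Controller, ControllerConfig, State
from .recording import EEGRecording
from .teb import BlinkDetectorConfig, TEBEvent, detect_teb


def merge_inputs(commands_gvn, commands_gvs, teb_events):
    """Time-sorted stream of all controller inputs (TEBs first on ties, so a
    switch takes effect before a command stamped at the same instant)."""
    def key(ev):
        return (ev.time_s, 0 if isinstance(ev, TEBEvent) else 1)
    return sorted([*commands_gvn, *commands_gvs, *teb_events], key=key)


def run_hybrid_controller(inputs, config: ControllerConfig | None = None):
    """Fold the FSM over a merged input stream, routing commands to the
    decoder that is active in the current state.

    Commands from the inactive classifier are dropped (in hardware only the
    active classifier runs); TEB events always reach the machine.
    """
    ctrl = Controller(config)
    actions, rows = [], []
    for ev in inputs:
        if isinstance(ev, CommandLabel):
            wanted = {State.DECODE_GVN: "gvn", State.DECODE_GVS: "gvs"}.get(ctrl.state)
            if ev.source != wanted:
                continue
        snap, action = ctrl.step(ev)
        if action is not None:
            actions.append((ev.time_s, action))
        kind = "TEB" if isinstance(ev, TEBEvent) else f"{ev.label}({ev.source})"
        rows.append({"time_s": ev.time_s, "input": kind, "state": snap.state.value,
                     **snap.buffers, "action": action.value if action else ""})
    trace = pd.DataFrame(rows, columns=["time_s", "input", "state", *BUFFERS, "action"])
    return actions, trace


def run_scenario(stream: EEGRecording, model_gvn: DecoderModel,
                 model_gvs: DecoderModel, threshold: float,
                 teb_cfg: BlinkDetectorConfig | None = None,
                 controller_cfg: ControllerConfig | None = None):
    """Decode a scenario stream with both classifiers and the blink switch,
    then drive the FSM.  Returns (actions, trace, inputs)."""
    teb_events = detect_teb(stream, threshold, teb_cfg)
    cmds_gvn = decode_recording(stream, model_gvn)
    cmds_gvs = decode_recording(stream, model_gvs)
    inputs = merge_inputs(cmds_gvn, cmds_gvs, teb_events)
    actions, trace = run_hybrid_controller(inputs, controller_cfg)
    return actions, trace, inputs
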