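"""Asynchronous exoskeleton controller: TEB-gated finite state machine with
three size-10 command buffers and 1:3 fill/empty dynamics.

States: SIT -> (TEB) -> DECODE_GVN -> (buffer full) -> STAND -> (TEB) ->
DECODE_GVS -> (buffer full) -> GAIT or back to SIT; a TEB during GAIT stops
gait and returns to STAND.  The transition topology is a plain data table
so alternative readings are pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .decoder import CommandLabel, GAIT, SIT, NOTHING_CMD
from .teb import TEBEvent


class State(str, Enum):
    SIT = "SIT"
    DECODE_GVN = "DECODE_GVN"
    STAND = "STAND"
    DECODE_GVS = "DECODE_GVS"
    GAIT = "GAIT"


class Action(str, Enum):
    STAND_UP = "STAND_UP"
    GAIT_START = "GAIT_START"
    GAIT_STOP = "GAIT_STOP"
    SIT_DOWN = "SIT_DOWN"


BUFFERS = ("sit_to_stand", "stand_to_gait", "stand_to_sit")


@dataclass
class CommandBuffer:
    """Level in [0, capacity]; fills by +fill_step, empties by -empty_step."""

    level: int = 0
    capacity: int = 10
    fill_step: int = 1
    empty_step: int = 3

    def fill(self) -> int:
        self.level = min(self.level + self.fill_step, self.capacity)
        return self.level

    def empty(self) -> int:
        self.level = max(self.level - self.empty_step, 0)
        return self.level

    @property
    def full(self) -> bool:
        return self.level >= self.capacity


def buffer_update(buffer: CommandBuffer, event: str) -> int:
    """Apply one FILL or EMPTY event and return the new level."""
    if event == "FILL":
        return buffer.fill()
    if event == "EMPTY":
        return buffer.empty()
    raise ValueError(f"unknown buffer event {event!r}")


# TEB-driven transitions: state -> (new state, action emitted on entry).
DEFAULT_TEB_TRANSITIONS = {
    State.SIT: (State.DECODE_GVN, None),
    State.STAND: (State.DECODE_GVS, None),
    State.GAIT: (State.STAND, Action.GAIT_STOP),
}


@dataclass(frozen=True)
class ControllerConfig:
    capacity: int = 10
    fill_step: int = 1
    empty_step: int = 3
    teb_transitions: dict = field(default_factory=lambda: dict(DEFAULT_TEB_TRANSITIONS))


@dataclass
class ControllerState:
    """FSM state plus the three buffer levels."""

    state: State = State.SIT
    buffers: dict = None

    def __post_init__(self):
        if self.buffers is None:
            self.buffers = {name: 0 for name in BUFFERS}


class Controller:
    """The buffered FSM.  Starts (and should terminate) in SIT."""

    def __init__(self, config: ControllerConfig | None = None):
        self.config = config or ControllerConfig()
        self.state = State.SIT
        self._buffers = {name: self._new_buffer() for name in BUFFERS}

    def _new_buffer(self) -> CommandBuffer:
        c = self.config
        return CommandBuffer(0, c.capacity, c.fill_step, c.empty_step)

    def _reset_buffers(self) -> None:
        self._buffers = {name: self._new_buffer() for name in BUFFERS}

    @property
    def snapshot(self) -> ControllerState:
        return ControllerState(self.state,
                               {n: b.level for n, b in self._buffers.items()})

    def step(self, event) -> tuple:
        """Advance by one input (CommandLabel or TEBEvent).

        Returns (ControllerState, Action or None).  Unlisted (state, input)
        pairs leave the machine unchanged; malformed inputs raise without
        mutating state.
        """
        if isinstance(event, TEBEvent):
            return self._step_teb()
        if isinstance(event, CommandLabel):
            return self._step_command(event.label)
        raise TypeError(f"unsupported controller input: {type(event).__name__}")

    def _step_teb(self):
        trans = self.config.teb_transitions.get(self.state)
        action = None
        if trans is not None:
            new_state, action = trans
            self.state = new_state
            self._reset_buffers()
        return self.snapshot, action

    def _step_command(self, label: str):
        if label not in (GAIT, SIT, NOTHING_CMD):
            raise ValueError(f"unknown command label {label!r}")
        action = None
        if self.state is State.DECODE_GVN:
            buf = self._buffers["sit_to_stand"]
            if label == GAIT:
                buf.fill()
            elif label == NOTHING_CMD:
                buf.empty()
            if buf.full:
                action = Action.STAND_UP
                self.state = State.STAND
                self._reset_buffers()
        elif self.state is State.DECODE_GVS:
            gait_buf = self._buffers["stand_to_gait"]
            sit_buf = self._buffers["stand_to_sit"]
            if label == GAIT:
                gait_buf.fill()
                sit_buf.empty()
            elif label == SIT:
                sit_buf.fill()
                gait_buf.empty()
            if gait_buf.full:
                action = Action.GAIT_START
                self.state = State.GAIT
                self._reset_buffers()
            elif sit_buf.full:
                action = Action.SIT_DOWN
                self.state = State.SIT
                self._reset_buffers()
        # Commands in non-decoder states are ignored (recurrent arrow).
        return self.snapshot, action


def run_controller(inputs, config: ControllerConfig | None = None):
    """Fold the FSM over time-sorted inputs (CommandLabel / TEBEvent mix).

    Returns (actions, trace): actions as [(time_s, Action)], trace as a
    DataFrame with one row per input (time, input, state, buffer levels,
    action).
    """
    def _time(ev):
        return ev.time_s

    times = [_time(ev) for ev in inputs]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("controller inputs must be sorted by time")

    ctrl = Controller(config)
    actions = []
    rows = []
    for ev in inputs:
        snap, action = ctrl.step(ev)
        if action is not None:
            actions.append((ev.time_s, action))
        kind = "TEB" if isinstance(ev, TEBEvent) else ev.label
        rows.append({"time_s": ev.time_s, "input": kind,
                     "state": snap.state.value, **snap.buffers,
                     "action": action.value if action else ""})
    trace = pd.DataFrame(rows, columns=["time_s", "input", "state",
                                        *BUFFERS, "action"])
    return actions, trace
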