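"""Run configuration: YAML-backed settings with paper-default values."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .filterbank import DEFAULT_BANDS


@dataclass
class RunConfig:
    """All tunables of a pipeline run; defaults match the published settings
    where one exists (filter bank edges, 2 s / 0.5 s window geometry,
    1.6 s / 0.4 s TEB window, size-10 buffers with 1:3 fill/empty)."""

    seed: int = 0
    sampling_rate: float = 500.0
    bands: list = field(default_factory=lambda: [list(b) for b in DEFAULT_BANDS])
    filter_order: int = 4
    window_s: float = 2.0
    shift_s: float = 0.5
    k: int = 6
    pair_completion: bool = True
    teb: dict = field(default_factory=lambda: {
        "band": [2.0, 15.0], "window_s": 1.6, "shift_s": 0.4,
        "min_gap_s": 0.15, "refractory_s": 2.0, "threshold_sigmas": 4.0,
    })
    controller: dict = field(default_factory=lambda: {
        "capacity": 10, "fill_step": 1, "empty_step": 3,
    })
    evaluation: dict = field(default_factory=lambda: {
        "n_reps": 100, "n_test": 10, "fd_offline": 4.60, "fd_online": 5.97,
    })

    def validate(self) -> "RunConfig":
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 1 <= self.k <= 24:
            raise ValueError("k must be in [1, 24]")
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) malformed")
        if self.window_s <= 0 or self.shift_s <= 0:
            raise ValueError("window and shift must be positive")
        if self.controller["capacity"] < 1 or self.controller["fill_step"] < 1 \
                or self.controller["empty_step"] < 1:
            raise ValueError("controller buffer settings must be positive")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f_.name for f_ in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw).validate()
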