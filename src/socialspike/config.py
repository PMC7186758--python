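"""Analysis configuration: every threshold and window in one place.

Values mirror the experimental analysis: 100 ms bins on a 10 frames/s
clock, 4 s state windows with the sync at the 2 s mark, 10 cm alone radius,
1 cm contact radius, 1 mm / 2 s stillness rule, +/-8 s perievent span,
10 deg angular bins, 5 cm near/far distance cut, and alpha = 0.05 with a
6-pair Bonferroni family for the variance comparisons.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .social_states import StateConfig


@dataclass
class AnalysisConfig:
    frame_rate_hz: float = 10.0
    bin_w_s: float = 0.1
    peth_half_span_s: float = 8.0
    peak_search_s: tuple[float, float] = (-4.0, 0.0)
    peak_smooth_s: float = 0.3
    angle_bin_deg: float = 10.0
    distance_cut_cm: float = 5.0
    alpha: float = 0.05
    state: StateConfig = field(default_factory=StateConfig)

    @classmethod
    def from_toml(cls, path) -> "AnalysisConfig":
        """Load from a TOML file; a ``[state]`` table feeds StateConfig."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        state = StateConfig(**raw.pop("state", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"state"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "peak_search_s" in raw:
            raw["peak_search_s"] = tuple(raw["peak_search_s"])
        return cls(state=state, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_search_s"] = list(self.peak_search_s)
        return d
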