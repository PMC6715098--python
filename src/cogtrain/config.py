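"""Engine-level configuration.

Defaults reproduce every design constant of the training system: 30
sessions of 17 slots over a 70-day module, a 6/4/7 easy/medium/hard mix
with the E E M M M H H H E E M H H H H E E positional pattern, profile
refreshes at sessions 13/19/25, the 2/2/3 strength/mid/weakness tier
partition, the 10% decrease / 90-minute / 72-hour / 3-orange flag
thresholds, the 1-per-72-hours email cap, the top-25% feedback target zone
and the 5-member CheerSquad cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adherence import AdherenceConfig

__all__ = ["EngineConfig"]


@dataclass(frozen=True)
class EngineConfig:
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)
    tier_sizes: tuple[int, int, int] = (2, 2, 3)
    session_pattern: str = "EEMMMHHHEEMHHHHEE"
    slots_per_session: int = 17
    sessions_per_module: int = 30
    refresh_points: tuple[int, ...] = (13, 19, 25)
    module_length_days: int = 70
    squad_max: int = 5
    target_zone_quantile: float = 0.75
    min_cohort: int = 20
    seed: int = 0
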