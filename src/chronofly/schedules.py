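"""Light schedules and Zeitgeber-time conventions.

Zeitgeber time (ZT) 0 is defined as lights-on of the entraining cycle.
Under constant darkness (DD) the schedule of the preceding entrainment is
kept only to anchor projected ZT; it does not gate activity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


@dataclass(frozen=True)
class LightSchedule:
    """A 24-h light:dark regime.

    Parameters
    ----------
    hours_light, hours_dark:
        Photophase and scotophase duration in hours; they must sum to 24.
    lights_on_clock_time:
        Wall-clock hour of lights-on, used when parsing monitor timestamps.
    regime_label:
        ``"LD"`` for a running light:dark cycle, ``"DD"`` for constant
        darkness (free-running conditions).
    """

    hours_light: float
    hours_dark: float
    lights_on_clock_time: float = 8.0
    regime_label: str = "LD"

    def __post_init__(self) -> None:
        if abs(self.hours_light + self.hours_dark - 24.0) > 1e-9:
            raise ValueError(
                f"hours_light + hours_dark must equal 24, got "
                f"{self.hours_light} + {self.hours_dark}"
            )
        if not 0.0 <= self.hours_light <= 24.0:
            raise ValueError(f"hours_light out of [0, 24]: {self.hours_light}")
        if not 0.0 <= self.lights_on_clock_time < 24.0:
            raise ValueError(
                f"lights_on_clock_time out of [0, 24): {self.lights_on_clock_time}"
            )
        if self.regime_label not in ("LD", "DD"):
            raise ValueError(f"regime_label must be LD or DD, got {self.regime_label!r}")

    def is_light(self, zt_hours: float) -> bool:
        """True when the lamp is on at the given Zeitgeber time.

        Always False under DD.
        """
        if self.regime_label == "DD":
            return False
        return (zt_hours % 24.0) < self.hours_light

    @property
    def label(self) -> str:
        if self.regime_label == "DD":
            return "DD"
        return f"LD{self.hours_light:g}:{self.hours_dark:g}"

    @classmethod
    def parse(cls, text: str) -> "LightSchedule":
        """Parse compact schedule notation, e.g. ``LD16:8@08:00`` or ``DD``.

        The ``@HH:MM`` clock-time suffix is optional and defaults to 08:00.
        """
        text = text.strip()
        if text.upper() == "DD":
            return cls(0.0, 24.0, regime_label="DD")
        m = re.fullmatch(
            r"LD\s*(\d+(?:\.\d+)?):(\d+(?:\.\d+)?)(?:@(\d{1,2})(?::(\d{2}))?)?",
            text,
            flags=re.IGNORECASE,
        )
        if m is None:
            raise ValueError(f"cannot parse light schedule {text!r}")
        light, dark = float(m.group(1)), float(m.group(2))
        clock = 8.0
        if m.group(3) is not None:
            clock = float(m.group(3)) + (float(m.group(4)) / 60.0 if m.group(4) else 0.0)
        return cls(light, dark, lights_on_clock_time=clock, regime_label="LD")


LD_12_12 = LightSchedule(12.0, 12.0)
LD_16_8 = LightSchedule(16.0, 8.0)
LD_8_16 = LightSchedule(8.0, 16.0)
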