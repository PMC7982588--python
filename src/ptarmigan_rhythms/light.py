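"""Light protocols and per-day light schedules.

Experiment time is measured in decimal hours since the start of the
recording; day ``d`` covers ``[24*d, 24*(d+1))``.  By convention lights-on
is anchored at clock hour 0, so Zeitgeber time (ZT 0 = lights-on) coincides
with the clock hour unless a protocol declares otherwise.  Photoperiod
transitions move the dusk (lights-off) while lights-on stays fixed, keeping
ZT 0 stable for anticipation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightProtocol",
    "LightSchedule",
    "build_light_schedule",
    "SP_PROTOCOL",
    "LP_PROTOCOL",
    "LL_PROTOCOL",
    "DD_PROTOCOL",
]


@dataclass(frozen=True)
class LightProtocol:
    """Declarative photoperiod protocol.

    Each segment is ``(start_day, photoperiod_h, lights_on_zt)``: from
    ``start_day`` onward the schedule ramps (at ``transition_rate`` h/day)
    toward ``photoperiod_h`` hours of light starting at ``lights_on_zt``.
    ``photoperiod_h == 0`` is constant darkness, ``24`` constant light.
    """

    name: str
    segments: tuple[tuple[int, float, float], ...]
    transition_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.transition_rate < 0:
            raise ValueError("transition_rate must be non-negative")
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        last_day = None
        for start_day, photoperiod, lights_on in self.segments:
            if not 0.0 <= photoperiod <= 24.0:
                raise ValueError(f"photoperiod {photoperiod} outside [0, 24]")
            if not 0.0 <= lights_on < 24.0:
                raise ValueError(f"lights_on_zt {lights_on} outside [0, 24)")
            if last_day is not None and start_day <= last_day:
                raise ValueError("segments must be ordered by start_day")
            last_day = start_day


@dataclass
class LightSchedule:
    """Per-day lights-on/off pairs plus an ``is_light`` predicate.

    ``lights_on[d]`` and ``lights_off[d]`` are clock hours within day ``d``.
    A photoperiod of 0 is encoded as ``lights_on == lights_off``, constant
    light as a full-day span (``lights_off - lights_on >= 24``).
    """

    lights_on: np.ndarray
    lights_off: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.lights_on = np.asarray(self.lights_on, dtype=float)
        self.lights_off = np.asarray(self.lights_off, dtype=float)
        if self.lights_on.shape != self.lights_off.shape:
            raise ValueError("lights_on/lights_off length mismatch")

    @property
    def n_days(self) -> int:
        return len(self.lights_on)

    def photoperiod(self, day: int) -> float:
        return float(self.lights_off[day] - self.lights_on[day])

    def is_constant_dark(self) -> bool:
        return bool(np.all(self.lights_off == self.lights_on))

    def is_constant_light(self) -> bool:
        return bool(np.all(self.lights_off - self.lights_on >= 24.0))

    def has_zeitgeber(self) -> bool:
        return not (self.is_constant_dark() or self.is_constant_light())

    def is_light(self, t) -> np.ndarray | bool:
        """True where experiment time ``t`` (hours) falls in the light phase."""
        t = np.asarray(t, dtype=float)
        day = np.clip((t // 24).astype(int), 0, self.n_days - 1)
        clock = t - 24.0 * (t // 24)
        out = (clock >= self.lights_on[day]) & (clock < self.lights_off[day])
        return out if out.ndim else bool(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "day": np.arange(self.n_days),
                "lights_on": self.lights_on,
                "lights_off": self.lights_off,
            }
        )


def build_light_schedule(protocol: LightProtocol, n_days: int) -> LightSchedule:
    """Expand a protocol into one lights-on/off pair per day.

    During a transition the photoperiod changes by exactly
    ``protocol.transition_rate`` hours per day (dusk moves, dawn fixed)
    until the segment's target photoperiod is reached.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rate = protocol.transition_rate
    segments = protocol.segments
    lights_on = np.zeros(n_days)
    lights_off = np.zeros(n_days)
    seg_idx = 0
    current = segments[0][1]  # first segment defines the starting photoperiod
    for day in range(n_days):
        while seg_idx + 1 < len(segments) and day >= segments[seg_idx + 1][0]:
            seg_idx += 1
        _, target, on_zt = segments[seg_idx]
        if day > 0 and current != target:
            step = min(rate, abs(target - current)) if rate > 0 else abs(target - current)
            current += float(np.sign(target - current)) * step
        lights_on[day] = on_zt
        # Dusk moves; light is truncated at midnight for late lights-on.
        lights_off[day] = on_zt + 24.0 if current >= 24.0 else min(on_zt + current, 24.0)
    return LightSchedule(lights_on=lights_on, lights_off=lights_off, name=protocol.name)


SP_PROTOCOL = LightProtocol(name="SP", segments=((0, 6.0, 0.0),))
LP_PROTOCOL = LightProtocol(name="LP", segments=((0, 16.0, 0.0),))
LL_PROTOCOL = LightProtocol(name="LL", segments=((0, 24.0, 0.0),))
DD_PROTOCOL = LightProtocol(name="DD", segments=((0, 0.0, 0.0),))
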