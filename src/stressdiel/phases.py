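"""Diurnal phase windows.

Expression peaks over the day/night cycle are binned into four clock
windows: Midday 08:00-16:00, Lateday 18:00-20:00, Midnight 22:00-02:00
(wrapping across 0), and Predawn 04:00-06:00.  Window membership is over
the twelve even sampling hours (2-h sampling), with inclusive endpoints;
together the windows partition all twelve hours.
"""

from __future__ import annotations

from .errors import ValidationError

# Tie-break / reporting order: predawn first (the largest group in both
# drought directions), then midday, lateday, midnight.
PHASE_ORDER: tuple[str, ...] = ("predawn", "midday", "lateday", "midnight")

PHASE_WINDOWS: dict[str, frozenset[int]] = {
    "predawn": frozenset({4, 6}),
    "midday": frozenset({8, 10, 12, 14, 16}),
    "lateday": frozenset({18, 20}),
    "midnight": frozenset({22, 0, 2}),
}

# Continuous clock spans (start, end) in hours; end may exceed 24 to
# express the midnight wrap.  Used when planting peak times.
PHASE_SPANS: dict[str, tuple[float, float]] = {
    "predawn": (4.0, 6.0),
    "midday": (8.0, 16.0),
    "lateday": (18.0, 20.0),
    "midnight": (22.0, 26.0),
}

EVEN_HOURS: tuple[int, ...] = tuple(range(0, 24, 2))


def validate_windows(windows: dict[str, frozenset[int]] | None = None) -> None:
    """Assert the windows partition the even sampling hours exactly once."""
    windows = PHASE_WINDOWS if windows is None else windows
    seen: list[int] = []
    for hours in windows.values():
        seen.extend(hours)
    if sorted(seen) != sorted(EVEN_HOURS):
        raise ValidationError(
            "phase windows must partition the even hours 0,2,...,22; "
            f"got coverage {sorted(seen)}"
        )


def window_of(hour: int, windows: dict[str, frozenset[int]] | None = None) -> str:
    """Name of the window containing an even clock hour."""
    windows = PHASE_WINDOWS if windows is None else windows
    for name, hours in windows.items():
        if hour in hours:
            return name
    raise ValidationError(f"hour {hour} belongs to no phase window")


validate_windows()
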