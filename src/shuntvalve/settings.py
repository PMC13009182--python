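"""Mapping between indicator angles and Certas Plus settings 1..8.

The dial has 8 settings laid out clockwise over the full 360 degrees,
each owning a 45-degree zone.  An angle of 0 degrees — magnet axis
superimposed on the RC->RHS reference axis — is the cutoff between
settings 2 and 3, which anchors the whole layout: zone(s) =
[(s-3)*45, (s-2)*45) degrees, half-open and lower-inclusive, and the
expected (zone-centre) angle of setting s is (s-2.5)*45, i.e. -67.5 for
setting 1 up to 247.5 for setting 8.  Angles are reported in [-90, 270)
to match that table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .geometry import wrap_angle

N_SETTINGS = 8
ZONE_WIDTH_DEG = 45.0
ANGLE_MIN_DEG = -90.0
ANGLE_MAX_DEG = 270.0


@dataclass(frozen=True)
class SettingPrediction:
    setting: int
    angle_deg: float  # normalised source angle
    zone_lo: float
    zone_hi: float


def _check_setting(setting: int) -> int:
    if not isinstance(setting, (int,)) or isinstance(setting, bool):
        if isinstance(setting, float) and setting.is_integer():
            setting = int(setting)
        else:
            raise ValueError(f"setting must be an integer 1..{N_SETTINGS}, got {setting!r}")
    if not 1 <= setting <= N_SETTINGS:
        raise ValueError(f"setting must be in 1..{N_SETTINGS}, got {setting}")
    return int(setting)


def zone_bounds(setting: int) -> tuple[float, float]:
    """Half-open angular zone [(s-3)*45, (s-2)*45) owned by a setting."""
    s = _check_setting(setting)
    return ((s - 3) * ZONE_WIDTH_DEG, (s - 2) * ZONE_WIDTH_DEG)


def setting_to_expected_angle(setting: int) -> float:
    """Zone-centre angle of a setting: (s - 2.5) * 45 degrees."""
    s = _check_setting(setting)
    return (s - 2.5) * ZONE_WIDTH_DEG


def angle_to_setting(angle_deg: float) -> SettingPrediction:
    """Assign a continuous indicator angle to its discrete setting.

    Any real angle is first wrapped into [-90, 270); zone boundaries are
    assigned upward (lower-inclusive), so exactly 0 degrees reads as
    setting 3.
    """
    if not math.isfinite(angle_deg):
        raise ValueError(f"angle must be finite, got {angle_deg!r}")
    a = wrap_angle(float(angle_deg))
    s = int(math.floor(a / ZONE_WIDTH_DEG)) + 3
    s = min(max(s, 1), N_SETTINGS)  # guard float edge at the wrap point
    lo, hi = zone_bounds(s)
    return SettingPrediction(setting=s, angle_deg=a, zone_lo=lo, zone_hi=hi)


def settings_adjacent(a: int, b: int, *, circular: bool = False) -> bool:
    """Whether two settings are equal or neighbours on the dial.

    Non-circular (default) adjacency is |a-b| <= 1, reflecting pressure
    adjacency; circular adjacency additionally treats 1 and 8 as
    neighbours, since they sit next to each other on the physical dial.
    """
    a = _check_setting(a)
    b = _check_setting(b)
    diff = abs(a - b)
    if circular:
        diff = min(diff, N_SETTINGS - diff)
    return diff <= 1


def zone_table() -> pd.DataFrame:
    """The full zone layout as a DataFrame (setting, lo, hi, expected_angle)."""
    rows = []
    for s in range(1, N_SETTINGS + 1):
        lo, hi = zone_bounds(s)
        rows.append(
            {
                "setting": s,
                "zone_lo_deg": lo,
                "zone_hi_deg": hi,
                "expected_angle_deg": setting_to_expected_angle(s),
            }
        )
    return pd.DataFrame(rows)
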