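"""Independently transcribed NEWS-2 band chart, used only as a test oracle.

Each function maps a (rounded) measurement to its sub-score by explicit
if/elif chains transcribed from the published chart — deliberately not
table-driven, so it shares no code path with the scorer under test.
"""

from __future__ import annotations


def resp_rate_points(v: float) -> int:
    v = round(v)
    if v <= 8:
        return 3
    if v <= 11:
        return 1
    if v <= 20:
        return 0
    if v <= 24:
        return 2
    return 3


def spo2_scale1_points(v: float) -> int:
    v = round(v)
    if v <= 91:
        return 3
    if v <= 93:
        return 2
    if v <= 95:
        return 1
    return 0


def spo2_scale2_points(v: float, on_oxygen: bool) -> int:
    v = round(v)
    if v <= 83:
        return 3
    if v <= 85:
        return 2
    if v <= 87:
        return 1
    if v <= 92:
        return 0
    # 93% and above scores only when breathing supplemental oxygen
    if not on_oxygen:
        return 0
    if v <= 94:
        return 1
    if v <= 96:
        return 2
    return 3


def supplemental_o2_points(on_oxygen: bool) -> int:
    return 2 if on_oxygen else 0


def sbp_points(v: float) -> int:
    v = round(v)
    if v <= 90:
        return 3
    if v <= 100:
        return 2
    if v <= 110:
        return 1
    if v <= 219:
        return 0
    return 3


def heart_rate_points(v: float) -> int:
    v = round(v)
    if v <= 40:
        return 3
    if v <= 50:
        return 1
    if v <= 90:
        return 0
    if v <= 110:
        return 1
    if v <= 130:
        return 2
    return 3


def consciousness_points(is_alert: bool) -> int:
    return 0 if is_alert else 3


def temperature_points(v: float) -> int:
    v = round(v, 1)
    if v <= 35.0:
        return 3
    if v <= 36.0:
        return 1
    if v <= 38.0:
        return 0
    if v <= 39.0:
        return 1
    return 2


#: band boundaries per parameter, for grid tests at boundary +/- 0.1
BOUNDARIES = {
    "resp_rate": [8, 9, 11, 12, 20, 21, 24, 25],
    "spo2_scale1": [91, 92, 93, 94, 95, 96],
    "spo2_scale2": [83, 84, 85, 86, 87, 88, 92, 93, 94, 95, 96, 97],
    "sbp": [90, 91, 100, 101, 110, 111, 219, 220],
    "heart_rate": [40, 41, 50, 51, 90, 91, 110, 111, 130, 131],
    "temperature": [35.0, 35.1, 36.0, 36.1, 38.0, 38.1, 39.0, 39.1],
}


def grid_values(parameter: str) -> list[float]:
    values = set()
    for b in BOUNDARIES[parameter]:
        for d in (-0.1, 0.0, 0.1):
            values.add(round(b + d, 2))
    return sorted(values)
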