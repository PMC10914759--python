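"""Biosensor panel constants shared across the package.

The panel comprises 18 graphene/peptide-TCPP biosensors named BM01..BM15 and
BM17..BM19 (BM16 does not exist), each read at six 10-minute intervals.
Feature columns are named ``<sensor>_<time>``, e.g. ``BM01_40``.
"""

from __future__ import annotations

SENSORS: tuple[str, ...] = tuple(
    f"BM{i:02d}" for i in list(range(1, 16)) + [17, 18, 19]
)

#: sentinel sensor_id for standard-curve wells (BM19 peptide-TCPP dilutions)
STD_SENSOR = "STD"

DEFAULT_TIMEPOINTS: tuple[int, ...] = (10, 20, 30, 40, 50, 60)

#: two-fold BM19 peptide-TCPP dilution series included on every plate, ng/ml
STANDARD_LEVELS: tuple[float, ...] = (800.0, 400.0, 200.0, 100.0, 50.0, 25.0)

#: lower limit of quantitation, ng/ml; concentrations strictly below are zeroed
DEFAULT_LLOQ = 2.98

#: 384-well coordinates A1..P24 in row-major order
WELLS_384: tuple[str, ...] = tuple(
    f"{row}{col}" for row in "ABCDEFGHIJKLMNOP" for col in range(1, 25)
)

#: assays per 384-well plate: 21 blocks of 18 sensor wells + 6 standard wells
ASSAYS_PER_PLATE = 21


def feature_name(sensor: str, time_min: int) -> str:
    return f"{sensor}_{time_min}"


def feature_names(timepoints=DEFAULT_TIMEPOINTS) -> list[str]:
    """All sensor_time feature columns, sensor-major then time."""
    return [feature_name(s, t) for s in SENSORS for t in timepoints]


def sensor_of_feature(name: str) -> str:
    return name.rsplit("_", 1)[0]
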