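"""Cell volume from linear dimensions, and salinity unit conversion.

The cell body is modelled as a cylinder of the cell's average width and
length plus two cones of the same base and height:

    V_cylinder = pi * (width/2)^2 * length
    V_2cones   = 2 * (1/3 * pi * (width/2)^2 * length)

so the total is always exactly 5/3 of the cylinder volume. Dimensions are
micrometres; totals are reported in picolitres (1000 um^3 = 1 pl).

Salinity given as % w/v NaCl (grams per 100 ml) converts to molarity with
the NaCl molar mass 58.44 g/mol: ``mol/l = percent * 10 / 58.44``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

NACL_MOLAR_MASS = 58.44  # g/mol
UM3_PER_PL = 1000.0


@dataclass(frozen=True)
class CellShape:
    """Width and length of a cell in micrometres."""

    width: float
    length: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.length < 0:
            raise ValueError("cell dimensions must be >= 0")


@dataclass(frozen=True)
class CellVolume:
    """Component volumes in um^3 and the total in picolitres."""

    v_cylinder: float
    v_2cones: float
    total_pl: float


def cell_volume(shape: CellShape) -> CellVolume:
    """Volume of a cell from the cylinder + two-cones model."""
    r = shape.width / 2.0
    v_cyl = math.pi * r**2 * shape.length
    v_cones = 2.0 * (math.pi * r**2 * shape.length / 3.0)
    return CellVolume(v_cyl, v_cones, (v_cyl + v_cones) / UM3_PER_PL)


def salinity_to_molarity(percent_wv: float) -> float:
    """Convert % w/v NaCl to mol/l (21% -> 3.59 mol/l at 2 decimals)."""
    if percent_wv < 0:
        raise ValueError("salinity must be >= 0")
    return percent_wv * 10.0 / NACL_MOLAR_MASS
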