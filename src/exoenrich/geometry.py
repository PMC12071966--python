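"""Geometric estimators for the culture chamber and the tumor interstitium.

Covers the order-of-magnitude arithmetic behind in-situ enrichment: the
cylindrical chamber volume and culture area, medium volume per cell relative
to a reference vessel, the interstitial volume fraction of a planar packed
cell layer, and the concentration a measured secreted factor would reach if
confined to the interstitial fraction of a tumor volume.

All formulas are exposed parametrically; no literature-specific constant is
hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

SQUARE_PACKING = math.pi / 4            # circle packing density, square lattice
HEXAGONAL_PACKING = math.pi / (2 * math.sqrt(3))


@dataclass(frozen=True)
class ChamberGeometry:
    """A shallow cylindrical culture chamber."""

    diameter_mm: float
    height_um: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.height_um < 0:
            raise ValueError("diameter must be > 0 and height >= 0")


def chamber_volume(geom: ChamberGeometry) -> float:
    """Chamber volume in uL (= mm^3): pi (d/2)^2 h."""
    radius_mm = geom.diameter_mm / 2
    height_mm = geom.height_um / 1000
    return math.pi * radius_mm ** 2 * height_mm


def chamber_area(geom: ChamberGeometry) -> float:
    """Culture surface area in cm^2."""
    radius_cm = geom.diameter_mm / 20
    return math.pi * radius_cm ** 2


def medium_per_cell(volume_uL: float, n_cells: float) -> float:
    """Medium volume per cell, uL/cell."""
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    return volume_uL / n_cells


def dilution_ratio(volume_uL: float, n_cells: float,
                   ref_volume_uL: float, ref_n_cells: float) -> float:
    """How many times more medium per cell a reference vessel provides.

    Both vessels' volume and cell count are explicit inputs; a ratio of ~100
    corresponds to a 100-fold concentration advantage of the smaller vessel.
    """
    return medium_per_cell(ref_volume_uL, ref_n_cells) / medium_per_cell(volume_uL, n_cells)


@dataclass(frozen=True)
class CellPackingGeometry:
    """Cells modeled as cylinders on a planar lattice.

    ``layer_height_um`` is the slab thickness over which the fraction is
    computed; by default it equals the cell height, i.e. the cells span the
    whole layer.
    """

    cell_diameter_um: float = 17.5
    cell_height_um: float = 10.0
    gap_um: float = 2.0
    packing: Literal["square", "hexagonal"] = "square"
    layer_height_um: float | None = None

    def __post_init__(self) -> None:
        if self.cell_diameter_um <= 0 or self.cell_height_um <= 0:
            raise ValueError("cell dimensions must be > 0")
        if self.gap_um < 0:
            raise ValueError("gap must be >= 0")
        if self.packing not in ("square", "hexagonal"):
            raise ValueError("packing must be 'square' or 'hexagonal'")
        if self.layer_height_um is None:
            object.__setattr__(self, "layer_height_um", self.cell_height_um)
        elif self.layer_height_um < self.cell_height_um:
            raise ValueError("layer_height_um must be >= cell_height_um")


def interstitial_fraction(geom: CellPackingGeometry) -> float:
    """Volume fraction of a packed cell layer not occupied by cells.

    Planar circle-packing density of disks of diameter d on a lattice of
    pitch d + gap, scaled by the height occupancy of the layer:

        fraction = 1 - rho_packing * (d / (d + gap))^2 * h_cell / h_layer
    """
    rho = SQUARE_PACKING if geom.packing == "square" else HEXAGONAL_PACKING
    areal = rho * (geom.cell_diameter_um / (geom.cell_diameter_um + geom.gap_um)) ** 2
    occupancy = geom.cell_height_um / geom.layer_height_um
    return 1.0 - areal * occupancy


@dataclass(frozen=True)
class TMEEstimate:
    interstitial_fraction: float
    tme_concentration: float  # ng/mL
    enrichment_factor: float


def tme_concentration(measured_ng_mL: float, assay_volume_uL: float,
                      tumor_volume_uL: float, fraction: float) -> TMEEstimate:
    """Concentration a secreted factor reaches when confined to the TME.

    The total mass found in the assay volume is assumed to originate from the
    interstitial fraction of the tumor volume, so

        C_tme = measured * assay_volume / (fraction * tumor_volume)

    and the enrichment factor is C_tme / measured.  Mass is conserved
    exactly: C_tme * fraction * tumor_volume = measured * assay_volume.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if measured_ng_mL < 0 or assay_volume_uL <= 0 or tumor_volume_uL <= 0:
        raise ValueError("volumes must be > 0 and concentration >= 0")
    conc = measured_ng_mL * assay_volume_uL / (fraction * tumor_volume_uL)
    return TMEEstimate(
        interstitial_fraction=fraction,
        tme_concentration=conc,
        enrichment_factor=conc / measured_ng_mL if measured_ng_mL > 0 else math.inf,
    )
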