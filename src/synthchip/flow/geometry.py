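"""Static-droplet-array geometry and its rasterization.

One SDA unit occupies a ``pitch x pitch`` tile (3.16 µm, matching the
electrode pitch).  A seam corridor (height = ``mouth_width``) runs
along the top of the reaction chamber, a pocket that opens onto the
corridor over its full width; the neck rises from the corridor's
upstream corner into the bypass top leg, which crosses the tile and
descends at the far side into the next unit's seam junction; and an
oil drain — the 0.2 µm capillary valve at the chamber's bottom corner
plus a neck-width slot back up to the seam — vents the chamber while
it fills.

The capillary logic at the operating conditions (water non-wetting at
135 deg, Ca ~ 1e-4): the advancing aqueous front pours into the
chamber first (widest opening, lowest entry barrier) while the
displaced oil escapes through the drain; when the front seals the
drain, the pressure rises until the neck admits the water into the
bypass and the filling moves one unit downstream.  When the plug tail
recedes, the oil through-path hugs the cavity's top strip, the thread
severs there, and the chamber keeps a stationary droplet.  Units in a
row are chained in series; rows are parallel chains fed by a common
injection channel, adjacent rows mirrored about the x-axis.

Rasterization snaps every feature edge to the uniform grid (default 32
cells per pitch, ~0.1 µm cells; 64 in the fine mode), so halving the
cell size reproduces the identical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = ["SDAGeometry", "DomainRaster", "build_geometry", "make_box_domain",
           "make_channel_domain"]

SOLID, FLUID = 0, 1


@dataclass(frozen=True)
class SDAGeometry:
    """SDA unit-array dimensions (µm) and array layout."""

    unit_pitch: float = 3.16
    valve_width: float = 0.2
    chamber_width: float = 1.78
    chamber_height: float = 1.3
    neck_width: float = 0.3
    channel_width: float = 0.6
    mouth_width: float = 0.4
    bypass_width: float = 0.4
    wall_thickness: float = 0.2
    n_units_x: int = 4
    n_units_y: int = 4
    mirrored: bool = True
    cells_per_pitch: int = 32

    def __post_init__(self) -> None:
        dims = (
            self.unit_pitch, self.valve_width, self.chamber_width,
            self.chamber_height, self.neck_width, self.channel_width,
            self.mouth_width, self.bypass_width, self.wall_thickness,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all geometry dimensions must be positive")
        if not self.valve_width < self.neck_width < self.channel_width:
            raise ValueError(
                "capillary barrier ordering requires "
                "valve_width < neck_width < channel_width"
            )
        if self.mouth_width <= self.neck_width:
            raise ValueError(
                "the chamber mouth must be wider than the neck or the chamber "
                "cannot fill before the bypass path opens"
            )
        if self.n_units_x < 1 or self.n_units_y < 1:
            raise ValueError("array must contain at least one unit")
        # fit is checked on the rasterized tile (feature edges snap to cells)
        _unit_tile(self)

    @property
    def cell_um(self) -> float:
        return self.unit_pitch / self.cells_per_pitch

    @property
    def chamber_area_um2(self) -> float:
        """Rasterized chamber area (what the census normalises against)."""
        h = self.cell_um
        cx = max(1, round(self.chamber_width / h))
        cy = max(1, round(self.chamber_height / h))
        return cx * cy * h * h


@dataclass
class DomainRaster:
    """Uniform-grid realisation of a flow domain.

    ``cell_type`` is 0 (solid) / 1 (fluid) over an (ny, nx) grid that
    includes a one-cell solid ring; y index 0 is the bottom row.
    ``inlet_cells`` / ``outlet_cells`` mark fluid cells whose left/right
    face carries the velocity-inlet / pressure-outlet condition.
    """

    h: float                      # cell size, µm
    cell_type: np.ndarray         # int8 (ny, nx)
    inlet_cells: np.ndarray       # bool (ny, nx)
    outlet_cells: np.ndarray      # bool (ny, nx)
    chamber_slices: dict = field(default_factory=dict)  # (row, col) -> (sy, sx)
    cavity_slices: dict = field(default_factory=dict)   # chamber + its mouth band
    plug_x: tuple[int, int] | None = None  # initial dispersed plug columns
    inj_x: tuple[int, int] | None = None   # injection-channel columns
    valve_cells: np.ndarray | None = None  # bool: capillary-valve passages
    neck_cells: np.ndarray | None = None   # bool: neck (bypass-entry) passages
    unit_of_cell: np.ndarray | None = None # int: unit id per cell (-1 outside)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_type.shape

    @property
    def fluid(self) -> np.ndarray:
        return self.cell_type == FLUID

    def fluid_area_um2(self) -> float:
        return float(self.fluid.sum()) * self.h * self.h

    def chambers(self) -> Iterator[tuple[tuple[int, int], tuple[slice, slice]]]:
        yield from self.chamber_slices.items()


def _cells(dim_um: float, h: float) -> int:
    return max(1, round(dim_um / h))


def _unit_tile(
    geom: SDAGeometry,
) -> tuple:
    """Rasterized fluid pattern of one upright unit plus its reaction-
    chamber and capillary-valve slices.

    Layout (upright; mirrored rows are flipped vertically; flow +x):

    * the seam corridor (height = mouth_width) runs along the top of the
      cavity from the tile seam; below it, open over its full width,
      lies the reaction chamber (the pocket the droplet ends up in);
    * the capillary valve (0.2 µm) pierces the chamber's bottom-right
      wall into a neck-width drain slot rising to the seam junction: it
      vents the displaced oil while the chamber fills from the top down
      and is the last place the aqueous front reaches, then shuts
      (capillary check valve) so the aqueous phase never passes;
    * once the cavity is full the pressure rises until the neck -- above
      the corridor at the upstream corner -- yields and admits the
      aqueous phase into the bypass top leg, which crosses the tile roof
      and descends at the far side into the next unit's seam junction.

    When the plug tail recedes, the oil through-path (corridor -> neck
    -> bypass) hugs the cavity's top strip: the aqueous thread severs
    there and the chamber below keeps its droplet.
    """
    h = geom.cell_um
    P = geom.cells_per_pitch
    wall = _cells(geom.wall_thickness, h)
    chan = _cells(geom.channel_width, h)
    mouth = _cells(geom.mouth_width, h)
    ch_x = _cells(geom.chamber_width, h)
    ch_y = _cells(geom.chamber_height, h)
    neck = _cells(geom.neck_width, h)
    byp = _cells(geom.bypass_width, h)
    valve = _cells(geom.valve_width, h)

    tile = np.zeros((P, P), dtype=np.int8)
    y0 = wall
    band_y0 = y0 + ch_y                 # corridor/band bottom
    band_y1 = band_y0 + mouth
    # seam corridor
    tile[band_y0:band_y1, 0:chan] = FLUID
    # cavity: reaction chamber (census region) plus the band above it
    cham = (slice(y0, band_y0), slice(chan, chan + ch_x))
    cavity = (slice(y0, band_y1), slice(chan, chan + ch_x))
    tile[y0:band_y1, chan : chan + ch_x] = FLUID
    # neck above the corridor at the upstream corner
    neck_sl = (slice(band_y1, band_y1 + wall), slice(chan, chan + neck))
    tile[neck_sl] = FLUID
    # bypass top leg and down leg
    bt0 = band_y1 + wall
    tile[bt0 : bt0 + byp, chan:P] = FLUID
    tile[band_y0:bt0, P - chan : P] = FLUID
    # capillary valve at the chamber's bottom-right corner -- the last
    # spot the filling front reaches, so the displaced oil drains until
    # the chamber is completely full -- followed by a neck-width drain
    # slot rising to the seam junction.  Valve and slot together form
    # the oil drain; the aqueous phase must never enter it from either
    # end.
    valve_sl = (slice(y0, y0 + valve), slice(chan + ch_x, P - chan))
    tile[valve_sl] = FLUID
    slot_sl = (slice(y0, band_y0), slice(P - chan, P - chan + neck))
    tile[slot_sl] = FLUID

    if bt0 + byp > P - wall:
        raise ValueError("unit features do not fit inside the pitch (roof)")
    if P - chan - (chan + ch_x) < 1:
        raise ValueError("unit features do not fit inside the pitch (valve wall)")
    if neck > ch_x:
        raise ValueError("neck wider than the chamber span allows")
    if mouth > ch_x:
        raise ValueError("mouth taller than the cavity allows")
    return tile, cham, valve_sl, neck_sl, cavity, slot_sl


def build_geometry(geom: SDAGeometry | None = None) -> tuple[SDAGeometry, DomainRaster]:
    """Rasterize the full array: injection channel + n_x × n_y units +
    collection channel, wrapped in a one-cell solid ring.

    The injection channel spans the full array height (it doubles as the
    feed manifold for the parallel rows) and initially carries the
    dispersed-phase plug, sized to ~1.6x the total chamber volume.
    """
    geom = geom or SDAGeometry()
    h = geom.cell_um
    P = geom.cells_per_pitch
    tile, cham, valve_sl, neck_sl, cavity, slot_sl = _unit_tile(geom)
    n_x, n_y = geom.n_units_x, geom.n_units_y

    chan = _cells(geom.channel_width, h)
    front_gap = _cells(0.8, h)          # oil between plug and array
    tail_gap = _cells(1.6, h)           # oil between inlet and plug
    n_chamber_cells = (cham[0].stop - cham[0].start) * (cham[1].stop - cham[1].start)
    inj_height = n_y * P
    plug_len = int(np.ceil(3.0 * n_x * n_y * n_chamber_cells / inj_height))
    inj_len = tail_gap + plug_len + front_gap
    coll_len = chan

    ny = n_y * P + 2                      # +2: solid ring
    nx = inj_len + n_x * P + coll_len + 2
    cell = np.zeros((ny, nx), dtype=np.int8)

    # injection channel (full height) and collection channel
    cell[1 : ny - 1, 1 : 1 + inj_len] = FLUID
    x_sda = 1 + inj_len
    cell[1 : ny - 1, x_sda + n_x * P : nx - 1] = FLUID

    chamber_slices: dict[tuple[int, int], tuple[slice, slice]] = {}
    cavity_slices: dict[tuple[int, int], tuple[slice, slice]] = {}
    valve_cells = np.zeros_like(cell, dtype=bool)
    neck_cells = np.zeros_like(cell, dtype=bool)
    unit_of_cell = np.full(cell.shape, -1, dtype=np.int32)
    for r in range(n_y):
        flipped = geom.mirrored and r % 2 == 1
        row_tile = tile[::-1, :] if flipped else tile
        y0 = 1 + r * P
        for c in range(n_x):
            x0 = x_sda + c * P
            cell[y0 : y0 + P, x0 : x0 + P] = row_tile
            unit_of_cell[y0 : y0 + P, x0 : x0 + P] = r * n_x + c
            sy, sx = cham
            vy, vx = valve_sl
            ky, kx = neck_sl
            cy, cx = cavity
            wy, wx = slot_sl
            if flipped:
                sy = slice(P - sy.stop, P - sy.start)
                vy = slice(P - vy.stop, P - vy.start)
                ky = slice(P - ky.stop, P - ky.start)
                cy = slice(P - cy.stop, P - cy.start)
                wy = slice(P - wy.stop, P - wy.start)
            chamber_slices[(r, c)] = (
                slice(y0 + sy.start, y0 + sy.stop),
                slice(x0 + sx.start, x0 + sx.stop),
            )
            cavity_slices[(r, c)] = (
                slice(y0 + cy.start, y0 + cy.stop),
                slice(x0 + cx.start, x0 + cx.stop),
            )
            valve_cells[y0 + vy.start : y0 + vy.stop,
                        x0 + vx.start : x0 + vx.stop] = True
            valve_cells[y0 + wy.start : y0 + wy.stop,
                        x0 + wx.start : x0 + wx.stop] = True
            neck_cells[y0 + ky.start : y0 + ky.stop,
                       x0 + kx.start : x0 + kx.stop] = True

    inlet = np.zeros_like(cell, dtype=bool)
    outlet = np.zeros_like(cell, dtype=bool)
    inlet[:, 1] = cell[:, 1] == FLUID
    outlet[:, nx - 2] = cell[:, nx - 2] == FLUID

    raster = DomainRaster(
        h=h,
        cell_type=cell,
        inlet_cells=inlet,
        outlet_cells=outlet,
        chamber_slices=chamber_slices,
        cavity_slices=cavity_slices,
        plug_x=(1 + tail_gap, 1 + tail_gap + plug_len),
        inj_x=(1, 1 + inj_len),
        valve_cells=valve_cells,
        neck_cells=neck_cells,
        unit_of_cell=unit_of_cell,
    )
    return geom, raster


def make_box_domain(nx: int, ny: int, h: float) -> DomainRaster:
    """Closed all-wall box (validation runs: static droplet relaxation)."""
    cell = np.zeros((ny + 2, nx + 2), dtype=np.int8)
    cell[1:-1, 1:-1] = FLUID
    empty = np.zeros_like(cell, dtype=bool)
    return DomainRaster(h=h, cell_type=cell, inlet_cells=empty, outlet_cells=empty.copy())


def make_channel_domain(nx: int, ny: int, h: float) -> DomainRaster:
    """Straight channel with a velocity inlet (left) and pressure outlet
    (right); walls top and bottom (validation runs: Poiseuille flow)."""
    cell = np.zeros((ny + 2, nx + 2), dtype=np.int8)
    cell[1:-1, 1:-1] = FLUID
    inlet = np.zeros_like(cell, dtype=bool)
    outlet = np.zeros_like(cell, dtype=bool)
    inlet[1:-1, 1] = True
    outlet[1:-1, nx] = True
    return DomainRaster(h=h, cell_type=cell, inlet_cells=inlet, outlet_cells=outlet)
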