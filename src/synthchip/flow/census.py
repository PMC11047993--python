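"""Droplet bookkeeping: per-chamber areas, counts and confinement.

The chamber area integrates the dispersed volume fraction over the
chamber rectangle (so a half-filled chamber reports half its area);
droplets are connected components of ``phi > 0.5``, and a droplet is
*confined* when every cell of its component lies inside a single
chamber rectangle (one cell of slack allows the meniscus sitting in the
mouth/valve opening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import DomainRaster
from .solver import PhaseState

__all__ = ["DropletCensus", "droplet_census", "bypass_dispersed_area",
           "render_phi"]


@dataclass
class DropletCensus:
    """Snapshot of the dispersed phase, chamber by chamber."""

    chamber_areas_um2: np.ndarray      # (n_rows, n_cols)
    chamber_confined: np.ndarray       # bool: exactly one confined droplet
    n_droplets: int
    droplet_areas_um2: np.ndarray      # per labelled droplet
    droplet_confined: np.ndarray       # bool per droplet
    t: float = 0.0

    def column_means(self) -> np.ndarray:
        """Mean chamber area per array column (column 0 nearest the inlet)."""
        return self.chamber_areas_um2.mean(axis=0)


def droplet_census(
    state: PhaseState,
    raster: DomainRaster,
    threshold: float = 0.5,
    slack_cells: int = 1,
) -> DropletCensus:
    """Measure droplets in the current phase field."""
    h2 = raster.h * raster.h
    if raster.chamber_slices:
        n_rows = 1 + max(r for r, _ in raster.chamber_slices)
        n_cols = 1 + max(c for _, c in raster.chamber_slices)
    else:
        n_rows = n_cols = 0
    areas = np.zeros((n_rows, n_cols))
    for (r, c), (sy, sx) in raster.chamber_slices.items():
        areas[r, c] = float(state.phi[sy, sx].sum()) * h2

    blob = (state.phi > threshold) & raster.fluid
    labels, n = ndimage.label(blob)
    droplet_areas = np.zeros(n)
    confined = np.zeros(n, dtype=bool)
    owner = np.full(n, -1, dtype=int)
    if n:
        # phi-weighted area per component
        droplet_areas = ndimage.sum_labels(
            state.phi, labels, index=np.arange(1, n + 1)
        ) * h2
        polygons = raster.cavity_slices or raster.chamber_slices
        slices = ndimage.find_objects(labels)
        for k, sl in enumerate(slices):
            if sl is None:
                continue
            for ci, ((r, c), (sy, sx)) in enumerate(polygons.items()):
                if (
                    sl[0].start >= sy.start - slack_cells
                    and sl[0].stop <= sy.stop + slack_cells
                    and sl[1].start >= sx.start - slack_cells
                    and sl[1].stop <= sx.stop + slack_cells
                ):
                    confined[k] = True
                    owner[k] = r * n_cols + c
                    break

    chamber_conf = np.zeros((n_rows, n_cols), dtype=bool)
    for idx in range(n_rows * n_cols):
        mine = np.nonzero(owner == idx)[0]
        chamber_conf[idx // n_cols, idx % n_cols] = (
            mine.size == 1 and confined[mine].all()
        )
    return DropletCensus(
        chamber_areas_um2=areas,
        chamber_confined=chamber_conf,
        n_droplets=int(n),
        droplet_areas_um2=np.asarray(droplet_areas, dtype=float),
        droplet_confined=confined,
        t=state.t,
    )


def bypass_dispersed_area(state: PhaseState, raster: DomainRaster) -> float:
    """Dispersed-phase area (µm²) sitting in the bypass network.

    Counts water inside the SDA tile footprint but outside the chamber
    cavities and oil drains — i.e. in corridors, necks, bypass legs and
    seam junctions, which should be clear once the droplets are formed.
    """
    if raster.unit_of_cell is None:
        return 0.0
    region = raster.unit_of_cell >= 0
    for sy, sx in (raster.cavity_slices or raster.chamber_slices).values():
        region[sy, sx] = False
    if raster.valve_cells is not None:
        region &= ~raster.valve_cells
    region &= raster.fluid
    return float(state.phi[region].sum()) * raster.h * raster.h


def render_phi(state: PhaseState, raster: DomainRaster, path) -> None:
    """Render the dispersed-phase field to a PNG (walls masked out)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    field = state.phi.astype(float).copy()
    field[~raster.fluid] = np.nan
    fig, ax = plt.subplots(figsize=(10, 10 * field.shape[0] / field.shape[1]))
    ax.imshow(field, origin="lower", vmin=0.0, vmax=1.0, cmap="coolwarm",
              interpolation="nearest")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
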