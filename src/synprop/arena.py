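"""Geometry of micropatterned stimulatory-spot arrays.

Microcontact printing deposits circular spots of stimulatory antibody
(e.g. anti-CD3) on a square grid in an otherwise adhesive but
non-stimulatory field (ICAM-1 + CCL21).  The reference layout is a
50,625 um^2 imaging field (225 um side) carrying 64 spots of 10 um
diameter at 30 um center-to-center pitch.  Each spot can hold only a
small number of simultaneously arrested cells (about one cell per 10-um
spot, about four per 20-um spot), which is what makes the substrate a
competitive, spatially limiting stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpotGrid", "build_spot_grid", "spot_containing", "write_grid", "read_grid"]


@dataclass(frozen=True)
class SpotGrid:
    """A square grid of circular stimulatory spots in a square field.

    Parameters
    ----------
    field_side
        Side of the square field, um.
    spot_diameter
        Diameter of each circular spot, um.
    pitch
        Center-to-center spacing between adjacent spots, um.
    centers
        ``(n_spots, 2)`` array of spot-center coordinates, um, ordered
        row-major (by y, then x).  Spot ids are row indices.
    capacity
        Maximum number of simultaneously arrested cells per spot.
    """

    field_side: float
    spot_diameter: float
    pitch: float
    centers: np.ndarray = field(repr=False)
    capacity: int = 1

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "centers", centers)
        r = self.spot_radius
        if centers.size:
            inside = (centers >= r - 1e-9) & (centers <= self.field_side - r + 1e-9)
            if not inside.all():
                raise ValueError("spot centers must keep spots fully inside the field")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")

    @property
    def spot_radius(self) -> float:
        return self.spot_diameter / 2.0

    @property
    def n_spots(self) -> int:
        return len(self.centers)

    @property
    def field_area(self) -> float:
        return self.field_side**2

    @property
    def total_capacity(self) -> int:
        """Total number of arrest sites in the field."""
        return self.n_spots * self.capacity

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_spots


def build_spot_grid(
    field_area: float,
    spot_diameter: float,
    pitch: float,
    capacity: int = 1,
) -> SpotGrid:
    """Construct the square spot grid for a field of given area.

    Centers are placed at ``spot_radius + k * pitch`` along each axis for
    every integer ``k >= 0`` that keeps the spot fully inside the field,
    anchoring the first spot tangent to the field corner.  For the
    reference 50,625-um^2 field with 10-um spots at 30-um pitch this
    yields the canonical 8 x 8 = 64 spots.

    Parameters
    ----------
    field_area
        Area of the (square) imaging field, um^2.
    spot_diameter
        Spot diameter, um.
    pitch
        Center-to-center spacing, um.  Must be >= ``spot_diameter`` so
        spots do not overlap.
    capacity
        Arrested cells each spot can hold simultaneously (default 1,
        appropriate for 10-um spots; use 4 for 20-um spots).
    """
    if field_area <= 0:
        raise ValueError("field_area must be positive")
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be positive")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    if pitch < spot_diameter:
        raise ValueError(
            f"pitch ({pitch} um) smaller than spot diameter ({spot_diameter} um): "
            "spots would overlap"
        )
    if capacity < 1:
        raise ValueError("capacity must be >= 1")

    side = math.sqrt(field_area)
    r = spot_diameter / 2.0
    # number of centers per axis: r + k*pitch <= side - r
    span = side - spot_diameter
    n_axis = int(math.floor(span / pitch + 1e-9)) + 1 if span >= 0 else 0
    coords = r + pitch * np.arange(n_axis)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")  # row-major by y then x
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    return SpotGrid(
        field_side=side,
        spot_diameter=spot_diameter,
        pitch=pitch,
        centers=centers,
        capacity=capacity,
    )


def spot_containing(
    point: tuple[float, float] | np.ndarray,
    grid: SpotGrid,
    margin: float = 0.0,
) -> int | None:
    """Return the id of the spot whose footprint contains ``point``, or None.

    A point belongs to a spot if its distance to the spot center is at
    most ``spot_radius + margin``.  With non-overlapping grids at most
    one spot can contain a point for margins below ``(pitch -
    spot_diameter) / 2``; ties (exactly equidistant) resolve to the
    lowest spot id.
    """
    if grid.n_spots == 0:
        return None
    p = np.asarray(point, dtype=float)
    d2 = np.sum((grid.centers - p) ** 2, axis=1)
    i = int(np.argmin(d2))
    if d2[i] <= (grid.spot_radius + margin) ** 2 + 1e-12:
        return i
    return None


def spots_containing_points(points: np.ndarray, grid: SpotGrid, margin: float = 0.0) -> np.ndarray:
    """Vectorized :func:`spot_containing` for an ``(n, 2)`` array.

    Returns an integer array with -1 for points outside all footprints.
    Exploits the regular grid: only the nearest center can contain the
    point.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    out = np.full(len(points), -1, dtype=np.int64)
    if grid.n_spots == 0:
        return out
    r = grid.spot_radius
    coords = np.unique(grid.centers[:, 0])
    n_axis = int(round(math.sqrt(grid.n_spots)))
    # nearest grid index per axis
    kx = np.clip(np.round((points[:, 0] - r) / grid.pitch), 0, n_axis - 1).astype(np.int64)
    ky = np.clip(np.round((points[:, 1] - r) / grid.pitch), 0, n_axis - 1).astype(np.int64)
    sid = ky * n_axis + kx
    cx = grid.centers[sid]
    d2 = np.sum((points - cx) ** 2, axis=1)
    hit = d2 <= (r + margin) ** 2 + 1e-12
    out[hit] = sid[hit]
    # fall back to exhaustive search when the grid is not a perfect square
    if n_axis * n_axis != grid.n_spots or len(coords) != n_axis:
        for j, p in enumerate(points):
            s = spot_containing(p, grid, margin)
            out[j] = -1 if s is None else s
    return out


def write_grid(grid: SpotGrid, path) -> None:
    """Serialize a grid to CSV (spot_id, x_um, y_um, radius_um, capacity)."""
    df = pd.DataFrame(
        {
            "spot_id": np.arange(grid.n_spots),
            "x_um": grid.centers[:, 0],
            "y_um": grid.centers[:, 1],
            "radius_um": grid.spot_radius,
            "capacity": grid.capacity,
        }
    )
    df.attrs["field_side"] = grid.field_side
    with open(path, "w") as fh:
        fh.write(f"# field_side_um={grid.field_side:.6f} pitch_um={grid.pitch:.6f}\n")
        df.to_csv(fh, index=False)


def read_grid(path) -> SpotGrid:
    """Read a grid written by :func:`write_grid`."""
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    radius = float(df["radius_um"].iloc[0])
    return SpotGrid(
        field_side=float(meta["field_side_um"]),
        spot_diameter=2 * radius,
        pitch=float(meta["pitch_um"]),
        centers=df[["x_um", "y_um"]].to_numpy(),
        capacity=int(df["capacity"].iloc[0]),
    )
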