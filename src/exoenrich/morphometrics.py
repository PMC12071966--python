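"""Cell-spreading morphometrics via minimum enclosing circles.

A freshly seeded cell is nearly round; after days of spreading it extends
appendages, and the smallest circle that still covers its outline grows with
the reach of those appendages.  The tortuosity index of a culture is the
ratio of the mean enclosing-circle area at a later time point to the mean at
a reference time point; 1 means no shape change, k^2 under uniform k-fold
elongation.

The minimum enclosing circle is computed with Welzl's move-to-front
algorithm (expected linear time with a deterministic shuffle); the circle is
exact for its 2- or 3-point support set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


class Circle(NamedTuple):
    center: tuple[float, float]
    radius: float

    @property
    def area(self) -> float:
        return math.pi * self.radius ** 2

    def contains(self, points, tol: float = 1e-9) -> bool:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return bool(np.all(d <= self.radius + tol))


@dataclass(frozen=True)
class CellOutline:
    """A planar polygonal outline of one cell (vertex coordinates in um)."""

    cell_id: str
    vertices: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("outline needs at least 3 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ValueError("outline vertices must be finite")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class TortuosityResult:
    mean_area_ref: float  # um^2
    mean_area_t: float
    index: float
    n_ref: int
    n_t: int

    def to_dict(self) -> dict:
        return {
            "mean_area_ref_um2": self.mean_area_ref,
            "mean_area_t_um2": self.mean_area_t,
            "tortuosity_index": self.index,
            "n_cells_ref": self.n_ref,
            "n_cells_t": self.n_t,
        }


def _circle_two(a, b) -> Circle:
    cx, cy = (a[0] + b[0]) / 2, (a[1] + b[1]) / 2
    return Circle((cx, cy), math.hypot(a[0] - cx, a[1] - cy))


def _circle_three(a, b, c) -> Circle | None:
    """Circumcircle of three points; None when (near-)collinear."""
    ax, ay = a
    bx, by = b[0] - ax, b[1] - ay
    cx, cy = c[0] - ax, c[1] - ay
    d = 2 * (bx * cy - by * cx)
    if d == 0:
        return None
    ux = (cy * (bx * bx + by * by) - by * (cx * cx + cy * cy)) / d
    uy = (bx * (cx * cx + cy * cy) - cx * (bx * bx + by * by)) / d
    return Circle((ax + ux, ay + uy), math.hypot(ux, uy))


def min_enclosing_circle(points) -> Circle:
    """Smallest circle containing every point (Welzl, move-to-front).

    The input order is randomized with a fixed-seed permutation, making the
    run deterministic while keeping the expected-linear behavior.  Degenerate
    inputs are handled: a single point yields a radius-0 circle, collinear
    points the diameter circle of their extremes.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    pts = [tuple(p) for p in pts]
    if len(pts) == 1:
        return Circle(pts[0], 0.0)
    rng = np.random.default_rng(0)
    pts = [pts[i] for i in rng.permutation(len(pts))]

    circle = None
    for i, p in enumerate(pts):
        if circle is not None and circle.contains(p):
            continue
        # p is on the boundary of the circle over pts[:i+1]
        circle = Circle(p, 0.0)
        for j, q in enumerate(pts[:i]):
            if circle.contains(q):
                continue
            # p and q both on the boundary
            circle = _circle_two(p, q)
            for r in pts[:j]:
                if circle.contains(r):
                    continue
                c3 = _circle_three(p, q, r)
                if c3 is None:  # collinear support: widest diameter circle
                    c3 = max(
                        (_circle_two(p, q), _circle_two(p, r), _circle_two(q, r)),
                        key=lambda c: c.radius,
                    )
                circle = c3
    return circle


def tortuosity_index(day_ref: Sequence[CellOutline],
                     day_t: Sequence[CellOutline]) -> TortuosityResult:
    """Ratio of mean enclosing-circle areas, later group over reference group.

    Group means of per-cell areas are used (not matched per-cell pairs); the
    two groups may differ in size.
    """
    if not day_ref or not day_t:
        raise ValueError("both outline groups must be non-empty")
    areas_ref = [min_enclosing_circle(o.vertices).area for o in day_ref]
    areas_t = [min_enclosing_circle(o.vertices).area for o in day_t]
    mean_ref = float(np.mean(areas_ref))
    mean_t = float(np.mean(areas_t))
    return TortuosityResult(
        mean_area_ref=mean_ref, mean_area_t=mean_t,
        index=mean_t / mean_ref, n_ref=len(areas_ref), n_t=len(areas_t),
    )


def read_outlines_csv(path) -> list[CellOutline]:
    """Read outlines from a ``cell_id,x_um,y_um`` CSV (vertex order kept)."""
    df = pd.read_csv(Path(path))
    required = {"cell_id", "x_um", "y_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"outline CSV needs columns {sorted(required)}")
    outlines = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        outlines.append(CellOutline(str(cell_id), grp[["x_um", "y_um"]].to_numpy()))
    return outlines


def write_outlines_csv(outlines: Sequence[CellOutline], path) -> None:
    frames = [
        pd.DataFrame({"cell_id": o.cell_id, "x_um": o.vertices[:, 0],
                      "y_um": o.vertices[:, 1]})
        for o in outlines
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
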