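"""Rotatable two-factor central composite designs with coded/actual transforms.

A central composite design (CCD) for two factors consists of a 2x2 factorial
(coded levels +/-1), four axial points at coded distance alpha, and replicated
center points.  The design is *rotatable* when alpha equals the fourth root of
the number of factorial runs, i.e. alpha = 4**(1/4) = sqrt(2) for two factors,
which places every non-center point on a circle of coded radius sqrt(2).

Coded units are related to actual units by a linear map with

    step = axial_halfrange / alpha

so that the axial points sit exactly at ``center +/- axial_halfrange`` and the
factorial points at ``center +/- axial_halfrange/alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ALPHA_TWO_FACTOR = math.sqrt(2.0)

#: canonical coded levels of a rotatable two-factor CCD
_CANONICAL_LEVELS = (-ALPHA_TWO_FACTOR, -1.0, 0.0, 1.0, ALPHA_TWO_FACTOR)

#: tolerance (coded units) for snapping printed/rounded actual levels back to
#: the canonical coded levels when reading a design from CSV
SNAP_TOL = 0.05

DESIGN_COLUMNS = ("run", "time_h", "volume_uL")
RESPONSE_COLUMNS = ("cell_per_mm2", "exosome_1e3_per_uL", "glucose_mg_dL")


class DesignError(ValueError):
    """Invalid design construction."""


class DesignParseError(ValueError):
    """A design CSV could not be parsed."""


@dataclass(frozen=True)
class Factor:
    """One controllable factor of the experiment.

    Parameters
    ----------
    name, unit
        Label and physical unit, e.g. ``("time", "h")``.
    center
        Actual value at coded 0.
    axial_halfrange
        Actual distance from the center to the axial (star) points, i.e. the
        half-width of the whole explored range.
    display_precision
        Decimal places used when actual levels are printed.
    """

    name: str
    unit: str
    center: float
    axial_halfrange: float
    display_precision: int = 2

    def __post_init__(self) -> None:
        if not math.isfinite(self.center):
            raise DesignError(f"factor {self.name!r}: center must be finite")
        if not (self.axial_halfrange > 0 and math.isfinite(self.axial_halfrange)):
            raise DesignError(f"factor {self.name!r}: axial_halfrange must be > 0")

    def step(self, alpha: float = ALPHA_TWO_FACTOR) -> float:
        """Actual units per coded unit."""
        return self.axial_halfrange / alpha


# The factor ranges used for the microbioreactor medium-exchange study:
# exchange interval 5-15 h, exchange volume 150-400 uL.
TIME_FACTOR = Factor("time", "h", center=10.0, axial_halfrange=5.0)
VOLUME_FACTOR = Factor("volume", "uL", center=275.0, axial_halfrange=125.0, display_precision=0)


def coded_to_actual(factor: Factor, x, alpha: float = ALPHA_TWO_FACTOR):
    """Map coded value(s) ``x`` to actual units for ``factor``."""
    return factor.center + np.asarray(x, dtype=float) * factor.step(alpha)


def actual_to_coded(factor: Factor, value, alpha: float = ALPHA_TWO_FACTOR):
    """Inverse of :func:`coded_to_actual`."""
    return (np.asarray(value, dtype=float) - factor.center) / factor.step(alpha)


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    coded: tuple[float, float]
    actual: tuple[float, float]
    point_class: str  # "factorial" | "axial" | "center"

    def __post_init__(self) -> None:
        if self.point_class not in ("factorial", "axial", "center"):
            raise DesignError(f"unknown point class {self.point_class!r}")


def _classify(coded: tuple[float, float], alpha: float, tol: float) -> str:
    x1, x2 = coded
    if abs(x1) <= tol and abs(x2) <= tol:
        return "center"
    if abs(abs(x1) - 1) <= tol and abs(abs(x2) - 1) <= tol:
        return "factorial"
    if (abs(x1) <= tol and abs(abs(x2) - alpha) <= tol) or (
        abs(x2) <= tol and abs(abs(x1) - alpha) <= tol
    ):
        return "axial"
    raise DesignParseError(f"coded point {coded} matches no CCD point class")


def _snap(x: float, tol: float) -> float:
    for level in _CANONICAL_LEVELS:
        if abs(x - level) <= tol:
            return level
    return x


@dataclass
class DesignMatrix:
    """A CCD with (optionally) aligned response vectors.

    ``responses`` maps a response name to a vector with exactly one value per
    design point, in run order.
    """

    factors: tuple[Factor, Factor]
    points: list[DesignPoint]
    alpha: float = ALPHA_TWO_FACTOR
    n_center: int = 0
    responses: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.points)
        for name, vec in self.responses.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise DesignError(
                    f"response {name!r} has {vec.size} values for {n} design points"
                )
            self.responses[name] = vec

    @property
    def n_runs(self) -> int:
        return len(self.points)

    def coded_array(self) -> np.ndarray:
        return np.array([p.coded for p in self.points], dtype=float)

    def actual_array(self) -> np.ndarray:
        return np.array([p.actual for p in self.points], dtype=float)

    def response(self, name: str) -> np.ndarray:
        try:
            return self.responses[name]
        except KeyError:
            raise KeyError(
                f"response {name!r} not present; have {sorted(self.responses)}"
            ) from None

    def with_responses(self, **responses) -> "DesignMatrix":
        merged = dict(self.responses)
        merged.update({k: np.asarray(v, dtype=float) for k, v in responses.items()})
        return DesignMatrix(self.factors, list(self.points), self.alpha, self.n_center, merged)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "run": [p.run_id for p in self.points],
                "time_h": [p.actual[0] for p in self.points],
                "volume_uL": [p.actual[1] for p in self.points],
            }
        )
        for name, vec in self.responses.items():
            df[name] = vec
        return df


def make_rotatable_ccd(
    factors: Sequence[Factor], n_center: int, round_display: bool = False
) -> DesignMatrix:
    """Build a rotatable two-factor CCD in standard order.

    Standard order is the four factorial points (-,-), (+,-), (-,+), (+,+),
    then the axial points (-a,0), (+a,0), (0,-a), (0,+a), then ``n_center``
    center replicates.

    With ``round_display`` the actual levels are rounded to each factor's
    ``display_precision`` (the form a lab protocol would print); coded levels
    stay exact either way.
    """
    if len(factors) != 2:
        raise DesignError("only two-factor designs are supported")
    if n_center < 1:
        raise DesignError("n_center must be >= 1")
    f1, f2 = factors
    alpha = 4 ** 0.25  # fourth root of the factorial run count
    coded_points = [
        (-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0),
        (-alpha, 0.0), (alpha, 0.0), (0.0, -alpha), (0.0, alpha),
    ] + [(0.0, 0.0)] * n_center
    points = []
    for i, (x1, x2) in enumerate(coded_points, start=1):
        a1 = float(coded_to_actual(f1, x1, alpha))
        a2 = float(coded_to_actual(f2, x2, alpha))
        if round_display:
            a1 = round(a1, f1.display_precision)
            a2 = round(a2, f2.display_precision)
        points.append(
            DesignPoint(
                run_id=i,
                coded=(x1, x2),
                actual=(a1, a2),
                point_class=_classify((x1, x2), alpha, 1e-12),
            )
        )
    return DesignMatrix((f1, f2), points, alpha=alpha, n_center=n_center)


def infer_factors(time_values, volume_values) -> tuple[Factor, Factor]:
    """Infer factor center/halfrange from the actual levels of a full CCD.

    In a CCD the axial points span the full explored range, so the center is
    the midpoint of the observed extremes and the axial halfrange is half the
    observed span.
    """
    t, v = np.asarray(time_values, float), np.asarray(volume_values, float)
    return (
        replace(TIME_FACTOR, center=float((t.max() + t.min()) / 2),
                axial_halfrange=float((t.max() - t.min()) / 2)),
        replace(VOLUME_FACTOR, center=float((v.max() + v.min()) / 2),
                axial_halfrange=float((v.max() - v.min()) / 2)),
    )


def read_design_csv(path, factors: tuple[Factor, Factor] | None = None,
                    snap_tol: float = SNAP_TOL) -> DesignMatrix:
    """Read a design (and any response columns) from CSV.

    The CSV must have header ``run,time_h,volume_uL``; any further numeric
    columns are read as responses.  Coded levels are recovered through the
    factor transforms and snapped to the canonical CCD levels within
    ``snap_tol`` coded units, which absorbs display rounding of printed actual
    levels (e.g. a printed 186 uL versus the exact 186.6 uL factorial level).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DesignParseError(f"{path}: empty design file") from None
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise DesignParseError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.loc[pd.to_numeric(df[col], errors="coerce").isna(), col]
            raise DesignParseError(
                f"{path}: non-numeric values in column {col!r}: {bad.tolist()[:3]}"
            )
    if df["run"].duplicated().any():
        dupes = sorted(df.loc[df["run"].duplicated(), "run"].unique().tolist())
        raise DesignParseError(f"{path}: duplicate run ids {dupes}")

    if factors is None:
        factors = infer_factors(df["time_h"], df["volume_uL"])
    f1, f2 = factors
    alpha = ALPHA_TWO_FACTOR
    points = []
    n_center = 0
    for _, row in df.iterrows():
        x1 = _snap(float(actual_to_coded(f1, row["time_h"], alpha)), snap_tol)
        x2 = _snap(float(actual_to_coded(f2, row["volume_uL"], alpha)), snap_tol)
        cls = _classify((x1, x2), alpha, snap_tol)
        n_center += cls == "center"
        points.append(
            DesignPoint(int(row["run"]), (x1, x2),
                        (float(row["time_h"]), float(row["volume_uL"])), cls)
        )
    responses = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in DESIGN_COLUMNS
    }
    return DesignMatrix((f1, f2), points, alpha=alpha, n_center=n_center,
                        responses=responses)


def write_design_csv(design: DesignMatrix, path) -> None:
    design.to_dataframe().to_csv(path, index=False)
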