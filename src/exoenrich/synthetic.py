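"""Seeded synthetic inputs matching the structure the analysis assumes.

Two generators:

* CCD response datasets — the 13-run rotatable design evaluated under known
  coded-unit polynomial coefficients plus i.i.d. Gaussian noise.  The default
  truth is the set of surfaces fitted to the bundled experimental design
  (re-derived at call time, never hard-coded) and the default noise SDs are
  the sample SDs of its five center replicates — the only replication
  information the study provides.

* Cell outlines — polygonal ellipse outlines with controllable elongation,
  random rotation/translation and vertex jitter, for exercising the
  enclosing-circle morphometrics.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import datasets
from .design import TIME_FACTOR, VOLUME_FACTOR, DesignMatrix, Factor, make_rotatable_ccd
from .morphometrics import CellOutline
from .rsm import TERMS, default_model_spec, fit_surface, _term_columns


def derived_truth_coefficients() -> dict[str, dict[str, float]]:
    """Coded-unit coefficients of the surfaces fitted to the bundled design.

    These are derived model fits (full quadratic for exosome content,
    first-order for cell density and glucose), not quantities reported by
    the study itself.
    """
    design = datasets.load_enrichment_design()
    return {
        name: fit_surface(design, name, default_model_spec(name)).coefficients
        for name in design.responses
    }


@dataclass(frozen=True)
class SyntheticCCDSpec:
    """Truth coefficients (coded units) and noise SD per response.

    ``coefficients`` maps response name -> {term: value} over the canonical
    term basis; missing terms are zero.  Defaults are the derived fits and
    center-replicate SDs of the bundled design.
    """

    coefficients: dict[str, dict[str, float]] = field(default_factory=derived_truth_coefficients)
    noise_sd: dict[str, float] = field(default_factory=datasets.center_replicate_sd)
    n_center: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {name!r} must be >= 0")


def synth_ccd(spec: SyntheticCCDSpec,
              factors: tuple[Factor, Factor] = (TIME_FACTOR, VOLUME_FACTOR)) -> DesignMatrix:
    """Generate a CCD dataset from known coefficients plus Gaussian noise."""
    design = make_rotatable_ccd(factors, n_center=spec.n_center)
    coded = design.coded_array()
    X = _term_columns(coded, TERMS)
    rng = np.random.default_rng(spec.seed)
    responses = {}
    for name, coefs in spec.coefficients.items():
        beta = np.array([coefs.get(t, 0.0) for t in TERMS])
        y = X @ beta
        sd = spec.noise_sd.get(name, 0.0)
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=y.shape)
        responses[name] = y
    return design.with_responses(**responses)


@dataclass(frozen=True)
class SyntheticOutlineSpec:
    """Polygonal ellipse outlines: semi-axes (base_radius * elongation,
    base_radius), randomly rotated and translated, with optional radial
    vertex jitter."""

    n_cells: int = 30
    base_radius_um: float = 9.0
    elongation: float = 1.0
    n_vertices: int = 48
    jitter_sd_um: float = 0.0
    field_um: float = 500.0  # side of the square field centers are drawn from
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if self.n_vertices < 8:
            raise ValueError("n_vertices must be >= 8")
        if self.n_cells < 1 or self.base_radius_um <= 0 or self.jitter_sd_um < 0:
            raise ValueError("invalid outline spec")


def synth_outlines(spec: SyntheticOutlineSpec) -> list[CellOutline]:
    """Generate seeded cell outlines of controlled elongation."""
    rng = np.random.default_rng(spec.seed)
    a = spec.base_radius_um * spec.elongation  # semi-major
    b = spec.base_radius_um                    # semi-minor
    phis = np.linspace(0.0, 2 * np.pi, spec.n_vertices, endpoint=False)
    outlines = []
    for i in range(spec.n_cells):
        theta = rng.uniform(0, 2 * np.pi)
        cx, cy = rng.uniform(0, spec.field_um, size=2)
        x = a * np.cos(phis)
        y = b * np.sin(phis)
        if spec.jitter_sd_um > 0:
            r = np.hypot(x, y)
            scale = 1 + rng.normal(0.0, spec.jitter_sd_um, size=r.shape) / r
            x, y = x * scale, y * scale
        xr = cx + x * np.cos(theta) - y * np.sin(theta)
        yr = cy + x * np.sin(theta) + y * np.cos(theta)
        outlines.append(CellOutline(f"cell{i:03d}", np.column_stack([xr, yr])))
    return outlines
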