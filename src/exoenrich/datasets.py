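"""Bundled example data: the 13-run medium-exchange optimization design.

The packaged CSV holds the experimental design matrix of the microbioreactor
medium-optimization study: a rotatable two-factor CCD over medium-exchange
interval (5-15 h) and exchanged volume (150-400 uL) with five center
replicates, and the three measured responses (adherent cell density per mm^2,
exosome concentration in 10^3 exosomes/uL, and residual glucose in mg/dL).

Actual factor levels are stored as printed in the study protocol (e.g. the
volume factorial levels appear as the rounded 186/363 uL rather than the
exact 186.6/363.4 uL); model fitting operates in coded units, so display
rounding never reaches the regression.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .design import TIME_FACTOR, VOLUME_FACTOR, DesignMatrix, read_design_csv

#: canonical response column names of the bundled design
CELL = "cell_per_mm2"
EXOSOME = "exosome_1e3_per_uL"
GLUCOSE = "glucose_mg_dL"
RESPONSES = (CELL, EXOSOME, GLUCOSE)


def design_csv_path():
    """Path-like handle on the packaged design CSV."""
    return resources.files("exoenrich.data") / "enrichment_design.csv"


def load_enrichment_design() -> DesignMatrix:
    """Load the bundled 13-run design with its three response vectors."""
    with resources.as_file(design_csv_path()) as p:
        return read_design_csv(p, factors=(TIME_FACTOR, VOLUME_FACTOR))


def center_replicate_sd(design: DesignMatrix | None = None) -> dict[str, float]:
    """Sample SD of each response over the center replicates (pure-error scale).

    These are the only replicated runs in the design and anchor the noise
    level of the synthetic-data generator.
    """
    if design is None:
        design = load_enrichment_design()
    center = np.array([p.point_class == "center" for p in design.points])
    return {
        name: float(np.std(vec[center], ddof=1))
        for name, vec in design.responses.items()
    }
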