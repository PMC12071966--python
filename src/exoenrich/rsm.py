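"""Response-surface fitting in coded units.

Responses are modeled as low-order polynomials in the coded factors,

    Y = b0 + sum_i b_i X_i + sum_i b_ii X_i^2 + sum_{i<j} b_ij X_i X_j,

estimated by ordinary least squares on the coded design columns.  Fitting in
coded units is the DOE convention: the factorial/axial structure makes the
linear columns orthogonal to the intercept, and display rounding of actual
levels cannot perturb the coefficients.

Default model forms per response of the bundled design: the exosome response
uses the full second-order polynomial (its surface is strongly curved and has
a large interaction), while cell density and glucose use first-order models —
the forms whose fitted values reproduce the study's predictive columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import ALPHA_TWO_FACTOR, DesignMatrix, Factor, actual_to_coded

#: canonical term order of the full second-order model
TERMS = ("intercept", "x1", "x2", "x1:x2", "x1^2", "x2^2")

FIRST_ORDER_TERMS = ("intercept", "x1", "x2")


class FitError(ValueError):
    """Model cannot be fitted to the design."""


class RankDeficiencyError(FitError):
    """The model columns are collinear on this design."""


@dataclass(frozen=True)
class ModelSpec:
    """Which polynomial terms enter the surface for one response."""

    response_name: str
    terms: tuple[str, ...] = TERMS

    def __post_init__(self) -> None:
        unknown = [t for t in self.terms if t not in TERMS]
        if unknown:
            raise FitError(f"unknown terms {unknown}; allowed: {list(TERMS)}")
        if "intercept" not in self.terms:
            raise FitError("the intercept term is always required")
        # normalize to canonical order
        object.__setattr__(
            self, "terms", tuple(t for t in TERMS if t in self.terms)
        )

    @classmethod
    def first_order(cls, response_name: str) -> "ModelSpec":
        return cls(response_name, FIRST_ORDER_TERMS)

    @classmethod
    def full_quadratic(cls, response_name: str) -> "ModelSpec":
        return cls(response_name, TERMS)


def default_model_spec(response_name: str) -> ModelSpec:
    """Default per-response model form (second-order for exosome content,
    first-order for cell density and glucose)."""
    if "exosome" in response_name.lower():
        return ModelSpec.full_quadratic(response_name)
    return ModelSpec.first_order(response_name)


def _term_columns(coded: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    x1, x2 = coded[..., 0], coded[..., 1]
    cols = {
        "intercept": np.ones_like(x1),
        "x1": x1,
        "x2": x2,
        "x1:x2": x1 * x2,
        "x1^2": x1 ** 2,
        "x2^2": x2 ** 2,
    }
    return np.stack([cols[t] for t in terms], axis=-1)


@dataclass
class SurfaceFit:
    """An ordinary-least-squares polynomial surface in coded units."""

    spec: ModelSpec
    coefficients: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    r2_adj: float
    factors: tuple[Factor, Factor]
    alpha: float = ALPHA_TWO_FACTOR
    pure_error_ss: float | None = None
    lack_of_fit_ss: float | None = None
    lof_F: float | None = None
    coef_se: dict[str, float] = field(default_factory=dict)

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.spec.terms])

    def actual_unit_coefficients(self) -> dict[str, float]:
        """Re-express the polynomial in actual units (exact transform).

        With x_i = (a_i - c_i)/s_i, expanding the coded polynomial gives the
        actual-unit coefficients in the same term basis.
        """
        c1, c2 = (f.center for f in self.factors)
        s1, s2 = (f.step(self.alpha) for f in self.factors)
        b = {t: self.coefficients.get(t, 0.0) for t in TERMS}
        out = {
            "intercept": (
                b["intercept"] - b["x1"] * c1 / s1 - b["x2"] * c2 / s2
                + b["x1:x2"] * c1 * c2 / (s1 * s2)
                + b["x1^2"] * c1 ** 2 / s1 ** 2 + b["x2^2"] * c2 ** 2 / s2 ** 2
            ),
            "x1": b["x1"] / s1 - b["x1:x2"] * c2 / (s1 * s2) - 2 * b["x1^2"] * c1 / s1 ** 2,
            "x2": b["x2"] / s2 - b["x1:x2"] * c1 / (s1 * s2) - 2 * b["x2^2"] * c2 / s2 ** 2,
            "x1:x2": b["x1:x2"] / (s1 * s2),
            "x1^2": b["x1^2"] / s1 ** 2,
            "x2^2": b["x2^2"] / s2 ** 2,
        }
        return {t: out[t] for t in self.spec.terms}

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response_name,
            "terms": list(self.spec.terms),
            "coefficients_coded": self.coefficients,
            "fitted": self.fitted.tolist(),
            "residuals": self.residuals.tolist(),
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "pure_error_ss": self.pure_error_ss,
            "lack_of_fit_ss": self.lack_of_fit_ss,
            "lof_F": self.lof_F,
        }


def fit_surface(design: DesignMatrix, response_name: str,
                spec: ModelSpec | None = None) -> SurfaceFit:
    """Fit one response surface by OLS on the coded design columns."""
    y = design.response(response_name)
    if spec is None:
        spec = default_model_spec(response_name)
    coded = design.coded_array()
    X = _term_columns(coded, spec.terms)
    n, p = X.shape
    if n <= p:
        raise FitError(
            f"{n} runs cannot identify {p} terms; need more runs than terms"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending terms: those whose removal restores full rank
        collinear = [
            t for i, t in enumerate(spec.terms)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise RankDeficiencyError(
            f"design cannot separate terms {collinear} for response "
            f"{response_name!r}"
        )
    res = sm.OLS(y, X).fit()
    fitted = np.asarray(res.fittedvalues)
    fit = SurfaceFit(
        spec=spec,
        coefficients=dict(zip(spec.terms, res.params)),
        fitted=fitted,
        residuals=y - fitted,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        factors=design.factors,
        alpha=design.alpha,
        coef_se=dict(zip(spec.terms, res.bse)),
    )
    center = np.array([p_.point_class == "center" for p_ in design.points])
    if center.sum() >= 2:
        yc = y[center]
        pe = float(np.sum((yc - yc.mean()) ** 2))
        resid_ss = float(np.sum(fit.residuals ** 2))
        lof = max(resid_ss - pe, 0.0)
        fit.pure_error_ss = pe
        fit.lack_of_fit_ss = lof
        df_pe = int(center.sum()) - 1
        df_lof = (n - p) - df_pe
        if df_lof > 0 and pe > 0:
            fit.lof_F = (lof / df_lof) / (pe / df_pe)
    return fit


def predict(fit: SurfaceFit, points, coded: bool = True,
            warn_extrapolation: bool = True) -> np.ndarray:
    """Evaluate the fitted polynomial at ``points`` (shape (..., 2)).

    Actual-unit inputs are converted through the factor transforms first.
    Points outside the design's coded radius sqrt(2) are extrapolations and
    trigger a warning (the values are still returned).
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not coded:
        f1, f2 = fit.factors
        pts = np.stack(
            [actual_to_coded(f1, pts[..., 0], fit.alpha),
             actual_to_coded(f2, pts[..., 1], fit.alpha)],
            axis=-1,
        )
    if warn_extrapolation:
        radii = np.linalg.norm(pts, axis=-1)
        if np.any(radii > fit.alpha + 1e-9):
            warnings.warn(
                "evaluating the surface outside the design region "
                f"(coded radius > {fit.alpha:.4g})",
                stacklevel=2,
            )
    out = _term_columns(pts, fit.spec.terms) @ fit.coef_vector
    return float(out[0]) if squeeze and np.ndim(out) else out


def anova(fit: SurfaceFit, design: DesignMatrix) -> pd.DataFrame:
    """ANOVA decomposition with lack-of-fit / pure-error split.

    Total (corrected) SS splits into model and residual; the residual splits
    into lack of fit and pure error, the latter estimated from the center
    replicates only.  F ratios are reported; no significance thresholding is
    applied.
    """
    y = design.response(fit.spec.response_name)
    n = y.size
    p = len(fit.spec.terms)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_resid = float(np.sum(fit.residuals ** 2))
    ss_model = ss_total - ss_resid
    df_model, df_resid = p - 1, n - p
    center = np.array([pt.point_class == "center" for pt in design.points])
    rows = [
        ("model", ss_model, df_model),
        ("residual", ss_resid, df_resid),
    ]
    if center.sum() >= 2:
        yc = y[center]
        ss_pe = float(np.sum((yc - yc.mean()) ** 2))
        df_pe = int(center.sum()) - 1
        rows.append(("lack_of_fit", max(ss_resid - ss_pe, 0.0), df_resid - df_pe))
        rows.append(("pure_error", ss_pe, df_pe))
    else:
        warnings.warn("fewer than 2 center replicates: pure error unavailable")
    rows.append(("total", ss_total, n - 1))
    table = pd.DataFrame(rows, columns=["source", "SS", "df"])
    table["MS"] = np.where(table["df"] > 0, table["SS"] / table["df"], np.nan)
    ms = dict(zip(table["source"], table["MS"]))
    fvals = []
    for src in table["source"]:
        if src == "model" and ms.get("residual", 0) > 0:
            fvals.append(ms["model"] / ms["residual"])
        elif src == "lack_of_fit" and ms.get("pure_error", 0) > 0:
            fvals.append(ms["lack_of_fit"] / ms["pure_error"])
        else:
            fvals.append(np.nan)
    table["F"] = fvals
    return table


def range_ratio(design: DesignMatrix, response_name: str) -> dict[str, float]:
    """Max/min ratio of an *experimental* response column.

    This is the simple spread statistic quoted for each response of the
    optimization study (e.g. 6.6 for exosome content); it is computed from the
    measured values, not from a fitted surface.
    """
    y = design.response(response_name)
    lo, hi = float(y.min()), float(y.max())
    if lo <= 0:
        raise ValueError(
            f"range ratio undefined: min of {response_name!r} is {lo} <= 0"
        )
    return {"min": lo, "max": hi, "ratio": hi / lo}


def backward_eliminate(design: DesignMatrix, response_name: str,
                       spec: ModelSpec | None = None,
                       p_threshold: float = 0.05) -> SurfaceFit:
    """Optional helper: drop the largest-p term while it exceeds threshold.

    Never invoked implicitly; the default per-response model forms are fixed
    for reproducibility.  The intercept is never dropped.
    """
    if spec is None:
        spec = ModelSpec.full_quadratic(response_name)
    terms = list(spec.terms)
    while len(terms) > 1:
        coded = design.coded_array()
        y = design.response(response_name)
        res = sm.OLS(y, _term_columns(coded, terms)).fit()
        pvals = dict(zip(terms, res.pvalues))
        droppable = {t: pv for t, pv in pvals.items() if t != "intercept"}
        worst = max(droppable, key=droppable.get)
        if droppable[worst] <= p_threshold:
            break
        terms.remove(worst)
    return fit_surface(design, response_name, ModelSpec(response_name, tuple(terms)))
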