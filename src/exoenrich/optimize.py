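"""Constrained multi-response optimization over the design box.

The reproduction path is the hard-constrained problem: maximize the predicted
exosome surface over the actual-unit box (exchange interval 5-15 h, exchange
volume 150-400 uL) subject to predicted glucose >= 40 mg/dL.  The optimum is
located by dense grid evaluation followed by a deterministic local polish
(SLSQP) of the continuous constrained problem.

A Derringer-Suich desirability composite is provided for heat-map parity with
DOE software output; it is secondary to the hard-constrained formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize

from .design import Factor, actual_to_coded
from .rsm import SurfaceFit, predict

CONSTRAINT_TOL = 1e-6


class InfeasibleError(RuntimeError):
    """No point in the box satisfies every constraint."""

    def __init__(self, message: str, most_violated: str, violation: float):
        super().__init__(message)
        self.most_violated = most_violated
        self.violation = violation


@dataclass(frozen=True)
class Constraint:
    """A hard bound on one fitted response (units of the response)."""

    response_name: str
    kind: Literal["floor", "ceiling", "range"]
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "floor" and self.low is None:
            raise ValueError("floor constraint needs `low`")
        if self.kind == "ceiling" and self.high is None:
            raise ValueError("ceiling constraint needs `high`")
        if self.kind == "range":
            if self.low is None or self.high is None:
                raise ValueError("range constraint needs `low` and `high`")
            if not self.low < self.high:
                raise ValueError("range constraint requires low < high")

    def slack(self, value):
        """Nonnegative where satisfied; most negative = most violated."""
        value = np.asarray(value, dtype=float)
        slack = np.full(value.shape, np.inf)
        if self.low is not None:
            slack = np.minimum(slack, value - self.low)
        if self.high is not None:
            slack = np.minimum(slack, self.high - value)
        return slack


@dataclass
class OptimizationSpec:
    objective_response: str
    direction: Literal["maximize", "minimize"] = "maximize"
    constraints: list[Constraint] = field(default_factory=list)
    # actual-unit box bounds (time_lo, time_hi), (volume_lo, volume_hi)
    box: tuple[tuple[float, float], tuple[float, float]] = ((5.0, 15.0), (150.0, 400.0))
    grid_resolution: int = 501
    polish: bool = True

    def __post_init__(self) -> None:
        if self.grid_resolution < 11:
            raise ValueError("grid_resolution must be >= 11")
        for lo, hi in self.box:
            if not lo < hi:
                raise ValueError("box bounds must satisfy lo < hi")


@dataclass
class OptimumResult:
    actual: tuple[float, float]  # (time h, volume uL)
    coded: tuple[float, float]
    predictions: dict[str, float]
    binding_constraints: list[str]
    objective_value: float
    desirability: float | None = None

    def to_dict(self) -> dict:
        return {
            "time_h": self.actual[0],
            "volume_uL": self.actual[1],
            "coded": list(self.coded),
            "predictions": self.predictions,
            "binding_constraints": self.binding_constraints,
            "objective_value": self.objective_value,
            "desirability": self.desirability,
        }


def _grid(spec: OptimizationSpec):
    (tlo, thi), (vlo, vhi) = spec.box
    t = np.linspace(tlo, thi, spec.grid_resolution)
    v = np.linspace(vlo, vhi, spec.grid_resolution)
    T, V = np.meshgrid(t, v, indexing="ij")
    return T, V


def _eval_fit(fit: SurfaceFit, T, V):
    pts = np.stack([T, V], axis=-1)
    return predict(fit, pts, coded=False, warn_extrapolation=False)


def optimize(fits: dict[str, SurfaceFit], spec: OptimizationSpec) -> OptimumResult:
    """Locate the constrained optimum of one fitted response over the box.

    Dense grid evaluation first; when ``spec.polish`` the best grid point
    seeds a deterministic SLSQP solve of the continuous problem, accepted only
    if it stays feasible and improves the objective.  Ties on the grid break
    toward smaller volume, then smaller time.
    """
    if spec.objective_response not in fits:
        raise KeyError(f"no fit for objective response {spec.objective_response!r}")
    for c in spec.constraints:
        if c.response_name not in fits:
            raise KeyError(f"no fit for constrained response {c.response_name!r}")

    sign = 1.0 if spec.direction == "maximize" else -1.0
    T, V = _grid(spec)
    obj = sign * _eval_fit(fits[spec.objective_response], T, V)

    feasible = np.ones(T.shape, dtype=bool)
    worst_name, worst_violation = None, np.inf
    for c in spec.constraints:
        slack = c.slack(_eval_fit(fits[c.response_name], T, V))
        feasible &= slack >= -CONSTRAINT_TOL
        best_slack = float(slack.max())
        if best_slack < worst_violation:
            worst_violation, worst_name = best_slack, c.response_name
    if not feasible.any():
        raise InfeasibleError(
            f"no grid point satisfies all constraints; most violated: "
            f"{worst_name} (best slack {worst_violation:.4g})",
            most_violated=worst_name, violation=-worst_violation,
        )

    flat_obj = np.where(feasible, obj, -np.inf).ravel()
    order = np.lexsort((T.ravel(), V.ravel(), -flat_obj))
    best = order[0]
    t_best, v_best, val_best = float(T.ravel()[best]), float(V.ravel()[best]), float(flat_obj[best])

    if spec.polish:
        (tlo, thi), (vlo, vhi) = spec.box

        def neg_obj(x):
            return -sign * predict(fits[spec.objective_response], x,
                                   coded=False, warn_extrapolation=False)

        cons = [
            {"type": "ineq",
             "fun": (lambda x, c=c: float(np.min(c.slack(
                 predict(fits[c.response_name], x, coded=False,
                         warn_extrapolation=False)))))}
            for c in spec.constraints
        ]
        res = minimize(neg_obj, x0=[t_best, v_best], method="SLSQP",
                       bounds=[(tlo, thi), (vlo, vhi)], constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-12})
        # accept the polished point whenever it is feasible and at least as
        # good; the grid argmax remains the fallback (SLSQP may stop with a
        # benign line-search flag at tight ftol)
        cand_val = -float(res.fun)
        slacks = [
            float(np.min(c.slack(predict(fits[c.response_name], res.x,
                                         coded=False, warn_extrapolation=False))))
            for c in spec.constraints
        ]
        in_box = tlo - 1e-12 <= res.x[0] <= thi + 1e-12 and vlo - 1e-12 <= res.x[1] <= vhi + 1e-12
        if cand_val >= val_best and in_box and all(s >= -CONSTRAINT_TOL for s in slacks):
            t_best = float(np.clip(res.x[0], tlo, thi))
            v_best = float(np.clip(res.x[1], vlo, vhi))
            val_best = cand_val

    f1, f2 = fits[spec.objective_response].factors
    alpha = fits[spec.objective_response].alpha
    coded = (float(actual_to_coded(f1, t_best, alpha)),
             float(actual_to_coded(f2, v_best, alpha)))
    predictions = {
        name: float(predict(fit, (t_best, v_best), coded=False,
                            warn_extrapolation=False))
        for name, fit in fits.items()
    }
    binding = []
    for c in spec.constraints:
        if abs(float(np.min(c.slack(predictions[c.response_name])))) < 1e-3:
            binding.append(c.response_name)
    (tlo, thi), (vlo, vhi) = spec.box
    for name, val, lo, hi in (("time", t_best, tlo, thi), ("volume", v_best, vlo, vhi)):
        if min(val - lo, hi - val) < 1e-9 * (hi - lo) + 1e-12:
            binding.append(f"{name}_bound")
    return OptimumResult(
        actual=(t_best, v_best), coded=coded, predictions=predictions,
        binding_constraints=binding,
        objective_value=sign * val_best if spec.direction == "minimize" else val_best,
    )


@dataclass(frozen=True)
class DesirabilityTarget:
    """One response's contribution to the Derringer-Suich composite."""

    goal: Literal["maximize", "minimize", "floor"]
    low: float
    high: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.low == self.high:
            raise ValueError("degenerate target: low == high")

    def score(self, yhat):
        yhat = np.asarray(yhat, dtype=float)
        if self.goal == "maximize":
            d = np.clip((yhat - self.low) / (self.high - self.low), 0.0, 1.0)
            return d ** self.weight
        if self.goal == "minimize":
            d = np.clip((self.high - yhat) / (self.high - self.low), 0.0, 1.0)
            return d ** self.weight
        # hard floor: 0 below the floor value, 1 at or above it
        return (yhat >= self.low).astype(float)


@dataclass
class DesirabilityField:
    time_h: np.ndarray
    volume_uL: np.ndarray
    per_response: dict[str, np.ndarray]
    overall: np.ndarray  # geometric mean, same grid shape
    argmax_actual: tuple[float, float]
    max_D: float


def desirability(fits: dict[str, SurfaceFit],
                 targets: dict[str, DesirabilityTarget],
                 box=((5.0, 15.0), (150.0, 400.0)),
                 grid_resolution: int = 501) -> DesirabilityField:
    """Evaluate the composite desirability D over the box on a dense grid.

    D is the geometric mean of the per-response desirabilities; the grid
    argmax is reported (ties break toward smaller volume then smaller time).
    """
    spec = OptimizationSpec("_", box=box, grid_resolution=grid_resolution)
    T, V = _grid(spec)
    per = {}
    logs = np.zeros(T.shape)
    zero = np.zeros(T.shape, dtype=bool)
    for name, target in targets.items():
        d = target.score(_eval_fit(fits[name], T, V))
        per[name] = d
        zero |= d <= 0
        with np.errstate(divide="ignore"):
            logs += np.where(d > 0, np.log(np.maximum(d, 1e-300)), 0.0)
    overall = np.where(zero, 0.0, np.exp(logs / max(len(targets), 1)))
    order = np.lexsort((T.ravel(), V.ravel(), -overall.ravel()))
    best = order[0]
    return DesirabilityField(
        time_h=T[:, 0], volume_uL=V[0, :], per_response=per, overall=overall,
        argmax_actual=(float(T.ravel()[best]), float(V.ravel()[best])),
        max_D=float(overall.ravel()[best]),
    )


@dataclass
class FeasibilityMap:
    time_h: np.ndarray
    volume_uL: np.ndarray
    feasible: np.ndarray  # boolean grid, shape (n_time, n_volume)
    # per volume grid value: time (h) at which the binding constraint's slack
    # crosses zero, NaN where no crossing occurs in the box
    boundary_time_h: np.ndarray
    binding_constraint: str | None


def feasibility_map(fits: dict[str, SurfaceFit],
                    spec: OptimizationSpec) -> FeasibilityMap:
    """Boolean feasibility grid plus the zero-slack contour of the binding
    constraint, traced as the crossing time per volume level."""
    T, V = _grid(spec)
    feasible = np.ones(T.shape, dtype=bool)
    slack_grids = {}
    for c in spec.constraints:
        slack = c.slack(_eval_fit(fits[c.response_name], T, V))
        slack_grids[c.response_name] = slack
        feasible &= slack >= -CONSTRAINT_TOL
    binding = None
    if slack_grids:
        # the binding constraint is the one with the smallest median slack
        binding = min(slack_grids, key=lambda k: float(np.median(slack_grids[k])))
    n_t, n_v = T.shape
    boundary = np.full(n_v, np.nan)
    if binding is not None:
        s = slack_grids[binding]
        t_axis = T[:, 0]
        for j in range(n_v):
            col = s[:, j]
            signs = np.sign(col)
            idx = np.nonzero(np.diff(signs) != 0)[0]
            if idx.size:
                i = idx[0]  # first crossing along increasing time
                t0, t1, s0, s1 = t_axis[i], t_axis[i + 1], col[i], col[i + 1]
                boundary[j] = t0 if s1 == s0 else t0 - s0 * (t1 - t0) / (s1 - s0)
    return FeasibilityMap(
        time_h=T[:, 0], volume_uL=V[0, :], feasible=feasible,
        boundary_time_h=boundary, binding_constraint=binding,
    )
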