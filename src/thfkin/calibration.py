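"""Fit free kinetic parameters to steady-state observables.

The objective is a weighted sum of squared log-residuals (concentrations
span several orders of magnitude, so log scale puts all targets on equal
footing), minimized by bounded trust-region least squares with seeded
log-uniform multi-starts.  A one-dimensional root solve recovers the
source-upregulation multiplier that reproduces a measured fold-increase
in total folate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .model import PathwayModel
from .observables import resolve_observable
from .scenarios import Scenario, WILDTYPE, apply_scenario, panb_oe_regulated, scenario_by_name
from .simulate import SteadyStateError, steady_state

__all__ = [
    "CalibrationError",
    "CalibrationTarget",
    "FitResult",
    "fit_wildtype",
    "fit_regulation_multiplier",
    "IdentifiabilityReport",
    "identifiability_report",
    "load_targets",
    "save_targets",
]

#: residual magnitude substituted when a parameter set has no steady state
_PENALTY = 1e3


class CalibrationError(RuntimeError):
    """Non-convergence or an infeasible target; carries the best FitResult
    (if any) as ``result``."""

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


@dataclass
class CalibrationTarget:
    """A measured steady-state observable.

    ``observable`` follows the grammar in :mod:`thfkin.observables`, with
    one extension: ``fold:<observable>`` targets the ratio of the
    observable under ``scenario`` to its wild-type value (dimensionless).
    ``scenario`` is a :class:`Scenario` or a scenario name.
    """

    observable: str
    value: float
    scenario: Scenario | str = "wildtype"
    weight: float = 1.0

    def __post_init__(self):
        if not (self.weight > 0 and math.isfinite(self.weight)):
            raise ValueError("weight must be finite and > 0")
        if not (self.value > 0 and math.isfinite(self.value)):
            raise ValueError("target value must be finite and > 0 (log-scale objective)")

    def resolved_scenario(self) -> Scenario:
        if isinstance(self.scenario, Scenario):
            return self.scenario
        return scenario_by_name(self.scenario)


@dataclass
class FitResult:
    params: dict[tuple[str, str], float]
    residuals: np.ndarray  # unweighted log residuals, one per target
    converged: bool
    objective: float       # sum of weighted squared log residuals
    n_evals: int
    seed: int
    model: PathwayModel = field(repr=False, default=None)
    stable_at_optimum: bool = True
    warnings: list[str] = field(default_factory=list)


def _predict(model: PathwayModel, targets: list[CalibrationTarget]) -> np.ndarray:
    """Steady-state predictions for each target, reusing one solve per
    scenario."""
    ss_cache: dict[Scenario, object] = {}

    def ss_for(scn: Scenario):
        if scn not in ss_cache:
            ss_cache[scn] = steady_state(apply_scenario(model, scn))
        return ss_cache[scn]

    out = np.empty(len(targets))
    for i, t in enumerate(targets):
        scn = t.resolved_scenario()
        obs = t.observable
        if obs.startswith("fold:"):
            fn = resolve_observable(obs[5:])
            out[i] = fn(model, ss_for(scn)) / fn(model, ss_for(WILDTYPE))
        else:
            out[i] = resolve_observable(obs)(model, ss_for(scn))
    return out


def fit_wildtype(
    model: PathwayModel,
    free_params: list[tuple[str, str]],
    targets: list[CalibrationTarget],
    bounds: dict[tuple[str, str], tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 10,
    residual_tol: float = 0.25,
) -> FitResult:
    """Weighted log-scale least squares on steady-state observables.

    Bounds default to a factor of 1e3 either side of the starting value.
    The first start is the model's current parameter vector; subsequent
    (seeded) starts are log-uniform within bounds and are tried only if
    an earlier start fails.  ``converged`` requires optimizer success and
    every unweighted |log residual| below ``residual_tol`` (0.25 log
    units, i.e. targets matched to within ~28%, comfortably inside
    typical replicate scatter).  Raises :class:`CalibrationError` with
    the best result attached when no start converges.
    """
    if not free_params:
        raise ValueError("free_params must not be empty")
    p0 = np.array([model.get_param(*p) for p in free_params])
    if np.any(p0 <= 0):
        raise CalibrationError("free parameters must start > 0 for log-scale fitting")
    bounds = bounds or {}
    lo = np.log([bounds.get(p, (v / 1e3, v * 1e3))[0] for p, v in zip(free_params, p0)])
    hi = np.log([bounds.get(p, (v / 1e3, v * 1e3))[1] for p, v in zip(free_params, p0)])
    w = np.sqrt([t.weight for t in targets])
    log_targets = np.log([t.value for t in targets])
    n_evals = 0

    def residuals(u):
        nonlocal n_evals
        n_evals += 1
        m = model.copy()
        for p, v in zip(free_params, np.exp(u)):
            m.set_param(*p, v)
        try:
            pred = _predict(m, targets)
        except SteadyStateError:
            return np.full(len(targets), _PENALTY)
        if np.any(pred <= 0):
            return np.full(len(targets), _PENALTY)
        return w * (np.log(pred) - log_targets)

    rng = np.random.default_rng(seed)
    starts = [np.log(p0)]
    starts += [rng.uniform(lo, hi) for _ in range(n_starts - 1)]

    best = None
    for u0 in starts:
        res = least_squares(
            residuals, np.clip(u0, lo, hi), bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        raw = res.fun / w
        converged = bool(res.success and np.max(np.abs(raw)) < residual_tol)
        fitted = dict(zip(free_params, np.exp(res.x)))
        m_fit = model.copy()
        for p, v in fitted.items():
            m_fit.set_param(*p, v)
        result = FitResult(
            params=fitted,
            residuals=raw,
            converged=converged,
            objective=float(np.sum(res.fun**2)),
            n_evals=n_evals,
            seed=seed,
            model=m_fit,
        )
        if best is None or result.objective < best.objective:
            best = result
        if converged:
            try:
                if not steady_state(m_fit).stable:
                    result.warnings.append("steady state at optimum is not stable")
                    result.stable_at_optimum = False
            except SteadyStateError:
                result.warnings.append("no steady state at optimum")
                result.stable_at_optimum = False
            return result
    raise CalibrationError(
        f"calibration did not converge in {n_starts} starts "
        f"(best max |log residual| = {np.max(np.abs(best.residuals)):.3g})",
        result=best,
    )


def fit_regulation_multiplier(
    model: PathwayModel,
    f_panb: float,
    folate_fold_target: float = 1.46,
    f_reg_max: float | None = None,
    xtol: float = 1e-12,
) -> float:
    """Source-flux multiplier reproducing a total-folate fold increase.

    Solves for ``f_reg`` such that steady-state [THF]+[CH2THF] in the
    ``panb_oe_regulated`` scenario is ``folate_fold_target`` times the
    wild-type value, exploiting the strict monotonicity of the fold in
    ``f_reg``.  The drain capacity bounds the reachable fold: as the
    upregulated supply approaches the summed drain vmax the folate pool
    diverges, so any attainable fold is bracketed below that limit.
    """
    if f_panb <= 1:
        raise ValueError("f_panb must be > 1 for the overexpression scenario")
    wt = steady_state(model)
    tf_wt = wt.conc["THF"] + wt.conc["CH2THF"]
    guess = wt.conc_vector(model)

    def fold(f_reg: float) -> float:
        scn = panb_oe_regulated(f_reg, f_panb=f_panb)
        ss = steady_state(apply_scenario(model, scn), guess=guess)
        return (ss.conc["THF"] + ss.conc["CH2THF"]) / tf_wt

    fold1 = fold(1.0)
    if folate_fold_target <= fold1:
        raise CalibrationError(
            f"target fold {folate_fold_target:g} is not above the fold at f_reg=1 "
            f"({fold1:g}); upregulation cannot decrease folate in this model"
        )
    if f_reg_max is None:
        capacity = sum(
            model.get_param(rid, "vmax") for rid in ("DRAIN_THF", "DRAIN_CH2THF")
        )
        f_reg_max = 0.999 * capacity / model.get_param("SRC_HMPt", "v0")
    hi = min(1.5, f_reg_max)
    while fold(hi) < folate_fold_target:
        if hi >= f_reg_max:
            raise CalibrationError(
                f"target fold {folate_fold_target:g} exceeds the maximum reachable "
                f"within drain capacity (f_reg <= {f_reg_max:g})"
            )
        hi = min(hi * 1.5, f_reg_max)
    return float(brentq(lambda f: fold(f) - folate_fold_target, 1.0, hi, xtol=xtol))


# --------------------------------------------------------------------------
# Identifiability
# --------------------------------------------------------------------------

@dataclass
class IdentifiabilityReport:
    """Objective profiles over +-span-fold around each fitted parameter.

    ``profiles`` columns: parameter, multiplier, objective.  ``flat``
    marks parameters whose profile barely moves the objective
    (non-identifiable given these targets).
    """

    profiles: pd.DataFrame
    flat: dict[str, bool]
    flat_tol: float

    def identifiable(self, param: tuple[str, str]) -> bool:
        return not self.flat[f"{param[0]}.{param[1]}"]


def identifiability_report(
    fit: FitResult,
    model: PathwayModel,
    targets: list[CalibrationTarget],
    span: float = 10.0,
    n_points: int = 9,
    flat_tol: float = 1e-3,
) -> IdentifiabilityReport:
    """Profile each fitted parameter over a +-``span``-fold range.

    Other parameters stay at their fitted values; the recorded objective
    is the weighted sum of squared log residuals.  A profile whose total
    range is below ``flat_tol`` is flagged flat: the targets do not
    constrain that parameter (e.g. any upstream mass-action constant when
    only fluxes are targeted, since the steady-state pathway flux is
    structurally fixed at v_net + v_PanB).
    """
    w = np.sqrt([t.weight for t in targets])
    log_targets = np.log([t.value for t in targets])
    rows = []
    flat = {}
    for p, v_fit in fit.params.items():
        key = f"{p[0]}.{p[1]}"
        objs = []
        for mult in np.geomspace(1.0 / span, span, n_points):
            m = fit.model.copy()
            m.set_param(*p, v_fit * mult)
            try:
                pred = _predict(m, targets)
                obj = float(np.sum((w * (np.log(pred) - log_targets)) ** 2))
            except (SteadyStateError, FloatingPointError):
                obj = float("nan")
            rows.append({"parameter": key, "multiplier": mult, "objective": obj})
            objs.append(obj)
        objs = np.array(objs)
        finite = objs[np.isfinite(objs)]
        flat[key] = bool(finite.size and (finite.max() - finite.min()) < flat_tol)
    return IdentifiabilityReport(profiles=pd.DataFrame(rows), flat=flat, flat_tol=flat_tol)


# --------------------------------------------------------------------------
# Targets file I/O (CSV: observable, scenario, value, weight)
# --------------------------------------------------------------------------

def load_targets(path) -> list[CalibrationTarget]:
    df = pd.read_csv(path)
    required = {"observable", "scenario", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"targets file needs columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CalibrationTarget(
                observable=row["observable"],
                scenario=row["scenario"],
                value=float(row["value"]),
                weight=float(row.get("weight", 1.0)) if "weight" in df.columns else 1.0,
            )
        )
    return out


def save_targets(targets: list[CalibrationTarget], path) -> None:
    pd.DataFrame(
        [
            {
                "observable": t.observable,
                "scenario": t.resolved_scenario().name,
                "value": t.value,
                "weight": t.weight,
            }
            for t in targets
        ]
    ).to_csv(path, index=False)
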