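"""Local parameter sensitivity of steady-state concentrations and fluxes.

Coefficients are scaled (elasticity-style) central log-log differences,

    c = [ln m(p (1+d)) - ln m(p (1-d))] / [ln(1+d) - ln(1-d)],

with every metric evaluation coming from a fresh steady-state solve.
These are dimensionless, so "insensitive" thresholds carry across
parameters of different units.

The two constant source fluxes must be perturbed jointly (the ``f_reg``
scenario multiplier); perturbing one alone breaks the supply balance and
no steady state exists, which ``local_sensitivity`` reports as an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .model import PathwayModel
from .observables import resolve_observable
from .simulate import SteadyState, SteadyStateError, steady_state

__all__ = ["SensitivityError", "SensitivityReport", "local_sensitivity", "sensitivity_scan"]


class SensitivityError(RuntimeError):
    """Steady state lost under a parameter perturbation."""


def _get_param(model: PathwayModel, rid: str, pname: str) -> float:
    if rid == "species":
        sp = model.species_by_id(pname)
        if not sp.fixed:
            raise ValueError(f"species {pname!r} is dynamic, not a fixed pool")
        return sp.init_conc
    return model.get_param(rid, pname)


def _set_param(model: PathwayModel, rid: str, pname: str, value: float) -> None:
    if rid == "species":
        model.species_by_id(pname).init_conc = value
    else:
        model.set_param(rid, pname, value)


def local_sensitivity(
    model: PathwayModel,
    param: tuple[str, str],
    metric,
    delta: float = 0.05,
    base_ss: SteadyState | None = None,
) -> float:
    """Normalized sensitivity d ln(metric) / d ln(parameter).

    ``param`` is a ``(reaction id, parameter name)`` pair, or
    ``("species", species id)`` to perturb a fixed-pool concentration;
    ``metric`` is an observable name (see :mod:`thfkin.observables`) or a
    callable ``f(model, steady_state)``.  A parameter whose current value
    is zero is untouched by a multiplicative perturbation, so its
    coefficient is exactly 0.
    """
    if not (0 < delta < 1):
        raise ValueError("delta must be in (0, 1)")
    rid, pname = param
    p0 = _get_param(model, rid, pname)
    if p0 == 0.0:
        return 0.0
    fn = resolve_observable(metric)
    if base_ss is None:
        base_ss = steady_state(model)
    guess = base_ss.conc_vector(model)

    values = []
    for mult, label in ((1.0 + delta, "up"), (1.0 - delta, "down")):
        m = model.copy()
        _set_param(m, rid, pname, p0 * mult)
        try:
            ss = steady_state(m, guess=guess)
        except SteadyStateError as exc:
            raise SensitivityError(
                f"steady state lost perturbing ({rid}, {pname}) {label} by {delta:g}: {exc}"
            ) from exc
        values.append(fn(m, ss))
    v_up, v_down = values
    if v_up <= 0 or v_down <= 0:
        raise SensitivityError(
            f"metric is non-positive under perturbation of ({rid}, {pname}); "
            "log-log coefficient undefined"
        )
    return (math.log(v_up) - math.log(v_down)) / (math.log1p(delta) - math.log1p(-delta))


@dataclass
class SensitivityReport:
    """Matrix of coefficients, one row per (parameter, metric) pair.

    ``table`` columns: parameter, metric, coefficient, delta, error
    (message for cells whose steady state was lost).  Sorted by
    |coefficient| descending.
    """

    table: pd.DataFrame

    def coefficient(self, param: tuple[str, str], metric: str) -> float:
        key = f"{param[0]}.{param[1]}"
        rows = self.table[(self.table.parameter == key) & (self.table.metric == str(metric))]
        if rows.empty:
            raise KeyError(f"no row for {key!r} x {metric!r}")
        return float(rows.coefficient.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sensitivity_scan(
    model: PathwayModel,
    parameters: list[tuple[str, str]],
    metrics: list,
    delta: float = 0.05,
) -> SensitivityReport:
    """Full parameter x metric scan; per-cell failures are recorded and
    the scan continues."""
    base_ss = steady_state(model)
    rows = []
    for param in parameters:
        for metric in metrics:
            try:
                c = local_sensitivity(model, param, metric, delta=delta, base_ss=base_ss)
                err = None
            except (SensitivityError, SteadyStateError) as exc:
                c, err = float("nan"), str(exc)
            rows.append(
                {
                    "parameter": f"{param[0]}.{param[1]}",
                    "metric": str(metric),
                    "coefficient": c,
                    "delta": delta,
                    "error": err,
                }
            )
    table = pd.DataFrame(rows)
    table = table.reindex(
        table.coefficient.abs().sort_values(ascending=False, na_position="last").index
    ).reset_index(drop=True)
    return SensitivityReport(table=table)
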