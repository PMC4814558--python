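"""ODE evaluation, time-course integration and steady-state solving.

The ODE state contains only the dynamic species; fixed pools enter the
rate laws as constants.  Steady states are found by damped least-squares
root finding in log-concentration space (guaranteeing positivity), with a
relaxation fallback (long stiff integration followed by polishing).

A structural subtlety of the reference network: because the two exchange
reactions run at the same constant rate and the PanB side reaction
returns both the pterin and the pABA moiety, the linear combination
[pABA] - [H2-HMPt] - [H2-HMPt-PP] is conserved by the dynamics.  The
steady state is therefore a one-dimensional manifold; every observable
except the pABA / H2-HMPt-PP split is unique on it.  ``steady_state``
detects such dynamic invariants numerically, pins them to the caller's
guess (matching what relaxation from that guess would reach), and counts
the associated ~zero Jacobian eigenvalues as neutral directions when
assessing local stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.optimize import least_squares

from .model import ConstantFlux, PathwayModel

__all__ = [
    "SimulationError",
    "SteadyStateError",
    "Trajectory",
    "SteadyState",
    "rhs",
    "fluxes_at",
    "jacobian",
    "simulate",
    "steady_state",
]

#: floor used when moving concentrations to log space
_LOG_FLOOR = 1e-30


class SimulationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, t_last: float = float("nan")):
        super().__init__(message)
        self.t_last = t_last


class SteadyStateError(RuntimeError):
    """No steady state found within the iteration/time budget."""


# --------------------------------------------------------------------------
# Fast(ish) evaluation context
# --------------------------------------------------------------------------

class _System:
    """Caches index structures of a model for repeated rhs evaluation."""

    def __init__(self, model: PathwayModel):
        self.model = model
        self.dyn_ids = [s.id for s in model.dynamic_species]
        self.n = len(self.dyn_ids)
        self.S = model.stoichiometric_matrix()
        self._fixed = {s.id: s.init_conc for s in model.fixed_species}

    def conc_map(self, x) -> dict[str, float]:
        d = dict(self._fixed)
        d.update(zip(self.dyn_ids, x))
        return d

    def flux_vector(self, x) -> np.ndarray:
        cm = self.conc_map(x)
        return np.array([r.flux(cm) for r in self.model.reactions])

    def rhs(self, x) -> np.ndarray:
        return self.S @ self.flux_vector(x)

    def v_ref(self, x) -> float:
        """Characteristic flux scale for residual normalization."""
        scale = max(
            (abs(r.law.v0) for r in self.model.reactions if isinstance(r.law, ConstantFlux)),
            default=0.0,
        )
        scale = max(scale, float(np.max(np.abs(self.flux_vector(x)), initial=0.0)))
        return scale if scale > 0 else 1.0

    def jacobian(self, x, abs_step: float = 1e-8, rel_step: float = 1e-4) -> np.ndarray:
        """Central finite-difference Jacobian, step max(abs_step, rel_step*|x_j|)."""
        x = np.asarray(x, dtype=float)
        J = np.empty((self.n, self.n))
        for j in range(self.n):
            h = max(abs_step, rel_step * abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            J[:, j] = (self.rhs(xp) - self.rhs(xm)) / (2 * h)
        return J


def _as_vector(model: PathwayModel, conc, sys: _System | None = None) -> np.ndarray:
    sys = sys or _System(model)
    if conc is None:
        return np.array([s.init_conc for s in model.dynamic_species], dtype=float)
    if isinstance(conc, Mapping):
        try:
            return np.array([conc[sid] for sid in sys.dyn_ids], dtype=float)
        except KeyError as exc:
            raise ValueError(f"missing concentration for dynamic species {exc}") from None
    x = np.asarray(conc, dtype=float)
    if x.shape != (sys.n,):
        raise ValueError(f"expected {sys.n} dynamic concentrations, got shape {x.shape}")
    return x


# --------------------------------------------------------------------------
# Public evaluation functions
# --------------------------------------------------------------------------

def rhs(model: PathwayModel, conc) -> np.ndarray:
    """Time derivatives S.v(conc) of the dynamic species, in model order.

    ``conc`` may be a vector (dynamic-species order) or a mapping by id.
    Negative concentrations are a domain error.
    """
    sys = _System(model)
    x = _as_vector(model, conc, sys)
    if np.any(x < 0):
        bad = [sid for sid, v in zip(sys.dyn_ids, x) if v < 0]
        raise ValueError(f"negative concentration(s) for {bad}")
    return sys.rhs(x)


def fluxes_at(model: PathwayModel, conc) -> dict[str, float]:
    """Signed per-reaction fluxes at the given state (reversible laws may
    return negative values)."""
    sys = _System(model)
    x = _as_vector(model, conc, sys)
    if np.any(x < 0):
        raise ValueError("negative concentration input")
    v = sys.flux_vector(x)
    return dict(zip((r.id for r in model.reactions), v.tolist()))


def jacobian(model: PathwayModel, conc) -> np.ndarray:
    """Finite-difference Jacobian of ``rhs`` w.r.t. the dynamic species."""
    sys = _System(model)
    return sys.jacobian(_as_vector(model, conc, sys))


# --------------------------------------------------------------------------
# Time course
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Integrated time course: concentrations and recomputed fluxes."""

    times: np.ndarray
    conc: pd.DataFrame  # index: time, columns: dynamic species ids
    flux: pd.DataFrame  # index: time, columns: reaction ids

    def to_tidy(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        c = self.conc.reset_index(names="time").melt(
            id_vars="time", var_name="species", value_name="concentration"
        )
        f = self.flux.reset_index(names="time").melt(
            id_vars="time", var_name="reaction", value_name="flux"
        )
        return c, f

    def write_csv(self, conc_path, flux_path) -> None:
        c, f = self.to_tidy()
        c.to_csv(conc_path, index=False)
        f.to_csv(flux_path, index=False)


def simulate(
    model: PathwayModel,
    t_end: float,
    init=None,
    n_points: int = 200,
    t_eval: Sequence[float] | None = None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Stiff-capable integration of the model ODEs.

    Concentrations within solver tolerance of zero are clipped to zero in
    the output; the flux matrix is recomputed from the reported
    concentrations.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    sys = _System(model)
    x0 = _as_vector(model, init, sys)
    if np.any(x0 < 0):
        raise ValueError("initial concentrations must be >= 0")
    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, n_points)
    t_eval = np.asarray(t_eval, dtype=float)

    sol = solve_ivp(
        lambda t, y: sys.rhs(y),
        (0.0, float(t_end)),
        x0,
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_last = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(f"integration failed at t={t_last:g}: {sol.message}", t_last)

    conc = sol.y.T.copy()
    clip_band = 100 * atol
    conc[(conc < 0) & (conc > -clip_band)] = 0.0
    flux = np.array([sys.flux_vector(row) for row in np.clip(conc, 0.0, None)])
    return Trajectory(
        times=sol.t,
        conc=pd.DataFrame(conc, index=sol.t, columns=sys.dyn_ids),
        flux=pd.DataFrame(flux, index=sol.t, columns=[r.id for r in model.reactions]),
    )


# --------------------------------------------------------------------------
# Steady state
# --------------------------------------------------------------------------

@dataclass
class SteadyState:
    """A converged steady state with fluxes and stability diagnostics.

    ``stable`` is True when no Jacobian eigenvalue has a real part above
    the neutral threshold; ``n_neutral`` counts ~zero eigenvalues, which
    correspond to conserved directions of the dynamics (``n_invariants``
    of them were detected structurally).
    """

    conc: dict[str, float]
    flux: dict[str, float]
    residual_norm: float
    stable: bool
    method: str
    eigenvalues: np.ndarray = field(repr=False, default=None)
    n_neutral: int = 0
    n_invariants: int = 0

    def conc_vector(self, model: PathwayModel) -> np.ndarray:
        return np.array([self.conc[s.id] for s in model.dynamic_species])


def _dynamic_invariants(sys: _System, x0: np.ndarray) -> np.ndarray:
    """Detect linear combinations c.x conserved by the dynamics.

    Candidates are left null vectors of the Jacobian at the guess; each is
    kept only if it also annihilates the Jacobian and the rhs at probe
    points elsewhere in state space (so stoichiometric conservation laws
    and rate-constant coincidences are both caught, local slow modes are
    not).  Returns a (k x n) matrix of row vectors (possibly k = 0).
    """
    x_ref = np.maximum(x0, 1e-12)
    probes = [x_ref, x_ref * 1.37, x_ref * 0.59, x_ref * 2.13]
    # fine FD steps: the default (stability-oriented) steps are too coarse
    # to resolve a null vector against curvature of saturating laws
    J0 = sys.jacobian(probes[0], abs_step=1e-12, rel_step=1e-6)
    _, s, Vh = np.linalg.svd(J0.T)
    s_max = max(s[0], 1e-300)
    cand = Vh[s <= 1e-6 * s_max]
    if cand.size == 0:
        return np.zeros((0, sys.n))
    rows = []
    for c in cand:
        ok = True
        for xp in probes[1:]:
            v_scale = sys.v_ref(xp)
            Jp = sys.jacobian(xp, abs_step=1e-12, rel_step=1e-6)
            if np.max(np.abs(c @ Jp)) > 1e-5 * s_max:
                ok = False
                break
            if abs(c @ sys.rhs(xp)) > 1e-7 * v_scale:
                ok = False
                break
        if ok:
            rows.append(c)
    return np.array(rows) if rows else np.zeros((0, sys.n))


def _polish(sys: _System, x_start: np.ndarray, x_pin: np.ndarray, C: np.ndarray,
            v_ref: float) -> np.ndarray:
    """Damped least-squares root polish in log space, holding invariants
    C.x at their values for ``x_pin``."""
    u0 = np.log(np.maximum(x_start, _LOG_FLOOR))
    if C.shape[0]:
        c_scale = np.abs(C) @ np.maximum(x_pin, 1e-12)
        c_scale = np.maximum(c_scale, 1e-30)
        c_target = C @ x_pin

    # cap at absurd concentrations so a wild optimizer step cannot overflow
    u_hi = np.log(1e12)

    def residuals(u):
        x = np.exp(np.minimum(u, u_hi))
        r = sys.rhs(x) / v_ref
        if C.shape[0]:
            r = np.concatenate([r, (C @ x - c_target) / c_scale])
        return r

    res = least_squares(
        residuals, u0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=2000 * sys.n,
    )
    return np.exp(np.minimum(res.x, u_hi))


def steady_state(
    model: PathwayModel,
    guess=None,
    method: str = "auto",
    tol: float = 1e-6,
    t_max: float = 1e9,
) -> SteadyState:
    """Solve for a stable steady state of the model.

    ``tol`` is relative: the converged max |d[X]/dt| must be below
    ``tol * v_ref`` where v_ref is the characteristic flux scale (the
    constant source flux for the reference model).  ``method`` is
    ``"auto"`` (root finding with relaxation fallback), ``"root"`` or
    ``"relaxation"``.
    """
    sys = _System(model)
    x0 = _as_vector(model, guess, sys)
    if np.any(x0 < 0):
        raise ValueError("guess concentrations must be >= 0")
    v_ref = sys.v_ref(np.maximum(x0, 1e-12))
    tol_abs = tol * v_ref
    C = _dynamic_invariants(sys, x0)

    solved_by = None
    x = None
    if method in ("auto", "root"):
        x_try = _polish(sys, np.maximum(x0, 1e-12), x0, C, v_ref)
        if np.max(np.abs(sys.rhs(x_try))) < tol_abs:
            x, solved_by = x_try, "root"
        elif method == "root":
            raise SteadyStateError(
                f"root finding did not converge (residual "
                f"{np.max(np.abs(sys.rhs(x_try))):.3g} > {tol_abs:.3g})"
            )

    if x is None:  # relaxation fallback (or explicit request)
        x_cur = x0.copy()
        t_done = 0.0
        stage_end = 1e4
        while stage_end <= t_max:
            sol = solve_ivp(
                lambda t, y: sys.rhs(y), (t_done, stage_end), x_cur,
                method="LSODA", rtol=1e-10, atol=1e-14,
            )
            if not sol.success:
                raise SteadyStateError(f"relaxation integration failed: {sol.message}")
            x_cur = sol.y[:, -1]
            t_done = stage_end
            if np.max(np.abs(sys.rhs(np.clip(x_cur, 0, None)))) < 100 * tol_abs:
                break
            stage_end *= 100
        x_cur = np.clip(x_cur, 0.0, None)
        x_try = _polish(sys, np.maximum(x_cur, _LOG_FLOOR), x0, C, v_ref)
        if np.max(np.abs(sys.rhs(x_try))) >= tol_abs:
            dx = sys.rhs(x_cur)
            worst = sys.dyn_ids[int(np.argmax(dx))]
            raise SteadyStateError(
                f"no steady state within the time budget; species {worst!r} "
                f"grows without bound (d[{worst}]/dt = {np.max(dx):.3g})"
            )
        x, solved_by = x_try, "relaxation"

    J = sys.jacobian(x)
    eigs = np.linalg.eigvals(J)
    max_abs = max(float(np.max(np.abs(eigs))), 1e-300)
    neutral_tol = max(1e-14, 1e-7 * max_abs)
    n_neutral = int(np.sum(np.abs(eigs) <= neutral_tol))
    stable = bool(np.all(eigs.real < neutral_tol))

    flux = sys.flux_vector(x)
    return SteadyState(
        conc=dict(zip(sys.dyn_ids, x.tolist())),
        flux=dict(zip((r.id for r in model.reactions), flux.tolist())),
        residual_norm=float(np.max(np.abs(sys.rhs(x)))),
        stable=stable,
        method=solved_by,
        eigenvalues=eigs,
        n_neutral=n_neutral,
        n_invariants=int(C.shape[0]),
    )
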