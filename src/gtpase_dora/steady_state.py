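"""Steady states and dose-response curves for the coupled switch circuit.

Three routes to the steady state are provided and cross-checked against each
other:

* ``steady_state_ode`` — stiff integration of the full six-ODE system to long
  time (the reference, initial-condition based route);
* ``steady_state_fixed_point`` — a bracketed scalar root on the mGTPase
  fractional activation y = mG*_ss, using the reduction

      y = X / (X + c_eff + h(y, k_feedback)),

  where X is the (transformed) receptor steady state and h collects the
  feedback-dependent part of the mGAP-mediated deactivation.  The map
  y ↦ y·(X + c_eff + h(y)) − X is strictly increasing on [0, 1], so the
  steady state is unique and brentq is safe;
* closed forms for the no-feedback models (``analytic_mass_action_steady``,
  ``analytic_hill_steady``).

Activation levels (the S → ∞ limits used to normalize DoRA curves) are
computed analytically by evaluating the same relations at the receptor's
maximal activation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import jac_array, kinetic_f, rhs_array
from .params import (
    STATE_NAMES,
    FeedbackLogic,
    Kinetics,
    KineticParameters,
    ModelSpec,
    SystemState,
)

__all__ = [
    "DerivedConstants",
    "DoseResponseCurve",
    "SteadyStateError",
    "receptor_steady",
    "receptor_max",
    "steady_state_ode",
    "steady_state_fixed_point",
    "analytic_mass_action_steady",
    "analytic_hill_steady",
    "activation_levels",
    "dose_response",
    "default_dose_grid",
]

#: Default dose grid: 60 log-spaced points spanning S in [1e-5, 1e3].
DEFAULT_S_RANGE = (1e-5, 1e3)
DEFAULT_N_DOSES = 60


class SteadyStateError(RuntimeError):
    """Raised when a steady-state computation fails to converge/bracket."""


def default_dose_grid(n: int = DEFAULT_N_DOSES, s_range=DEFAULT_S_RANGE) -> np.ndarray:
    return np.logspace(np.log10(s_range[0]), np.log10(s_range[1]), n)


@dataclass(frozen=True)
class DerivedConstants:
    """Composite constants of the steady-state algebra.

    a_M, b_M: mass-action no-feedback composites (a_M uses the no-feedback
    mGAP steady state k_on_mGAP/k_off_mGAP).  c, d, e: feedback-model
    composites entering h(y).  a_H, b_H: Hill analogues of a_M, b_M.
    """

    a_M: float
    b_M: float
    c: float
    d: float
    e: float
    a_H: float
    b_H: float

    @classmethod
    def from_params(cls, p: KineticParameters, spec: ModelSpec | None = None) -> "DerivedConstants":
        hill = ModelSpec(kinetics=Kinetics.HILL, hill=(spec.hill if spec else ModelSpec().hill))
        mGAP0 = p.k_on_mGAP / p.k_off_mGAP
        # a vanished activation pathway sends the composite to +inf, which the
        # downstream algebra maps to zero activation (degenerate but defined)
        def _ratio(num: float, den: float) -> float:
            return num / den if den > 0 else float("inf")

        r_m = _ratio(p.k_off_mGEF * p.k_off_mG, p.k_on_mG * p.k_on_mGEF)
        r_t = _ratio(p.k_off_tGEF * p.k_off_tG, p.k_on_tG * p.k_on_tGEF)
        return cls(
            a_M=mGAP0 * r_m,
            b_M=p.tGAP * r_t,
            c=mGAP0 * r_m,
            d=(p.k_on_tGEF / (p.k_off_tGEF * p.k_off_mGAP)) * r_m,
            e=r_m / p.k_off_mGAP,
            a_H=(lambda f: 0.0 if f == 0 else _ratio(p.k_off_mG, p.k_on_mG) * f)(
                kinetic_f(mGAP0, hill)
            ),
            b_H=(lambda f: 0.0 if f == 0 else _ratio(p.k_off_tG, p.k_on_tG) * f)(
                kinetic_f(p.tGAP, hill)
            ),
        )


# ---------------------------------------------------------------------------
# receptor
# ---------------------------------------------------------------------------

def receptor_steady(S, params: KineticParameters, spec: ModelSpec):
    """Steady-state receptor fractional activation R*_ss at dose S.

    Mass action: k_on_R·S / (k_on_R·S + k_off_R);
    Hill: k_on_R·f_act(S) / (k_on_R·f_act(S) + k_off_R).
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("stimulus dose must be >= 0")
    drive = params.k_on_R * np.asarray(
        S if spec.kinetics is Kinetics.MASS_ACTION else kinetic_f(S, spec), dtype=float
    )
    out = drive / (drive + params.k_off_R)
    return out if out.ndim else float(out)


def receptor_max(params: KineticParameters, spec: ModelSpec) -> float:
    """R*_ss as S → ∞: 1 under mass action; k_on_R/(k_on_R+k_off_R) under Hill
    (f_act saturates at 1, so the receptor cannot be fully occupied)."""
    if spec.kinetics is Kinetics.MASS_ACTION:
        return 1.0
    return params.k_on_R / (params.k_on_R + params.k_off_R)


# ---------------------------------------------------------------------------
# feedback composites h(y)
# ---------------------------------------------------------------------------

def _tG_star_of_y(y: float, p: KineticParameters, spec: ModelSpec) -> float:
    """tG*_ss as a function of y = mG*_ss (the h2 map)."""
    if spec.kinetics is Kinetics.MASS_ACTION:
        b_M = DerivedConstants.from_params(p).b_M
        return y / (y + b_M) if y > 0 or b_M > 0 else 0.0
    tGEF = (p.k_on_tGEF / p.k_off_tGEF) * kinetic_f(y, spec)
    b_H = (p.k_off_tG / p.k_on_tG) * kinetic_f(p.tGAP, spec)
    ft = kinetic_f(tGEF, spec)
    return ft / (ft + b_H)


def _tGEF_of_y(y: float, p: KineticParameters, spec: ModelSpec) -> float:
    """tGEF_ss as a function of y = mG*_ss (the h1 map)."""
    kt = p.k_on_tGEF / p.k_off_tGEF
    if spec.kinetics is Kinetics.MASS_ACTION:
        return kt * y
    return kt * kinetic_f(y, spec)


def _h_mass(y: float, k_fb: float, logic: FeedbackLogic, consts: DerivedConstants) -> float:
    """Mass-action feedback composite h(y, k_feedback)."""
    if logic is FeedbackLogic.AND:
        return k_fb * consts.d * y * y / (y + consts.b_M)
    if logic is FeedbackLogic.OR:
        return k_fb * (consts.d * y + consts.e * y / (y + consts.b_M))
    return 0.0


def _dh_dy_mass(y: float, k_fb: float, logic: FeedbackLogic, consts: DerivedConstants) -> float:
    b = consts.b_M
    if logic is FeedbackLogic.AND:
        return k_fb * consts.d * (y * y + 2.0 * b * y) / (y + b) ** 2
    if logic is FeedbackLogic.OR:
        return k_fb * (consts.d + consts.e * b / (y + b) ** 2)
    return 0.0


def _h_hill(y: float, k_fb: float, p: KineticParameters, spec: ModelSpec) -> float:
    """Hill feedback composite h_Hill(y, k_feedback) = (k_off_mG/k_on_mG)·f_act(mGAP_ss(y))."""
    from .model import feedback_F

    mGAP = p.k_on_mGAP / p.k_off_mGAP
    if k_fb > 0:
        tGEF = _tGEF_of_y(y, p, spec)
        tG = _tG_star_of_y(y, p, spec)
        mGAP = mGAP + (k_fb / p.k_off_mGAP) * feedback_F(tGEF, tG, spec)
    f = kinetic_f(mGAP, spec)
    if f == 0:
        return 0.0
    return (p.k_off_mG / p.k_on_mG) * f if p.k_on_mG > 0 else float("inf")


def _F1(x: float, p: KineticParameters, spec: ModelSpec) -> float:
    """Hill drive F1(R*) = f_act((k_on_mGEF/k_off_mGEF)·f_act(R*))."""
    return kinetic_f((p.k_on_mGEF / p.k_off_mGEF) * kinetic_f(x, spec), spec)


# ---------------------------------------------------------------------------
# fixed-point route
# ---------------------------------------------------------------------------

def _solve_y(X: float, h, xtol: float = 1e-15) -> float:
    """Root of g(y) = y·(X + h(y)) − X on [0, 1]; h here includes c_eff.

    g is strictly increasing, g(0) = −X ≤ 0 and g(1) > 0 whenever the
    deactivation pathway h(1) is nonzero, so the bracket is guaranteed.
    """
    if X <= 0.0:
        return 0.0
    g = lambda y: y * (X + h(y)) - X  # noqa: E731
    g1 = g(1.0)
    if g1 < 0:
        raise SteadyStateError(
            "no sign change on [0, 1] for the mG* fixed point "
            f"(g(1) = {g1:.3g}); degenerate deactivation pathway"
        )
    return brentq(g, 0.0, 1.0, xtol=xtol, rtol=8.9e-16)


def _mG_fixed_point(x: float, p: KineticParameters, spec: ModelSpec) -> float:
    """mG*_ss at receptor activation x, for any of the six model variants.

    Without feedback (or at k_feedback = 0, where any feedback model
    degenerates exactly) the deactivation composite is y-independent and the
    scalar equation is solved in closed form; otherwise by bracketed root.
    """
    consts = DerivedConstants.from_params(p, spec)
    no_fb = spec.feedback_logic is FeedbackLogic.NONE or p.k_feedback == 0
    if spec.kinetics is Kinetics.MASS_ACTION:
        X, base = x, consts.c
        h = lambda y: consts.c + _h_mass(y, p.k_feedback, spec.feedback_logic, consts)  # noqa: E731
    else:
        X, base = _F1(x, p, spec), consts.a_H
        h = lambda y: _h_hill(y, p.k_feedback, p, spec)  # noqa: E731
    if no_fb:
        return X / (X + base) if (X > 0 or base > 0) else 0.0
    return _solve_y(X, h)


def _reconstruct(x: float, y: float, p: KineticParameters, spec: ModelSpec) -> SystemState:
    """Rebuild the full steady state from (R*_ss, mG*_ss)."""
    from .model import feedback_F

    if spec.kinetics is Kinetics.MASS_ACTION:
        mGEF = (p.k_on_mGEF / p.k_off_mGEF) * x
    else:
        mGEF = (p.k_on_mGEF / p.k_off_mGEF) * kinetic_f(x, spec)
    tGEF = _tGEF_of_y(y, p, spec)
    tG = _tG_star_of_y(y, p, spec)
    mGAP = p.k_on_mGAP / p.k_off_mGAP
    if spec.feedback_logic is not FeedbackLogic.NONE and p.k_feedback > 0:
        mGAP += (p.k_feedback / p.k_off_mGAP) * feedback_F(tGEF, tG, spec)
    return SystemState(R_star=x, mGEF=mGEF, mG_star=y, tGEF=tGEF, tG_star=tG, mGAP=mGAP)


def steady_state_fixed_point(S: float, params: KineticParameters, spec: ModelSpec) -> SystemState:
    """Steady state at dose S via the scalar fixed point on mG*_ss."""
    x = receptor_steady(S, params, spec)
    y = _mG_fixed_point(x, params, spec)
    return _reconstruct(x, y, params, spec)


# ---------------------------------------------------------------------------
# ODE route
# ---------------------------------------------------------------------------

def steady_state_ode(
    S: float,
    params: KineticParameters,
    spec: ModelSpec,
    t_end: float = 1e8,
    tol: float = 1e-9,
    y0: SystemState | None = None,
) -> SystemState:
    """Steady state by stiff integration of the full system to long time.

    Integrates from the all-zero initial condition (or ``y0``) in
    geometrically growing time chunks up to ``t_end``, exiting early once
    every residual satisfies |dy/dt| <= tol·(1 + |y|).  Non-convergence at
    t_end raises ``SteadyStateError`` carrying the residual.
    """
    y = (y0 or SystemState.zero()).to_array()
    fun = lambda t, v: rhs_array(v, S, params, spec)  # noqa: E731
    jac = lambda t, v: jac_array(v, S, params, spec)  # noqa: E731

    def converged(v):
        res = np.abs(rhs_array(v, S, params, spec))
        # implied state correction |rhs_i / J_ii|: a residual on a slow mode
        # (small decay constant) means the state is still far from rest
        damp = np.abs(np.diag(jac_array(v, S, params, spec)))
        err = res / np.maximum(damp, 1e-300)
        return bool(np.all(err <= tol * (1.0 + np.abs(v)))), res

    t0 = 0.0
    for t1 in (1e2, 1e4, 1e6, t_end):
        if t1 > t_end:
            break
        sol = solve_ivp(
            fun, (t0, t1), y, method="BDF", jac=jac,
            rtol=1e-10, atol=1e-12, t_eval=(t1,),
        )
        if not sol.success:
            raise SteadyStateError(f"integrator failed at S={S}: {sol.message}")
        y = sol.y[:, -1]
        ok, res = converged(y)
        if ok:
            return SystemState.from_array(np.clip(y, 0.0, None))
        t0 = t1
    raise SteadyStateError(
        f"steady state not reached by t={t_end:g} at S={S}; residual={res}"
    )


# ---------------------------------------------------------------------------
# closed forms (no feedback)
# ---------------------------------------------------------------------------

def analytic_mass_action_steady(R_star: float, consts: DerivedConstants, feedback: bool = False):
    """No-feedback mass-action closed forms:
    mG* = R*/(R* + a_M),  tG* = mG*/(mG* + b_M)."""
    if feedback:
        raise ValueError("closed forms apply to the no-feedback model only")
    if not (0.0 <= R_star <= 1.0):
        raise ValueError(f"R_star must lie in [0, 1], got {R_star}")
    if R_star == 0.0 and consts.a_M == 0.0:
        mG = 0.0
    else:
        mG = R_star / (R_star + consts.a_M)
    tG = mG / (mG + consts.b_M) if (mG > 0 or consts.b_M > 0) else 0.0
    return mG, tG


def analytic_hill_steady(R_star: float, params: KineticParameters, spec: ModelSpec):
    """No-feedback Hill closed forms:
    mG* = F1(R*)/(F1(R*) + a_H),  tG* = F2(R*)/(F2(R*) + b_H), where
    F1 = f_act(k_mGEF·f_act(R*)) and F2 = f_act(k_tGEF·f_act(mG*))."""
    if spec.feedback_logic is not FeedbackLogic.NONE:
        raise ValueError("closed forms apply to the no-feedback model only")
    consts = DerivedConstants.from_params(params, spec)
    F1 = _F1(R_star, params, spec)
    mG = F1 / (F1 + consts.a_H) if (F1 > 0 or consts.a_H > 0) else 0.0
    F2 = kinetic_f((params.k_on_tGEF / params.k_off_tGEF) * kinetic_f(mG, spec), spec)
    tG = F2 / (F2 + consts.b_H) if (F2 > 0 or consts.b_H > 0) else 0.0
    return mG, tG


# ---------------------------------------------------------------------------
# activation levels and dose-response assembly
# ---------------------------------------------------------------------------

def activation_levels(params: KineticParameters, spec: ModelSpec):
    """(R*_max, mG*_max, tG*_max): the S → ∞ steady-state limits.

    Computed analytically by evaluating the fixed point at the receptor's
    maximal activation; mG*_max is the 'mGTPase activation level' used to
    normalize DoRA curves.
    """
    x_max = receptor_max(params, spec)
    y_max = _mG_fixed_point(x_max, params, spec)
    tG_max = _tG_star_of_y(y_max, params, spec)
    return x_max, y_max, tG_max


@dataclass(frozen=True)
class DoseResponseCurve:
    """Per-dose steady states on a strictly increasing dose grid, plus the
    S → ∞ activation levels used for normalization."""

    S_grid: np.ndarray
    states: np.ndarray  # shape (n_doses, 6), columns ordered as STATE_NAMES
    R_max: float
    mG_max: float
    tG_max: float
    params: KineticParameters
    spec: ModelSpec

    def __post_init__(self) -> None:
        S = np.asarray(self.S_grid, dtype=float)
        if S.ndim != 1 or len(S) < 2:
            raise ValueError("S_grid must be a 1-D vector with >= 2 doses")
        if np.any(S <= 0) or np.any(np.diff(S) <= 0):
            raise ValueError("S_grid must be strictly increasing and positive")
        if self.states.shape != (len(S), 6):
            raise ValueError("states must have shape (n_doses, 6)")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def R_star(self) -> np.ndarray:
        return self.column("R_star")

    @property
    def mG_star(self) -> np.ndarray:
        return self.column("mG_star")

    @property
    def tG_star(self) -> np.ndarray:
        return self.column("tG_star")

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "S", self.S_grid)
        return df

    def to_csv(self, path) -> None:
        """Tidy CSV with a '#'-prefixed header block recording provenance."""
        import io

        buf = io.StringIO()
        meta = {**self.params.to_dict(), **self.spec.to_dict(),
                "R_max": self.R_max, "mG_max": self.mG_max, "tG_max": self.tG_max}
        for k, v in meta.items():
            buf.write(f"# {k} = {v}\n")
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def dose_response(
    params: KineticParameters,
    spec: ModelSpec,
    S_grid: np.ndarray | None = None,
    method: str = "fixed_point",
) -> DoseResponseCurve:
    """Dose-response curve: per-dose steady states plus activation levels.

    ``method`` selects the solver route: 'fixed_point' (default) or 'ode'
    (cross-check mode, much slower).
    """
    if S_grid is None:
        S_grid = default_dose_grid()
    S_grid = np.asarray(S_grid, dtype=float)
    states = np.empty((len(S_grid), 6))
    for i, S in enumerate(S_grid):
        try:
            if method == "fixed_point":
                st = steady_state_fixed_point(S, params, spec)
            elif method == "ode":
                st = steady_state_ode(S, params, spec)
            else:
                raise ValueError(f"unknown method {method!r}")
        except SteadyStateError as err:
            raise SteadyStateError(f"dose S={S:g}: {err}") from err
        states[i] = st.to_array()
    R_max, mG_max, tG_max = activation_levels(params, spec)
    return DoseResponseCurve(
        S_grid=S_grid, states=states, R_max=R_max, mG_max=mG_max, tG_max=tG_max,
        params=params, spec=spec,
    )
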