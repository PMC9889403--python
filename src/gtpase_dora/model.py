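"""Right-hand side of the six-ODE coupled GTPase switch system.

Dynamics (fractional activations R*, mG*, tG*; concentrations mGEF, tGEF,
mGAP; stimulus dose S):

    dR*/dt   = k_on_R  f(S) (1 - R*)      - k_off_R  R*
    dmGEF/dt = k_on_mGEF f(R*)            - k_off_mGEF mGEF
    dmG*/dt  = k_on_mG f(mGEF) (1 - mG*)  - k_off_mG f(mGAP) mG*
    dtGEF/dt = k_on_tGEF f(mG*)           - k_off_tGEF tGEF
    dtG*/dt  = k_on_tG f(tGEF) (1 - tG*)  - k_off_tG f(tGAP) tG*
    dmGAP/dt = k_on_mGAP + k_feedback F(tGEF, tG*) - k_off_mGAP mGAP

where f is the identity under mass action or the activating Hill function
f_act(x) = x^n / (K^n + x^n), and F encodes the negative-feedback crosstalk
from tGEF and active tGTPase onto mGAP production (0 / product / sum for the
no-feedback / AND / OR variants).
"""

from __future__ import annotations

import numpy as np

from .params import FeedbackLogic, Kinetics, KineticParameters, ModelSpec, SystemState

__all__ = ["kinetic_f", "feedback_F", "rhs", "rhs_array", "jac_array"]


def kinetic_f(x, spec: ModelSpec):
    """Regulatory kinetics f(x): identity (mass action) or Hill f_act(x).

    Accepts scalars or arrays; raises on negative input.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("kinetic_f requires nonnegative input")
    if spec.kinetics is Kinetics.MASS_ACTION:
        out = x
    else:
        K, n = spec.hill.K, spec.hill.n
        xn = np.power(x, n)
        out = xn / (K**n + xn)
        # f_act(0) = 0 exactly (0^n/ (K^n + 0) ); guard 0/0 for x=0, n<... none needed
    return out if out.ndim else float(out)


def feedback_F(tGEF, tG_star, spec: ModelSpec):
    """Feedback crosstalk F(tGEF, tG*): 0, f(tGEF)·f(tG*) (AND) or sum (OR)."""
    if spec.feedback_logic is FeedbackLogic.NONE:
        return 0.0 * np.asarray(tGEF, dtype=float) if np.ndim(tGEF) else 0.0
    a = kinetic_f(tGEF, spec)
    b = kinetic_f(tG_star, spec)
    if spec.feedback_logic is FeedbackLogic.AND:
        return a * b
    return a + b


def rhs_array(
    y: np.ndarray, S: float, params: KineticParameters, spec: ModelSpec
) -> np.ndarray:
    """Time-derivatives of (R*, mGEF, mG*, tGEF, tG*, mGAP) as a 6-vector.

    Operates on a raw state vector (for the ODE integrator).  Transient
    negative round-off excursions from the solver are clipped to zero before
    entering f, which is only defined on nonnegative arguments.
    """
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state passed to rhs: {y}")
    if S < 0:
        raise ValueError(f"stimulus dose must be >= 0, got {S}")
    R, mGEF, mG, tGEF, tG, mGAP = np.clip(y, 0.0, None)
    p = params
    f = lambda x: kinetic_f(x, spec)  # noqa: E731
    dR = p.k_on_R * f(S) * (1.0 - R) - p.k_off_R * R
    dmGEF = p.k_on_mGEF * f(R) - p.k_off_mGEF * mGEF
    dmG = p.k_on_mG * f(mGEF) * (1.0 - mG) - p.k_off_mG * f(mGAP) * mG
    dtGEF = p.k_on_tGEF * f(mG) - p.k_off_tGEF * tGEF
    dtG = p.k_on_tG * f(tGEF) * (1.0 - tG) - p.k_off_tG * f(p.tGAP) * tG
    dmGAP = p.k_on_mGAP + p.k_feedback * feedback_F(tGEF, tG, spec) - p.k_off_mGAP * mGAP
    return np.array([dR, dmGEF, dmG, dtGEF, dtG, dmGAP])


def rhs(state: SystemState, S: float, params: KineticParameters, spec: ModelSpec) -> np.ndarray:
    """Time-derivatives at a typed SystemState (thin wrapper over rhs_array)."""
    return rhs_array(state.to_array(), S, params, spec)


def _df(x: float, spec: ModelSpec) -> float:
    """Derivative of the regulatory kinetics f."""
    if spec.kinetics is Kinetics.MASS_ACTION:
        return 1.0
    K, n = spec.hill.K, spec.hill.n
    if x <= 0.0:
        return 0.0 if n > 1 else (1.0 / K if n == 1 else float("inf"))
    xn = x**n
    return n * K**n * xn / (x * (K**n + xn) ** 2)


def jac_array(
    y: np.ndarray, S: float, params: KineticParameters, spec: ModelSpec
) -> np.ndarray:
    """Analytic Jacobian of rhs_array — keeps the stiff integrator fast and
    stable for extreme rate-constant ratios."""
    R, mGEF, mG, tGEF, tG, mGAP = np.clip(y, 0.0, None)
    p = params
    f = lambda x: kinetic_f(x, spec)  # noqa: E731
    df = lambda x: _df(x, spec)  # noqa: E731
    J = np.zeros((6, 6))
    J[0, 0] = -p.k_on_R * f(S) - p.k_off_R
    J[1, 0] = p.k_on_mGEF * df(R)
    J[1, 1] = -p.k_off_mGEF
    J[2, 1] = p.k_on_mG * df(mGEF) * (1.0 - mG)
    J[2, 2] = -p.k_on_mG * f(mGEF) - p.k_off_mG * f(mGAP)
    J[2, 5] = -p.k_off_mG * df(mGAP) * mG
    J[3, 2] = p.k_on_tGEF * df(mG)
    J[3, 3] = -p.k_off_tGEF
    J[4, 3] = p.k_on_tG * df(tGEF) * (1.0 - tG)
    J[4, 4] = -p.k_on_tG * f(tGEF) - p.k_off_tG * f(p.tGAP)
    if spec.feedback_logic is FeedbackLogic.AND:
        J[5, 3] = p.k_feedback * df(tGEF) * f(tG)
        J[5, 4] = p.k_feedback * f(tGEF) * df(tG)
    elif spec.feedback_logic is FeedbackLogic.OR:
        J[5, 3] = p.k_feedback * df(tGEF)
        J[5, 4] = p.k_feedback * df(tG)
    J[5, 5] = -p.k_off_mGAP
    return J
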