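"""The DoRA distance metric and its feedback-strength derivatives.

The metric for a downstream species Y (mG* or tG*) is

    D_Y = ∫_S | Y_ss/Y_ss,max − R*_ss/R*_ss,max | · d(R*_ss/R*_ss,max)/dS dS,

the dose-weighted separation between the normalized species curve v and the
normalized receptor occupancy u.  Substituting u for S shows this equals the
area between the curve v(u) and the diagonal — zero means perfect alignment.

Both quadrature forms are implemented: the u-substituted area form (the
default, exact for the piecewise-linear interpolant, including sign
crossings) and the S-weighted integral form with the analytic du/dS weight.
The finite dose grid truncates the S → ∞ tail, so the quadrature is closed
with the analytic endpoint (u, v) = (1, 1), bounding the tail contribution
by the final trapezoid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FeedbackLogic, Kinetics, KineticParameters, ModelSpec
from .steady_state import (
    DerivedConstants,
    DoseResponseCurve,
    _dh_dy_mass,
    _h_mass,
    _mG_fixed_point,
    dose_response,
    receptor_max,
    receptor_steady,
)

__all__ = [
    "NormalizedCurves",
    "DoRAResult",
    "normalize",
    "distance_metric",
    "metric_area_equivalence",
    "feedback_derivative_mass_action",
    "metric_derivative_wrt_feedback",
]


@dataclass(frozen=True)
class NormalizedCurves:
    """Dose-response curves normalized by their S → ∞ activation levels.

    u is the normalized receptor occupancy; v_mG and v_tG the normalized
    GTPase curves on the same dose grid.  S/params/spec are carried when the
    curves come from a model (needed for the S-weighted integral form) and
    absent for purely synthetic fixtures.
    """

    u: np.ndarray
    v_mG: np.ndarray
    v_tG: np.ndarray
    S: np.ndarray | None = None
    params: KineticParameters | None = None
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        for name in ("u", "v_mG", "v_tG"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 1 or len(a) != len(np.asarray(self.u)):
                raise ValueError(f"{name} must be 1-D and congruent with u")
            if np.any(a < -1e-12) or np.any(a > 1.0 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1]")

    def v(self, species: str) -> np.ndarray:
        if species == "mG":
            return np.asarray(self.v_mG, dtype=float)
        if species == "tG":
            return np.asarray(self.v_tG, dtype=float)
        raise ValueError(f"species must be 'mG' or 'tG', got {species!r}")


@dataclass(frozen=True)
class DoRAResult:
    """Distance metrics for both GTPases plus the mGTPase activation level."""

    metric_mG: float
    metric_tG: float
    mG_activation: float
    params_id: str = ""

    def to_dict(self) -> dict:
        return {
            "params_id": self.params_id,
            "metric_mG": self.metric_mG,
            "metric_tG": self.metric_tG,
            "mG_activation": self.mG_activation,
        }


def normalize(curve: DoseResponseCurve) -> NormalizedCurves:
    """Divide each species by its own S → ∞ activation level."""
    for name, m in (("R_max", curve.R_max), ("mG_max", curve.mG_max), ("tG_max", curve.tG_max)):
        if m <= 0:
            raise ValueError(f"degenerate model: activation level {name} = {m}")
    return NormalizedCurves(
        u=curve.R_star / curve.R_max,
        v_mG=curve.mG_star / curve.mG_max,
        v_tG=curve.tG_star / curve.tG_max,
        S=curve.S_grid,
        params=curve.params,
        spec=curve.spec,
    )


def _with_endpoint(u: np.ndarray, v: np.ndarray, append: bool):
    """Close the quadrature at the analytic S → ∞ node (u, v) = (1, 1)."""
    if append and u[-1] < 1.0:
        return np.append(u, 1.0), np.append(v, 1.0)
    return u, v


def _area_between(u: np.ndarray, v: np.ndarray) -> float:
    """Exact area between the piecewise-linear curve v(u) and the diagonal.

    Splits intervals where v − u changes sign so that |v − u| is integrated
    exactly for the linear interpolant.
    """
    d = v - u
    du = np.diff(u)
    d0, d1 = d[:-1], d[1:]
    same = d0 * d1 >= 0
    # same-sign trapezoid
    area_same = 0.5 * np.abs(d0 + d1) * du
    # sign change: two triangles split at the interior zero of the linear Δ
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(same, 0.0, d0 / (d0 - d1))  # crossing position in [0, 1]
    area_cross = 0.5 * du * (np.abs(d0) * t + np.abs(d1) * (1.0 - t))
    return float(np.sum(np.where(same, area_same, area_cross)))


def distance_metric(
    norm: NormalizedCurves, species: str = "mG", append_endpoint: bool = True
) -> float:
    """DoRA distance metric for one species: area between v(u) and the diagonal."""
    u = np.asarray(norm.u, dtype=float)
    if len(u) < 2:
        raise ValueError("distance_metric needs at least 2 grid points")
    u, v = _with_endpoint(u, norm.v(species), append_endpoint)
    return _area_between(u, v)


def _du_dS(S: np.ndarray, params: KineticParameters, spec: ModelSpec) -> np.ndarray:
    """Analytic derivative of the normalized receptor occupancy w.r.t. dose."""
    kon, koff = params.k_on_R, params.k_off_R
    if spec.kinetics is Kinetics.MASS_ACTION:
        dx = kon * koff / (kon * S + koff) ** 2
    else:
        K, n = spec.hill.K, spec.hill.n
        f = S**n / (K**n + S**n)
        df = n * K**n * S ** (n - 1.0) / (K**n + S**n) ** 2
        dx = kon * koff * df / (kon * f + koff) ** 2
    return dx / receptor_max(params, spec)


def metric_area_equivalence(norm: NormalizedCurves, species: str = "mG"):
    """(integral_form, area_form) of the metric — two independent quadratures.

    The integral form evaluates |v − u|·du/dS on the dose grid with the
    analytic du/dS weight and applies the trapezoidal rule in S; the area
    form integrates |v − u| in u.  Both close the S → ∞ tail with the
    (1, 1) endpoint.  The two converge to the same value as the grid is
    refined.
    """
    if norm.S is None or norm.params is None or norm.spec is None:
        raise ValueError("integral form requires model-backed curves (S, params, spec)")
    u = np.asarray(norm.u, dtype=float)
    v = norm.v(species)
    S = np.asarray(norm.S, dtype=float)
    w = np.abs(v - u) * _du_dS(S, norm.params, norm.spec)
    integral = float(np.trapezoid(w, S))
    if u[-1] < 1.0:  # tail beyond the last dose, bounded by one trapezoid in u
        integral += 0.5 * np.abs(v[-1] - u[-1]) * (1.0 - u[-1])
    area = distance_metric(norm, species, append_endpoint=True)
    return integral, area


# ---------------------------------------------------------------------------
# feedback-strength derivatives (mass action closed form + finite differences)
# ---------------------------------------------------------------------------

def _rel_dy_dk(y: float, k_fb: float, logic: FeedbackLogic, consts: DerivedConstants) -> float:
    """(1/y)·∂y/∂k_feedback from the implicit fixed-point relation:

        −(1/k_fb) / [ (y/h)·∂h/∂y + ((c+h)/h)·1/(1−y) ].
    """
    h = _h_mass(y, k_fb, logic, consts)
    dh = _dh_dy_mass(y, k_fb, logic, consts)
    denom = (y / h) * dh + ((consts.c + h) / h) / (1.0 - y)
    return -(1.0 / k_fb) / denom


def feedback_derivative_mass_action(
    params: KineticParameters, spec: ModelSpec, k_feedback: float, S: float
) -> float:
    """∂(mG*_ss/mG*_ss,max)/∂k_feedback, closed form (mass action only).

    Evaluates the relative-derivative decomposition at y = mG*_ss(S) and
    y_max = mG*_ss,max; singular at k_feedback = 0 (use finite differences
    there, where the model degenerates to no feedback).
    """
    if spec.kinetics is not Kinetics.MASS_ACTION:
        raise ValueError("closed-form feedback derivative is mass action only")
    if spec.feedback_logic is FeedbackLogic.NONE:
        raise ValueError("feedback derivative requires AND or OR logic")
    if not (k_feedback > 0):
        raise ValueError("closed form divides by k_feedback; it must be > 0")
    p = params.replace(k_feedback=k_feedback)
    consts = DerivedConstants.from_params(p, spec)
    x = receptor_steady(S, p, spec)
    if x <= 0:
        return 0.0
    y = _mG_fixed_point(x, p, spec)
    y_max = _mG_fixed_point(receptor_max(p, spec), p, spec)
    logic = spec.feedback_logic
    g = _rel_dy_dk(y, k_feedback, logic, consts)
    g_max = _rel_dy_dk(y_max, k_feedback, logic, consts)
    return (g - g_max) * (y / y_max)


def metric_derivative_wrt_feedback(
    params: KineticParameters,
    spec: ModelSpec,
    k_feedback: float,
    S_grid: np.ndarray | None = None,
    species: str = "mG",
    mode: str = "auto",
    rel_step: float = 1e-4,
) -> float:
    """d(distance metric)/d(k_feedback).

    mode='analytic' differentiates under the integral with the mass-action
    closed-form derivative (valid because the normalized mGTPase curve never
    drops below the receptor curve under mass action, so |v − u| = v − u);
    mode='fd' central-differences the full metric (the only route for Hill
    kinetics); 'auto' picks analytic where available.
    """
    from .steady_state import default_dose_grid

    if S_grid is None:
        S_grid = default_dose_grid()
    if mode == "auto":
        mode = (
            "analytic"
            if (spec.kinetics is Kinetics.MASS_ACTION and species == "mG")
            else "fd"
        )
    if mode == "analytic":
        p = params.replace(k_feedback=k_feedback)
        u = receptor_steady(S_grid, p, spec) / receptor_max(p, spec)
        dv = np.array(
            [feedback_derivative_mass_action(params, spec, k_feedback, S) for S in S_grid]
        )
        u_ext = np.append(u, 1.0) if u[-1] < 1.0 else u
        dv_ext = np.append(dv, 0.0) if u[-1] < 1.0 else dv  # v ≡ 1 at the endpoint
        return float(np.trapezoid(dv_ext, u_ext))
    if mode != "fd":
        raise ValueError(f"unknown mode {mode!r}")
    dk = rel_step * k_feedback
    vals = []
    for k in (k_feedback + dk, k_feedback - dk):
        curve = dose_response(params.replace(k_feedback=k), spec, S_grid)
        vals.append(distance_metric(normalize(curve), species))
    return (vals[0] - vals[1]) / (2.0 * dk)


def dora_result(
    params: KineticParameters,
    spec: ModelSpec,
    S_grid: np.ndarray | None = None,
    params_id: str = "",
) -> DoRAResult:
    """Convenience: dose-response → normalize → both metrics + activation level."""
    curve = dose_response(params, spec, S_grid)
    norm = normalize(curve)
    return DoRAResult(
        metric_mG=distance_metric(norm, "mG"),
        metric_tG=distance_metric(norm, "tG"),
        mG_activation=curve.mG_max,
        params_id=params_id,
    )
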