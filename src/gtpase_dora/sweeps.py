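"""Sweep and comparison experiments over the kinetic-parameter space.

Four experiment families:

* single-parameter sweeps (metric vs mGTPase activation level as one rate
  constant is tuned);
* feedback-strength sweeps with trend classification over sampled parameter
  spaces (the regime maps: which activation levels make feedback help or
  hurt alignment);
* AND-vs-OR logic-gate comparison under the matched-activation constraint
  (different k_feedback values chosen so both gates reach the same mGTPase
  activation level);
* cascade-length comparison (paired mG vs tG metrics).

All sampling is log-uniform and seeded; every experiment is reproducible
bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .dora import dora_result
from .params import FeedbackLogic, KineticParameters, ModelSpec
from .steady_state import (
    SteadyStateError,
    _mG_fixed_point,
    _tG_star_of_y,
    _tGEF_of_y,
    receptor_max,
)

__all__ = [
    "TrendLabel",
    "TrendClassification",
    "SweepConfig",
    "SweepResult",
    "classify_trend",
    "sample_parameter_space",
    "sweep_single_parameter",
    "binned_mean_metric",
    "default_feedback_grid",
    "feedback_trend",
    "feedback_trend_map",
    "match_or_feedback_strength",
    "compare_logic_gates",
    "compare_cascade",
]


class TrendLabel(enum.Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    DEC_THEN_INC = "dec_then_inc"
    INC_THEN_DEC = "inc_then_dec"
    FLAT = "flat"


@dataclass(frozen=True)
class TrendClassification:
    """Sign pattern of tolerance-filtered successive changes.

    ``label`` is None when the filtered pattern shows two or more sign
    changes (``ambiguous`` flags such series for manual review).
    """

    label: TrendLabel | None
    tolerance: float
    ambiguous: bool = False


def classify_trend(values, tolerance: float = 0.01) -> TrendClassification:
    """Classify an ordered series as one of the five trend labels.

    A change counts only once the value moves by more than ``tolerance``
    (relative) away from the last anchor point, so appending values that
    differ by less than the tolerance never changes the classification.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("classify_trend needs at least 1 value")
    signs: list[int] = []
    anchor = v[0]
    for x in v[1:]:
        scale = max(abs(anchor), abs(x), 1e-300)
        if abs(x - anchor) <= tolerance * scale:
            continue
        s = 1 if x > anchor else -1
        if not signs or signs[-1] != s:
            signs.append(s)
        anchor = x
    if not signs:
        return TrendClassification(TrendLabel.FLAT, tolerance)
    if len(signs) == 1:
        lab = TrendLabel.INCREASING if signs[0] > 0 else TrendLabel.DECREASING
        return TrendClassification(lab, tolerance)
    if len(signs) == 2:
        lab = TrendLabel.DEC_THEN_INC if signs[0] < 0 else TrendLabel.INC_THEN_DEC
        return TrendClassification(lab, tolerance)
    return TrendClassification(None, tolerance, ambiguous=True)


@dataclass(frozen=True)
class SweepConfig:
    """One sweep/sampling experiment: which constants vary, over what ranges.

    ``ranges`` maps parameter names to (lo, hi) positive bounds; sampling is
    log-uniform.  ``n_samples`` is the number of random parameter sets for
    space-sampling experiments; ``n_sweep_points`` the number of log-spaced
    points for single-parameter sweeps.
    """

    base: KineticParameters = field(default_factory=KineticParameters)
    spec: ModelSpec = field(default_factory=ModelSpec)
    ranges: dict = field(default_factory=dict)
    n_samples: int = 500
    n_sweep_points: int = 9
    seed: int = 0
    trend_tolerance: float = 0.01

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name} must satisfy 0 < lo <= hi, got {(lo, hi)}")


@dataclass(frozen=True)
class SweepResult:
    """Ordered results of a single-parameter sweep, with per-point failures."""

    parameter: str
    values: np.ndarray
    results: list  # DoRAResult per successful point, in sweep order
    failures: list  # (value, message) pairs

    @property
    def metric_mG(self) -> np.ndarray:
        return np.array([r.metric_mG for r in self.results])

    @property
    def metric_tG(self) -> np.ndarray:
        return np.array([r.metric_tG for r in self.results])

    @property
    def mG_activation(self) -> np.ndarray:
        return np.array([r.mG_activation for r in self.results])


def sample_parameter_space(cfg: SweepConfig) -> list[KineticParameters]:
    """Seeded log-uniform samples of the configured constants over the base set."""
    rng = np.random.default_rng(cfg.seed)
    names = sorted(cfg.ranges)
    sets = []
    for _ in range(cfg.n_samples):
        draw = {
            name: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            for name, (lo, hi) in ((n, cfg.ranges[n]) for n in names)
        }
        sets.append(cfg.base.replace(**draw))
    return sets


def sweep_single_parameter(cfg: SweepConfig, S_grid=None) -> SweepResult:
    """Metric-vs-activation sweep of exactly one log-spaced rate constant."""
    if len(cfg.ranges) != 1:
        raise ValueError(f"expected exactly one swept parameter, got {sorted(cfg.ranges)}")
    (name, (lo, hi)), = cfg.ranges.items()
    values = np.logspace(np.log10(lo), np.log10(hi), cfg.n_sweep_points)
    results, failures = [], []
    for val in values:
        try:
            res = dora_result(
                cfg.base.replace(**{name: float(val)}), cfg.spec, S_grid,
                params_id=f"{name}={val:.6g}",
            )
            results.append(res)
        except SteadyStateError as err:
            failures.append((float(val), str(err)))
    return SweepResult(parameter=name, values=values, results=results, failures=failures)


def binned_mean_metric(results, n_bins: int = 10, species: str = "mG"):
    """Equal-width bins on mG_activation over [0, 1]: per-bin mean and sd.

    Returns (table, empty_bins) where table rows are
    (bin_center, mean, sd, count) for non-empty bins.
    """
    act = np.array([r.mG_activation for r in results])
    met = np.array([getattr(r, f"metric_{species}") for r in results])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(act, edges) - 1, 0, n_bins - 1)
    rows, empty = [], []
    for b in range(n_bins):
        m = met[idx == b]
        center = 0.5 * (edges[b] + edges[b + 1])
        if len(m) == 0:
            empty.append(center)
            continue
        rows.append((center, float(np.mean(m)), float(np.std(m)), int(len(m))))
    return rows, empty


def default_feedback_grid(n: int = 9, top_exponent: float = 2.6) -> np.ndarray:
    """{0} ∪ log-spaced feedback strengths up to 10^2.6 (zero handled by the
    degenerate no-feedback path)."""
    return np.concatenate([[0.0], np.logspace(-1.0, top_exponent, n - 1)])


def feedback_trend(
    params: KineticParameters,
    spec: ModelSpec,
    k_fb_grid: np.ndarray | None = None,
    S_grid=None,
    tolerance: float = 0.01,
    species: str = "mG",
):
    """(no-feedback activation level, metric trend under a k_feedback sweep).

    k_feedback = 0 is evaluated through the no-feedback model (the feedback
    term vanishes identically there).
    """
    if spec.feedback_logic is FeedbackLogic.NONE:
        raise ValueError("feedback_trend requires a feedback model spec")
    if k_fb_grid is None:
        k_fb_grid = default_feedback_grid()
    none_spec = ModelSpec(kinetics=spec.kinetics, feedback_logic=FeedbackLogic.NONE, hill=spec.hill)
    metrics = []
    act0 = None
    for k in k_fb_grid:
        sp = none_spec if k == 0 else spec
        res = dora_result(params.replace(k_feedback=float(k)), sp, S_grid)
        if act0 is None:
            act0 = res.mG_activation
        metrics.append(getattr(res, f"metric_{species}"))
    if act0 is None:  # pragma: no cover - empty grid is a config error
        raise ValueError("empty feedback grid")
    return act0, classify_trend(metrics, tolerance), np.array(metrics)


def feedback_trend_map(cfg: SweepConfig, k_fb_grid=None, S_grid=None):
    """Regime map: per sampled parameter set, the no-feedback activation level
    and the metric trend label under the feedback sweep.

    Returns a list of (activation0, TrendClassification) with solver failures
    skipped (recorded as a third element message list).
    """
    rows, failures = [], []
    for i, p in enumerate(sample_parameter_space(cfg)):
        try:
            act0, trend, _ = feedback_trend(
                p, cfg.spec, k_fb_grid, S_grid, tolerance=cfg.trend_tolerance
            )
            rows.append((act0, trend))
        except SteadyStateError as err:
            failures.append((i, str(err)))
    return rows, failures


# ---------------------------------------------------------------------------
# logic-gate comparison under matched activation
# ---------------------------------------------------------------------------

def _gate_terms_at(y: float, params: KineticParameters, spec: ModelSpec):
    """(f(tGEF_ss), f(tG*_ss)) evaluated at mG* = y — the h1/h2 gate inputs."""
    from .model import kinetic_f

    tGEF = _tGEF_of_y(y, params, spec)
    tG = _tG_star_of_y(y, params, spec)
    return float(kinetic_f(tGEF, spec)), float(kinetic_f(tG, spec))


def match_or_feedback_strength(
    params: KineticParameters, spec: ModelSpec, k_fb_AND: float, tol: float = 1e-10
) -> float:
    """k_feedback for the OR gate giving the same mGTPase activation level as
    the AND gate at ``k_fb_AND``.

    Matching the saturating mGAP level requires
    k_AND·h1(y_max)·h2(y_max) = k_OR·(h1(y_max) + h2(y_max)); that closed
    form is used as the initial guess and cross-check, and a bracketed root
    on the activation mismatch refines it.
    """
    if k_fb_AND == 0:
        return 0.0
    and_spec = ModelSpec(kinetics=spec.kinetics, feedback_logic=FeedbackLogic.AND, hill=spec.hill)
    or_spec = ModelSpec(kinetics=spec.kinetics, feedback_logic=FeedbackLogic.OR, hill=spec.hill)
    x_max = receptor_max(params, and_spec)
    y_target = _mG_fixed_point(x_max, params.replace(k_feedback=k_fb_AND), and_spec)
    h1, h2 = _gate_terms_at(y_target, params, spec)
    if h1 + h2 == 0:
        raise SteadyStateError("degenerate gate terms; cannot match activation")
    guess = k_fb_AND * h1 * h2 / (h1 + h2)

    def mismatch(k_or: float) -> float:
        y = _mG_fixed_point(x_max, params.replace(k_feedback=k_or), or_spec)
        return y - y_target

    if abs(mismatch(guess)) <= tol:
        return float(guess)
    lo, hi = guess, guess
    for _ in range(60):  # y_max(OR) decreases in k_OR, so expand until bracketed
        lo, hi = lo / 2.0, hi * 2.0
        if mismatch(lo) * mismatch(hi) < 0:
            return float(brentq(mismatch, lo, hi, xtol=1e-14, rtol=8.9e-16))
    raise SteadyStateError("could not bracket the matched OR feedback strength")


def compare_logic_gates(
    param_sets,
    k_fb_AND_values,
    spec: ModelSpec,
    S_grid=None,
):
    """Paired AND/OR metrics under matched activation, plus the mean
    perpendicular distance from the pairs to the diagonal.

    Returns (pairs, mean_diagonal_distance, failures); each pair is a dict
    with both metrics, both feedback strengths and the shared activation
    level.  Per-pair solver failures are logged and skipped.
    """
    and_spec = ModelSpec(kinetics=spec.kinetics, feedback_logic=FeedbackLogic.AND, hill=spec.hill)
    or_spec = ModelSpec(kinetics=spec.kinetics, feedback_logic=FeedbackLogic.OR, hill=spec.hill)
    pairs, failures = [], []
    for i, (p, k_and) in enumerate(zip(param_sets, k_fb_AND_values)):
        try:
            k_or = match_or_feedback_strength(p, spec, float(k_and))
            res_and = dora_result(p.replace(k_feedback=float(k_and)), and_spec, S_grid)
            res_or = dora_result(p.replace(k_feedback=k_or), or_spec, S_grid)
            pairs.append(
                {
                    "k_fb_AND": float(k_and),
                    "k_fb_OR": k_or,
                    "metric_AND": res_and.metric_mG,
                    "metric_OR": res_or.metric_mG,
                    "metric_tG_AND": res_and.metric_tG,
                    "metric_tG_OR": res_or.metric_tG,
                    "mG_activation_AND": res_and.mG_activation,
                    "mG_activation_OR": res_or.mG_activation,
                }
            )
        except SteadyStateError as err:
            failures.append((i, str(err)))
    if pairs:
        d = np.array([abs(q["metric_AND"] - q["metric_OR"]) for q in pairs]) / np.sqrt(2.0)
        mean_dist = float(np.mean(d))
    else:
        mean_dist = float("nan")
    return pairs, mean_dist, failures


def compare_cascade(results):
    """Cascade-length comparison from paired (metric_mG, metric_tG) results.

    Returns a summary dict: counts of pairs above / on / below the diagonal
    (below = tGTPase aligns better than mGTPase) and the mG activation
    levels of the below-diagonal subset.
    """
    pairs = np.array([(r.metric_mG, r.metric_tG) for r in results])
    act = np.array([r.mG_activation for r in results])
    if len(pairs) == 0:
        raise ValueError("compare_cascade needs at least one result")
    below = pairs[:, 1] < pairs[:, 0]
    above = pairs[:, 1] > pairs[:, 0]
    return {
        "pairs": pairs,
        "n_above": int(np.sum(above)),
        "n_below": int(np.sum(below)),
        "n_on": int(len(pairs) - np.sum(above) - np.sum(below)),
        "below_activations": act[below],
        "activations": act,
    }
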