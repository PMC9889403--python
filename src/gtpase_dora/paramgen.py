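"""Synthetic kinetic-parameter generation and analytic curve fixtures.

Everything downstream (steady states, metrics, sweeps) is exercised against
inputs built here: documented baseline parameter sets, seeded log-uniform
spaces, activation-regime presets found by rejection sampling, and toy
normalized curves with closed-form metric values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .dora import NormalizedCurves
from .params import Kinetics, KineticParameters, ModelSpec
from .sweeps import SweepConfig, sample_parameter_space
from .steady_state import activation_levels

__all__ = [
    "DEFAULT_RANGES",
    "Regime",
    "RegimePreset",
    "default_parameters",
    "default_sampling_ranges",
    "preset_for_regime",
    "toy_curve_fixtures",
    "michaelian_metric",
]

#: Default log-uniform sampling range per rate constant; the mGAP production
#: rate and the feedback strength carry their own stated sweep ranges.
DEFAULT_RANGES = {
    "rate_constant": (1e-2, 1e1),
    "k_on_mGAP": (1e-2, 1.0),
    "k_feedback": (0.0, 10**2.6),
}


def default_parameters(spec: ModelSpec | None = None) -> KineticParameters:
    """Documented baseline: every rate constant and tGAP equal to 1, no feedback.

    Under mass action this gives a_M = b_M = 1, hence an mGTPase activation
    level of exactly 1/2; under the default Hill spec (K = 0.5, n = 1.5) all
    activation levels are finite and interior to (0, 1).
    """
    return KineticParameters()


def default_sampling_ranges(spec: ModelSpec) -> dict:
    """The sampled parameter space per kinetics: {k_on_mG, k_on_tG, k_on_mGAP}
    under mass action, expanded with k_on_R under Hill kinetics (where the
    receptor activation level also moves)."""
    r = DEFAULT_RANGES["rate_constant"]
    ranges = {"k_on_mG": r, "k_on_tG": r, "k_on_mGAP": DEFAULT_RANGES["k_on_mGAP"]}
    if spec.kinetics is Kinetics.HILL:
        ranges["k_on_R"] = r
    return ranges


class Regime(enum.Enum):
    HIGH_ACTIVATION = "high"
    INTERMEDIATE_ACTIVATION = "intermediate"
    LOW_ACTIVATION = "low"


#: Operational activation-level windows per regime.
_REGIME_INTERVALS = {
    Regime.HIGH_ACTIVATION: (0.8, 1.0),
    Regime.INTERMEDIATE_ACTIVATION: (0.4, 0.6),
    Regime.LOW_ACTIVATION: (0.0, 0.2),
}


@dataclass(frozen=True)
class RegimePreset:
    """Target window for the mGTPase activation level plus a base template."""

    name: Regime
    interval: tuple = ()
    base: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self) -> None:
        if not self.interval:
            object.__setattr__(self, "interval", _REGIME_INTERVALS[self.name])
        lo, hi = self.interval
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"regime interval must be within [0, 1], got {self.interval}")


def preset_for_regime(
    preset: RegimePreset | Regime,
    spec: ModelSpec,
    seed: int = 0,
    max_rejections: int = 10_000,
    ranges: dict | None = None,
) -> KineticParameters:
    """Rejection-sample the default space until the no-feedback mGTPase
    activation level lands in the preset's window; deterministic under seed.

    ``ranges`` restricts which constants are drawn (default: the full
    kinetics-appropriate sampling space)."""
    if isinstance(preset, Regime):
        preset = RegimePreset(name=preset)
    lo, hi = preset.interval
    cfg = SweepConfig(
        base=preset.base, spec=spec,
        ranges=ranges if ranges is not None else default_sampling_ranges(spec),
        n_samples=max_rejections, seed=seed,
    )
    for p in sample_parameter_space(cfg):
        _, mG_max, _ = activation_levels(p, spec)
        if lo <= mG_max <= hi:
            return p
    raise RuntimeError(
        f"no parameter set with mG activation in [{lo}, {hi}] after "
        f"{max_rejections} rejections (spec={spec.to_dict()})"
    )


def michaelian_metric(a: float) -> float:
    """Closed-form metric of the Michaelian curve v(u) = (1+a)u/(u+a):

        ∫₀¹ (v − u) du = (1+a)·[1 − a·ln((1+a)/a)] − 1/2.
    """
    return (1.0 + a) * (1.0 - a * math.log((1.0 + a) / a)) - 0.5


def toy_curve_fixtures(a: float = 1.0, n_points: int = 201) -> dict:
    """Analytic normalized-curve fixtures with their exact metric values.

    Returns name -> (NormalizedCurves, expected_metric):
      * 'perfect'    v ≡ u (metric 0);
      * 'saturated'  v ≡ 1 (metric 1/2);
      * 'michaelian' v = (1+a)u/(u+a), the mass-action no-feedback shape.
    """
    u = np.linspace(0.0, 1.0, n_points)
    fixtures = {
        "perfect": (u.copy(), 0.0),
        "saturated": (np.ones_like(u), 0.5),
        "michaelian": ((1.0 + a) * u / (u + a), michaelian_metric(a)),
    }
    out = {}
    for name, (v, expected) in fixtures.items():
        out[name] = (NormalizedCurves(u=u, v_mG=v, v_tG=v.copy()), expected)
    return out
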