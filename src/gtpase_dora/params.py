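"""Parameter and state containers for the coupled GTPase switch circuit.

The circuit couples a receptor, a monomeric GTPase switch (mG) and a
heterotrimeric GTPase switch (tG) through their GEFs and GAPs.  Each switch
variable is a fractional activation in [0, 1]; GEF/GAP variables are
concentrations.  ``tGAP`` is a fixed parameter, not a dynamic variable.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "Kinetics",
    "FeedbackLogic",
    "HillSpec",
    "ModelSpec",
    "KineticParameters",
    "SystemState",
    "STATE_NAMES",
]


class Kinetics(enum.Enum):
    """Form of the regulatory function f: linear (mass action) or Hill."""

    MASS_ACTION = "mass_action"
    HILL = "hill"


class FeedbackLogic(enum.Enum):
    """How tGEF and active tGTPase jointly drive mGAP production.

    NONE deletes the feedback loops (F = 0); AND multiplies the two
    regulator terms; OR adds them.
    """

    NONE = "none"
    AND = "and"
    OR = "or"


@dataclass(frozen=True)
class HillSpec:
    """Half-maximal activation constant K and Hill coefficient n of f_act."""

    K: float = 0.5
    n: float = 1.5

    def __post_init__(self) -> None:
        if not (self.K > 0):
            raise ValueError(f"Hill constant K must be > 0, got {self.K}")
        if not (self.n > 0):
            raise ValueError(f"Hill coefficient n must be > 0, got {self.n}")


@dataclass(frozen=True)
class ModelSpec:
    """Kinetics choice plus feedback logic; the six model variants.

    The ``hill`` field is ignored under mass-action kinetics.
    """

    kinetics: Kinetics = Kinetics.MASS_ACTION
    feedback_logic: FeedbackLogic = FeedbackLogic.NONE
    hill: HillSpec = field(default_factory=HillSpec)

    def __post_init__(self) -> None:
        if not isinstance(self.kinetics, Kinetics):
            raise TypeError(f"kinetics must be a Kinetics member, got {self.kinetics!r}")
        if not isinstance(self.feedback_logic, FeedbackLogic):
            raise TypeError(
                f"feedback_logic must be a FeedbackLogic member, got {self.feedback_logic!r}"
            )
        if not isinstance(self.hill, HillSpec):
            raise TypeError(f"hill must be a HillSpec, got {self.hill!r}")

    @property
    def has_feedback(self) -> bool:
        return self.feedback_logic is not FeedbackLogic.NONE

    def to_dict(self) -> dict:
        return {
            "kinetics": self.kinetics.value,
            "feedback_logic": self.feedback_logic.value,
            "hill_K": self.hill.K,
            "hill_n": self.hill.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            kinetics=Kinetics(d.get("kinetics", "mass_action")),
            feedback_logic=FeedbackLogic(d.get("feedback_logic", "none")),
            hill=HillSpec(K=float(d.get("hill_K", 0.5)), n=float(d.get("hill_n", 1.5))),
        )


# Rate-constant field names, in the flat-config key order.
RATE_NAMES = (
    "k_on_R",
    "k_off_R",
    "k_on_mGEF",
    "k_off_mGEF",
    "k_on_mG",
    "k_off_mG",
    "k_on_tGEF",
    "k_off_tGEF",
    "k_on_tG",
    "k_off_tG",
    "k_on_mGAP",
    "k_off_mGAP",
)


@dataclass(frozen=True)
class KineticParameters:
    """All rate constants, the feedback strength, and the fixed tGAP pool.

    Every constant is nonnegative; every ``k_off`` that appears as a divisor
    in the steady-state algebra must be strictly positive.  ``k_feedback = 0``
    reduces any feedback model to the no-feedback model exactly.
    """

    k_on_R: float = 1.0
    k_off_R: float = 1.0
    k_on_mGEF: float = 1.0
    k_off_mGEF: float = 1.0
    k_on_mG: float = 1.0
    k_off_mG: float = 1.0
    k_on_tGEF: float = 1.0
    k_off_tGEF: float = 1.0
    k_on_tG: float = 1.0
    k_off_tG: float = 1.0
    k_on_mGAP: float = 1.0
    k_off_mGAP: float = 1.0
    k_feedback: float = 0.0
    tGAP: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        for name in ("k_off_R", "k_off_mGEF", "k_off_mG", "k_off_tGEF", "k_off_tG", "k_off_mGAP"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} is used as a divisor and must be > 0")

    def replace(self, **kwargs) -> "KineticParameters":
        d = self.to_dict()
        d.update(kwargs)
        return KineticParameters(**d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown kinetic-parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


STATE_NAMES = ("R_star", "mGEF", "mG_star", "tGEF", "tG_star", "mGAP")


@dataclass(frozen=True)
class SystemState:
    """The six dynamic variables at one stimulus dose.

    ``R_star``, ``mG_star``, ``tG_star`` are fractional activations in [0, 1];
    ``mGEF``, ``tGEF``, ``mGAP`` are nonnegative concentrations.
    """

    R_star: float
    mGEF: float
    mG_star: float
    tGEF: float
    tG_star: float
    mGAP: float

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (6,):
            raise ValueError(f"expected a 6-vector, got shape {y.shape}")
        return cls(**dict(zip(STATE_NAMES, y.tolist())))

    @classmethod
    def zero(cls) -> "SystemState":
        """Default initial condition: everything inactive / unexpressed."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
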