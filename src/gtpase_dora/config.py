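"""Experiment configuration: parsing, validation, serialization.

A run is described by a flat YAML/JSON document naming one experiment and
its inputs.  Validation applies defaults, checks every type invariant, and
reports *all* violations, not just the first.  A parsed configuration
serializes back to an equivalent document (round-trip identity), and the
resolved form is copied verbatim into each run's output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .params import FeedbackLogic, HillSpec, Kinetics, KineticParameters, ModelSpec, RATE_NAMES

__all__ = ["ExperimentConfig", "ConfigError", "validate_config", "EXPERIMENTS"]

EXPERIMENTS = (
    "dose_response",
    "activation_sweep",
    "feedback_sweep",
    "logic_compare",
    "cascade_compare",
)


class ConfigError(ValueError):
    """Carries the full list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class ExperimentConfig:
    """One fully resolved experiment run."""

    experiment: str
    params: KineticParameters
    spec: ModelSpec
    seed: int = 0
    n_doses: int = 60
    s_range: tuple = (1e-5, 1e3)
    # single-parameter sweep
    sweep_parameter: str = "k_on_mGAP"
    sweep_range: tuple = (1e-2, 1.0)
    n_sweep_points: int = 9
    # sampled spaces
    ranges: dict = field(default_factory=dict)
    n_samples: int = 500
    trend_tolerance: float = 0.01
    diagonal_threshold: float = 0.1
    warnings: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "experiment": self.experiment,
            "seed": self.seed,
            "n_doses": self.n_doses,
            "s_range": list(self.s_range),
            "sweep_parameter": self.sweep_parameter,
            "sweep_range": list(self.sweep_range),
            "n_sweep_points": self.n_sweep_points,
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "n_samples": self.n_samples,
            "trend_tolerance": self.trend_tolerance,
            "diagonal_threshold": self.diagonal_threshold,
            "params": self.params.to_dict(),
        }
        d.update(self.spec.to_dict())
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def validate_config(raw: str | dict) -> ExperimentConfig:
    """Parse + validate a raw config document, applying defaults.

    Raises ``ConfigError`` listing every violation found.
    """
    if isinstance(raw, str):
        try:
            doc = yaml.safe_load(raw) or {}
        except yaml.YAMLError as err:
            raise ConfigError([f"not parseable as YAML/JSON: {err}"]) from err
    else:
        doc = dict(raw)
    if not isinstance(doc, dict):
        raise ConfigError([f"top level must be a mapping, got {type(doc).__name__}"])

    errors: list[str] = []
    warnings: list[str] = []

    experiment = doc.get("experiment", "dose_response")
    if experiment not in EXPERIMENTS:
        errors.append(f"unknown experiment {experiment!r}; expected one of {EXPERIMENTS}")

    # model spec -----------------------------------------------------------
    kin_raw = doc.get("kinetics", "mass_action")
    logic_raw = doc.get("feedback_logic", "none")
    kinetics = logic = None
    try:
        kinetics = Kinetics(kin_raw)
    except ValueError:
        errors.append(f"kinetics must be one of {[k.value for k in Kinetics]}, got {kin_raw!r}")
    try:
        logic = FeedbackLogic(logic_raw)
    except ValueError:
        errors.append(
            f"feedback_logic must be one of {[k.value for k in FeedbackLogic]}, got {logic_raw!r}"
        )
    if kinetics is Kinetics.HILL and "hill_K" not in doc and "hill_n" not in doc:
        warnings.append("kinetics=hill with no Hill constants; defaults K=0.5, n=1.5 applied")
    hill = None
    try:
        hill = HillSpec(K=float(doc.get("hill_K", 0.5)), n=float(doc.get("hill_n", 1.5)))
    except (TypeError, ValueError) as err:
        errors.append(str(err))

    # kinetic parameters ---------------------------------------------------
    praw = doc.get("params", {}) or {}
    params = None
    if not isinstance(praw, dict):
        errors.append("params must be a mapping of rate constants")
    else:
        base = KineticParameters().to_dict()
        known = set(base)
        for key, val in praw.items():
            if key not in known:
                errors.append(f"params: unknown field {key!r}")
                continue
            try:
                v = float(val)
            except (TypeError, ValueError):
                errors.append(f"params.{key}: not a number ({val!r})")
                continue
            if v < 0:
                errors.append(f"params.{key}: must be >= 0, got {v}")
                continue
            base[key] = v
        try:
            params = KineticParameters.from_dict(base)
        except ValueError as err:
            errors.append(str(err))

    # scalars --------------------------------------------------------------
    def _get(name, default, cast, check=None, msg=""):
        try:
            v = cast(doc.get(name, default))
        except (TypeError, ValueError):
            errors.append(f"{name}: not a valid {cast.__name__}")
            return default
        if check is not None and not check(v):
            errors.append(f"{name}: {msg}, got {v}")
            return default
        return v

    seed = _get("seed", 0, int, lambda v: v >= 0, "must be >= 0")
    n_doses = _get("n_doses", 60, int, lambda v: v >= 2, "must be >= 2")
    n_samples = _get("n_samples", 500, int, lambda v: v >= 0, "must be >= 0")
    n_sweep_points = _get("n_sweep_points", 9, int, lambda v: v >= 1, "must be >= 1")
    trend_tolerance = _get("trend_tolerance", 0.01, float, lambda v: v >= 0, "must be >= 0")
    diagonal_threshold = _get(
        "diagonal_threshold", 0.1, float, lambda v: v > 0, "must be > 0"
    )

    def _interval(name, default, positive=True):
        v = doc.get(name, list(default))
        try:
            lo, hi = float(v[0]), float(v[1])
        except (TypeError, ValueError, IndexError):
            errors.append(f"{name}: must be a [lo, hi] pair")
            return default
        if (positive and lo <= 0) or lo >= hi:
            errors.append(f"{name}: must satisfy 0 < lo < hi, got {v}")
            return default
        return (lo, hi)

    s_range = _interval("s_range", (1e-5, 1e3))
    sweep_range = _interval("sweep_range", (1e-2, 1.0))

    sweep_parameter = doc.get("sweep_parameter", "k_on_mGAP")
    if sweep_parameter not in RATE_NAMES + ("k_feedback", "tGAP"):
        errors.append(f"sweep_parameter: unknown parameter {sweep_parameter!r}")

    ranges = {}
    rraw = doc.get("ranges", {}) or {}
    if not isinstance(rraw, dict):
        errors.append("ranges must be a mapping name -> [lo, hi]")
    else:
        for key, pair in rraw.items():
            if key not in RATE_NAMES + ("k_feedback", "tGAP"):
                errors.append(f"ranges: unknown parameter {key!r}")
                continue
            try:
                lo, hi = float(pair[0]), float(pair[1])
            except (TypeError, ValueError, IndexError):
                errors.append(f"ranges.{key}: must be a [lo, hi] pair")
                continue
            if not (0 < lo <= hi):
                errors.append(f"ranges.{key}: must satisfy 0 < lo <= hi, got {pair}")
                continue
            ranges[key] = (lo, hi)

    if errors:
        raise ConfigError(errors)

    return ExperimentConfig(
        experiment=experiment,
        params=params,
        spec=ModelSpec(kinetics=kinetics, feedback_logic=logic, hill=hill),
        seed=seed,
        n_doses=n_doses,
        s_range=s_range,
        sweep_parameter=sweep_parameter,
        sweep_range=sweep_range,
        n_sweep_points=n_sweep_points,
        ranges=ranges,
        n_samples=n_samples,
        trend_tolerance=trend_tolerance,
        diagonal_threshold=diagonal_threshold,
        warnings=tuple(warnings),
    )
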