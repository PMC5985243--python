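"""Model parameter registry: costs, probabilities, and simulation constants.

Every scalar input of the cost-effectiveness model lives here as a
:class:`ParameterSpec` with a base value and (where an uncertainty range is
published) low/high bounds used by the sensitivity analyses.  Monetary values
are 2016 US dollars; probabilities are annual per-driver unless noted.

A :class:`ParameterSet` is immutable; overrides produce a new instance.  The
probabilistic sensitivity analysis draws each ``triangular`` parameter from a
triangular(low, mode=base, high) distribution.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "ModelConstants",
    "ParameterSpec",
    "ParameterSet",
    "load_parameters",
    "sample_psa",
    "sample_triangular",
]

KINDS = ("cost", "probability", "rate", "count", "utility")
DISTRIBUTIONS = ("triangular", "fixed", "empirical")


class ConfigError(ValueError):
    """Raised for malformed configuration files or invalid overrides."""


@dataclass(frozen=True)
class ParameterSpec:
    """One model input with its base value, plausible range and sampling law.

    ``kind`` drives validation: probabilities and utilities must lie in
    [0, 1], costs must be non-negative, rates in [0, 1].
    """

    name: str
    base: float
    low: float
    high: float
    kind: str
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.distribution not in DISTRIBUTIONS:
            raise ConfigError(
                f"{self.name}: unknown distribution {self.distribution!r}"
            )
        if not (self.low <= self.base <= self.high):
            raise ConfigError(
                f"{self.name}: require low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )
        if self.kind in ("probability", "utility", "rate"):
            if self.low < 0.0 or self.high > 1.0:
                raise ConfigError(
                    f"{self.name}: {self.kind} values must lie in [0, 1], got "
                    f"({self.low}, {self.high})"
                )
        if self.kind == "cost" and self.low < 0.0:
            raise ConfigError(f"{self.name}: cost must be non-negative")

    @property
    def varied(self) -> bool:
        """True if the PSA actually samples this parameter."""
        return self.distribution == "triangular" and self.low < self.high


@dataclass(frozen=True)
class ModelConstants:
    """Simulation-level constants (not varied in the PSA)."""

    discount_rate: float
    annual_vmt: float
    productivity_fraction: float
    parking_spot_ratio: float
    n_iterations: int
    n_timesteps: int
    wtp_threshold: float
    moore_halving_period: float
    healthy_utility: float
    severe_injury_utility: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.discount_rate < 1.0):
            raise ConfigError("discount_rate must lie in [0, 1)")
        if self.n_timesteps < 1:
            raise ConfigError("n_timesteps must be >= 1")
        if not (0.0 <= self.severe_injury_utility <= self.healthy_utility <= 1.0):
            raise ConfigError(
                "require 0 <= severe_injury_utility <= healthy_utility <= 1"
            )


def _c(name, low, base, high):  # published cost with a range -> triangular
    return ParameterSpec(name, base, low, high, "cost", "triangular")


def _cf(name, base):  # cost with no published range -> fixed
    return ParameterSpec(name, base, base, base, "cost", "fixed")


def _p(name, low, base, high, dist="triangular"):
    return ParameterSpec(name, base, low, high, "probability", dist)


def _pf(name, base):
    return ParameterSpec(name, base, base, base, "probability", "fixed")


_DEFAULT_SPECS: tuple[ParameterSpec, ...] = (
    # --- crash costs by severity, human-piloted vehicle column ---
    _c("crash_cost_pdo_hpv", 2_976, 4_251, 5_526),
    _c("crash_cost_minor_hpv", 3_129, 12_282, 61_352),
    _c("crash_cost_severe_hpv", 200_241, 274_553, 1_101_865),
    _c("crash_cost_fatal_hpv", 1_072_412, 1_532_018, 1_991_623),
    # --- crash costs, autonomous vehicle column (scaled for AV equipment) ---
    _c("crash_cost_pdo_av", 3_123, 4_615, 5_799),
    _c("crash_cost_minor_av", 3_864, 13_332, 62_717),
    _c("crash_cost_severe_av", 214_206, 294_503, 1_127_800),
    _c("crash_cost_fatal_av", 1_086_965, 1_552_808, 2_018_650),
    # --- vehicle purchase prices ---
    _c("cost_vehicle_av", 122_218, 183_666, 265_648),
    _c("cost_vehicle_av_5yr", 33_229, 56_539, 100_383),
    _c("cost_vehicle_hpv", 17_218, 33_666, 70_648),
    _c("cost_vehicle_taxi_hpv", 92_699, 132_427, 172_155),
    _c("cost_vehicle_taxi_av", 197_699, 282_427, 367_155),
    # --- recurring and one-off costs ---
    _cf("cost_ownership_annual", 8_536),
    _c("cost_funeral", 6_206, 7_332, 8_687),
    _c("cost_productivity_annual", 552, 1_657, 2_762),
    _c("cost_parking_spot", 47_600, 102_000, 176_800),
    _c("cost_parking_spot_taxi", 0, 30_000, 80_000),
    _c("cost_taxi_salary", 19_432, 27_760, 36_088),
    # --- annual crash probabilities and conditional severity splits ---
    _pf("prob_crash_hpv", 0.0646),
    _pf("split_pdo_hpv", 0.6091),
    _pf("split_minor_hpv", 0.3766),
    _pf("split_severe_hpv", 0.0090),
    _pf("split_fatal_hpv", 0.0054),
    _p("prob_crash_av", 0.06729, 0.08385, 0.09319),
    _p("split_pdo_av", 0.9551, 0.9654, 0.9777),
    _p("split_minor_av", 0.0220, 0.0315, 0.0409),
    _p("split_severe_av", 2.09e-4, 2.99e-3, 3.88e-3),
    _p("split_fatal_av", 6.48e-5, 9.26e-5, 1.20e-4),
    # --- model constants ---
    ParameterSpec("discount_rate", 0.03, 0.0, 0.07, "rate", "fixed"),
    ParameterSpec("annual_vmt", 14_133, 14_133, 14_133, "count", "fixed"),
    ParameterSpec("productivity_fraction", 0.3, 0.0, 1.0, "rate", "fixed"),
    ParameterSpec("parking_spot_ratio", 3.4, 3.4, 3.4, "count", "fixed"),
    ParameterSpec("n_iterations", 10_000, 1, 10_000_000, "count", "fixed"),
    ParameterSpec("n_timesteps", 100, 1, 1_000, "count", "fixed"),
    _cf("wtp_threshold", 140_000),
    ParameterSpec("moore_halving_period", 2, 2, 2, "count", "fixed"),
    ParameterSpec("healthy_utility", 0.85, 0.0, 1.0, "utility", "fixed"),
    ParameterSpec("severe_injury_utility", 0.60, 0.0, 1.0, "utility", "fixed"),
    # --- calibrated structural choices, exposed for scenario analysis ---
    ParameterSpec("parking_amortization_years", 30, 1, 100, "count", "fixed"),
    ParameterSpec("parking_amortization_rate", 0.0, 0.0, 0.2, "rate", "fixed"),
    ParameterSpec("vehicle_mean_lifespan", 15, 1, 40, "count", "fixed"),
    ParameterSpec("vehicle_lifespan_shape", 4.0, 0.5, 20.0, "count", "fixed"),
    ParameterSpec("av_maintenance_premium_rate", 0.01, 0.0, 1.0, "rate", "fixed"),
    # scenario switch: inflate HPV crash probability for unreported crashes
    ParameterSpec("unreported_crash_multiplier", 1.0, 1.0, 2.0, "count", "fixed"),
)


class ParameterSet:
    """Immutable registry of :class:`ParameterSpec` keyed by name."""

    def __init__(self, specs: Mapping[str, ParameterSpec]):
        self._specs: dict[str, ParameterSpec] = dict(specs)

    # -- construction ------------------------------------------------------
    @classmethod
    def default(cls) -> "ParameterSet":
        return cls({s.name: s for s in _DEFAULT_SPECS})

    def with_values(self, overrides: Mapping[str, object]) -> "ParameterSet":
        """Return a new set with overrides applied.

        A scalar override replaces the base value (bounds widen to contain
        it); a mapping with any of ``low``/``base``/``high`` replaces those
        fields.  Unknown names and kind-invalid values raise
        :class:`ConfigError` naming the parameter.
        """
        unknown = sorted(set(overrides) - set(self._specs))
        if unknown:
            raise ConfigError(f"unknown parameter(s): {', '.join(unknown)}")
        new = dict(self._specs)
        for name, val in overrides.items():
            old = new[name]
            if isinstance(val, Mapping):
                bad = sorted(set(val) - {"low", "base", "high", "distribution"})
                if bad:
                    raise ConfigError(f"{name}: unknown field(s) {bad}")
                fields = {
                    "low": float(val.get("low", old.low)),
                    "base": float(val.get("base", old.base)),
                    "high": float(val.get("high", old.high)),
                    "distribution": val.get("distribution", old.distribution),
                }
            else:
                v = float(val)  # scalar: move the base, keep range around it
                fields = {
                    "low": min(old.low, v),
                    "base": v,
                    "high": max(old.high, v),
                    "distribution": old.distribution,
                }
            new[name] = ParameterSpec(name, fields["base"], fields["low"],
                                      fields["high"], old.kind,
                                      fields["distribution"])
        return ParameterSet(new)

    # -- access ------------------------------------------------------------
    def spec(self, name: str) -> ParameterSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise ConfigError(f"unknown parameter: {name}") from None

    def value(self, name: str) -> float:
        return self.spec(name).base

    def __getitem__(self, name: str) -> float:
        return self.value(name)

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def names(self) -> list[str]:
        return list(self._specs)

    def varied_names(self) -> list[str]:
        return [n for n, s in self._specs.items() if s.varied]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._specs == other._specs

    @property
    def constants(self) -> ModelConstants:
        v = self.value
        return ModelConstants(
            discount_rate=v("discount_rate"),
            annual_vmt=v("annual_vmt"),
            productivity_fraction=v("productivity_fraction"),
            parking_spot_ratio=v("parking_spot_ratio"),
            n_iterations=int(v("n_iterations")),
            n_timesteps=int(v("n_timesteps")),
            wtp_threshold=v("wtp_threshold"),
            moore_halving_period=v("moore_halving_period"),
            healthy_utility=v("healthy_utility"),
            severe_injury_utility=v("severe_injury_utility"),
        )

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (s.name, s.kind, s.low, s.base, s.high, s.distribution)
            for s in self._specs.values()
        ]
        return pd.DataFrame(
            rows, columns=["name", "kind", "low", "base", "high", "distribution"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def effective_values(self) -> dict[str, float]:
        return {n: s.base for n, s in self._specs.items()}

    def write_config(self, path_or_stream) -> None:
        """Dump the effective base values as a flat YAML mapping."""
        doc = yaml.safe_dump(self.effective_values(), sort_keys=False)
        if hasattr(path_or_stream, "write"):
            path_or_stream.write(doc)
        else:
            Path(path_or_stream).write_text(doc)


def load_parameters(config=None) -> ParameterSet:
    """Build a :class:`ParameterSet` from a flat YAML config (or mapping).

    ``config`` may be None (defaults), a mapping of overrides, or a path to a
    YAML file.  Keys absent from the config keep their base values; unknown
    keys are rejected.
    """
    base = ParameterSet.default()
    if config is None:
        return base
    if isinstance(config, Mapping):
        return base.with_values(config)
    try:
        text = Path(config).read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {config}: {exc}") from exc
    try:
        data = yaml.safe_load(io.StringIO(text))
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config {config}: {exc}") from exc
    if data is None:
        return base
    if not isinstance(data, Mapping):
        raise ConfigError(f"config {config} must be a flat key-value mapping")
    return base.with_values(data)


def sample_triangular(spec: ParameterSpec, rng: np.random.Generator, size=None):
    """One (or ``size``) draw(s) from triangular(low, mode=base, high).

    Degenerate ranges (low == high) return the base value exactly.
    """
    if spec.low >= spec.high:
        return np.full(size, spec.base) if size is not None else spec.base
    return rng.triangular(spec.low, spec.base, spec.high, size=size)


def sample_psa(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One probabilistic-sensitivity-analysis draw of the parameter set.

    Every ``triangular`` parameter with a proper range is replaced by a
    single triangular draw (mode at the base value); fixed parameters are
    left untouched.  Draw order follows registry order so results are
    reproducible for a given generator state.
    """
    new = {}
    for name in params.names():
        s = params.spec(name)
        if s.varied:
            draw = float(sample_triangular(s, rng))
            new[name] = dataclasses.replace(s, base=draw)
        else:
            new[name] = s
    return ParameterSet(new)
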