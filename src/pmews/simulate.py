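"""Synthetic prehospital cohort generator.

Generates labeled patient cohorts in **raw measurement space** (vital signs
and social factors, not scores) under a latent-severity two-class model:

1. the gold-standard label is drawn first, ``needs_ems ~ Bernoulli(p)``;
2. a latent illness severity ``z ~ Normal(mu_class, sigma_class)`` is drawn
   conditional on the label (negatives standardised to mean 0, SD 1);
3. each physiological parameter's severity *band* is chosen through a
   cumulative-logit ordinal link on z — ``P(sub-score >= k | z) =
   expit(slope*z - c_k)`` — and the measured value is then drawn uniformly
   on the chosen band's printed grid (open-ended bands capped at documented
   physiological extremes); two-sided bands (e.g. brady- vs tachycardia)
   pick the high side with a fixed per-parameter probability;
4. social flags are Bernoulli with logistic links on z; performance status
   uses an ordinal link; age is drawn from a truncated normal conditional
   on the age>65 flag so the flag and the emitted age always agree.

The label therefore influences measurements *only* through z, and scored
cohorts genuinely exercise the banded scoring engine. Generator parameters
are calibrated (see :mod:`pmews.calibrate`) so that the simulate -> score ->
evaluate chain reproduces the published cohort summary statistics; the
shipped result of that calibration is :func:`reference_config`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .bands import ConfigurationError, load_instrument
from .scoring import (
    CONSCIOUSNESS_CANONICAL,
    Consciousness,
    PHYSIO_PARAMETERS,
)

__all__ = [
    "OrdinalLink",
    "BinaryLink",
    "AgeModel",
    "GeneratorConfig",
    "simulate_cohort",
    "reference_config",
    "DEFAULT_CAPS",
    "SOCIAL_FLAGS",
]

REFERENCE_CONFIG_RESOURCE = "reference_config_v1.json"

#: caps closing the open-ended printed bands (documented physiological
#: extremes for a living transported adult; configurable per run)
DEFAULT_CAPS = {
    "respiratory_rate": (2, 60),
    "spo2": (60, 100),
    "heart_rate": (20, 200),
    "systolic_bp": (40, 250),
    "temperature": (30.0, 42.0),
}

SOCIAL_FLAGS = ("age_over_65", "socially_isolated", "chronic_disease")


@dataclass(frozen=True)
class OrdinalLink:
    """Cumulative-logit link: P(level >= k | z) = expit(slope*z - cutpoints[k-1])."""

    slope: float
    cutpoints: tuple[float, ...]

    def validate(self, name: str) -> None:
        if len(self.cutpoints) == 0:
            raise ConfigurationError(f"{name}: ordinal link needs >=1 cutpoint")
        if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ConfigurationError(
                f"{name}: cutpoints must be strictly increasing"
            )

    def levels(self, z: np.ndarray, u: np.ndarray) -> np.ndarray:
        c = np.asarray(self.cutpoints)
        p_ge = expit(self.slope * z[:, None] - c[None, :])  # decreasing in k
        return (u[:, None] < p_ge).sum(axis=1)


@dataclass(frozen=True)
class BinaryLink:
    """Bernoulli flag with log-odds = intercept + slope*z."""

    intercept: float
    slope: float

    def draw(self, z: np.ndarray, u: np.ndarray) -> np.ndarray:
        return u < expit(self.intercept + self.slope * z)


@dataclass(frozen=True)
class AgeModel:
    """Age conditional on the age>65 flag: truncated normals per stratum."""

    mu_under: float
    sd_under: float
    mu_over: float
    sd_over: float
    min_age: float = 12.0
    max_age: float = 100.0

    def validate(self) -> None:
        if not (self.min_age < 65.0 < self.max_age):
            raise ConfigurationError("age model must straddle the 65-year boundary")
        if self.sd_under <= 0 or self.sd_over <= 0:
            raise ConfigurationError("age SDs must be positive")

    def draw(self, over_65: np.ndarray, u: np.ndarray) -> np.ndarray:
        age = np.empty(len(over_65))
        m = over_65
        if m.any():
            a = (65.0 - self.mu_over) / self.sd_over
            b = (self.max_age - self.mu_over) / self.sd_over
            age[m] = truncnorm.ppf(u[m], a, b, loc=self.mu_over, scale=self.sd_over)
        if (~m).any():
            a = (self.min_age - self.mu_under) / self.sd_under
            b = (65.0 - self.mu_under) / self.sd_under
            age[~m] = truncnorm.ppf(
                u[~m], a, b, loc=self.mu_under, scale=self.sd_under
            )
        age = np.round(age, 1)
        # the flag is re-derived from age downstream; keep them consistent
        age[m] = np.maximum(age[m], 65.1)
        age[~m] = np.minimum(age[~m], 65.0)
        return age


@dataclass
class GeneratorConfig:
    """Full parameterisation of the latent-severity cohort simulator."""

    prevalence: float
    mu1: float
    sigma1: float
    physio: dict[str, OrdinalLink]
    social_flags: dict[str, BinaryLink]
    performance_status: OrdinalLink
    age: AgeModel
    mu0: float = 0.0
    sigma0: float = 1.0
    high_side_prob: dict[str, float] = field(default_factory=dict)
    caps: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_CAPS))
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must be in (0, 1)")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ConfigurationError("severity SDs must be positive")
        for name in PHYSIO_PARAMETERS:
            if name not in self.physio:
                raise ConfigurationError(f"physio link missing for {name}")
            self.physio[name].validate(name)
        for name in SOCIAL_FLAGS:
            if name not in self.social_flags:
                raise ConfigurationError(f"social flag link missing for {name}")
        self.performance_status.validate("performance_status")
        if len(self.performance_status.cutpoints) != 4:
            raise ConfigurationError("performance_status needs 4 cutpoints (levels 0-4)")
        for p, (lo, hi) in self.caps.items():
            if lo >= hi:
                raise ConfigurationError(f"caps for {p}: lo >= hi")
        for p, w in self.high_side_prob.items():
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"high_side_prob for {p} not in [0, 1]")
        self.age.validate()

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["caps"] = {k: list(v) for k, v in self.caps.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        d["physio"] = {
            k: OrdinalLink(v["slope"], tuple(v["cutpoints"]))
            for k, v in d["physio"].items()
        }
        d["social_flags"] = {
            k: BinaryLink(v["intercept"], v["slope"])
            for k, v in d["social_flags"].items()
        }
        ps = d["performance_status"]
        d["performance_status"] = OrdinalLink(ps["slope"], tuple(ps["cutpoints"]))
        d["age"] = AgeModel(**d["age"])
        d["caps"] = {k: tuple(v) for k, v in d["caps"].items()}
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _level_bands(instrument, caps) -> dict[str, dict[int, list[tuple[float, float, int]]]]:
    """Per parameter: sub-score level -> [(lo, hi, precision), ...] with caps."""
    out = {}
    for name, table in instrument["tables"].items():
        cap_lo, cap_hi = caps.get(name, (-np.inf, np.inf))
        levels: dict[int, list] = {}
        for band in table.bands:
            lo = band.lo if band.lo is not None else cap_lo
            hi = band.hi if band.hi is not None else cap_hi
            lo, hi = max(lo, cap_lo), min(hi, cap_hi)
            if lo > hi:
                raise ConfigurationError(
                    f"caps for {name} leave band {band} empty"
                )
            levels.setdefault(band.score, []).append((lo, hi, table.precision))
        out[name] = {k: sorted(v) for k, v in levels.items()}
    return out


def _uniform_on_grid(lo, hi, precision, u):
    """Uniform draw on the printed grid of [lo, hi] from uniforms u."""
    scale = 10 ** precision
    lo_g = int(np.ceil(np.rint(lo * scale)))
    hi_g = int(np.floor(np.rint(hi * scale)))
    k = np.minimum((u * (hi_g - lo_g + 1)).astype(int), hi_g - lo_g)
    return (lo_g + k) / scale


def simulate_cohort(
    config: GeneratorConfig, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Simulate ``n`` labeled patients; deterministic given (config, n, seed).

    Returns a DataFrame in the patient-CSV schema (including ``needs_ems``).
    ``seed=None`` falls back to ``config.seed``. The random draw order is
    fixed (label, severity, vitals in instrument order, social factors,
    age), and every record passes the scoring module's validation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    instrument = load_instrument()
    level_bands = _level_bands(instrument, config.caps)

    y = rng.random(n) < config.prevalence
    z = np.where(y, config.mu1, config.mu0) + np.where(
        y, config.sigma1, config.sigma0
    ) * rng.standard_normal(n)

    cols: dict[str, np.ndarray] = {}
    for name in PHYSIO_PARAMETERS:
        link = config.physio[name]
        u_level = rng.random(n)
        u_side = rng.random(n)
        u_val = rng.random(n)
        levels = link.levels(z, u_level)
        if name == "consciousness":
            tokens = np.array(
                [CONSCIOUSNESS_CANONICAL[Consciousness(k)] for k in range(4)]
            )
            cols[name] = tokens[levels]
            continue
        p_high = config.high_side_prob.get(name, 0.5)
        values = np.empty(n)
        for lev, bands in level_bands[name].items():
            m = levels == lev
            if not m.any():
                continue
            if len(bands) == 1:
                lo, hi, prec = bands[0]
                values[m] = _uniform_on_grid(lo, hi, prec, u_val[m])
            else:  # two-sided level: low band first (sorted by lo)
                high = u_side < p_high
                for band, pick in ((bands[0], m & ~high), (bands[1], m & high)):
                    if pick.any():
                        lo, hi, prec = band
                        values[pick] = _uniform_on_grid(lo, hi, prec, u_val[pick])
        cols[name] = values

    flags = {}
    for flag in SOCIAL_FLAGS:
        flags[flag] = config.social_flags[flag].draw(z, rng.random(n))
    ps = config.performance_status.levels(z, rng.random(n))
    age = config.age.draw(flags["age_over_65"], rng.random(n))

    width = len(str(n))
    return pd.DataFrame(
        {
            "patient_id": [f"sim-{seed}-{i:0{width}d}" for i in range(n)],
            "respiratory_rate": cols["respiratory_rate"].astype(int),
            "spo2": cols["spo2"].astype(int),
            "heart_rate": cols["heart_rate"].astype(int),
            "systolic_bp": cols["systolic_bp"].astype(int),
            "temperature_c": np.round(cols["temperature"], 1),
            "consciousness": cols["consciousness"],
            "age_years": age,
            "socially_isolated": flags["socially_isolated"].astype(int),
            "chronic_disease": flags["chronic_disease"].astype(int),
            "performance_status": ps.astype(int),
            "needs_ems": y.astype(int),
        }
    )


def reference_config() -> GeneratorConfig:
    """The shipped calibrated generator configuration.

    Produced by running :func:`pmews.calibrate.calibrate` against the
    published summary constraints and frozen as a versioned JSON resource;
    its calibration report is available via
    :func:`pmews.calibrate.reference_calibration_report`.
    """
    res = resources.files("pmews").joinpath("data", REFERENCE_CONFIG_RESOURCE)
    if not res.is_file():
        raise FileNotFoundError(
            f"{REFERENCE_CONFIG_RESOURCE} missing; run the calibration "
            "(pmews calibrate) to regenerate it"
        )
    return GeneratorConfig.from_dict(json.loads(res.read_text()))
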