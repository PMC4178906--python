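"""Banded ordinal scoring tables.

Early-warning instruments assign each vital sign an integer sub-score by
looking the measured value up in an ordered table of intervals (the printed
"bands"). Printed band tables are stated at a finite precision (whole
breaths/min, 0.1 degC, ...), so a measured value is first rounded half-up to
the table's precision and then matched against the bands on that grid.

Two defects of printed tables are handled explicitly:

* **Gaps.** Some tables leave values uncovered even on their own grid (the
  canonical example here: an oxygen saturation of exactly 89% falls between
  the "<89" and "90-93" bands). The ``nearest_higher_score`` gap rule assigns
  any residual uncovered value to the adjacent band with the *higher*
  sub-score — the fail-safe direction for a triage instrument.
* **Overlaps.** Overlapping bands are a configuration error and are rejected
  when the table is loaded, never silently resolved.

Tables ship as a versioned JSON resource (``data/pmews_bands_v1.json``) so
the instrument is auditable and swappable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Band",
    "ScoreBandTable",
    "ConfigurationError",
    "ValidationError",
    "round_half_up",
    "load_instrument",
    "load_band_tables",
    "DEFAULT_RESOURCE",
]

DEFAULT_RESOURCE = "pmews_bands_v1.json"


class ConfigurationError(ValueError):
    """An instrument definition or generator configuration is ill-formed."""


class ValidationError(ValueError):
    """An input value is outside its physiologically admissible range."""


def round_half_up(values, decimals: int = 0):
    """Round non-negative values half-up to ``decimals`` decimal places.

    Banker's rounding (numpy's default) would send 38.85 to 38.8; printed
    clinical tables are read half-up, so 38.85 -> 38.9.
    """
    v = np.asarray(values, dtype=float)
    f = 10.0 ** decimals
    out = np.floor(v * f + 0.5) / f
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Band:
    """One closed interval of a scoring table; ``None`` marks an open end."""

    lo: float | None
    hi: float | None
    score: int


class ScoreBandTable:
    """An ordered interval -> sub-score lookup for one vital-sign parameter.

    Parameters
    ----------
    parameter : name of the vital sign (e.g. ``"heart_rate"``).
    units : measurement units, for error messages.
    precision : number of decimals of the printed grid (0 for integer vitals,
        1 for temperature).
    plausible_range : ``(lo, hi)`` admissible measurement range; values
        outside raise :class:`ValidationError`.
    bands : iterable of :class:`Band`, in increasing value order.
    gap_rule : only ``"nearest_higher_score"`` is defined.
    """

    def __init__(
        self,
        parameter: str,
        units: str,
        precision: int,
        plausible_range: tuple[float, float],
        bands: Iterable[Band],
        gap_rule: str = "nearest_higher_score",
    ):
        self.parameter = parameter
        self.units = units
        self.precision = int(precision)
        self.plausible_range = (float(plausible_range[0]), float(plausible_range[1]))
        self.bands = list(bands)
        self.gap_rule = gap_rule
        self._scale = 10 ** self.precision
        self._lo_g = np.array(
            [self._to_grid(b.lo, -math.inf) for b in self.bands], dtype=float
        )
        self._hi_g = np.array(
            [self._to_grid(b.hi, math.inf) for b in self.bands], dtype=float
        )
        self._scores = np.array([b.score for b in self.bands], dtype=int)
        self._check()

    def _to_grid(self, x: float | None, default: float) -> float:
        if x is None:
            return default
        return float(np.rint(x * self._scale))

    def _check(self) -> None:
        if not self.bands:
            raise ConfigurationError(f"{self.parameter}: empty band table")
        if self.gap_rule != "nearest_higher_score":
            raise ConfigurationError(
                f"{self.parameter}: unknown gap rule {self.gap_rule!r}"
            )
        order = np.argsort(self._lo_g, kind="stable")
        lo, hi = self._lo_g[order], self._hi_g[order]
        if np.any(lo > hi):
            raise ConfigurationError(f"{self.parameter}: band with lo > hi")
        # overlap: next band must start strictly after the previous ends
        if np.any(lo[1:] <= hi[:-1]):
            raise ConfigurationError(f"{self.parameter}: overlapping bands")
        if not np.array_equal(order, np.arange(len(self.bands))):
            raise ConfigurationError(f"{self.parameter}: bands not in value order")

    @property
    def max_score(self) -> int:
        return int(self._scores.max())

    def severity_is_monotone(self) -> bool:
        """True if sub-scores never decrease moving away from the zero band."""
        scores = list(self._scores)
        if 0 not in scores:
            return False
        i0 = scores.index(0)
        left = scores[: i0 + 1]
        right = scores[i0:]
        return all(a >= b for a, b in zip(left, left[1:])) and all(
            b >= a for a, b in zip(right, right[1:])
        )

    def grid_values(self) -> np.ndarray:
        """Every admissible value on the table's rounding grid."""
        lo, hi = self.plausible_range
        lo_g = int(np.ceil(np.rint(lo * self._scale)))
        hi_g = int(np.floor(np.rint(hi * self._scale)))
        return np.arange(lo_g, hi_g + 1) / self._scale

    def _resolve_gap(self, g: float) -> int:
        below = [(hi, s) for hi, s in zip(self._hi_g, self._scores) if hi < g]
        above = [(lo, s) for lo, s in zip(self._lo_g, self._scores) if lo > g]
        candidates = []
        if below:
            candidates.append(max(below)[1])
        if above:
            candidates.append(min(above)[1])
        if not candidates:  # pragma: no cover - empty table rejected at init
            raise ConfigurationError(f"{self.parameter}: no band near value")
        return int(max(candidates))

    def score_values(self, values, *, validate: bool = True) -> np.ndarray:
        """Vectorised sub-score lookup (rounding, bands, then gap rule)."""
        v = np.asarray(values, dtype=float)
        scalar = v.ndim == 0
        v = np.atleast_1d(v)
        if np.isnan(v).any():
            raise ValidationError(
                f"{self.parameter}: missing value (NaN) under strict policy"
            )
        if validate:
            lo, hi = self.plausible_range
            bad = (v < lo) | (v > hi)
            if bad.any():
                shown = np.unique(v[bad])[:5]
                raise ValidationError(
                    f"{self.parameter}: value(s) {shown.tolist()} outside "
                    f"plausible range [{lo}, {hi}] {self.units}"
                )
        g = np.rint(round_half_up(v, self.precision) * self._scale)
        out = np.full(v.shape, -1, dtype=int)
        for lo_g, hi_g, s in zip(self._lo_g, self._hi_g, self._scores):
            m = (g >= lo_g) & (g <= hi_g)
            out[m] = s
        unmatched = out < 0
        if unmatched.any():
            for gv in np.unique(g[unmatched]):
                out[unmatched & (g == gv)] = self._resolve_gap(gv)
        return int(out[0]) if scalar else out

    def score_value(self, value: float) -> int:
        """Sub-score of a single measurement."""
        return int(self.score_values(value))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ScoreBandTable({self.parameter!r}, {len(self.bands)} bands)"


def _read_resource(source=None) -> dict:
    if source is None:
        text = (
            resources.files("pmews").joinpath("data", DEFAULT_RESOURCE).read_text()
        )
        return json.loads(text)
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return json.load(fh)


def load_instrument(source=None) -> dict:
    """Load the full instrument definition (band tables + consciousness map).

    Returns a dict with keys ``tables`` (parameter name ->
    :class:`ScoreBandTable`), ``consciousness_levels`` (token -> sub-score)
    and ``version``.
    """
    raw = _read_resource(source)
    tables = {}
    for p in raw["numeric_parameters"]:
        tables[p["name"]] = ScoreBandTable(
            parameter=p["name"],
            units=p["units"],
            precision=p["precision"],
            plausible_range=tuple(p["plausible_range"]),
            bands=[Band(b["lo"], b["hi"], b["score"]) for b in p["bands"]],
            gap_rule=raw.get("gap_rule", "nearest_higher_score"),
        )
    return {
        "version": raw.get("version", "?"),
        "tables": tables,
        "consciousness_levels": dict(raw["consciousness_levels"]),
    }


def load_band_tables(source=None) -> dict[str, ScoreBandTable]:
    """Parameter name -> :class:`ScoreBandTable` for the packaged instrument."""
    return load_instrument(source)["tables"]
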