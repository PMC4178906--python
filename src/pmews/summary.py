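"""Descriptive cohort summary (counts, percentages, means, SDs).

Percentages are rounded half-up to one decimal and means/SDs displayed at
two decimals, the precision at which such cohort tables are conventionally
printed. Standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = ["CohortSummary", "percentage", "round_half_up_decimal", "describe_cohort"]


def round_half_up_decimal(x: float, decimals: int) -> float:
    """Decimal half-up rounding of a float for display (38.85, 1 -> 38.9)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int) -> float:
    """100*count/total, rounded half-up to one decimal place."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be in [0, total]")
    value = Decimal(100 * count) / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    """Counts/percentages of the cohort characteristics plus score moments."""

    n_total: int
    n_labeled: int
    n_age_over_65: int
    pct_age_over_65: float
    n_isolated: int
    pct_isolated: float
    n_chronic: int
    pct_chronic: float
    n_needs_ems: int
    pct_needs_ems: float
    n_no_ems: int
    pct_no_ems: float
    age_mean: float
    age_sd: float
    physio_mean: float
    physio_sd: float
    social_mean: float
    social_sd: float
    total_mean: float
    total_sd: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        """Aligned characteristics table (flags first, then moments)."""
        rows = [
            ("Age > 65", self.n_age_over_65, self.pct_age_over_65),
            ("Social isolation", self.n_isolated, self.pct_isolated),
            ("Chronic disease", self.n_chronic, self.pct_chronic),
            ("Need of the EMS response", self.n_needs_ems, self.pct_needs_ems),
            ("Did not require the EMS response", self.n_no_ems, self.pct_no_ems),
        ]
        lines = [f"{'Character':<34}{'N':>6}{'%':>8}"]
        for name, n, pct in rows:
            lines.append(f"{name:<34}{n:>6}{pct:>8.1f}")
        lines.append("")
        lines.append(f"{'':<22}{'Mean':>8}{'SD':>8}")
        for name, m, s in [
            ("Age", self.age_mean, self.age_sd),
            ("Physiological score", self.physio_mean, self.physio_sd),
            ("Social score", self.social_mean, self.social_sd),
            ("PMEWS", self.total_mean, self.total_sd),
        ]:
            lines.append(
                f"{name:<22}"
                f"{round_half_up_decimal(m, 2):>8.2f}"
                f"{round_half_up_decimal(s, 2):>8.2f}"
            )
        return "\n".join(lines)


def describe_cohort(scored: pd.DataFrame) -> CohortSummary:
    """Summarise a scored cohort (output of ``score_dataframe``).

    Requires the score columns; the ``needs_ems`` column is optional (label
    counts are zero when absent). Raises on an empty cohort.
    """
    if len(scored) == 0:
        raise ValueError("empty cohort")
    for col in ("age_years", "physiological_score", "social_score", "total_pmews"):
        if col not in scored.columns:
            raise ValueError(f"missing required column: {col}")
    n = len(scored)
    age = pd.to_numeric(scored["age_years"]).to_numpy(dtype=float)
    iso = pd.to_numeric(scored["socially_isolated"]).to_numpy(dtype=int)
    chron = pd.to_numeric(scored["chronic_disease"]).to_numpy(dtype=int)

    def sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    if "needs_ems" in scored.columns and scored["needs_ems"].notna().any():
        lab = pd.to_numeric(scored["needs_ems"]).dropna().astype(int)
        n_lab = len(lab)
        n_pos = int(lab.sum())
    else:
        n_lab, n_pos = 0, 0

    n_over = int((age > 65).sum())
    n_iso = int(iso.sum())
    n_chr = int(chron.sum())
    return CohortSummary(
        n_total=n,
        n_labeled=n_lab,
        n_age_over_65=n_over,
        pct_age_over_65=percentage(n_over, n),
        n_isolated=n_iso,
        pct_isolated=percentage(n_iso, n),
        n_chronic=n_chr,
        pct_chronic=percentage(n_chr, n),
        n_needs_ems=n_pos,
        pct_needs_ems=percentage(n_pos, n_lab) if n_lab else float("nan"),
        n_no_ems=n_lab - n_pos,
        pct_no_ems=percentage(n_lab - n_pos, n_lab) if n_lab else float("nan"),
        age_mean=float(age.mean()),
        age_sd=sd(age),
        physio_mean=float(scored["physiological_score"].mean()),
        physio_sd=sd(scored["physiological_score"].to_numpy()),
        social_mean=float(scored["social_score"].mean()),
        social_sd=sd(scored["social_score"].to_numpy()),
        total_mean=float(scored["total_pmews"].mean()),
        total_sd=sd(scored["total_pmews"].to_numpy()),
    )
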