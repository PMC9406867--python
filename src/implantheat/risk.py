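"""Three-tier heating-risk classification and exam-category tabulation.

RF and GC channels are classified separately.  Tier 3 ("attention") means a
limit is exceeded; tier 2 ("warning") means no limit is exceeded but a
repetition or extension of the sequence — or the thermal steady state —
would exceed it; tier 1 is safe.  Limit equality stays in the lower tier
(strict inequalities, configurable).
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from implantheat.errors import ValidationError
from implantheat.rf import Limits, temporal_averages

__all__ = [
    "Scenario",
    "TierReport",
    "rf_tier",
    "gc_tier",
    "classify_matrix",
    "category_percentages",
]

ANATOMIES = ("hip", "knee", "shoulder")


@dataclass
class Scenario:
    """Stress metrics of one (configuration, sequence) pair."""

    scenario_id: str
    anatomy: str
    region: str = ""
    field_strength: str = ""
    sequence: str = ""
    xi_wb: float | None = None  # W/kg
    xi_10g: float | None = None  # W/kg
    psi: float | None = None
    TS: float | None = None  # s
    p: float | None = None  # W/m^3
    theta_end_max: float | None = None  # degC
    theta_inf_max: float | None = None  # degC

    def __post_init__(self) -> None:
        if self.anatomy not in ANATOMIES:
            raise ValidationError(f"unknown anatomy {self.anatomy!r}")
        for name in ("xi_wb", "xi_10g", "psi", "TS", "p", "theta_end_max", "theta_inf_max"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative")

    @property
    def has_rf(self) -> bool:
        return None not in (self.xi_wb, self.xi_10g, self.psi, self.TS)

    @property
    def has_gc(self) -> bool:
        return None not in (self.theta_end_max, self.theta_inf_max)


@dataclass
class TierReport:
    """Per-scenario tiers plus aggregate counts."""

    table: pd.DataFrame
    rf_counts: dict[int, int] = field(default_factory=dict)
    gc_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_scenarios(self) -> int:
        return len(self.table)


def rf_tier(scenario: Scenario, limits: Limits | None = None) -> int:
    """RF risk tier from the four SAR limit inequalities.

    Tier 3 if any of {6-min whole-body > K1, per-TR whole-body > 2*K1,
    6-min 10 g > K2_eff, per-TR 10 g > 2*K2_eff} holds; tier 2 if the
    per-TR averages exceed K1 / K2_eff; else tier 1.  K2_eff doubles K2 for
    knee implants.
    """
    limits = limits or Limits()
    if not scenario.has_rf:
        raise ValidationError(f"scenario {scenario.scenario_id!r} is missing RF metrics")
    k2 = limits.k2_effective(scenario.anatomy)
    wb_tr, wb_iec = temporal_averages(scenario.psi, scenario.xi_wb, scenario.TS, limits)
    g10_tr, g10_iec = temporal_averages(scenario.psi, scenario.xi_10g, scenario.TS, limits)
    if (
        wb_iec > limits.K1
        or wb_tr > 2.0 * limits.K1
        or g10_iec > k2
        or g10_tr > 2.0 * k2
    ):
        return 3
    if wb_tr > limits.K1 or g10_tr > k2:
        return 2
    return 1


def rf_inequality_values(scenario: Scenario, limits: Limits | None = None) -> dict:
    """The four limit ratios backing the RF tier decision (value / limit)."""
    limits = limits or Limits()
    k2 = limits.k2_effective(scenario.anatomy)
    wb_tr, wb_iec = temporal_averages(scenario.psi, scenario.xi_wb, scenario.TS, limits)
    g10_tr, g10_iec = temporal_averages(scenario.psi, scenario.xi_10g, scenario.TS, limits)
    return {
        "sar_wb_iec": wb_iec,
        "sar_wb_tr": wb_tr,
        "sar_10g_iec": g10_iec,
        "sar_10g_tr": g10_tr,
        "K1": limits.K1,
        "K2_eff": k2,
    }


def gc_tier(scenario: Scenario, limits: Limits | None = None) -> int:
    """GC risk tier from end-of-sequence and steady-state temperature rises.

    Tier 3 if the end-of-sequence rise exceeds the anatomy threshold (3 degC
    for knee, 2 degC otherwise); tier 2 if only the steady-state rise does;
    else tier 1.
    """
    limits = limits or Limits()
    if not scenario.has_gc:
        raise ValidationError(f"scenario {scenario.scenario_id!r} is missing GC metrics")
    if scenario.theta_inf_max < scenario.theta_end_max * (1 - 1e-9):
        raise ValidationError(
            "inconsistent metrics: steady-state rise below end-of-sequence rise"
        )
    threshold = limits.gc_threshold(scenario.anatomy)
    if scenario.theta_end_max > threshold:
        return 3
    if scenario.theta_inf_max > threshold:
        return 2
    return 1


def classify_matrix(
    scenarios: list[Scenario], limits: Limits | None = None
) -> TierReport:
    """Classify a scenario matrix and aggregate tier counts.

    Rows are ordered deterministically by (anatomy, region, field strength,
    sequence); duplicate scenario ids are rejected.
    """
    limits = limits or Limits()
    ids = [s.scenario_id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate scenario ids")
    ordered = sorted(
        scenarios, key=lambda s: (s.anatomy, s.region, s.field_strength, s.sequence)
    )
    rows = []
    for s in ordered:
        row = {
            "scenario_id": s.scenario_id,
            "anatomy": s.anatomy,
            "region": s.region,
            "field_strength": s.field_strength,
            "sequence": s.sequence,
            "rf_tier": rf_tier(s, limits) if s.has_rf else None,
            "gc_tier": gc_tier(s, limits) if s.has_gc else None,
            "gc_threshold": limits.gc_threshold(s.anatomy),
        }
        if s.has_rf:
            row.update(rf_inequality_values(s, limits))
        rows.append(row)
    table = pd.DataFrame(rows)
    rf_counts = {
        t: int((table["rf_tier"] == t).sum()) if "rf_tier" in table else 0
        for t in (1, 2, 3)
    }
    gc_counts = {
        t: int((table["gc_tier"] == t).sum()) if "gc_tier" in table else 0
        for t in (1, 2, 3)
    }
    return TierReport(table=table, rf_counts=rf_counts, gc_counts=gc_counts)


def category_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Percentages of labelled counts, rounded half-up to one decimal."""
    if any(c < 0 for c in counts.values()):
        raise ValidationError("counts must be nonnegative")
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("total count is zero")
    out = {}
    for label, c in counts.items():
        pct = decimal.Decimal(100 * c) / decimal.Decimal(total)
        out[label] = float(pct.quantize(decimal.Decimal("0.1"), decimal.ROUND_HALF_UP))
    return out
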