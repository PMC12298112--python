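"""Threshold-based tremor screening.

Screening decisions are single-feature cutoff comparisons.  The shipped
default rules place cutoffs on the x-axis spectral band power — 19.35 W/Hz on
the gyroscope for the overall parkinsonian screen, 9.07 and 6.43 W/Hz on the
accelerometer for rest and action tremor respectively — with the convention
that a feature value at or above the cutoff is positive.  An alternative
profile with the 19.71 W/Hz screening cutoff is provided, as both values
circulate for this feature; the default follows the tabulated operating
point.  Shipped values are demonstration defaults, not clinical claims:
re-derive cutoffs on your own labeled data with
:func:`tremorkit.stats.roc_analysis`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import ClassificationError


@dataclass(frozen=True)
class CutoffRule:
    """One screening rule: compare ``feature_name`` against ``threshold``.

    ``ge_positive`` marks values ≥ threshold positive (the boundary is
    inclusive); ``le_positive`` inverts the direction.
    """

    feature_name: str
    threshold: float
    direction: str = "ge_positive"
    label: str = "screen"

    def decide(self, value: float) -> bool:
        if self.direction == "ge_positive":
            return value >= self.threshold
        if self.direction == "le_positive":
            return value <= self.threshold
        raise ClassificationError(f"unknown rule direction {self.direction!r}")


DEFAULT_RULES: tuple[CutoffRule, ...] = (
    CutoffRule("PSD_gyr_x", 19.35, "ge_positive", "pd_screen"),
    CutoffRule("PSD_acc_x", 9.07, "ge_positive", "rest_tremor"),
    CutoffRule("PSD_acc_x", 6.43, "ge_positive", "action_tremor"),
)

#: Alternative profile using the 19.71 W/Hz screening cutoff.
ALT_RULES: tuple[CutoffRule, ...] = (
    CutoffRule("PSD_gyr_x", 19.71, "ge_positive", "pd_screen"),
) + DEFAULT_RULES[1:]

RULE_PROFILES: dict[str, tuple[CutoffRule, ...]] = {
    "default": DEFAULT_RULES,
    "alt_screen": ALT_RULES,
}


def classify(
    features: Mapping[str, float],
    rules: Iterable[CutoffRule] = DEFAULT_RULES,
) -> dict[str, bool]:
    """Apply every rule to one feature row; returns {label: positive?}.

    Decisions are deterministic and monotone: raising a feature can only turn
    a ``ge_positive`` decision positive, never the reverse.
    """
    out: dict[str, bool] = {}
    for rule in rules:
        value = features.get(rule.feature_name)
        if value is None or pd.isna(value):
            raise ClassificationError(
                f"feature {rule.feature_name!r} required by rule "
                f"{rule.label!r} is missing"
            )
        out[rule.label] = rule.decide(float(value))
    return out


def classify_table(
    table: pd.DataFrame, rules: Iterable[CutoffRule] = DEFAULT_RULES
) -> pd.DataFrame:
    """Apply :func:`classify` to every row of a feature table; decision
    columns are appended after the id columns."""
    rules = tuple(rules)
    decisions = [classify(row, rules) for row in table.to_dict("records")]
    out = table[[c for c in ("subject", "device", "repetition") if c in table.columns]].copy()
    for rule in rules:
        out[rule.label] = [d[rule.label] for d in decisions]
    return out
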