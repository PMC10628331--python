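"""Critical value list (CVL): data-driven panic-value thresholds.

A critical (panic) value is a result so far from normal that it signals an
immediately life-threatening state.  Laboratories keep a per-item list of
low/high thresholds; a result at or beyond either bound triggers a callback.
Here the list is machine-readable data, and it is also exposed as a
day-level hard classifier: a patient-day is predicted positive when any of
its results breaches its item's thresholds.  This is the baseline the
gradient-boosted model is compared against.

The shipped default fixture contains 22 numeric rules (12 chemistry, 7
hematology, 3 coagulation).  Item-code mapping between a site's LIS codes and
the fixture is handled by an optional alias table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_RULES_RESOURCE = "cvl_rules.json"


@dataclass(frozen=True)
class CVLRule:
    """Thresholds for one item; critical when value <= low or value >= high."""

    item_code: str
    low: float | None = None
    high: float | None = None
    units: str = ""
    name: str = ""
    category: str = ""

    def __post_init__(self):
        if self.low is None and self.high is None:
            raise ValueError(f"rule {self.item_code!r} has neither bound")
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise ValueError(f"rule {self.item_code!r}: low must be < high")

    def breaches(self, value: float) -> bool:
        if self.low is not None and value <= self.low:
            return True
        if self.high is not None and value >= self.high:
            return True
        return False


class CVLRuleSet:
    """Rules keyed by item_code, with vectorised flagging and day prediction."""

    def __init__(self, rules, aliases: dict[str, str] | None = None):
        self.rules: dict[str, CVLRule] = {}
        for rule in rules:
            if rule.item_code in self.rules:
                raise ValueError(f"duplicate rule for {rule.item_code!r}")
            self.rules[rule.item_code] = rule
        #: maps site-specific LIS item codes onto fixture item codes
        self.aliases = dict(aliases or {})

    def __len__(self) -> int:
        return len(self.rules)

    def __contains__(self, item_code: str) -> bool:
        return self._canonical(item_code) in self.rules

    def __getitem__(self, item_code: str) -> CVLRule:
        return self.rules[self._canonical(item_code)]

    def _canonical(self, item_code: str) -> str:
        return self.aliases.get(item_code, item_code)

    def flag_results(self, results: pd.DataFrame) -> pd.Series:
        """Boolean per result row: does it breach its item's thresholds?

        Results for items without a rule are never critical.
        """
        codes = results["item_code"].map(lambda c: self._canonical(c))
        low = codes.map({c: r.low for c, r in self.rules.items()})
        high = codes.map({c: r.high for c, r in self.rules.items()})
        value = results["value"]
        flags = ((value <= pd.to_numeric(low, errors="coerce"))
                 | (value >= pd.to_numeric(high, errors="coerce")))
        return flags.fillna(False).astype(bool)

    def predict_days(self, results: pd.DataFrame) -> pd.DataFrame:
        """Day-level predictions: one row per (patient_id, test_date).

        ``prediction`` is 1 when any of the day's results is critical.
        """
        if results.empty:
            raise ValueError("predict_days: empty result set")
        df = results[["patient_id", "test_date"]].copy()
        df["flag"] = self.flag_results(results).to_numpy()
        out = (df.groupby(["patient_id", "test_date"], sort=True)["flag"]
               .any().astype(int).rename("prediction").reset_index())
        return out


def flag_result(item_code: str, value: float, rules: CVLRuleSet) -> bool:
    """True iff the item has a rule and the value breaches it (bounds inclusive)."""
    if item_code not in rules:
        return False
    return rules[item_code].breaches(value)


def cvl_predict(day_results: pd.DataFrame, rules: CVLRuleSet) -> str:
    """Classify one patient-day of results: 'positive' iff any result flags."""
    if day_results.empty:
        raise ValueError("cvl_predict: empty result set")
    keys = day_results[["patient_id", "test_date"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("cvl_predict: results must share one (patient_id, test_date)")
    return "positive" if bool(rules.flag_results(day_results).any()) else "negative"


def _parse_rules(payload: dict, aliases=None) -> CVLRuleSet:
    rules = []
    for raw in payload["rules"]:
        low, high = raw.get("low"), raw.get("high")
        for bound in (low, high):
            if bound is not None and not math.isfinite(float(bound)):
                raise ValueError(f"non-numeric threshold in rule {raw.get('item_code')!r}")
        rules.append(CVLRule(
            item_code=raw["item_code"],
            low=None if low is None else float(low),
            high=None if high is None else float(high),
            units=raw.get("units", ""),
            name=raw.get("name", ""),
            category=raw.get("category", ""),
        ))
    return CVLRuleSet(rules, aliases)


def load_cvl(path=None, aliases: dict[str, str] | None = None) -> CVLRuleSet:
    """Load a rule set from JSON; with no path, the shipped 22-rule default."""
    if path is None:
        text = resources.files("labmort.data").joinpath(DEFAULT_RULES_RESOURCE).read_text()
    else:
        text = Path(path).read_text()
    return _parse_rules(json.loads(text), aliases)
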