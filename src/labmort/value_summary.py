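"""Per-item robust scaling parameters (the "value summary list").

For each laboratory item the quartiles Q1 and Q3 are computed over all of the
item's values, Tukey fences are derived as Q1 - 1.5*IQR and Q3 + 1.5*IQR, and
the reference mean mu_k and standard deviation sigma_k are then computed over
the values inside the closed fence interval.  These (mu_k, sigma_k) pairs are
what standardizes raw results into SDL units downstream.

Conventions, fixed for determinism and recorded in the serialized output:
quantiles use linear interpolation between order statistics (numpy's default,
"type 7"); sigma_k uses the sample (n-1) denominator; the fence interval is
closed, so boundary values are not outliers.  The fence is applied once (no
iteration).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = 1
QUANTILE_RULE = "linear"     # numpy interpolation="linear", i.e. type 7
SD_DENOMINATOR = "n-1"

_ENTRY_FIELDS = ("item_code", "q1", "q3", "fence_low", "fence_high",
                 "mu", "sigma", "n_total", "n_used")


@dataclass
class ValueSummaryEntry:
    """Robust scaling parameters for one laboratory item."""

    item_code: str
    q1: float
    q3: float
    fence_low: float
    fence_high: float
    mu: float
    sigma: float
    n_total: int
    n_used: int

    @property
    def degenerate(self) -> bool:
        """True when sigma_k is unusable (fenced subset < 2 values or zero spread)."""
        return self.sigma == 0.0


@dataclass
class ValueSummaryList:
    """Mapping item_code -> :class:`ValueSummaryEntry` plus provenance."""

    entries: dict[str, ValueSummaryEntry]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, item_code: str) -> ValueSummaryEntry:
        return self.entries[item_code]

    def __contains__(self, item_code: str) -> bool:
        return item_code in self.entries

    def frame(self) -> pd.DataFrame:
        """Entries as a DataFrame indexed by item_code."""
        return pd.DataFrame([asdict(e) for e in self.entries.values()]).set_index("item_code")


def summarize_item(item_code: str, values: np.ndarray) -> ValueSummaryEntry:
    """Build the summary entry for a single item's values."""
    values = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=QUANTILE_RULE)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    used = values[(values >= lo) & (values <= hi)]
    if len(used) < 2:
        mu = float(used.mean()) if len(used) else float("nan")
        sigma = 0.0
    else:
        mu = float(used.mean())
        sigma = float(used.std(ddof=1))
    return ValueSummaryEntry(item_code, float(q1), float(q3), float(lo), float(hi),
                             mu, sigma, int(len(values)), int(len(used)))


def build_value_summary(results: pd.DataFrame,
                        provenance: dict | None = None) -> ValueSummaryList:
    """Compute the value summary list from long-format results.

    Parameters
    ----------
    results : DataFrame with at least ``item_code`` and ``value`` columns
        (a ``Cohort.results`` frame qualifies).

    Items whose fenced subset has fewer than 2 values, or whose fenced values
    have zero spread, are retained with ``sigma = 0`` and flagged degenerate;
    featurization skips them with a counted warning.
    """
    if results is None or len(results) == 0:
        raise ValueError("build_value_summary: results must be non-empty")
    entries: dict[str, ValueSummaryEntry] = {}
    for code, grp in results.groupby("item_code", sort=True):
        entries[str(code)] = summarize_item(str(code), grp["value"].to_numpy())
    prov = dict(provenance or {})
    prov.setdefault("n_results", int(len(results)))
    return ValueSummaryList(entries, prov)


def save_value_summary(summary: ValueSummaryList, path) -> None:
    """Serialize to JSON at full floating precision."""
    payload = {
        "format_version": FORMAT_VERSION,
        "quantile_rule": QUANTILE_RULE,
        "sd_denominator": SD_DENOMINATOR,
        "provenance": summary.provenance,
        "entries": [asdict(e) for e in summary.entries.values()],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_value_summary(path) -> ValueSummaryList:
    """Load a summary saved by :func:`save_value_summary`; lossless round-trip."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported value summary format_version: {version!r}")
    entries = {}
    for raw in payload["entries"]:
        for fieldname in _ENTRY_FIELDS:
            if fieldname not in raw:
                raise ValueError(f"value summary entry missing field '{fieldname}'")
        entry = ValueSummaryEntry(**{k: raw[k] for k in _ENTRY_FIELDS})
        entries[entry.item_code] = entry
    return ValueSummaryList(entries, payload.get("provenance", {}))
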