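"""Bud-site sequence classification and tabulation.

A new daughter cell is scored by where its first two or three buds emerge
relative to the mother-daughter junction: adjacent to the junction pole
(``A``) or at the opposite pole (``O``).  The ordered sequence of calls
determines the budding pattern:

* all ``A``  -> **axial** (typical of non-filamentous haploids),
* all ``O``  -> **unipolar** (the filamentous signature),
* any mix    -> **bipolar**.

Angles are measured from the junction-pole axis, so 0° is the junction pole
and 180° the opposite pole; the equatorial threshold that separates an
``A`` call from an ``O`` call is configurable (default 90°, ties -> ``O``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PATTERN_ORDER

__all__ = [
    "BuddingPattern",
    "PatternTally",
    "call_site_from_angle",
    "classify_sequence",
    "sites_from_angles",
    "classify_records",
    "tabulate",
    "tallies_to_frame",
]


class BuddingPattern(str, Enum):
    AXIAL = "axial"
    BIPOLAR = "bipolar"
    UNIPOLAR = "unipolar"


_VALID_CODES = frozenset({"A", "O"})


def call_site_from_angle(angle_deg: float, threshold_deg: float = 90.0) -> str:
    """Call one bud site adjacent (``A``) or opposite (``O``) from its angle.

    The tie ``angle == threshold`` is assigned to ``O`` — conservative
    toward the filamentous (unipolar) call.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"bud angle {angle_deg!r} outside [0, 180] degrees")
    if not 0.0 <= threshold_deg <= 180.0:
        raise ValueError(f"threshold {threshold_deg!r} outside [0, 180] degrees")
    return "A" if angle_deg < threshold_deg else "O"


def sites_from_angles(
    angles_deg: Sequence[float], threshold_deg: float = 90.0
) -> list[str]:
    return [call_site_from_angle(a, threshold_deg) for a in angles_deg]


def classify_sequence(sites: Iterable[str]) -> BuddingPattern:
    """Classify one ordered A/O bud-site sequence of length 2 or 3."""
    seq = list(sites)
    if len(seq) not in (2, 3):
        raise ValueError(
            f"bud site sequence must have 2 or 3 sites, got {len(seq)}"
        )
    bad = [s for s in seq if s not in _VALID_CODES]
    if bad:
        raise ValueError(f"unknown site code(s) {bad!r}; expected 'A' or 'O'")
    if all(s == "A" for s in seq):
        return BuddingPattern.AXIAL
    if all(s == "O" for s in seq):
        return BuddingPattern.UNIPOLAR
    return BuddingPattern.BIPOLAR


_SITE_COLS = ("site_1", "site_2", "site_3")
_ANGLE_COLS = ("angle_1", "angle_2", "angle_3")


def _row_sites(row: pd.Series, threshold_deg: float) -> list[str]:
    sites: list[str] = []
    have_sites = any(
        c in row.index and isinstance(row[c], str) and row[c] for c in _SITE_COLS
    )
    if have_sites:
        for c in _SITE_COLS:
            v = row.get(c)
            if isinstance(v, str) and v:
                sites.append(v)
    else:
        for c in _ANGLE_COLS:
            v = row.get(c)
            if v is not None and not pd.isna(v):
                sites.append(call_site_from_angle(float(v), threshold_deg))
    return sites


def classify_records(
    records: pd.DataFrame, threshold_deg: float = 90.0
) -> pd.DataFrame:
    """Classify a bud-record table, returning it with ``n_sites``/``pattern``.

    Accepts either explicit ``site_1..site_3`` letter columns or
    ``angle_1..angle_3`` in degrees (letters win when both are present).
    """
    out = records.copy()
    patterns: list[str] = []
    n_sites: list[int] = []
    for _, row in out.iterrows():
        sites = _row_sites(row, threshold_deg)
        patterns.append(classify_sequence(sites).value)
        n_sites.append(len(sites))
    out["n_sites"] = n_sites
    out["pattern"] = patterns
    return out


@dataclass(frozen=True)
class PatternTally:
    """Pattern counts for one (condition, window, n_sites) group."""

    condition: str
    window: object
    n_sites: int
    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.get(p, 0) for p in PATTERN_ORDER)

    def count(self, pattern: str | BuddingPattern) -> int:
        return self.counts.get(str(getattr(pattern, "value", pattern)), 0)

    def percent(self, pattern: str | BuddingPattern) -> float | None:
        """Percentage of cells showing ``pattern``; None for an empty group."""
        tot = self.total
        if tot == 0:
            return None
        return 100.0 * self.count(pattern) / tot


def tabulate(
    classified: pd.DataFrame,
    by: Sequence[str] = ("condition", "window", "n_sites"),
) -> list[PatternTally]:
    """One :class:`PatternTally` per group of classified bud records."""
    if "pattern" not in classified.columns:
        raise ValueError("records must be classified first (no 'pattern' column)")
    tallies: list[PatternTally] = []
    if len(classified) == 0:
        return tallies
    for keys, grp in classified.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        info = dict(zip(by, keys))
        counts = {p: int((grp["pattern"] == p).sum()) for p in PATTERN_ORDER}
        tallies.append(
            PatternTally(
                condition=str(info.get("condition", "")),
                window=info.get("window"),
                n_sites=int(info.get("n_sites", 0)),
                counts=counts,
            )
        )
    return tallies


def tallies_to_frame(tallies: Iterable[PatternTally]) -> pd.DataFrame:
    rows = []
    for t in tallies:
        row: dict = {
            "condition": t.condition,
            "window": t.window,
            "n_sites": t.n_sites,
            "total": t.total,
        }
        for p in PATTERN_ORDER:
            row[f"n_{p}"] = t.count(p)
            pct = t.percent(p)
            row[f"pct_{p}"] = np.nan if pct is None else pct
        rows.append(row)
    return pd.DataFrame(rows)
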