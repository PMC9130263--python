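"""Two-sided Fisher exact test on 2x2 tables, and window-to-window comparisons.

The p-value is computed by enumerating the hypergeometric distribution over
the fixed table margins and summing the probabilities of all tables no more
probable than the observed one (the conventional two-sided definition; a
relative tolerance of 1e-7 guards floating-point ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .patterns import BuddingPattern, PatternTally

__all__ = [
    "FisherResult",
    "Transition",
    "fisher_exact_2x2",
    "compare_groups",
    "significant_transitions",
]

_TIE_REL_TOL = 1e-7


def fisher_exact_2x2(table: Sequence[int]) -> float:
    """Two-sided Fisher exact p for the 2x2 table ``(a, b, c, d)``.

    Rows are groups, columns outcome/non-outcome counts.  All entries must
    be non-negative integers and the table must contain at least one count.
    """
    if len(table) != 4:
        raise ValueError("table must be (a, b, c, d)")
    a, b, c, d = (int(x) for x in table)
    if any(int(x) != x or x < 0 for x in table):
        raise ValueError(f"table entries must be non-negative integers: {table!r}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table: Fisher test undefined")

    row1, col1 = a + b, a + c
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    # numerical guard: p is a probability in (0, 1]
    return min(max(p, float(p_obs)), 1.0)


@dataclass(frozen=True)
class FisherResult:
    """One pattern-vs-rest comparison between two tallied groups."""

    pattern: str
    groups: tuple[str, str]
    table: tuple[int, int, int, int]
    p_value: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _label(t: PatternTally) -> str:
    return f"{t.condition}/{t.window}"


def compare_groups(
    t1: PatternTally,
    t2: PatternTally,
    pattern: str | BuddingPattern,
    alpha: float = 0.05,
) -> FisherResult:
    """Fisher-test one pattern (vs all others) between two tallies.

    The 2x2 table is {pattern count, other-pattern count} x {group 1,
    group 2}; both tallies must score the same number of bud sites.
    """
    if t1.n_sites != t2.n_sites:
        raise ValueError(
            f"cannot compare tallies with different n_sites "
            f"({t1.n_sites} vs {t2.n_sites})"
        )
    pat = str(getattr(pattern, "value", pattern))
    a, c = t1.count(pat), t2.count(pat)
    b, d = t1.total - a, t2.total - c
    p = fisher_exact_2x2((a, b, c, d))
    return FisherResult(
        pattern=pat,
        groups=(_label(t1), _label(t2)),
        table=(a, b, c, d),
        p_value=p,
        alpha=alpha,
    )


@dataclass(frozen=True)
class Transition:
    """A significant unipolar increase between two consecutive windows."""

    window_from: object
    window_to: object
    percent_from: float
    percent_to: float
    result: FisherResult


def significant_transitions(
    tallies: Sequence[PatternTally],
    alpha: float = 0.05,
    pattern: str | BuddingPattern = BuddingPattern.UNIPOLAR,
    bonferroni: bool = False,
) -> list[Transition]:
    """Find consecutive-window increases of a pattern at significance alpha.

    ``tallies`` must be the window-ordered tallies of one condition and one
    bud-site depth.  Only increases count: a significant *decrease* in the
    tested pattern is not reported.  With ``bonferroni=True`` alpha is
    divided by the number of consecutive comparisons.
    """
    if len(tallies) < 2:
        raise ValueError("need at least two windows to test for transitions")
    n_sites = {t.n_sites for t in tallies}
    conditions = {t.condition for t in tallies}
    if len(n_sites) > 1 or len(conditions) > 1:
        raise ValueError(
            "tallies must share one condition and one n_sites "
            f"(got conditions={sorted(conditions)}, n_sites={sorted(n_sites)})"
        )
    pat = str(getattr(pattern, "value", pattern))
    n_tests = len(tallies) - 1
    eff_alpha = alpha / n_tests if bonferroni else alpha
    out: list[Transition] = []
    for t1, t2 in zip(tallies, tallies[1:]):
        if t1.total == 0 or t2.total == 0:
            continue  # empty window: nothing to test (flagged upstream)
        res = compare_groups(t1, t2, pat, alpha=eff_alpha)
        p1, p2 = t1.percent(pat), t2.percent(pat)
        if p2 > p1 and res.significant:
            out.append(
                Transition(
                    window_from=t1.window,
                    window_to=t2.window,
                    percent_from=p1,
                    percent_to=p2,
                    result=res,
                )
            )
    return out
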