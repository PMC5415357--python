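"""Group comparisons and summary presentation (mean ± s.e.m.).

One nerve = one animal = one observation.  Two-group comparisons use
Welch's unequal-variance t-test; paired designs use the paired t-test;
multi-group designs use one-way ANOVA followed by the Newman-Keuls
step-down procedure on the studentized range of ordered means.
Normality is assumed, not tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupTable:
    """Per-nerve metric values for one experimental group."""

    label: str
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return int(self.values.size)


def _as_group(g, label: str = "group") -> GroupTable:
    return g if isinstance(g, GroupTable) else GroupTable(label, np.asarray(g, float))


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Degrees of freedom by the Welch–Satterthwaite approximation.
    """
    a, b = _as_group(a, "a"), _as_group(b, "b")
    if a.n < 2 or b.n < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(a.values, b.values, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t(before, after) -> tuple[float, float, float]:
    """Paired t-test (one-sample t on differences, df = n - 1).

    A zero-variance, non-zero shift is degenerate: t is +/-inf and p = 0,
    reported as such rather than raised.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = after - before
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, float(n - 1), 1.0
        return float(np.sign(d.mean()) * np.inf), float(n - 1), 0.0
    res = sps.ttest_rel(after, before)
    return float(res.statistic), float(n - 1), float(res.pvalue)


def anova_nk(groups: Sequence) -> dict:
    """One-way ANOVA with Newman-Keuls post hoc on ordered means.

    The step-down procedure compares ordered group means with the
    studentized range distribution: the comparison of means r steps apart
    uses q with parameter r; a non-significant span blocks all
    comparisons nested inside it (p-values are made monotone along the
    step-down path).

    Returns ``{"F", "p", "df", "pairwise"}`` with ``pairwise`` a list of
    ``{"a", "b", "q", "p", "significant"}`` dicts at alpha = 0.05.
    """
    groups = [_as_group(g, f"g{i}") for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    ns = np.array([g.n for g in groups])
    n_total = int(ns.sum())
    df_err = n_total - k

    F, p = sps.f_oneway(*[g.values for g in groups])
    means = np.array([g.values.mean() for g in groups])
    sse = sum(((g.values - g.values.mean()) ** 2).sum() for g in groups)
    ms_err = sse / df_err

    order = np.argsort(means)          # ascending
    pairwise = []
    # step-down over spans from widest to narrowest; a retained (non-sig)
    # span caps the significance of everything nested inside it
    blocked_p: dict[tuple[int, int], float] = {}
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            i, j = order[lo], order[hi]
            if ms_err == 0:
                q = 0.0 if means[j] == means[i] else np.inf
            else:
                se = np.sqrt(ms_err / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[j] - means[i]) / se
            p_q = float(sps.studentized_range.sf(q, span, df_err)) if np.isfinite(q) else 0.0
            # monotonicity: nested comparisons cannot be more significant
            # than the span containing them
            parents = [
                blocked_p[key] for key in blocked_p
                if key[0] <= lo and hi <= key[1]
            ]
            if parents:
                p_q = max(p_q, max(parents))
            blocked_p[(lo, hi)] = p_q
            pairwise.append({
                "a": groups[i].label,
                "b": groups[j].label,
                "q": float(q),
                "p": p_q,
                "significant": bool(p_q < 0.05),
            })
    return {"F": float(F), "p": float(p), "df": (k - 1, df_err), "pairwise": pairwise}


def significance_stars(p: float) -> str:
    """Figure-legend star convention: *p<0.05, **p<0.01, ***p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize(groups: Sequence, reference: Optional[str] = None) -> pd.DataFrame:
    """Tidy mean ± s.e.m. table, one row per group.

    s.e.m. = SD/sqrt(n) with ddof=1; absent (NaN) for n = 1.  If
    ``reference`` names a group, each other group gains a Welch p-value
    and star annotation against it.
    """
    groups = [_as_group(g, f"g{i}") for i, g in enumerate(groups)]
    ref = next((g for g in groups if g.label == reference), None)
    rows = []
    for g in groups:
        if g.n == 0:
            raise ValueError(f"group {g.label!r} is empty")
        sem = float(g.values.std(ddof=1) / np.sqrt(g.n)) if g.n >= 2 else float("nan")
        row = {
            "group": g.label,
            "mean": float(g.values.mean()),
            "sem": sem,
            "n": g.n,
        }
        if ref is not None and g.label != ref.label and g.n >= 2 and ref.n >= 2:
            _, _, p = welch_t(ref, g)
            row["p_vs_ref"] = p
            row["stars"] = significance_stars(p)
        rows.append(row)
    return pd.DataFrame(rows)
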