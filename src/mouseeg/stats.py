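"""Genotype group statistics: one-way ANOVA, Tukey HSD, percent change.

F and q statistics are computed from their sums-of-squares definitions;
tail probabilities come from the F and studentized-range distributions
(scipy evaluates the studentized-range CDF by numerical integration).
Unequal group sizes use the Tukey-Kramer harmonic-mean correction.

No correction is applied across metrics or frequency bands: group
comparisons are reported per band/metric, each with its own ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import DegenerateInputError, ParameterError

__all__ = [
    "AnovaResult",
    "TukeyPair",
    "one_way_anova",
    "tukey_hsd",
    "percent_change",
    "group_stats_table",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_diff: float  # mean_b - mean_a
    q: float
    p_adj: float


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise ParameterError("need at least 2 groups")
    for name, vals in out.items():
        if vals.size < 2:
            raise ParameterError(f"group {name!r} has fewer than 2 subjects")
        if not np.isfinite(vals).all():
            raise ParameterError(f"group {name!r} contains non-finite values")
    return out


def _sums_of_squares(groups: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    return ss_between, ss_within, df_between, df_within


def one_way_anova(groups) -> AnovaResult:
    """Classic between/within mean-square ratio with an F-distribution p."""
    g = _as_groups(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(g)
    if ssw == 0:
        if ssb == 0:
            raise DegenerateInputError(
                "zero within-group variance with equal means; F undefined"
            )
        return AnovaResult(float("inf"), dfb, dfw, 0.0)
    msb = ssb / dfb
    msw = ssw / dfw
    F = msb / msw
    return AnovaResult(float(F), dfb, dfw, float(sstats.f.sf(F, dfb, dfw)))


def tukey_hsd(groups) -> list[TukeyPair]:
    """All pairwise comparisons with studentized-range adjusted p-values.

    q = |mean_i - mean_j| / sqrt(MSW / n_h) with n_h the harmonic mean of the
    two group sizes (Tukey-Kramer).
    """
    g = _as_groups(groups)
    _, ssw, _, dfw = _sums_of_squares(g)
    if ssw == 0:
        raise DegenerateInputError("zero within-group variance; q undefined")
    msw = ssw / dfw
    k = len(g)
    names = list(g)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = g[names[i]], g[names[j]]
            diff = b.mean() - a.mean()
            n_h = 2.0 / (1.0 / a.size + 1.0 / b.size)
            q = abs(diff) / np.sqrt(msw / n_h)
            p = float(sstats.studentized_range.sf(q, k, dfw))
            out.append(TukeyPair(names[i], names[j], float(diff), float(q),
                                 min(max(p, 0.0), 1.0)))
    return out


def percent_change(group_means: dict[str, float], reference: str = "WT") -> dict:
    """Per-group percent change relative to a reference group's mean."""
    if reference not in group_means:
        raise ParameterError(f"reference group {reference!r} missing")
    ref = group_means[reference]
    if ref == 0:
        raise ParameterError("reference mean is zero; percent change undefined")
    return {
        name: 100.0 * (mean - ref) / ref
        for name, mean in group_means.items()
        if name != reference
    }


def group_stats_table(
    table: pd.DataFrame, reference: str = "WT"
) -> pd.DataFrame:
    """Per-metric ANOVA + Tukey + percent change on a long-format table.

    ``table`` columns: subject_id, genotype, metric, value. Metrics with a
    degenerate distribution are reported with NaN statistics rather than
    aborting the run.
    """
    rows = []
    for metric, sub in table.groupby("metric", sort=True):
        groups = {
            gt: s["value"].to_numpy(dtype=float) for gt, s in sub.groupby("genotype")
        }
        means = {gt: float(v.mean()) for gt, v in groups.items()}
        try:
            an = one_way_anova(groups)
            pairs = tukey_hsd(groups)
            pct = percent_change(means, reference) if reference in means else {}
        except (DegenerateInputError, ParameterError):
            rows.append(dict(metric=metric, F=np.nan, p=np.nan, comparison="",
                             mean_diff=np.nan, p_adj=np.nan, pct_change=np.nan))
            continue
        for pair in pairs:
            other = pair.group_b if pair.group_a == reference else pair.group_a
            rows.append(
                dict(
                    metric=metric,
                    F=an.F,
                    p=an.p,
                    comparison=f"{pair.group_a}-{pair.group_b}",
                    mean_diff=pair.mean_diff,
                    p_adj=pair.p_adj,
                    pct_change=pct.get(other, np.nan)
                    if reference in (pair.group_a, pair.group_b)
                    else np.nan,
                )
            )
    return pd.DataFrame(rows)
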