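"""Group comparison and clonal-expansion arithmetic.

Genotype groups are compared with the Tukey-Kramer procedure: a one-way
ANOVA pooled error mean square, then for each pair of groups the
studentized-range statistic

    q = |m_i - m_j| / sqrt((MSE / 2) (1/n_i + 1/n_j))

with p-values from the studentized-range distribution with k groups and
N - k error degrees of freedom.  The Kramer form handles unequal group
sizes; with k = 2 the p-value reduces exactly to the pooled two-sample
t-test (q = sqrt(2) |t|).

The clonal-expansion helpers encode the bulk-sequencing dilution identity:
a variant at within-cell heteroplasmy h confined to a fraction c of cells
reads out at 100*c*h percent in bulk (e.g. 38% affected cells at 50%
heteroplasmy gives an expected bulk frequency of 19%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MitomutError
from .mutfreq import SampleSummary


class StatsError(MitomutError):
    pass


@dataclass
class PairwiseResult:
    pair: tuple[str, str]
    mean_diff: float       # m_i - m_j (signed)
    q_statistic: float
    p_value: float
    stars: str             # "" / "*" / "**"


@dataclass
class GroupComparison:
    labels: list[str]
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]   # sample SD (n-1 denominator)
    anova_mse: float
    df_error: int
    pairwise: list[PairwiseResult]

    def result(self, a: str, b: str) -> PairwiseResult:
        for r in self.pairwise:
            if set(r.pair) == {a, b}:
                return r
        raise KeyError((a, b))


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tukey_kramer(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """All-pairs Tukey-Kramer comparison of >= 2 groups.

    Degenerate case: if every observation is identical across all groups
    the contrast carries no information and p is defined as 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise StatsError("need at least two groups")
    data = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, x in data.items():
        if len(x) < 2:
            raise StatsError(f"group {g!r} has fewer than 2 values")

    k = len(labels)
    N = sum(len(x) for x in data.values())
    df_error = N - k
    means = {g: float(x.mean()) for g, x in data.items()}
    sds = {g: float(x.std(ddof=1)) for g, x in data.items()}
    sse = sum(float(((x - means[g]) ** 2).sum()) for g, x in data.items())
    mse = sse / df_error

    pairwise = []
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        if mse == 0.0:
            # all groups internally constant: identical means are a null
            # contrast (p=1); different means are an infinite q (p=0)
            q = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt((mse / 2.0) * (1.0 / len(data[a]) + 1.0 / len(data[b])))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_error))
            p = min(max(p, 0.0), 1.0)
        pairwise.append(
            PairwiseResult(pair=(a, b), mean_diff=diff, q_statistic=q,
                           p_value=p, stars=_stars(p))
        )
    return GroupComparison(labels=labels,
                           n={g: len(x) for g, x in data.items()},
                           mean=means, sd=sds, anova_mse=mse,
                           df_error=df_error, pairwise=pairwise)


def tukey_critical_q(alpha: float, k: int, df: int) -> float:
    """Critical studentized-range value q such that P(Q > q) = alpha."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


# ---------------------------------------------------------------------------
# clonal-expansion mixture arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureExpectation:
    cell_fraction: float
    within_cell_heteroplasmy: float
    expected_bulk_frequency: float  # percent


def expected_bulk_frequency(cell_fraction: float,
                            within_cell_heteroplasmy: float) -> float:
    """Bulk-tissue variant frequency (percent) expected when a fraction of
    cells carries the variant at a given within-cell heteroplasmy."""
    for name, v in (("cell_fraction", cell_fraction),
                    ("within_cell_heteroplasmy", within_cell_heteroplasmy)):
        if not 0.0 <= v <= 1.0:
            raise StatsError(f"{name} must lie in [0, 1], got {v}")
    return 100.0 * cell_fraction * within_cell_heteroplasmy


def detectable_heteroplasmy(cell_fraction: float,
                            bulk_frequency: float) -> tuple[float, bool]:
    """Within-cell heteroplasmy implied by a bulk frequency (percent).

    Returns (heteroplasmy, feasible).  When the implied heteroplasmy
    exceeds 1 the configuration is impossible (the bulk signal cannot come
    from that few cells); the value is capped at 1 and flagged infeasible.
    """
    if cell_fraction <= 0.0 or cell_fraction > 1.0:
        raise StatsError("cell_fraction must lie in (0, 1]")
    if bulk_frequency < 0.0:
        raise StatsError("bulk_frequency must be non-negative")
    h = bulk_frequency / (100.0 * cell_fraction)
    if h > 1.0:
        return 1.0, False
    return h, True


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

DEFAULT_METRICS = ("total_mut_freq", "n_nonsyn_gt1", "n_pathogenic_gt1",
                   "insertion_freq", "deletion_freq")


def _metric_value(summary: SampleSummary, metric: str) -> float:
    if hasattr(summary, metric):
        return float(getattr(summary, metric))
    if metric in summary.region_mut_freq:
        return float(summary.region_mut_freq[metric])
    raise StatsError(f"unknown metric {metric!r}")


def cohort_report(
    summaries: Sequence[SampleSummary],
    group_by: Sequence[str] = ("polg_genotype",),
    metrics: Sequence[str] = DEFAULT_METRICS,
) -> dict[str, pd.DataFrame]:
    """Mean +/- SD tables and Tukey-Kramer contrasts per organ x metric.

    Samples are grouped by the given SampleMeta fields (sorted group
    labels, so the report is order-invariant).  Returns
    ``{"means": ..., "tests": ...}`` DataFrames.
    """
    if not summaries:
        raise StatsError("no summaries given")
    organs = sorted({s.meta.organ for s in summaries})

    def group_label(s: SampleSummary) -> str:
        return "|".join(str(getattr(s.meta, f)) for f in group_by)

    mean_rows, test_rows = [], []
    for organ in organs:
        organ_summaries = [s for s in summaries if s.meta.organ == organ]
        labels = sorted({group_label(s) for s in organ_summaries})
        for metric in metrics:
            values = {
                lab: [_metric_value(s, metric) for s in organ_summaries
                      if group_label(s) == lab]
                for lab in labels
            }
            for lab in labels:
                if not values[lab]:
                    raise StatsError(f"empty group {lab!r} for organ {organ}")
                x = np.asarray(values[lab], dtype=float)
                mean_rows.append({
                    "organ": organ, "metric": metric, "group": lab,
                    "n": len(x), "mean": float(x.mean()),
                    "sd": float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
                })
            if len(labels) >= 2 and all(len(v) >= 2 for v in values.values()):
                comp = tukey_kramer(values)
                for r in comp.pairwise:
                    test_rows.append({
                        "organ": organ, "metric": metric,
                        "group_a": r.pair[0], "group_b": r.pair[1],
                        "mean_diff": r.mean_diff, "q": r.q_statistic,
                        "p_value": r.p_value, "stars": r.stars,
                    })
    return {
        "means": pd.DataFrame(mean_rows),
        "tests": pd.DataFrame(test_rows),
    }
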