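"""Group comparisons between mismatch-response populations.

Non-overlapping neurons (responsive in only one interleaved session) are
compared with the two-sided Wilcoxon-Mann-Whitney test; overlapping
neurons (mismatch-responsive in both sessions) with the two-sided
Wilcoxon signed-rank test, when at least two exist.  No normality is
assumed anywhere.  A within-mouse permutation test provides a robustness
check that respects the nested (neurons within mice) structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(x.size))


@dataclass
class GroupComparison:
    test_used: str
    statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    note: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class MismatchComparison:
    unpaired: GroupComparison
    paired: GroupComparison | None = None
    overlap_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "unpaired": self.unpaired.to_dict(),
            "paired": self.paired.to_dict() if self.paired else None,
            "overlap_ids": list(self.overlap_ids),
        }


def compare_mismatch_groups(
    responses_s1: pd.Series,
    responses_s2: pd.Series,
    overlap_ids=(),
) -> MismatchComparison:
    """Compare mismatch responses between two interleaved sessions.

    ``responses_s1``/``responses_s2`` are mean mismatch responses indexed
    by neuron id (each neuron appears in the session(s) where it was
    classified mismatch-responsive).  Non-overlapping neurons enter an
    unpaired Mann-Whitney test; overlapping neurons a paired signed-rank
    test if there are at least two (otherwise the paired test is skipped
    with a logged notice).  Both tests are two-sided.
    """
    overlap = set(overlap_ids)
    a = responses_s1[~responses_s1.index.isin(overlap)].to_numpy(dtype=float)
    b = responses_s2[~responses_s2.index.isin(overlap)].to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 non-overlapping neurons")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    unpaired = GroupComparison(
        "mann_whitney", float(stat), float(p),
        float(a.mean()), _sem(a), len(a), float(b.mean()), _sem(b), len(b),
    )

    paired = None
    pair_ids = sorted(overlap & set(responses_s1.index) & set(responses_s2.index))
    if len(pair_ids) >= 2:
        x = responses_s1.loc[pair_ids].to_numpy(dtype=float)
        y = responses_s2.loc[pair_ids].to_numpy(dtype=float)
        if np.allclose(x, y):
            stat_w, p_w = 0.0, 1.0
        else:
            stat_w, p_w = stats.wilcoxon(x, y, alternative="two-sided")
        paired = GroupComparison(
            "signed_rank", float(stat_w), float(p_w),
            float(x.mean()), _sem(x), len(x), float(y.mean()), _sem(y), len(y),
        )
    elif pair_ids:
        logger.info("paired test skipped: only %d overlapping neuron(s)", len(pair_ids))
    return MismatchComparison(unpaired, paired, pair_ids)


def permutation_test(
    values,
    group_labels,
    mouse_ids,
    n_perm: int = 1000,
    seed: int | None = None,
    statistic=None,
) -> float:
    """Two-sided permutation p-value for a two-group difference, stratified by mouse.

    Group labels are shuffled within each mouse; the default statistic is
    the difference of group means.  A mouse in which only one group is
    represented contributes no label exchanges.  p = (1 + #{|T_perm| >=
    |T_obs|}) / (n_perm + 1).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    mouse_ids = np.asarray(mouse_ids)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("permutation_test expects exactly 2 groups")
    if statistic is None:
        def statistic(vals, labels):
            return vals[labels == groups[0]].mean() - vals[labels == groups[1]].mean()

    exchangeable = [
        np.nonzero(mouse_ids == m)[0]
        for m in np.unique(mouse_ids)
        if len(np.unique(group_labels[mouse_ids == m])) > 1
    ]
    if not exchangeable:
        raise ValueError("no mouse has both groups represented; labels are not exchangeable")

    rng = np.random.default_rng(seed)
    t_obs = statistic(values, group_labels)
    count = 0
    labels = group_labels.copy()
    for _ in range(n_perm):
        labels[:] = group_labels
        for idx in exchangeable:
            labels[idx] = labels[rng.permutation(idx)]
        if abs(statistic(values, labels)) >= abs(t_obs) - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def scaling_summary(responses_by_level: dict) -> tuple[pd.DataFrame, bool]:
    """Mean +/- s.e.m. of responses per stimulus-deviation level.

    Levels are sorted ascending; the monotonicity indicator is True when
    means strictly increase with the deviation.  s.e.m. is NaN for a
    single-neuron level.
    """
    if not responses_by_level:
        raise ValueError("no levels given")
    rows = []
    for level in sorted(responses_by_level):
        vals = np.asarray(responses_by_level[level], dtype=float)
        if vals.size == 0:
            raise ValueError(f"level {level!r} is empty")
        rows.append({"level": level, "n": vals.size, "mean": float(vals.mean()), "sem": _sem(vals)})
    df = pd.DataFrame(rows)
    monotonic = bool(np.all(np.diff(df["mean"].to_numpy()) > 0)) if len(df) >= 2 else True
    return df, monotonic
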