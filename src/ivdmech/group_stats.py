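"""Outlier exclusion and the nested group comparison.

Viscoelastic properties are measured as several indents per specimen, with
three specimens per group; group (control vs mdg) is a fixed factor and
specimen a random factor.  For this design the group F-test with the
containment denominator degrees of freedom — number of specimens minus
number of groups, so F(1, 4) for 3 + 3 specimens — coincides with a one-way
ANOVA on the specimen means, which is taken as the normative definition
here; unbalanced indent counts are handled by weighting specimen means
equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "InsufficientReplicationError",
    "exclude_outliers",
    "compare_groups",
]

DEFAULT_CELL = ("structure", "level", "stage", "group")


class InsufficientReplicationError(ValueError):
    """A group has fewer than two specimens after exclusion."""


@dataclass(frozen=True)
class GroupComparison:
    """Result of the group fixed-effect test with specimen as random factor."""

    F: float
    df1: int
    df2: int
    p: float
    n_excluded: int
    group_means: dict[str, float]
    group_sds: dict[str, float]
    n_specimens: dict[str, int]

    @property
    def significant(self) -> bool:
        """Significance at the study's fixed alpha = 0.05."""
        return self.p < 0.05


def exclude_outliers(
    observations: pd.DataFrame,
    k: float = 3.0,
    cell: tuple[str, ...] = DEFAULT_CELL,
    value_col: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-pass k-sigma exclusion within each analysis cell.

    Within each cell (by default structure x level x stage x group, pooled
    over specimens), observations deviating from the cell mean by more than
    ``k`` sample standard deviations are excluded.  The rule is applied once
    to the original mean/SD — it does not iterate.

    Returns
    -------
    (kept, excluded) : tuple of DataFrame
    """
    if value_col not in observations.columns:
        raise KeyError(f"missing column {value_col!r}")
    cell = tuple(c for c in cell if c in observations.columns)
    if cell:
        grouped = observations.groupby(list(cell), sort=False)[value_col]
        mean = grouped.transform("mean")
        sd = grouped.transform("std")
    else:
        mean = pd.Series(observations[value_col].mean(), index=observations.index)
        sd = pd.Series(observations[value_col].std(), index=observations.index)
    dev = (observations[value_col] - mean).abs()
    # cells with < 2 observations have undefined SD: keep everything there
    keep = ~(dev > k * sd.fillna(np.inf))
    return observations[keep].copy(), observations[~keep].copy()


def compare_groups(
    observations: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    specimen_col: str = "specimen",
    n_excluded: int = 0,
) -> GroupComparison:
    """Group fixed-effect F-test with specimen as the random factor.

    Specimen means are computed first (equal weight per specimen regardless
    of indent count), then a one-way ANOVA across groups is performed on
    them.  The denominator degrees of freedom follow the containment
    convention, df2 = n_specimens - n_groups, and depend only on specimen
    counts, never on indent counts.

    Raises
    ------
    InsufficientReplicationError
        If any group has fewer than two specimens.
    """
    for col in (value_col, group_col, specimen_col):
        if col not in observations.columns:
            raise KeyError(f"missing column {col!r}")
    means = (
        observations.groupby([group_col, specimen_col], sort=False)[value_col]
        .mean()
        .reset_index()
    )
    counts = means.groupby(group_col, sort=False)[specimen_col].nunique()
    if (counts < 2).any() or len(counts) < 2:
        raise InsufficientReplicationError(
            "need >= 2 groups with >= 2 specimens each; got "
            + ", ".join(f"{g}: {n}" for g, n in counts.items())
        )

    groups = [sub[value_col].to_numpy() for _, sub in means.groupby(group_col, sort=False)]
    n_groups = len(groups)
    n_spec = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = n_groups - 1
    df2 = n_spec - n_groups
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        F = np.inf if ms_between > 0 else 0.0
    else:
        F = ms_between / ms_within
    p = float(stats.f.sf(F, df1, df2))

    by_group = means.groupby(group_col, sort=False)[value_col]
    return GroupComparison(
        F=float(F),
        df1=df1,
        df2=df2,
        p=p,
        n_excluded=n_excluded,
        group_means={g: float(v) for g, v in by_group.mean().items()},
        group_sds={g: float(v) for g, v in by_group.std().items()},
        n_specimens={g: int(v) for g, v in counts.items()},
    )
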