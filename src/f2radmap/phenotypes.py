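"""Phenotype-table helpers: parental group contrasts.

Works on long-format tables with one row per sample, a role/type column
distinguishing the two parental lines from progeny, and one column per
trait (e.g. days to flowering, days to bud).
"""

from __future__ import annotations

import pandas as pd


def parental_contrast(
    table: pd.DataFrame,
    trait: str,
    group_col: str = "role",
    parent1: str = "parent1",
    parent2: str = "parent2",
) -> dict[str, float]:
    """Mean trait difference between the two parental groups.

    Returns the per-group means, the contrast mean(parent2) - mean(parent1),
    and the range of pairwise differences between individual replicates.
    """
    g1 = table.loc[table[group_col] == parent1, trait].dropna()
    g2 = table.loc[table[group_col] == parent2, trait].dropna()
    if g1.empty or g2.empty:
        raise ValueError("both parental groups need at least one phenotyped replicate")
    diffs = [b - a for a in g1 for b in g2]
    return {
        "mean_parent1": float(g1.mean()),
        "mean_parent2": float(g2.mean()),
        "contrast": float(g2.mean() - g1.mean()),
        "min_pair_diff": float(min(diffs)),
        "max_pair_diff": float(max(diffs)),
        "n_parent1": int(len(g1)),
        "n_parent2": int(len(g2)),
    }
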