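"""Replicate-based genotype concordance/discordance and error-rate estimation.

Biological replicates of the same (homozygous) parent should genotype
identically; the fraction of disagreeing calls between replicate pairs is
therefore a direct readout of the per-call genotyping error rate. Because an
error in either member of a pair produces a discordance, the per-sample
error rate is roughly half the mean pairwise discordance (ignoring the
O(e^2) chance of coincident errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io import A, B, H, MISSING, GenotypeMatrix

#: discordance categories, named as in AB-format reports
CATEGORIES = ("A-B", "A-AB", "B-AB")


@dataclass
class DiscordanceReport:
    pair_discordance: dict[tuple[str, str], float]
    mean_discordance: float
    category_counts: dict[str, int]
    missing_involved: int
    compared: int
    estimated_error_rate: float

    def category_fractions(self) -> dict[str, float]:
        total = sum(self.category_counts.values())
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: v / total for c, v in self.category_counts.items()}


def _pair_category(a: int, b: int) -> str:
    s = {a, b}
    if s == {A, B}:
        return "A-B"
    if s == {A, H}:
        return "A-AB"
    return "B-AB"


def pairwise_discordance(matrix: GenotypeMatrix, replicate_group: str) -> DiscordanceReport:
    """Discordance over all unordered replicate pairs within a role group.

    Per pair, discordance = discordant / (discordant + concordant) over sites
    where both calls are non-missing; sites with a missing call in either
    member are tallied separately and excluded from the denominator.
    """
    idx = matrix.role_index(replicate_group)
    if len(idx) < 2:
        raise ValueError(f"replicate group {replicate_group!r} has fewer than 2 samples")
    cat_counts = {c: 0 for c in CATEGORIES}
    pair_disc: dict[tuple[str, str], float] = {}
    missing_involved = 0
    compared = 0
    for i, j in combinations(idx, 2):
        gi, gj = matrix.calls[i], matrix.calls[j]
        ok = (gi != MISSING) & (gj != MISSING)
        missing_involved += int((~ok).sum())
        disc = ok & (gi != gj)
        n_ok = int(ok.sum())
        compared += n_ok
        pair_disc[(matrix.samples[i], matrix.samples[j])] = (
            float(disc.sum() / n_ok) if n_ok else float("nan")
        )
        for a, b in zip(gi[disc], gj[disc]):
            cat_counts[_pair_category(int(a), int(b))] += 1
    mean_disc = float(np.nanmean(list(pair_disc.values())))
    return DiscordanceReport(
        pair_discordance=pair_disc,
        mean_discordance=mean_disc,
        category_counts=cat_counts,
        missing_involved=missing_involved,
        compared=compared,
        estimated_error_rate=estimate_error_rate(mean_disc),
    )


def estimate_error_rate(mean_discordance: float) -> float:
    """Per-sample genotype error rate estimated as half the mean replicate
    discordance (each of the two replicates contributes errors independently;
    the neglected coincident-error term is O(e^2))."""
    return mean_discordance / 2.0


def heterozygosity(matrix: GenotypeMatrix) -> pd.Series:
    """Heterozygous fraction of called genotypes per individual. For true F2
    progeny this converges to 0.5; heterozygote undercalling depresses it."""
    called = (matrix.calls != MISSING).sum(axis=1)
    het = (matrix.calls == H).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    return pd.Series(frac, index=matrix.samples, name="heterozygosity")
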