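"""Segregating-variant detection between phenotypic extreme groups.

For low-coverage data where a full QTL scan is impossible, compare the
earliest- and latest-phenotype progeny directly: a variant "segregates"
between the groups when each group has enough calls, each group's calls are
internally consistent, and the two group consensus calls differ. Candidates
are then annotated with their distance to nearby candidate genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CALL_CHARS, MISSING, GenotypeMatrix


@dataclass
class ExtremesConfig:
    low_cutoff: float = 127.0  # trait units (days); strict <
    high_cutoff: float = 137.0  # strict >
    min_calls_per_group: int = 4
    min_within_group_consistency: float = 0.70  # exclusive ("over 70%")
    proximity_bp: int = 1000

    def __post_init__(self) -> None:
        if self.low_cutoff >= self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")
        if not 0.5 < self.min_within_group_consistency <= 1.0:
            raise ValueError("consistency threshold outside (0.5, 1]")


def select_extremes(
    phenotypes: pd.Series, config: ExtremesConfig
) -> tuple[list[str], list[str]]:
    """Sample ids with phenotype strictly below low_cutoff / strictly above
    high_cutoff. The strict inequalities keep the groups disjoint."""
    low = phenotypes.index[phenotypes < config.low_cutoff].tolist()
    high = phenotypes.index[phenotypes > config.high_cutoff].tolist()
    return low, high


def _group_consensus(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker modal call, its fraction of non-missing calls, and the
    non-missing count, for one group's (samples x markers) calls."""
    counts = np.stack([(calls == c).sum(axis=0) for c in (0, 1, 2)])
    called = counts.sum(axis=0)
    modal = counts.argmax(axis=0).astype(np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        consistency = np.where(called > 0, counts.max(axis=0) / called, 0.0)
    modal[called == 0] = MISSING
    return modal, consistency, called


def segregating_variants(
    matrix: GenotypeMatrix,
    low_group: list[str],
    high_group: list[str],
    config: ExtremesConfig | None = None,
) -> pd.DataFrame:
    """Apply the three segregation rules in order: (1) at least
    ``min_calls_per_group`` calls in each group; (2) within-group
    consistency (modal-call fraction among non-missing calls) strictly above
    the threshold in each group; (3) differing group consensus calls.
    """
    if config is None:
        config = ExtremesConfig()
    if not low_group or not high_group:
        raise ValueError("both extreme groups must be non-empty")
    pos = {s: i for i, s in enumerate(matrix.samples)}
    low_idx = np.array([pos[s] for s in low_group])
    high_idx = np.array([pos[s] for s in high_group])
    mod_l, con_l, n_l = _group_consensus(matrix.calls[low_idx])
    mod_h, con_h, n_h = _group_consensus(matrix.calls[high_idx])
    enough = (n_l >= config.min_calls_per_group) & (n_h >= config.min_calls_per_group)
    consistent = (con_l > config.min_within_group_consistency) & (
        con_h > config.min_within_group_consistency
    )
    differs = (mod_l != mod_h) & (mod_l != MISSING) & (mod_h != MISSING)
    keep = enough & consistent & differs
    mk = matrix.markers
    return pd.DataFrame(
        {
            "marker": mk["id"].to_numpy()[keep],
            "chrom": mk["chrom"].to_numpy()[keep],
            "bp": mk["bp"].to_numpy()[keep],
            "consensus_low": [CALL_CHARS[int(c)] for c in mod_l[keep]],
            "consensus_high": [CALL_CHARS[int(c)] for c in mod_h[keep]],
            "consistency_low": con_l[keep],
            "consistency_high": con_h[keep],
            "n_low": n_l[keep],
            "n_high": n_h[keep],
        }
    )


def annotate_proximity(
    variants: pd.DataFrame,
    gene_intervals: list[tuple[str, int, int, str]],
    proximity_bp: int = 1000,
) -> pd.DataFrame:
    """Distance from each variant to its nearest gene interval.

    Variant positions are 1-based; intervals are 0-based half-open (BED), so
    interval [start, end) covers 1-based positions start+1 .. end. Distance
    is 0 inside a gene, otherwise the number of bases strictly between the
    variant and the nearest interval edge; variants within ``proximity_bp``
    are flagged.
    """
    out = variants.copy()
    nearest_gene, nearest_dist = [], []
    for _, row in out.iterrows():
        best_gene, best_dist = "", np.inf
        for chrom, start, end, name in gene_intervals:
            if chrom != row["chrom"]:
                continue
            pos0 = int(row["bp"]) - 1  # to 0-based
            if start <= pos0 < end:
                d = 0
            elif pos0 < start:
                d = start - pos0 - 1
            else:
                d = pos0 - end
            if d < best_dist:
                best_dist, best_gene = d, name
        nearest_gene.append(best_gene)
        nearest_dist.append(best_dist if np.isfinite(best_dist) else np.nan)
    out["nearest_gene"] = nearest_gene
    out["distance_bp"] = nearest_dist
    out["within_proximity"] = pd.Series(nearest_dist, index=out.index) <= proximity_bp
    return out
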