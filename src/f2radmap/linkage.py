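"""Linkage-map construction for an F2 intercross.

Pairwise recombination fractions come from the two-locus F2 codominant
multinomial likelihood, maximised by EM (the double-heterozygote class mixes
coupling and repulsion phases and is fractionally assigned). Markers are
clustered into linkage groups by a chi-square test of r = 0.5, ordered by a
seriation heuristic minimising the sum of adjacent recombination fractions
(with reference ordering as an alternative), and map distances accumulate
through the Kosambi map function. Diagnostics cover outlier markers,
per-individual crossover counts, genetic-vs-physical order correlation, and
the map-length inflation caused by genotype errors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import chi2, spearmanr

from .io import A, B, H, MISSING, GenotypeMatrix

LN10 = np.log(10.0)

__all__ = [
    "LinkageConfig",
    "RecombinationEstimate",
    "LinkageGroup",
    "GeneticMap",
    "kosambi_cM",
    "kosambi_inverse",
    "estimate_rf",
    "pairwise_rf",
    "adjacent_rf",
    "group_markers",
    "order_markers",
    "build_map",
    "remove_outlier_markers",
    "count_crossovers",
    "order_correlation",
    "inflation_diagnostics",
]


@dataclass
class LinkageConfig:
    grouping_p_threshold: float = 1e-23
    ordering: str = "seriation"  # or "reference"
    outlier_k: int = 4
    outlier_rf_threshold: float = 0.35
    min_group_size: int = 7
    min_informative: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.grouping_p_threshold < 1:
            raise ValueError("grouping_p_threshold outside (0, 1)")
        if self.ordering not in ("seriation", "reference"):
            raise ValueError(f"unknown ordering mode {self.ordering!r}")


@dataclass
class RecombinationEstimate:
    r: float
    lod: float
    n_informative: int


# ---------------------------------------------------------------------------
# Kosambi map function
# ---------------------------------------------------------------------------

def kosambi_cM(r):
    """Kosambi distance d = 25 ln((1+2r)/(1-2r)) in cM, for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d):
    """Inverse Kosambi: r = (e^{4d/100} - 1) / (2 (e^{4d/100} + 1))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    e = np.exp(4 * d / 100.0)
    r = (e - 1) / (2 * (e + 1))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# two-locus EM
# ---------------------------------------------------------------------------

def _class_probs(r):
    """The nine F2 two-locus genotype-class probabilities at recombination
    fraction r, ordered (AA, AH, AB, HA, HH, HB, BA, BH, BB)."""
    r = np.asarray(r, dtype=float)
    paa = (1 - r) ** 2 / 4
    pab = r**2 / 4
    pah = r * (1 - r) / 2
    phh = ((1 - r) ** 2 + r**2) / 2
    return np.stack(
        [paa, pah, pab, pah, phh, pah, pab, pah, paa], axis=-1
    )


def _em_rf(counts: np.ndarray, tol: float = 1e-6, max_iter: int = 1000):
    """Vectorised EM over the trailing axis of nine class counts.

    counts[..., c] with c ordered as in :func:`_class_probs`. Returns
    (r_hat, lod, n). Cells with zero informative count give nan/0.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    # recombinant gametes contributed deterministically by each class
    weights = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0], dtype=float)
    fixed = (counts * weights).sum(axis=-1)
    n_hh = counts[..., 4]
    safe_n = np.where(n > 0, n, 1.0)
    r = np.full(n.shape, 0.25)
    for _ in range(max_iter):
        w_hh = 2 * r**2 / ((1 - r) ** 2 + r**2)
        r_new = (fixed + n_hh * w_hh) / (2 * safe_n)
        r_new = np.clip(r_new, 1e-9, 0.5)
        if np.all(np.abs(r_new - r) < tol):
            r = r_new
            break
        r = r_new
    ll_hat = _loglik(r, counts)
    ll_null = _loglik(np.full(n.shape, 0.5), counts)
    lod = np.maximum((ll_hat - ll_null) / LN10, 0.0)
    r = np.where(n > 0, r, np.nan)
    lod = np.where(n > 0, lod, 0.0)
    return r, lod, n


def _loglik(r, counts):
    p = _class_probs(np.clip(r, 1e-12, 0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(p)
    return np.where(counts > 0, terms, 0.0).sum(axis=-1)


def _pair_class_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    ok = (gi != MISSING) & (gj != MISSING)
    code = 3 * gi[ok].astype(np.int64) + gj[ok]
    return np.bincount(code, minlength=9)


def estimate_rf(
    calls_i: np.ndarray, calls_j: np.ndarray, min_informative: int = 10
) -> RecombinationEstimate:
    """Maximum-likelihood recombination fraction between two markers from
    jointly non-missing F2 genotype calls, with the LOD of linkage."""
    if calls_i.shape != calls_j.shape:
        raise ValueError("call vectors must cover the same individuals")
    counts = _pair_class_counts(calls_i, calls_j)
    n = int(counts.sum())
    if n < min_informative:
        raise ValueError(f"only {n} jointly called individuals (< {min_informative})")
    r, lod, _ = _em_rf(counts)
    return RecombinationEstimate(float(r), float(lod), n)


def pairwise_rf(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs recombination fractions for a (individuals x markers) call
    matrix. Returns (R, LOD, N) square arrays; diagonal r = 0.

    Class counts for every pair come from one-hot matrix products, the EM
    runs vectorised over all pairs at once.
    """
    g = calls
    m = g.shape[1]
    oh = [(g == c).astype(np.float64) for c in (A, H, B)]
    counts = np.empty((m, m, 9))
    for i, oi in enumerate(oh):
        for j, oj in enumerate(oh):
            counts[:, :, 3 * i + j] = oi.T @ oj
    r, lod, n = _em_rf(counts)
    np.fill_diagonal(r, 0.0)
    return r, lod, n


def adjacent_rf(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recombination fraction and LOD for consecutive marker pairs only."""
    m = calls.shape[1]
    counts = np.stack(
        [_pair_class_counts(calls[:, j], calls[:, j + 1]) for j in range(m - 1)]
    )
    r, lod, _ = _em_rf(counts)
    return r, lod


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def linkage_p_values(lod: np.ndarray) -> np.ndarray:
    """p-value of the test of r = 0.5 from the linkage LOD via
    X^2 = 2 ln(10) LOD with one degree of freedom."""
    return chi2.sf(2 * LN10 * np.asarray(lod), df=1)


def group_markers(
    r: np.ndarray, lod: np.ndarray, config: LinkageConfig | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Cluster markers into linkage groups: transitive closure over pairs
    whose linkage p-value clears the threshold. Groups below
    ``min_group_size`` markers are discarded (returned separately)."""
    if config is None:
        config = LinkageConfig()
    m = r.shape[0]
    p = linkage_p_values(lod)
    linked = (p < config.grouping_p_threshold) & ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(linked), directed=False)
    groups, discarded = [], []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        (groups if len(idx) >= config.min_group_size else discarded).append(idx)
    groups.sort(key=len, reverse=True)
    return groups, discarded


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def _path_cost(order: np.ndarray, d: np.ndarray) -> float:
    return float(d[order[:-1], order[1:]].sum())


def _greedy_path(d: np.ndarray, start: int) -> np.ndarray:
    m = d.shape[0]
    visited = np.zeros(m, dtype=bool)
    order = [start]
    visited[start] = True
    for _ in range(m - 1):
        row = d[order[-1]].copy()
        row[visited] = np.inf
        nxt = int(np.argmin(row))
        order.append(nxt)
        visited[nxt] = True
    return np.array(order)


def _two_opt(order: np.ndarray, d: np.ndarray, max_sweeps: int = 50) -> np.ndarray:
    """Path 2-opt: reverse segments while the sum of adjacent distances
    improves. Reversing order[i:j+1] only changes the two boundary edges."""
    order = order.copy()
    m = len(order)
    for _ in range(max_sweeps):
        improved = False
        for i in range(m - 1):
            a = order[i - 1] if i > 0 else -1
            for j in range(i + 1, m):
                b = order[j + 1] if j + 1 < m else -1
                old = (d[a, order[i]] if a >= 0 else 0.0) + (
                    d[order[j], b] if b >= 0 else 0.0
                )
                new = (d[a, order[j]] if a >= 0 else 0.0) + (
                    d[order[i], b] if b >= 0 else 0.0
                )
                if new < old - 1e-12:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = True
        if not improved:
            break
    return order


def order_markers(
    group: np.ndarray,
    r: np.ndarray,
    config: LinkageConfig | None = None,
    bp: np.ndarray | None = None,
) -> np.ndarray:
    """Order the markers of one linkage group.

    seriation mode: greedy nearest-neighbour path on the r-hat distance
    matrix refined by 2-opt, minimising the sum of adjacent recombination
    fractions; reference mode: physical (bp) order. Orientation is flipped
    if needed so the Spearman correlation with physical position is >= 0.
    """
    if config is None:
        config = LinkageConfig()
    group = np.asarray(group)
    if len(group) < 2:
        raise ValueError("cannot order fewer than 2 markers")
    if config.ordering == "reference":
        if bp is None:
            raise ValueError("reference ordering needs physical positions")
        return group[np.argsort(bp[group], kind="stable")]
    d = r[np.ix_(group, group)].copy()
    d = np.where(np.isnan(d), 0.5, d)
    np.fill_diagonal(d, 0.0)
    # start from the putative telomere: the marker farthest from the rest
    start = int(np.argmax(d.sum(axis=1)))
    order = _two_opt(_greedy_path(d, start), d)
    ordered = group[order]
    if bp is not None and len(group) > 2:
        rho = spearmanr(np.arange(len(ordered)), bp[ordered]).statistic
        if rho is not None and not np.isnan(rho) and rho < 0:
            ordered = ordered[::-1]
    return ordered


# ---------------------------------------------------------------------------
# map
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    name: str
    table: pd.DataFrame  # columns: id, chrom, bp, cM (cumulative)

    @property
    def length_cM(self) -> float:
        return float(self.table["cM"].iloc[-1]) if len(self.table) else 0.0

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def density_per_Mb(self) -> float:
        span = (self.table["bp"].max() - self.table["bp"].min()) / 1e6
        return self.n_markers / span if span > 0 else float("nan")


@dataclass
class GeneticMap:
    groups: list[LinkageGroup] = field(default_factory=list)

    @property
    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for g in self.groups:
            t = g.table.copy()
            t.insert(0, "group", g.name)
            parts.append(t)
        if not parts:
            return pd.DataFrame(columns=["group", "id", "chrom", "bp", "cM"])
        return pd.concat(parts, ignore_index=True)

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [g.name for g in self.groups],
                "n_markers": [g.n_markers for g in self.groups],
                "length_cM": [g.length_cM for g in self.groups],
                "density_per_Mb": [g.density_per_Mb for g in self.groups],
            }
        )


# capping r-hat just below 0.5 keeps Kosambi finite for unlinked neighbours
_R_CAP = 0.4999


def build_map(
    matrix: GenotypeMatrix,
    ordered_groups: list[np.ndarray],
    r: np.ndarray,
) -> GeneticMap:
    """Accumulate Kosambi distances over adjacent ordered markers in each
    group. Group names come from the majority chromosome of their markers."""
    mk = matrix.markers
    groups = []
    seen: dict[str, int] = {}
    for idx in ordered_groups:
        idx = np.asarray(idx)
        adj = np.clip(r[idx[:-1], idx[1:]], 0.0, _R_CAP) if len(idx) > 1 else np.array([])
        adj = np.where(np.isnan(adj), _R_CAP, adj)
        cm = np.concatenate([[0.0], np.cumsum(kosambi_cM(adj))]) if len(idx) > 1 else np.array([0.0])
        table = pd.DataFrame(
            {
                "id": mk["id"].to_numpy()[idx],
                "chrom": mk["chrom"].to_numpy()[idx],
                "bp": mk["bp"].to_numpy()[idx],
                "cM": cm,
            }
        )
        name = table["chrom"].mode().iat[0]
        if name in seen:
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 1
        groups.append(LinkageGroup(name, table))
    groups.sort(key=lambda g: g.name)
    return GeneticMap(groups)


def remove_outlier_markers(
    matrix: GenotypeMatrix,
    ordered_groups: list[np.ndarray],
    r: np.ndarray,
    config: LinkageConfig | None = None,
) -> tuple[list[np.ndarray], list[str]]:
    """Drop markers out of linkage with their ordered neighbourhood: mean
    r-hat to the k nearest ordered neighbours above the threshold."""
    if config is None:
        config = LinkageConfig()
    k = config.outlier_k
    kept_groups, removed = [], []
    ids = matrix.markers["id"].to_numpy()
    for idx in ordered_groups:
        idx = np.asarray(idx)
        m = len(idx)
        keep = np.ones(m, dtype=bool)
        for pos in range(m):
            lo = max(0, pos - k // 2)
            hi = min(m, pos + k // 2 + 1)
            nb = [idx[q] for q in range(lo, hi) if q != pos]
            if not nb:
                continue
            vals = r[idx[pos], nb]
            vals = vals[~np.isnan(vals)]
            if len(vals) and vals.mean() > config.outlier_rf_threshold:
                keep[pos] = False
                removed.append(str(ids[idx[pos]]))
        kept_groups.append(idx[keep])
    return kept_groups, removed


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def count_crossovers(matrix: GenotypeMatrix, gmap: GeneticMap) -> pd.DataFrame:
    """Crossovers per individual per linkage group by scanning consecutive
    non-missing calls: a hom<->het transition counts 1, hom<->opposite-hom
    counts 2 (a double recombinant), missing calls are skipped."""
    col_of = {mid: j for j, mid in enumerate(matrix.markers["id"])}
    prog = matrix.progeny_index
    out = {}
    for g in gmap.groups:
        cols = np.array([col_of[m] for m in g.table["id"]])
        calls = matrix.calls[np.ix_(prog, cols)]
        counts = np.zeros(len(prog), dtype=np.int64)
        for i in range(len(prog)):
            v = calls[i][calls[i] != MISSING]
            if len(v) > 1:
                counts[i] = int(np.abs(np.diff(v.astype(np.int64))).sum())
        out[g.name] = counts
    df = pd.DataFrame(out, index=[matrix.samples[i] for i in prog])
    return df


def order_correlation(gmap: GeneticMap) -> pd.Series:
    """Spearman rank correlation between genetic order and physical position
    per linkage group (orientation already chosen during ordering)."""
    rhos = {}
    for g in gmap.groups:
        if g.n_markers < 3:
            rhos[g.name] = float("nan")
            continue
        rhos[g.name] = float(
            spearmanr(np.arange(g.n_markers), g.table["bp"].to_numpy()).statistic
        )
    return pd.Series(rhos, name="spearman_rho")


def inflation_diagnostics(map_corrected: GeneticMap, map_uncorrected: GeneticMap) -> dict:
    """Compare total lengths of maps built from corrected vs raw genotypes.

    Genotype errors masquerade as double recombinants and can only lengthen
    the estimated map; the ratio quantifies that inflation.
    """
    lc, lu = map_corrected.total_length_cM, map_uncorrected.total_length_cM
    nc = map_corrected.n_markers - len(map_corrected.groups)
    nu = map_uncorrected.n_markers - len(map_uncorrected.groups)
    if map_corrected.n_markers == 0 or map_uncorrected.n_markers == 0:
        raise ValueError("cannot diagnose inflation on an empty map")
    mean_int_c = lc / nc if nc > 0 else float("nan")
    mean_int_u = lu / nu if nu > 0 else float("nan")
    return {
        "length_corrected_cM": lc,
        "length_uncorrected_cM": lu,
        "ratio": lu / lc if lc > 0 else float("inf"),
        "mean_interval_corrected_cM": mean_int_c,
        "mean_interval_uncorrected_cM": mean_int_u,
        "excess_per_interval_cM": mean_int_u - mean_int_c,
    }
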