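"""Genome-wide single-QTL scanning on an F2 genotype matrix.

The primary scan is nonparametric: at each marker the tie-corrected
Kruskal-Wallis statistic H over the genotype classes, reported on the LOD
scale as H / (2 ln 10) — appropriate for traits such as flowering time whose
distributions are far from normal. Genome-wide significance comes from a
permutation test of the maximum LOD; support intervals use the conventional
1.5-LOD drop; variance explained and allelic effects come from a
Haley-Knott least-squares fit at the peak marker
(PVE = 100 (1 - 10^{-2 LOD / n})).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import A, B, H, MISSING, GenotypeMatrix
from .linkage import GeneticMap

LN10 = np.log(10.0)


@dataclass
class ScanConfig:
    model: str = "nonparametric"
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("nonparametric", "haley_knott"):
            raise ValueError(f"unknown scan model {self.model!r}")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha outside (0, 1]")


@dataclass
class QTLPeak:
    marker: str
    group: str
    cM: float
    bp: int
    lod: float
    interval_markers: tuple[str, str]
    interval_cM: tuple[float, float]
    interval_bp: tuple[int, int]
    pve: float | None = None
    additive: float | None = None
    dominance: float | None = None


@dataclass
class ScanResult:
    table: pd.DataFrame  # marker, group, cM, bp, lod
    threshold: float
    perm_maxima: np.ndarray
    peaks: list[QTLPeak] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kruskal-Wallis core
# ---------------------------------------------------------------------------

def _kw_stat(ranks: np.ndarray, masks: list[np.ndarray], tie_factor: float) -> np.ndarray:
    """Tie-corrected H for columns sharing one missingness pattern.

    ranks: (N,) ranks of the phenotype subset; masks: per-class boolean
    arrays (N, k). Classes with fewer than 2 members at a column make that
    column nan (caller falls back to an exact recomputation).
    """
    N = len(ranks)
    h = np.zeros(masks[0].shape[1])
    small = np.zeros(masks[0].shape[1], dtype=bool)
    n_classes = np.zeros(masks[0].shape[1], dtype=int)
    for mask in masks:
        n_c = mask.sum(axis=0)
        r_c = ranks @ mask
        present = n_c > 0
        small |= (n_c == 1)
        n_classes += present.astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            h += np.where(n_c > 0, r_c**2 / np.maximum(n_c, 1), 0.0)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    h = h / tie_factor if tie_factor > 0 else np.full_like(h, np.nan)
    h[small] = np.nan  # needs exact handling with those individuals dropped
    h[n_classes < 2] = np.nan
    return h


def _tie_factor(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    n = len(y)
    if n < 2:
        return 0.0
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def _kw_exact(g: np.ndarray, y: np.ndarray) -> float:
    """Single-marker H dropping classes with < 2 members (ranks recomputed
    over the remaining individuals)."""
    keep = np.zeros(len(g), dtype=bool)
    n_classes = 0
    for c in (A, H, B):
        sel = g == c
        if sel.sum() >= 2:
            keep |= sel
            n_classes += 1
    if n_classes < 2:
        raise ValueError("fewer than 2 genotype classes with >= 2 members")
    yk, gk = y[keep], g[keep]
    ranks = rankdata(yk)
    n = len(yk)
    h = 0.0
    for c in (A, H, B):
        sel = gk == c
        if sel.any():
            h += ranks[sel].sum() ** 2 / sel.sum()
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tf = _tie_factor(yk)
    return h / tf if tf > 0 else 0.0


class _SortedPhenotype:
    """Tie structure of a phenotype vector in sorted order, reused across
    permutations (permuting the phenotype only permutes which individual
    carries which sorted value, never the sorted values themselves)."""

    def __init__(self, y_sorted: np.ndarray):
        self.y = y_sorted
        n = len(y_sorted)
        new_seg = np.concatenate([[True], y_sorted[1:] != y_sorted[:-1]])
        self.seg_id = np.cumsum(new_seg) - 1  # tie-segment per sorted row
        starts = np.flatnonzero(new_seg)
        self.seg_ends = np.concatenate([starts[1:] - 1, [n - 1]])


def _scan_sorted(calls_sorted: np.ndarray, prep: _SortedPhenotype) -> np.ndarray:
    """Tie-corrected Kruskal-Wallis LOD per marker, with genotype rows
    pre-sorted by phenotype.

    In sorted order the subset rank of a non-missing call is a cumulative
    count of non-missing calls, and midranks within phenotype-tie segments
    are segment-boundary averages, so the whole scan is a handful of
    cumulative sums and reductions — no per-column ranking.
    """
    n, m = calls_sorted.shape
    S = calls_sorted != MISSING
    has_missing = S.size and not S.all()
    if has_missing:
        C = np.cumsum(S, axis=0)
        N = C[-1].astype(float)
        c_end = C[prep.seg_ends]  # non-missing count up to each segment end
        c_before = np.vstack([np.zeros(m, dtype=C.dtype), c_end[:-1]])
        # midrank shared by every selected row of a tie segment
        mid = (c_before[prep.seg_id] + 1 + c_end[prep.seg_id]) / 2.0
        t = (c_end - c_before).astype(float)  # subset tie sizes per segment
        tie_sum = (t**3 - t).sum(axis=0)
    else:
        # complete columns: the subset midranks are the global midranks,
        # identical for every column, so rank sums reduce to matvecs
        N = np.full(m, float(n))
        ends = prep.seg_ends.astype(float)
        starts = np.concatenate([[0.0], ends[:-1] + 1])
        mr = ((starts + ends) / 2.0 + 1.0)[prep.seg_id]  # (n,)
        sizes = ends - starts + 1
        tie_sum = np.full(m, (sizes**3 - sizes).sum())
    h = np.zeros(m)
    n_classes = np.zeros(m, dtype=int)
    singleton = np.zeros(m, dtype=bool)
    for c in (A, H, B):
        mask = calls_sorted == c
        n_c = mask.sum(axis=0)
        r_c = (mid * mask).sum(axis=0) if has_missing else mr @ mask
        n_classes += n_c > 0
        singleton |= n_c == 1
        with np.errstate(invalid="ignore", divide="ignore"):
            h += np.where(n_c > 0, r_c**2 / np.maximum(n_c, 1), 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
        tie_term = 1.0 - tie_sum / (N**3 - N)
        h = h / tie_term
    h[(N < 3) | (tie_term <= 0)] = 0.0
    # columns needing the dropped-class convention: recompute exactly
    bad = singleton | (n_classes < 2)
    for k in np.flatnonzero(bad):
        try:
            h[k] = _kw_exact(calls_sorted[:, k], prep.y)
        except ValueError:
            h[k] = 0.0
    return np.maximum(h, 0.0) / (2 * LN10)


def _scan_lod(calls: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Kruskal-Wallis LOD per marker for (individuals x markers) calls."""
    order = np.argsort(y, kind="stable")
    return _scan_sorted(calls[order], _SortedPhenotype(y[order]))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _aligned_phenotype(matrix: GenotypeMatrix, phenotypes: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    prog = matrix.progeny_index
    names = [matrix.samples[i] for i in prog]
    missing = [s for s in names if s not in phenotypes.index]
    if missing:
        raise ValueError(f"progeny without phenotype: {missing[:5]}")
    return prog, phenotypes.loc[names].to_numpy(dtype=float)


def scan_np(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    gmap: GeneticMap | None = None,
) -> pd.DataFrame:
    """Nonparametric (Kruskal-Wallis) single-QTL scan at every marker.

    Returns a frame with marker, group, cM (map coordinates when a genetic
    map is supplied, otherwise physical order), bp and lod.
    """
    prog, y = _aligned_phenotype(matrix, phenotypes)
    if gmap is not None:
        mf = gmap.to_frame()
        col_of = {mid: j for j, mid in enumerate(matrix.markers["id"])}
        cols = np.array([col_of[m] for m in mf["id"]], dtype=np.intp)
        lod = _scan_lod(matrix.calls[np.ix_(prog, cols)], y)
        return pd.DataFrame(
            {
                "marker": mf["id"],
                "group": mf["group"],
                "cM": mf["cM"],
                "bp": mf["bp"],
                "lod": lod,
            }
        )
    lod = _scan_lod(matrix.calls[prog], y)
    mk = matrix.markers
    return pd.DataFrame(
        {
            "marker": mk["id"],
            "group": mk["chrom"],
            "cM": np.nan,
            "bp": mk["bp"],
            "lod": lod,
        }
    )


def permutation_threshold(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    config: ScanConfig,
    gmap: GeneticMap | None = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide LOD threshold: the (1 - alpha) type-7 quantile of the
    maximum LOD over ``n_permutations`` phenotype permutations (fixed seed)."""
    prog, y = _aligned_phenotype(matrix, phenotypes)
    calls = matrix.calls[prog]
    rng = np.random.default_rng(config.seed)
    maxima = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        yp = y[rng.permutation(len(y))]
        maxima[b] = np.nanmax(_scan_lod(calls, yp))
    threshold = float(np.quantile(maxima, 1 - config.alpha, method="linear"))
    return threshold, maxima


def lod_interval(
    scan_table: pd.DataFrame, peak_row: int, lod_drop: float = 1.5
) -> tuple[int, int]:
    """1.5-LOD (by default) support interval around a peak.

    Within the peak's linkage group, the interval spans from the first to
    the last marker whose LOD reaches peak - drop (the widest region with
    qualifying endpoints), expanded one marker beyond on each side (the
    nearest flanking markers outside the region). Returns integer row
    indices into ``scan_table`` (inclusive).
    """
    group = scan_table["group"].iloc[peak_row]
    rows = np.flatnonzero((scan_table["group"] == group).to_numpy())
    lod = scan_table["lod"].to_numpy()[rows]
    pos = int(np.flatnonzero(rows == peak_row)[0])
    cutoff = lod[pos] - lod_drop
    above = np.flatnonzero(lod >= cutoff)
    lo = max(0, int(above.min()) - 1)
    hi = min(len(rows) - 1, int(above.max()) + 1)
    return int(rows[lo]), int(rows[hi])


#: LOD cap applied when the residual sum of squares vanishes (phenotype
#: fully determined by genotype); keeps PVE strictly below 100.
_LOD_CAP_LOG_RATIO = 12.0


def fit_hk(
    matrix: GenotypeMatrix, phenotypes: pd.Series, marker: str
) -> dict:
    """Haley-Knott regression at one marker: least squares of phenotype on
    the additive (x_a in {-1,0,1}) and dominance (x_d = [g == H]) codes.

    Returns lod, pve (percent), additive, dominance, n, degenerate flag.
    """
    prog, y = _aligned_phenotype(matrix, phenotypes)
    j = int(np.flatnonzero(matrix.markers["id"].to_numpy() == marker)[0])
    g = matrix.calls[prog, j]
    ok = g != MISSING
    g, y = g[ok], y[ok]
    n = len(y)
    if n < 4:
        raise ValueError("too few phenotyped, genotyped individuals")
    x_a = g.astype(float) - 1.0
    x_d = (g == H).astype(float)
    X = np.column_stack([np.ones(n), x_a, x_d])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient design: a genotype class is absent")
    beta, rss1, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = float(rss1[0]) if len(rss1) else float(((y - X @ beta) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    if rss0 <= 0:  # constant phenotype: nothing to explain
        degenerate = False
        lod = 0.0
    else:
        degenerate = rss1 <= 1e-12 * rss0
        log_ratio = _LOD_CAP_LOG_RATIO if degenerate else np.log10(rss0 / rss1)
        lod = (n / 2) * log_ratio
    pve = 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))
    return {
        "lod": float(lod),
        "pve": float(pve),
        "additive": float(beta[1]),
        "dominance": float(beta[2]),
        "n": n,
        "degenerate": bool(degenerate),
    }


def scan_hk(matrix: GenotypeMatrix, phenotypes: pd.Series) -> pd.DataFrame:
    """Haley-Knott LOD at every marker (used for cross-checking the
    nonparametric scan on near-normal traits)."""
    prog, y = _aligned_phenotype(matrix, phenotypes)
    rows = []
    for j, mid in enumerate(matrix.markers["id"]):
        g = matrix.calls[prog, j]
        ok = g != MISSING
        yk, gk = y[ok], g[ok]
        n = len(yk)
        x = np.column_stack([np.ones(n), gk.astype(float) - 1.0, (gk == H).astype(float)])
        rank = np.linalg.matrix_rank(x)
        if rank < 2 or n < 4:
            rows.append((mid, np.nan))
            continue
        beta, rss1, *_ = np.linalg.lstsq(x, yk, rcond=None)
        rss1 = float(rss1[0]) if len(rss1) else float(((yk - x @ beta) ** 2).sum())
        rss0 = float(((yk - yk.mean()) ** 2).sum())
        if rss1 <= 0:
            rows.append((mid, (n / 2) * _LOD_CAP_LOG_RATIO))
        else:
            rows.append((mid, (n / 2) * np.log10(rss0 / rss1)))
    return pd.DataFrame(rows, columns=["marker", "lod"])


def effect_summary(
    matrix: GenotypeMatrix, phenotypes: pd.Series, marker: str
) -> pd.DataFrame:
    """Per-genotype-class phenotype means, SDs and counts at one marker
    (classes labelled AA / AB / BB; AA carries the parent-1 allele)."""
    prog, y = _aligned_phenotype(matrix, phenotypes)
    j = int(np.flatnonzero(matrix.markers["id"].to_numpy() == marker)[0])
    g = matrix.calls[prog, j]
    rows = []
    for code, label in ((A, "AA"), (H, "AB"), (B, "BB")):
        sel = g == code
        n = int(sel.sum())
        rows.append(
            {
                "class": label,
                "n": n,
                "mean": float(y[sel].mean()) if n else float("nan"),
                "sd": float(y[sel].std(ddof=1)) if n > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_scan(
    matrix: GenotypeMatrix,
    phenotypes: pd.Series,
    config: ScanConfig | None = None,
    gmap: GeneticMap | None = None,
) -> ScanResult:
    """Scan, threshold, and per-peak summaries in one call.

    A peak is the maximum-LOD marker of each linkage group whose LOD clears
    the genome-wide permutation threshold; each peak gets its LOD-drop
    support interval and a Haley-Knott fit.
    """
    if config is None:
        config = ScanConfig()
    table = scan_np(matrix, phenotypes, gmap)
    threshold, maxima = permutation_threshold(matrix, phenotypes, config, gmap)
    peaks = []
    for group, sub in table.groupby("group", sort=False):
        k = sub["lod"].idxmax()
        if not np.isfinite(table.loc[k, "lod"]) or table.loc[k, "lod"] < threshold:
            continue
        lo, hi = lod_interval(table, int(k), config.lod_drop)
        try:
            fit = fit_hk(matrix, phenotypes, table.loc[k, "marker"])
        except ValueError:
            fit = {"pve": None, "additive": None, "dominance": None}
        peaks.append(
            QTLPeak(
                marker=table.loc[k, "marker"],
                group=group,
                cM=float(table.loc[k, "cM"]),
                bp=int(table.loc[k, "bp"]),
                lod=float(table.loc[k, "lod"]),
                interval_markers=(table.loc[lo, "marker"], table.loc[hi, "marker"]),
                interval_cM=(float(table.loc[lo, "cM"]), float(table.loc[hi, "cM"])),
                interval_bp=(int(table.loc[lo, "bp"]), int(table.loc[hi, "bp"])),
                pve=fit["pve"],
                additive=fit["additive"],
                dominance=fit["dominance"],
            )
        )
    return ScanResult(table=table, threshold=threshold, perm_maxima=maxima, peaks=peaks)
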