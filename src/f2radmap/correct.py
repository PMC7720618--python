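"""Sliding-window genotype correction and imputation for dense F2 marker data.

In an F2 individual the true genotype is piecewise constant along a
chromosome, changing only at crossovers, so a call that disagrees with its
physical neighbourhood is far more likely a genotyping error (typically a
heterozygote undercalled as a homozygote) than a real double recombinant.
The corrector replaces such calls with the local window consensus and fills
missing calls the same way, refusing to act across putative crossover zones
where the two window halves disagree (the "crossover guard").

A preliminary binning step collapses short runs of homozygous-majority
markers embedded in heterozygous regions — the signature of clustered
undercalls at a locus — into a single representative marker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import A, B, H, MISSING, GenotypeMatrix

CALL_LABELS = ["A", "AB", "B", "missing"]
_ROW = {A: 0, H: 1, B: 2, MISSING: 3}


@dataclass
class CorrectionConfig:
    """Tuning knobs of the corrector.

    window_size is in markers (odd, centred on the focal call);
    consensus_min_fraction is the modal-call fraction required to call a
    window consensus; het_minor_fraction is the both-homozygotes evidence
    level at which a window is deemed heterozygous regardless of the modal
    call; max_hom_run / run_span_bp bound the binning step.
    """

    max_hom_run: int = 8
    run_span_bp: int = 150
    window_size: int = 15
    consensus_min_fraction: float = 0.8
    crossover_guard: bool = True
    impute_min_fraction: float = 0.8
    het_minor_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        for name in ("consensus_min_fraction", "impute_min_fraction"):
            v = getattr(self, name)
            if not 0.5 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0.5, 1]")


@dataclass
class CorrectionReport:
    n_calls: int = 0
    n_corrected: int = 0
    n_missing_before: int = 0
    n_imputed: int = 0
    #: 4x4 from-call x to-call counts, rows/cols ordered A, AB, B, missing
    type_matrix: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))
    markers_removed: list[str] = field(default_factory=list)

    @property
    def corrected_fraction(self) -> float:
        return self.n_corrected / self.n_calls if self.n_calls else 0.0

    @property
    def imputed_fraction(self) -> float:
        return self.n_imputed / self.n_missing_before if self.n_missing_before else 0.0

    def type_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.type_matrix, index=CALL_LABELS, columns=CALL_LABELS)

    def merge(self, other: "CorrectionReport") -> "CorrectionReport":
        out = CorrectionReport(
            n_calls=max(self.n_calls, other.n_calls),
            n_corrected=self.n_corrected + other.n_corrected,
            n_missing_before=max(self.n_missing_before, other.n_missing_before),
            n_imputed=self.n_imputed + other.n_imputed,
            type_matrix=self.type_matrix + other.type_matrix,
            markers_removed=self.markers_removed + other.markers_removed,
        )
        return out


# ---------------------------------------------------------------------------
# qc-hetero binning
# ---------------------------------------------------------------------------

def _majority_call(counts_a: np.ndarray, counts_h: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Population-majority call per marker; ties resolved in favour of H,
    then A (a tie between genotype classes carries no homozygous signal)."""
    stacked = np.stack([counts_h, counts_a, counts_b])  # H wins ties
    order = np.array([H, A, B], dtype=np.int8)
    out = order[np.argmax(stacked, axis=0)]
    out[(counts_a + counts_h + counts_b) == 0] = MISSING
    return out


def bin_hetero_runs(
    matrix: GenotypeMatrix, config: CorrectionConfig | None = None
) -> tuple[GenotypeMatrix, CorrectionReport]:
    """Collapse short homozygous-majority runs inside heterozygous regions.

    A maximal run of up to ``max_hom_run`` consecutive markers whose
    population-majority call is homozygous, spanning at most ``run_span_bp``
    and flanked on both sides by H-majority markers, is replaced by its first
    marker; that representative's call per individual is the individual's
    majority call over the run (ties -> missing).
    """
    if config is None:
        config = CorrectionConfig()
    out = matrix.copy()
    report = CorrectionReport(
        n_calls=int((matrix.calls != MISSING).sum()),
        n_missing_before=int((matrix.calls == MISSING).sum()),
    )
    prog = matrix.progeny_index
    rows = prog if len(prog) else np.arange(matrix.n_samples)
    keep = np.ones(matrix.n_markers, dtype=bool)
    bp = matrix.markers["bp"].to_numpy()
    ids = matrix.markers["id"].to_numpy()

    for _chrom, sl in matrix.chromosome_slices():
        g = matrix.calls[rows, sl]
        maj = _majority_call((g == A).sum(0), (g == H).sum(0), (g == B).sum(0))
        m = len(maj)
        is_hom = (maj == A) | (maj == B)
        j = 0
        offset = sl.start
        while j < m:
            if not is_hom[j]:
                j += 1
                continue
            k = j
            while k + 1 < m and is_hom[k + 1]:
                k += 1
            run_len = k - j + 1
            span = bp[offset + k] - bp[offset + j]
            flanked = j > 0 and k < m - 1 and maj[j - 1] == H and maj[k + 1] == H
            if flanked and run_len <= config.max_hom_run and span <= config.run_span_bp:
                cols = np.arange(offset + j, offset + k + 1)
                sub = out.calls[:, cols]
                na = (sub == A).sum(1)
                nh = (sub == H).sum(1)
                nb = (sub == B).sum(1)
                stacked = np.stack([na, nh, nb])
                best = np.argmax(stacked, axis=0).astype(np.int8)
                top = stacked.max(axis=0)
                tie = (stacked == top).sum(axis=0) > 1
                rep = best
                rep[(top == 0) | tie] = MISSING
                out.calls[:, offset + j] = rep
                keep[offset + j + 1 : offset + k + 1] = False
                report.markers_removed.extend(ids[offset + j + 1 : offset + k + 1])
            j = k + 1
    return out.take_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# window consensus machinery
# ---------------------------------------------------------------------------

def _consensus_from_counts(
    ca: np.ndarray, ch: np.ndarray, cb: np.ndarray, config: CorrectionConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Consensus call (-1 = none) and its supporting fraction, elementwise.

    The window is heterozygous when both homozygote classes each reach
    ``het_minor_fraction`` of the non-missing calls (two-allele evidence), or
    when H is modal with at least ``consensus_min_fraction`` support;
    otherwise the modal homozygote wins if it reaches
    ``consensus_min_fraction``.
    """
    tot = ca + ch + cb
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(tot > 0, ca / tot, 0.0)
        fh = np.where(tot > 0, ch / tot, 0.0)
        fb = np.where(tot > 0, cb / tot, 0.0)
    cmf = config.consensus_min_fraction
    t = config.het_minor_fraction
    # two-allele evidence requires some actual heterozygote calls too,
    # otherwise windows straddling a direct A|B junction look "het"
    cond_h = ((fa >= t) & (fb >= t) & (fh >= t)) | (
        (ch >= ca) & (ch >= cb) & (fh >= cmf)
    )
    cond_a = ~cond_h & (ca >= ch) & (ca >= cb) & (fa >= cmf)
    cond_b = ~cond_h & ~cond_a & (cb >= ch) & (cb >= ca) & (fb >= cmf)
    cons = np.full(tot.shape, MISSING, dtype=np.int8)
    cons[cond_h] = H
    cons[cond_a] = A
    cons[cond_b] = B
    cons[tot == 0] = MISSING
    support = np.choose(np.clip(cons, 0, 2), [fa, fh, fb])
    support[cons == MISSING] = 0.0
    return cons, support


def _modal_from_counts(ca: np.ndarray, ch: np.ndarray, cb: np.ndarray) -> np.ndarray:
    """Strict modal call per element; ties or no calls give missing."""
    stacked = np.stack([ca, ch, cb])
    top = stacked.max(axis=0)
    modal = stacked.argmax(axis=0).astype(np.int8)
    tie = (stacked == top).sum(axis=0) > 1
    modal[(top == 0) | tie] = MISSING
    return modal


def _window_state(g: np.ndarray, config: CorrectionConfig):
    """Per-call window consensus, support and crossover-guard mask for one
    chromosome block g of shape (samples, markers)."""
    n, m = g.shape
    half = config.window_size // 2
    if m < config.window_size:
        warnings.warn(
            f"window ({config.window_size}) larger than chromosome ({m} markers); truncated",
            stacklevel=3,
        )
    oh = np.stack([(g == A), (g == H), (g == B)]).astype(np.int32)  # (3, n, m)
    cum = np.concatenate([np.zeros((3, n, 1), dtype=np.int32), np.cumsum(oh, axis=2)], axis=2)
    idx = np.arange(m)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(m, idx + half + 1)
    win = cum[:, :, hi] - cum[:, :, lo] - oh  # exclude the focal call
    cons, support = _consensus_from_counts(win[0], win[1], win[2], config)
    if config.crossover_guard:
        left = cum[:, :, idx] - cum[:, :, lo]
        right = cum[:, :, hi] - cum[:, :, idx + 1]
        lmod = _modal_from_counts(left[0], left[1], left[2])
        rmod = _modal_from_counts(right[0], right[1], right[2])
        # act only where both half-windows agree on a defined modal call;
        # disagreement or an empty/tied half marks a putative crossover zone
        # (incl. terminal crossovers where one half lies off-chromosome)
        guard = ~((lmod != MISSING) & (rmod != MISSING) & (lmod == rmod))
    else:
        guard = np.zeros_like(cons, dtype=bool)
    return cons, support, guard


# ---------------------------------------------------------------------------
# correction and imputation
# ---------------------------------------------------------------------------

def correct_genotypes(
    matrix: GenotypeMatrix, config: CorrectionConfig | None = None
) -> tuple[GenotypeMatrix, CorrectionReport]:
    """Single deterministic pass replacing non-missing calls that disagree
    with their window consensus (progeny only; parents are homozygous by
    construction and are left untouched)."""
    if config is None:
        config = CorrectionConfig()
    out = matrix.copy()
    prog = matrix.progeny_index
    rows = prog if len(prog) else np.arange(matrix.n_samples)
    report = CorrectionReport(
        n_calls=int((matrix.calls[rows] != MISSING).sum()),
        n_missing_before=int((matrix.calls[rows] == MISSING).sum()),
    )
    for _chrom, sl in matrix.chromosome_slices():
        g = out.calls[rows, sl]
        cons, _support, guard = _window_state(g, config)
        fix = (g != MISSING) & (cons != MISSING) & (cons != g) & ~guard
        if fix.any():
            frm = g[fix]
            to = cons[fix]
            for f, t in zip(frm, to):
                report.type_matrix[_ROW[int(f)], _ROW[int(t)]] += 1
            report.n_corrected += int(fix.sum())
            g[fix] = to
            out.calls[rows, sl] = g
    return out, report


def impute_missing(
    matrix: GenotypeMatrix, config: CorrectionConfig | None = None
) -> tuple[GenotypeMatrix, CorrectionReport]:
    """Fill missing calls with the window consensus when its support reaches
    ``impute_min_fraction`` and the crossover guard does not object."""
    if config is None:
        config = CorrectionConfig()
    out = matrix.copy()
    prog = matrix.progeny_index
    rows = prog if len(prog) else np.arange(matrix.n_samples)
    report = CorrectionReport(
        n_calls=int((matrix.calls[rows] != MISSING).sum()),
        n_missing_before=int((matrix.calls[rows] == MISSING).sum()),
    )
    fully_missing = [
        matrix.samples[i]
        for i in rows
        if matrix.n_markers and (matrix.calls[i] == MISSING).all()
    ]
    if fully_missing:
        warnings.warn(f"individuals with no calls at all, nothing to impute: {fully_missing}")
    for _chrom, sl in matrix.chromosome_slices():
        g = out.calls[rows, sl]
        cons, support, guard = _window_state(g, config)
        fill = (g == MISSING) & (cons != MISSING) & (support >= config.impute_min_fraction) & ~guard
        if fill.any():
            to = cons[fill]
            for t in to:
                report.type_matrix[_ROW[MISSING], _ROW[int(t)]] += 1
            report.n_imputed += int(fill.sum())
            g[fill] = to
            out.calls[rows, sl] = g
    return out, report


def correct_and_impute(
    matrix: GenotypeMatrix, config: CorrectionConfig | None = None
) -> tuple[GenotypeMatrix, CorrectionReport]:
    """bin_hetero_runs -> correct_genotypes -> impute_missing, with merged
    accounting (the standard order of the correction stage)."""
    if config is None:
        config = CorrectionConfig()
    binned, rep0 = bin_hetero_runs(matrix, config)
    corrected, rep1 = correct_genotypes(binned, config)
    imputed, rep2 = impute_missing(corrected, config)
    report = rep0.merge(rep1).merge(rep2)
    # fractions are relative to the state entering each step
    report.n_calls = rep1.n_calls
    report.n_missing_before = rep2.n_missing_before
    return imputed, report
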