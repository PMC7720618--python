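"""SNP/individual filter cascade, parentage assignment and AB conversion.

Mirrors the usual GBS workflow for a biparental F2 population: biallelic
SNPs only, high-missingness individuals removed, low-depth calls masked,
minor-allele-frequency and site-missingness filters, exclusion of sites that
are heterozygous in a parent or monomorphic between parents, a chi-square
test against the Mendelian 1:2:1 expectation, and finally recoding relative
to the parent-1 allele (A / H / B).

Site statistics (MAF, missingness, segregation) are computed over progeny
only: parents are excluded from the SNP set before filtering.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as fio
from .io import A, B, H, MISSING, GenotypeMatrix


@dataclass
class FilterConfig:
    min_depth_call: int = 5
    maf_min: float = 0.05
    site_max_missing: float = 0.20
    individual_max_missing: float = 0.90
    seg_distortion_alpha: float = 0.01
    expected_ratio: tuple[float, float, float] = (0.25, 0.5, 0.25)

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min outside [0, 0.5]")
        for name in ("site_max_missing", "individual_max_missing", "seg_distortion_alpha"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        if abs(sum(self.expected_ratio) - 1) > 1e-9:
            raise ValueError("expected_ratio must sum to 1")


@dataclass
class SegregationTestResult:
    counts: tuple[int, int, int]
    statistic: float
    p_value: float
    excluded: bool


@dataclass
class CascadeReport:
    """Per-stage accounting: (stage, SNPs in, SNPs out, individuals in/out)."""

    stages: list[tuple[str, int, int, int, int]] = field(default_factory=list)

    def add(self, name: str, snps_in: int, snps_out: int, ind_in: int, ind_out: int) -> None:
        self.stages.append((name, snps_in, snps_out, ind_in, ind_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages,
            columns=["stage", "snps_in", "snps_out", "individuals_in", "individuals_out"],
        )

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------

def mask_low_depth(matrix: GenotypeMatrix, min_depth_call: int) -> GenotypeMatrix:
    """Set calls with depth below the threshold to missing (depth < 5 is the
    conventional guard against heterozygotes sampled on one allele only)."""
    if min_depth_call <= 0:
        return matrix
    if matrix.depths is None:
        raise ValueError("no depth matrix available but min_depth_call > 0")
    out = matrix.copy()
    out.calls[out.depths < min_depth_call] = MISSING
    return out


def drop_individuals(
    matrix: GenotypeMatrix, individual_max_missing: float
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove samples whose missing-call fraction exceeds the threshold."""
    if matrix.n_markers == 0:
        return matrix, []
    miss = (matrix.calls == MISSING).mean(axis=1)
    keep = miss <= individual_max_missing
    removed = [s for s, k in zip(matrix.samples, keep) if not k]
    return matrix.take_samples(np.flatnonzero(keep)), removed


def _progeny_counts(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = matrix.calls[matrix.progeny_index]
    return (g == A).sum(0), (g == H).sum(0), (g == B).sum(0)


def filter_maf(matrix: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    """Drop sites with minor allele frequency below the threshold, counting
    alleles over called progeny genotypes."""
    nA, nH, nB = _progeny_counts(matrix)
    called = nA + nH + nB
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = (2 * np.minimum(nA, nB) + nH) / (2 * called)
    maf = np.where(called > 0, maf, 0.0)
    return matrix.take_markers(np.flatnonzero(maf >= maf_min))


def filter_site_missing(matrix: GenotypeMatrix, site_max_missing: float) -> GenotypeMatrix:
    """Keep sites genotyped in more than (1 - site_max_missing) of progeny."""
    n = len(matrix.progeny_index)
    if n == 0:
        return matrix
    nA, nH, nB = _progeny_counts(matrix)
    called_frac = (nA + nH + nB) / n
    return matrix.take_markers(np.flatnonzero(called_frac > 1 - site_max_missing))


def assign_parentage(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Convert a ref-coded matrix to AB coding using parental replicates.

    A site is excluded when any parental replicate is heterozygous there,
    or when the per-parent consensus alleles (majority over non-missing
    replicates; ties undetermined) are equal or undetermined. Remaining
    sites are recoded so A is the parent-1 homozygote.

    Returns the AB matrix and a per-excluded-site report with a reason.
    """
    p1 = matrix.role_index("parent1")
    p2 = matrix.role_index("parent2")
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("need at least one replicate of each parent")

    def consensus(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = matrix.calls[idx]
        het_any = (g == H).any(axis=0)
        n_ref = (g == A).sum(axis=0)
        n_alt = (g == B).sum(axis=0)
        cons = np.full(matrix.n_markers, MISSING, dtype=np.int8)
        cons[n_ref > n_alt] = A
        cons[n_alt > n_ref] = B
        cons[(n_ref == 0) & (n_alt == 0)] = MISSING
        cons[n_ref == n_alt] = MISSING  # tie or all-missing: undetermined
        return cons, het_any

    c1, het1 = consensus(p1)
    c2, het2 = consensus(p2)
    het_any = het1 | het2
    undetermined = (c1 == MISSING) | (c2 == MISSING)
    monomorphic = (~undetermined) & (c1 == c2)
    keep = ~(het_any | undetermined | monomorphic)

    reasons = np.select(
        [het_any, undetermined, monomorphic],
        ["parental_het", "undetermined_consensus", "monomorphic"],
        default="",
    )
    report = pd.DataFrame(
        {
            "marker": matrix.markers["id"].to_numpy()[~keep],
            "reason": reasons[~keep],
        }
    )

    out = matrix.take_markers(np.flatnonzero(keep))
    flip = (c1 == B)[keep]  # parent-1 carries the alt allele: swap A<->B
    g = out.calls
    cols = np.flatnonzero(flip)
    sub = g[:, cols]
    hom = (sub == A) | (sub == B)
    sub[hom] = (2 - sub[hom]).astype(np.int8)
    g[:, cols] = sub
    # swap ref/alt in marker metadata so ref stays the parent-1 allele
    mk = out.markers
    r = mk.loc[flip, "ref"].copy()
    mk.loc[flip, "ref"] = mk.loc[flip, "alt"]
    mk.loc[flip, "alt"] = r
    out.coding = "ab"
    return out, report


def segregation_test(
    counts: tuple[int, int, int],
    expected_ratio: tuple[float, float, float] = (0.25, 0.5, 0.25),
    alpha: float = 0.01,
) -> SegregationTestResult:
    """Chi-square goodness-of-fit against the F2 1:2:1 expectation.

    With 2 degrees of freedom the survival function has the closed form
    p = exp(-X^2 / 2).
    """
    n = sum(counts)
    if n <= 0:
        raise ValueError("zero genotype calls")
    exp = np.asarray(expected_ratio) * n
    x2 = float(((np.asarray(counts) - exp) ** 2 / exp).sum())
    p = math.exp(-x2 / 2)
    return SegregationTestResult(tuple(counts), x2, p, excluded=p < alpha)


def filter_segregation(
    matrix: GenotypeMatrix, config: FilterConfig
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop sites with significant segregation distortion among called
    progeny genotypes; returns the filtered matrix and per-site results."""
    nA, nH, nB = _progeny_counts(matrix)
    n = nA + nH + nB
    exp = np.asarray(config.expected_ratio)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = n[:, None] * exp[None, :]
        x2 = ((np.stack([nA, nH, nB], axis=1) - e) ** 2 / e).sum(axis=1)
    x2 = np.where(n > 0, x2, np.inf)
    p = np.exp(-x2 / 2)
    keep = p >= config.seg_distortion_alpha
    table = pd.DataFrame(
        {
            "marker": matrix.markers["id"],
            "nA": nA,
            "nH": nH,
            "nB": nB,
            "X2": x2,
            "p": p,
            "excluded": ~keep,
        }
    )
    return matrix.take_markers(np.flatnonzero(keep)), table


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def basic_filters(
    matrix: GenotypeMatrix, config: FilterConfig, report: CascadeReport | None = None
) -> tuple[GenotypeMatrix, CascadeReport]:
    """The four site/individual filters that precede parentage assignment
    (individual missingness, depth masking, MAF, site missingness).

    Replicate-discordance QC belongs on this output: the later
    parental-heterozygote exclusion removes precisely the sites where
    replicates disagree, and would erase the signal."""
    if report is None:
        report = CascadeReport()

    def log(stage: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
        report.add(stage, before.n_markers, after.n_markers, before.n_samples, after.n_samples)

    m0 = matrix
    log("biallelic_parse", m0, m0)

    m1, _removed = drop_individuals(m0, config.individual_max_missing)
    log("drop_individuals", m0, m1)

    if m1.depths is not None and config.min_depth_call > 0:
        m2 = mask_low_depth(m1, config.min_depth_call)
    else:
        m2 = m1
    log("mask_low_depth", m1, m2)

    m3 = filter_maf(m2, config.maf_min)
    log("maf", m2, m3)

    m4 = filter_site_missing(m3, config.site_max_missing)
    log("site_missing", m3, m4)
    return m4, report


def run_cascade(
    vcf: str | os.PathLike | GenotypeMatrix,
    roles: dict[str, str] | None,
    config: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, CascadeReport]:
    """Run the full filter cascade on a VCF path (or an already-parsed
    ref-coded matrix) and return the AB matrix plus per-stage accounting."""
    if config is None:
        config = FilterConfig()
    if isinstance(vcf, GenotypeMatrix):
        matrix = vcf
    else:
        if roles is None:
            raise ValueError("sample roles required when reading a VCF")
        matrix = fio.read_vcf(vcf, roles)

    m4, report = basic_filters(matrix, config)

    def log(stage: str, before: GenotypeMatrix, after: GenotypeMatrix) -> None:
        report.add(stage, before.n_markers, after.n_markers, before.n_samples, after.n_samples)

    if m4.coding == "ref":
        m5, _parent_report = assign_parentage(m4)
    else:
        m5 = m4
    log("parentage_ab", m4, m5)

    m6, _seg = filter_segregation(m5, config)
    log("segregation", m5, m6)

    return m6, report
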