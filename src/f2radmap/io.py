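"""Readers/writers for the pipeline's exchange formats and the AB genotype matrix.

The central container is :class:`GenotypeMatrix`: individuals x ordered markers
with calls in {A, H, B, missing}. Internally calls are int8 codes
(``A=0, H=1, B=2, MISSING=-1``). Two codings exist:

* ``"ref"`` — calls relative to the VCF REF allele (0 = hom-ref, 1 = het,
  2 = hom-alt), the state straight after VCF parsing;
* ``"ab"``  — calls relative to parental origin (A = homozygous parent-1
  allele, B = homozygous parent-2 allele), the state after parentage
  assignment.

Coordinate conventions: SNP positions are 1-based (VCF); intervals are
0-based half-open (BED). Conversions happen only at module boundaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

A, H, B, MISSING = 0, 1, 2, -1

CALL_CHARS = {A: "A", H: "H", B: "B", MISSING: "-"}
#: accepted on read; "AB" is the report-facing spelling of the heterozygote
CHAR_CALLS = {
    "A": A,
    "H": H,
    "AB": H,
    "B": B,
    "-": MISSING,
    "−": MISSING,
    ".": MISSING,
}

ROLES = ("parent1", "parent2", "progeny")

MARKER_COLUMNS = ["id", "chrom", "bp", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x markers call matrix with marker metadata and sample roles.

    Parameters
    ----------
    samples
        Sample identifiers, unique, VCF column order preserved.
    roles
        One of ``parent1 | parent2 | progeny`` per sample.
    markers
        DataFrame with columns ``id, chrom, bp, ref, alt`` sorted by
        (chrom, bp); ``bp`` is 1-based.
    calls
        int8 array of shape (n_samples, n_markers).
    depths
        Optional per-call read depth, same shape.
    coding
        ``"ref"`` or ``"ab"`` (see module docstring).
    """

    samples: list[str]
    roles: list[str]
    markers: pd.DataFrame
    calls: np.ndarray
    depths: np.ndarray | None = None
    coding: str = "ab"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("sample ids must be unique")
        if len(self.roles) != len(self.samples):
            raise ValueError("one role per sample required")
        bad = set(self.roles) - set(ROLES)
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"call matrix shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.depths is not None and self.depths.shape != self.calls.shape:
            raise ValueError("depth matrix shape differs from call matrix")
        mk = self.markers
        if len(mk) and mk["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        for chrom, grp in mk.groupby("chrom", sort=False):
            if not grp["bp"].is_monotonic_increasing:
                raise ValueError(f"markers on {chrom} not sorted by bp")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def role_index(self, role: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.roles) == role)

    @property
    def progeny_index(self) -> np.ndarray:
        return self.role_index("progeny")

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
            depths=None if self.depths is None else self.depths[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            samples=[self.samples[i] for i in index],
            roles=[self.roles[i] for i in index],
            calls=self.calls[index],
            depths=None if self.depths is None else self.depths[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            samples=list(self.samples),
            roles=list(self.roles),
            markers=self.markers.copy(),
            calls=self.calls.copy(),
            depths=None if self.depths is None else self.depths.copy(),
        )

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """Contiguous marker slices per chromosome, in stored order."""
        out = []
        chroms = self.markers["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        start = 0
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[start]:
                out.append((chroms[start], slice(start, j)))
                start = j
        return out


def empty_markers() -> pd.DataFrame:
    return pd.DataFrame(columns=MARKER_COLUMNS).astype(
        {"id": str, "chrom": str, "bp": np.int64, "ref": str, "alt": str}
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, sample_roles: dict[str, str]) -> GenotypeMatrix:
    """Parse a VCF into a ref-coded :class:`GenotypeMatrix`.

    Indels and sites with other than two alleles are dropped at parse.
    Missing GT becomes the missing call; depths come from the per-sample
    DP field when present.

    Parameters
    ----------
    sample_roles
        Maps every sample name in the VCF to ``parent1 | parent2 | progeny``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_roles]
    if unknown:
        raise ValueError(f"samples without a role: {unknown}")
    roles = [sample_roles[s] for s in samples]

    rows, call_cols, depth_cols = [], [], []
    any_dp = False
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multiallelic (or ALT-less) site
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        rows.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, ref, alt))
        call_cols.append(remap[np.clip(var.gt_types, 0, 3)])
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_dp = True
            d = dp[:, 0].astype(np.int32)
            d[d < 0] = 0
            depth_cols.append(d)
        else:
            depth_cols.append(np.zeros(len(samples), dtype=np.int32))
    vcf.close()

    markers = (
        pd.DataFrame(rows, columns=MARKER_COLUMNS) if rows else empty_markers()
    )
    calls = (
        np.column_stack(call_cols).astype(np.int8)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    depths = np.column_stack(depth_cols).astype(np.int32) if (rows and any_dp) else None
    order = np.lexsort((markers["bp"].to_numpy(), markers["chrom"].to_numpy())) if rows else np.array([], dtype=int)
    markers = markers.iloc[order].reset_index(drop=True) if rows else markers
    if rows:
        calls = calls[:, order]
        if depths is not None:
            depths = depths[:, order]
    return GenotypeMatrix(samples, roles, markers, calls, depths, coding="ref")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as VCF 4.2 text with GT and DP per sample.

    In AB coding, A is written as the parent-1 homozygous genotype (0/0 under
    the ref=parent-1-allele convention) and B as 1/1.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in pd.unique(matrix.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        has_dp = matrix.depths is not None
        fmt = "GT:DP" if has_dp else "GT"
        mk = matrix.markers
        for j in range(matrix.n_markers):
            fields = [
                str(mk["chrom"].iat[j]),
                str(int(mk["bp"].iat[j])),
                str(mk["id"].iat[j]),
                str(mk["ref"].iat[j]),
                str(mk["alt"].iat[j]),
                ".",
                ".",
                ".",
                fmt,
            ]
            for i in range(matrix.n_samples):
                gt = _GT_STRINGS[int(matrix.calls[i, j])]
                if has_dp:
                    gt += f":{int(matrix.depths[i, j])}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# AB-matrix TSV
# ---------------------------------------------------------------------------

def write_matrix(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the AB-matrix TSV: a role header line, then one row per marker
    (id, chrom, bp, ref, alt, one single-character call per sample)."""
    with open(path, "w") as fh:
        fh.write("#coding\t" + matrix.coding + "\n")
        fh.write("#roles\t" + "\t".join(matrix.roles) + "\n")
        fh.write("marker\tchrom\tbp\tref\talt\t" + "\t".join(matrix.samples) + "\n")
        mk = matrix.markers
        for j in range(matrix.n_markers):
            row = [
                str(mk["id"].iat[j]),
                str(mk["chrom"].iat[j]),
                str(int(mk["bp"].iat[j])),
                str(mk["ref"].iat[j]),
                str(mk["alt"].iat[j]),
            ] + [CALL_CHARS[int(c)] for c in matrix.calls[:, j]]
            fh.write("\t".join(row) + "\n")


def read_matrix(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the TSV written by :func:`write_matrix` (round-trip lossless,
    except per-call depths, which the TSV does not carry)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    coding = "ab"
    roles: list[str] | None = None
    body_start = 0
    for ln in lines:
        if ln.startswith("#coding\t"):
            coding = ln.split("\t", 1)[1]
            body_start += 1
        elif ln.startswith("#roles\t"):
            roles = ln.split("\t")[1:]
            body_start += 1
        else:
            break
    header = lines[body_start].split("\t")
    if header[:5] != ["marker", "chrom", "bp", "ref", "alt"]:
        raise ValueError(f"unexpected matrix header: {header[:5]}")
    samples = header[5:]
    if roles is None:
        roles = ["progeny"] * len(samples)
    rows, cols = [], []
    for k, ln in enumerate(lines[body_start + 1 :], start=1):
        parts = ln.split("\t")
        if len(parts) != 5 + len(samples):
            raise ValueError(f"row {k}: expected {5 + len(samples)} fields, got {len(parts)}")
        rows.append((parts[0], parts[1], int(parts[2]), parts[3], parts[4]))
        try:
            cols.append([CHAR_CALLS[c] for c in parts[5:]])
        except KeyError as exc:
            raise ValueError(f"row {k} (marker {parts[0]}): unknown call symbol {exc}") from None
    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS) if rows else empty_markers()
    calls = (
        np.array(cols, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, roles, markers, calls, coding=coding)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """Read a BED3+ file into (chrom, start, end, name) tuples.

    Coordinates stay 0-based half-open as in the file. Unnamed intervals get
    an empty-string name. ``start >= end`` is an error.
    """
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for k, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if len(parts) < 3:
                raise ValueError(f"line {k}: BED needs at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"line {k}: start {start} >= end {end}")
            out.append((chrom, start, end, parts[3] if len(parts) > 3 else ""))
    return out
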