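"""Nonparametric genome scan with permutation threshold and peak summary.

Scans the corrected matrix against the simulated flowering-time phenotype
(Kruskal-Wallis LOD at every mapped marker), sets the 5% genome-wide
threshold from 1000 phenotype permutations, and summarises each
significant peak: 1.5-LOD support interval, Haley-Knott variance explained
and allelic effects. The simulated QTL sits on C2 at 60 cM with 9% PVE.
"""

from _shared import SEED, ensure_results
from f2radmap import io as fio, qtl, synth

out = ensure_results()
matrix = fio.read_matrix(out / "matrix_corrected.tsv")
pheno = synth.read_phenotypes(out / "phenotypes.tsv")

cfg = qtl.ScanConfig(n_permutations=1000, alpha=0.05, seed=SEED)
res = qtl.run_scan(matrix, pheno, cfg)
res.table.to_csv(out / "scan.tsv", sep="\t", index=False)

print(f"genome-wide 5% threshold: LOD {res.threshold:.2f}")
tab = res.table
k = int(tab["lod"].idxmax())
flag = "significant" if tab["lod"].iloc[k] >= res.threshold else "suggestive (below threshold)"
lo, hi = qtl.lod_interval(tab, k, cfg.lod_drop)
fit = qtl.fit_hk(matrix, pheno, tab["marker"].iloc[k])
print(
    f"top peak {tab['marker'].iloc[k]} on {tab['group'].iloc[k]} @ "
    f"{tab['bp'].iloc[k]/1e6:.2f} Mb: LOD {tab['lod'].iloc[k]:.2f} [{flag}]"
)
print(
    f"  1.5-LOD interval {tab['bp'].iloc[lo]/1e6:.2f}-{tab['bp'].iloc[hi]/1e6:.2f} Mb; "
    f"PVE {fit['pve']:.2f}%, additive effect {fit['additive']:.2f} days"
)
print(qtl.effect_summary(matrix, pheno, tab["marker"].iloc[k]).to_string(index=False))
print("(at 9% simulated PVE and n=192 the genome-wide detection power of the "
      "nonparametric scan is ~60%, so near-threshold peaks are expected)")
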