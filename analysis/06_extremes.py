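"""Early- vs late-flowering extreme groups and segregating variants.

Selects progeny flowering before 127 or after 137 days, applies the three
segregation rules (>=4 calls per group, >70% within-group consistency,
differing consensus), and annotates candidates with distance to a small
synthetic candidate-gene set around the simulated QTL (stand-in intervals,
not real gene models)."""

from _shared import ensure_results, qtl_spec, scenario_map, simulate_bundle
from f2radmap import extremes, io as fio, synth

out = ensure_results()
bundle = simulate_bundle()
matrix = fio.read_matrix(out / "matrix_corrected.tsv")
pheno = synth.read_phenotypes(out / "phenotypes.tsv")

cfg = extremes.ExtremesConfig()
low, high = extremes.select_extremes(pheno.loc[[
    s for s, r in zip(matrix.samples, matrix.roles) if r == "progeny"
]], cfg)
print(f"{len(low)} early (<{cfg.low_cutoff:.0f} d) and "
      f"{len(high)} late (>{cfg.high_cutoff:.0f} d) individuals")

variants = extremes.segregating_variants(matrix, low, high, cfg)

# synthetic candidate-gene intervals flanking the true QTL marker
j = synth.qtl_marker_index(scenario_map(), qtl_spec())
qtl_bp = int(bundle.truth.markers["bp"].iloc[j])
genes = [("C2", qtl_bp - 600, qtl_bp + 400, "FLC_like_synthetic")]
annotated = extremes.annotate_proximity(variants, genes, cfg.proximity_bp)
annotated.to_csv(out / "segregating_variants.tsv", sep="\t", index=False)

print(f"{len(annotated)} segregating variants; "
      f"{int(annotated['within_proximity'].sum())} within "
      f"{cfg.proximity_bp} bp of a candidate gene")
if len(annotated):
    print(annotated.head(10).to_string(index=False))
else:
    print("(a 9%-PVE locus shifts the tails only weakly, so no marker reaches "
          ">70% within-group consistency in both tails — the three rules are "
          "deliberately conservative; they approach certain detection only as "
          "the locus effect grows)")
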