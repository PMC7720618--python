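"""Simulate the synthetic F2 study and write its observed data.

Writes results/simulated.vcf (GT+DP for 199 samples) and
results/phenotypes.tsv, and prints the realized genotype-class and
missingness composition so later stages can be read against known truth.
"""

import numpy as np

from _shared import ensure_results, simulate_bundle
from f2radmap import synth
from f2radmap.io import A, B, H, MISSING

out = ensure_results()
bundle = simulate_bundle()
synth.emit_vcf(bundle, out / "simulated.vcf")
synth.write_phenotypes(bundle.phenotypes, out / "phenotypes.tsv")

truth = bundle.truth.calls[bundle.truth.progeny_index]
obs = bundle.observed.calls[bundle.observed.progeny_index]
print(f"simulated {bundle.truth.n_markers} markers x {bundle.truth.n_samples} samples")
for name, g in (("true", truth), ("observed", obs)):
    fr = {c: float((g == code).mean()) for c, code in
          (("A", A), ("H", H), ("B", B), ("missing", MISSING))}
    print(f"  {name:9s} " + "  ".join(f"{k}={v:.3f}" for k, v in fr.items()))
print(f"phenotype range: {bundle.phenotypes.min():.1f} .. {bundle.phenotypes.max():.1f} days")
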