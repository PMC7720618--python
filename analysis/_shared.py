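"""Shared scenario for the numbered analysis scripts.

One synthetic F2 study at desk scale: four chromosomes (named like
B. napus A/C-genome chromosomes) of 200 cM carrying 700 markers each,
192 progeny, 4 + 3 parental replicates, 12% heterozygote undercall, 6.5%
hom->het miscalls (the rate that reproduces ~12% parental replicate
discordance), 20% missing calls, and one flowering-time QTL on C2
explaining 9% of phenotypic variance. Every script re-derives what it
needs deterministically from SEED.
"""

from pathlib import Path

from f2radmap import synth

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"

CHROM_NAMES = ["A1", "A2", "C1", "C2"]


def scenario_map() -> synth.SimMap:
    return synth.SimMap.uniform(
        4, 700, length_cM=200.0, length_bp=40_000_000, names=CHROM_NAMES
    )


def error_model() -> synth.ErrorModel:
    return synth.ErrorModel(u_het_to_hom=0.12, e_hom_to_het=0.065, p_missing=0.20)


def qtl_spec() -> synth.QTLSpec:
    return synth.QTLSpec(
        chromosome="C2", cM=60.0, additive=5.0, dominance=0.0,
        target_pve=0.09, baseline=132.0,
    )


def simulate_bundle() -> synth.TruthBundle:
    return synth.simulate_bundle(
        scenario_map(), 192, error_model(), qtl_spec(),
        n_rep_p1=4, n_rep_p2=3, seed=SEED,
    )


def ensure_results() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
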