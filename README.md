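# f2radmap

Genotype-error-aware linkage and QTL mapping for F2 intercross populations
genotyped by ddRAD / GBS.

Reduced-representation sequencing of an F2 population (two inbred parents,
e.g. a spring × winter *Brassica napus* cross segregating for flowering
time) delivers tens of thousands of SNPs — but at low coverage the dominant
failure mode is **heterozygote undercalling**: a true AB genotype sampled on
one allele only is called homozygous. Every such error looks like a double
recombinant downstream and can inflate a genetic map several-fold.
`f2radmap` implements the full analysis chain for this setting:

1. **filters** — VCF → biallelic SNPs, individual/depth/MAF/missingness
   filters, parental-replicate consensus, exclusion of parental-het and
   monomorphic sites, chi-square test against the F2 1:2:1 expectation
   (df 2, p = e^(−X²/2)), AB recoding (A = parent-1 homozygote).
2. **qc** — pairwise genotype discordance between biological replicates of
   the parents; the per-sample error rate is estimated as discordance/2.
3. **correct** — hetero-run binning plus a sliding-window corrector and
   imputer with a crossover guard, with a full from→to correction-type
   accounting.
4. **linkage** — pairwise recombination fractions by EM on the two-locus F2
   likelihood, linkage grouping, seriation or reference ordering, Kosambi
   distances (d = 25·ln((1+2r)/(1−2r))), outlier removal, crossover counts,
   genetic-vs-physical order correlation, and map-inflation diagnostics.
5. **qtl** — nonparametric (Kruskal–Wallis) single-QTL genome scan with
   LOD = H/(2 ln 10), permutation-based genome-wide thresholds, 1.5-LOD
   support intervals, and Haley–Knott fits
   (PVE = 100·(1 − 10^(−2·LOD/n))).
6. **extremes** — variants segregating between early- and late-phenotype
   progeny (≥4 calls/group, >70% within-group consistency, differing
   consensus) with candidate-gene proximity annotation.
7. **digest** — in-silico double restriction digestion (IUPAC motifs,
   e.g. HinfI GANTC + HpyCH4IV ACGT) with different-end fragment and
   size-window coverage statistics for enzyme-pair evaluation.
8. **synth** — a first-class synthetic-data generator (Haldane meiosis,
   replicated homozygous parents, parametric or depth-based genotyping
   error, single-QTL phenotypes with configurable PVE) so every stage can
   be validated against known truth.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study —
four 200 cM chromosomes with 700 markers each, 192 progeny, 4+3 parental
replicates, 12% heterozygote undercall, 6.5% hom→het miscalls, 20% missing
calls, one flowering-time QTL on C2 (9% PVE) — and write their tables under
`results/`:

```bash
cd analysis
python 01_simulate.py && python 02_filter_qc.py && python 03_correct.py
python 04_linkage_map.py && python 05_qtl_scan.py
python 06_extremes.py && python 07_digest.py
```

Selected output (seed 2026):

```
parent1: mean discordance 11.69%, estimated error rate 5.84%, categories {'A-B': 0.0, 'A-AB': 1.0, 'B-AB': 0.0}
parent2: mean discordance 13.32%, estimated error rate 6.66%, categories {'A-B': 0.0, 'A-AB': 0.0, 'B-AB': 1.0}

corrected 6.89% of calls; imputed 83.56% of missing; 0 markers binned away
genotype accuracy vs truth: before 74.60%, after 94.92%

uncorrected map: 9410 cM -> inflation ratio 4.4, excess 7.41 cM/interval

genome-wide 5% threshold: LOD 3.72
top peak C2_M211 on C2 @ 12.02 Mb: LOD 3.42 [suggestive (below threshold)]
  1.5-LOD interval 9.27-17.85 Mb; PVE 7.66%, additive effect 4.52 days
```

Reading this: the parental replicates disagree at ~12% of calls, all of it
homozygote-vs-heterozygote conflict, so the per-sample error rate is ~6%.
The corrector recovers 95% genotype accuracy from 75%, and without it the
estimated map would be 4.4× too long — each marker interval picking up
~7 cM of spurious distance from errors scored as double recombinants. The
scan peaks exactly at the simulated QTL position (C2, 12 Mb = 60 cM) with a
fitted PVE near the simulated 9%; at that effect size and n = 192 the
genome-wide detection power is only ~60%, and in this replicate the peak
sits just below the 5% threshold — a faithful picture of what a 9%-PVE
locus looks like in an F2 of this size.

Every stage is also exposed as a CLI
(`f2radmap simulate|filter|concord|correct|map|scan|extremes|digest|run`);
`f2radmap run --config run.yaml --outdir out/` executes the whole pipeline
reproducibly and writes a machine-readable run report.

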