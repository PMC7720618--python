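# Methods

`f2radmap` re-implements, as one tested pipeline, the analysis chain used to
build a genotype-error-aware linkage map and run a QTL scan on a ddRAD-typed
F2 intercross: SNP filtering and AB conversion, replicate-based error
estimation, sliding-window genotype correction/imputation, EM recombination
fractions with Kosambi distances, a nonparametric permutation-thresholded
genome scan, an extremes-group segregating-variant screen, and in-silico
double-digest statistics. A synthetic-data module generates F2 populations
with known truth so that every stage is verifiable at desk scale.

## Synthetic F2 populations

Meiosis follows the Haldane model: per gamete and chromosome the crossover
count is Poisson(L/100) for map length L in cM, crossover positions are
uniform in map distance, and there is no interference. Each progeny is the
union of two independent gametes, giving the expected ¼ : ½ : ¼ genotype
ratio per marker; the two parents are fully homozygous (all-A, all-B) and
each parental replicate receives independent error draws — which is what
makes replicate discordance informative about the error rate.

Maps are *estimated* downstream with the Kosambi function while gametes are
generated under Haldane. The mismatch is deliberate (it mirrors common
practice) and small at the sub-centimorgan marker spacings used here: the
two functions agree to first order in r.

Two observation models are offered, and they are not a joint model of the
empirical depth profile:

* **parametric** — per-call probabilities: `u_het_to_hom` (heterozygote
  undercall; the undercalled H becomes A or B with equal probability),
  `e_hom_to_het`, `e_hom_flip`, and an unconditional `p_missing`.
  `ErrorModel.allele_flip(eps)` expresses a per-allele miscall rate ε as
  the equivalent genotype rates (u = e = 2ε(1−ε), flip = ε²).
* **depth** — negative-binomial read depth per call (mean `depth_mean`,
  dispersion `depth_dispersion`); a true heterozygote with depth D is read
  as Binomial(D, ½) alternate alleles and called homozygous when all reads
  agree (probability 2·0.5^D); depth below `min_depth_call` is missing.

The reference scenario mirrors the emulated study design: 192 progeny,
4 + 3 parental replicates, `u_het_to_hom = 0.12`, `p_missing = 0.20`.
`e_hom_to_het` defaults to 0.065 because truly homozygous simulated parents
differ only through hom→het miscalls, and 0.065 reproduces both the ~12%
replicate-discordance regime (2·0.065·0.935 ≈ 12.2%) and a realistic
fraction of sites lost to parental-heterozygote exclusion. The phenotype is
single-QTL: y = μ + a·x_a + d·x_d + N(0, σ²) with x_a ∈ {−1,0,1},
x_d = [het]; when a target PVE is given, σ² = (a²/2 + d²/4)(1−PVE)/PVE from
the F2 genetic variance. Defaults a = 5 days, d = 0, PVE = 0.09, μ = 132
days. Errors are independent across calls; there is no locus-level allele
dropout correlation and no read-level simulation.

## Filter cascade

Stage order follows the standard GBS workflow: biallelic SNP parse →
individual missingness (> 0.9 removed) → depth masking (calls < 5 reads set
missing) → MAF ≥ 0.05 → site call rate > 0.8 → exclusion of sites
heterozygous in any parental replicate or monomorphic between parental
consensuses → chi-square 1 : 2 : 1 segregation test (p < 0.01 excluded) →
AB recode. Site statistics use progeny only; parents are excluded from the
SNP set before filtering. Parental consensus is the majority call over
non-missing replicates with ties excluded (the underlying study does not
state a resolution rule). For the df-2 segregation test the p-value is the
closed form exp(−X²/2), identical to the chi-square survival function.

Replicate discordance is computed on the output of the four basic filters,
*before* parental-heterozygote exclusion: that filter removes exactly the
sites where replicates disagree and would erase the signal. Pairs with a
missing call at a site are tallied separately and excluded from the
discordance denominator. The error estimator e = discordance/2 ignores
coincident errors, a documented O(e²) bias.

## Sliding-window correction and imputation

In an F2 the true genotype along a chromosome is piecewise constant, so a
call disagreeing with its physical neighbourhood is more plausibly an error
than a double recombinant. The corrector makes a single deterministic pass
per chromosome (all consensuses computed from the input state):

* **Window consensus** (default 15 markers centred on the focal call,
  truncated at ends; the focal call is excluded): heterozygous when both
  homozygote classes and H each reach 20% of the non-missing window calls,
  or when H is modal with ≥ 80% support; otherwise the modal homozygote if
  it has ≥ 80% support; otherwise undefined. The extra requirement of
  actual H evidence in the two-allele rule prevents windows straddling a
  direct A|B junction from being read as heterozygous.
* **Crossover guard** (default on): a call is only corrected or imputed
  when both half-windows have a defined, *agreeing* modal call. A
  disagreement, an empty half (chromosome end) or a tied half marks a
  putative crossover zone and blocks edits. Modal calls, not
  consensus-fraction calls, are used for the halves: the guard detects
  phase changes and should not be noise-sensitive.
* **Imputation** fills a missing call with the window consensus when its
  supporting fraction reaches 80% and the guard allows it.
* **Hetero-run binning** first collapses runs of ≤ 8 consecutive
  homozygous-majority markers spanning ≤ 150 bp and flanked by H-majority
  markers into their first marker (per-individual majority call, ties
  missing). Majority is taken population-wise over progeny, since
  per-individual binning would change matrix dimensions per individual.

Known behaviour on perfect data: a true double-recombinant island of one
(sometimes up to three) markers is locally indistinguishable from an error
and gets flattened; such islands arise at ~10⁻⁴ per call under Haldane
meiosis at the marker densities used here. Data without recombination are
never altered. A second pass changes ≤ 0.1% of calls at the ~6% error rate
the discordance estimate implies; at the 12% undercall extreme, windows
containing clustered errors defer some corrections to where a second pass
would find them (~0.3%), the accepted cost of single-pass semantics. On the
reference correction scenario (2 × 1000 markers at 200 cM, n = 192, 6%
undercall, 20% missing) accuracy against truth moves from ~78% to ~99% and
~96% of missing calls are imputed.

## Linkage mapping

Pairwise recombination fractions maximise the two-locus F2 codominant
multinomial likelihood by EM: every genotype class contributes a fixed
recombinant-gamete count except the double heterozygote, whose expected
count is 2r²/((1−r)² + r²); the update is r ← (expected recombinant
gametes)/(2n), iterated to |Δr| < 10⁻⁶ from r₀ = 0.25, clipped to
[10⁻⁹, 0.5]. LOD is log₁₀ L(r̂)/L(0.5). The all-pairs version forms the
nine class-count matrices as one-hot matrix products and runs the EM
vectorised over every pair at once.

Grouping joins marker pairs whose test of r = 0.5 (X² = 2 ln 10 · LOD, 1 df)
beats a p-threshold (default 10⁻²³, exposed as configuration; the threshold
semantics are *not* equivalent to MSTMap's internal p-value) and takes the
transitive closure; groups under 7 markers are discarded. Note the
threshold's feasibility depends on n: LOD is bounded by n·log₁₀2, so at
n ≲ 80 the default cannot link even perfectly cosegregating markers.

Ordering is a seriation heuristic — greedy nearest-neighbour path on the
r̂ matrix refined by 2-opt until no improving reversal, minimising the sum
of adjacent r̂ (the "sum of recombination events" objective) — rather than
a bit-for-bit MSTMap reproduction; reference (physical) ordering is
available and mirrors the emulated study's manual order correction against
the genome. Orientation makes the Spearman correlation with bp
non-negative. Map positions accumulate Kosambi distances over adjacent
ordered pairs, with adjacent r̂ capped at 0.4999 to keep distances finite.
Outlier markers (mean r̂ to the 4 nearest ordered neighbours > 0.35) are
dropped. Crossovers are counted from consecutive non-missing calls
(hom↔het = 1, hom↔opposite hom = 2, missing skipped). Because every
surviving genotype error is scored as a double recombinant, injected error
monotonically inflates map length; inflation diagnostics report corrected
vs uncorrected totals, their ratio and the per-interval excess.

## QTL scanning

The scan is nonparametric, suited to non-normal traits: at each marker the
tie-corrected Kruskal–Wallis H over genotype classes, reported as
LOD = H/(2 ln 10) (a convention choice). Classes with fewer than two
members are dropped with ranks recomputed, and markers with fewer than two
such classes scan as zero. The implementation sorts individuals by
phenotype once; subset ranks then become cumulative counts and tie-segment
midranks become boundary averages, so a whole-genome scan is a few
cumulative sums — and a permutation is just a row shuffle. Correctness is
pinned to `scipy.stats.kruskal` in the tests.

Genome-wide significance is the (1 − α) type-7 quantile (fixed for
cross-implementation determinism) of the maximum LOD over seeded phenotype
permutations (default 1000, α = 0.05). The 1.5-LOD support interval spans
first to last marker within the peak's group at LOD ≥ peak − 1.5, expanded
one marker beyond each side. Peak fits use Haley–Knott regression on
(x_a, x_d): LOD = (n/2)·log₁₀(RSS₀/RSS₁), PVE = 100(1 − 10^(−2·LOD/n)),
additive effect the x_a coefficient; an exact fit (RSS₁ = 0) is capped and
flagged. Scanning is at markers only — the matrix is imputed upstream and
dense, so pseudomarkers add nothing.

Calibration and power at the reference conditions (19 × 200 cM
chromosomes, 1 cM spacing, n = 192): the permutation threshold achieves a
genome-wide false-positive rate of ~5%, sitting near LOD 4.1 for this
3800 cM genome. At 9% PVE the expected peak LOD is ~4.5 ± 1.9, so
detection power is near 60% — support intervals cover the true location in
≥ 85% of detections, and the fitted PVE at the genome-wide peak averages
~11% (upward selection bias over the simulated 9%). Interval coverage is
reported conditional on detection because support intervals attach to
detected QTL; unconditional coverage would conflate detection failures
with interval miscoverage.

## Extremes screen

Progeny with phenotype strictly below 127 / strictly above 137 days form
the early/late groups. A variant segregates when each group has ≥ 4
non-missing calls, each group's modal-call fraction among non-missing calls
("consistency", the study leaves the term undefined) is strictly above
70%, and the group consensuses differ (heterozygous consensuses are
allowed). Proximity to candidate genes uses BED half-open intervals:
distance 0 inside a gene, otherwise the count of bases strictly between the
variant and the nearest edge, flagged at ≤ 1 kb. The three rules are
deliberately conservative; at 9% PVE the tails are only weakly enriched
and typically no variant passes, with detection probability approaching 1
as the locus effect grows.

## In-silico digestion

Recognition motifs are IUPAC-degenerate and scanned on the top strand with
overlapping matches allowed; the cut position is match start + offset.
Single-strand scanning suffices for the strand-symmetric site families of
HinfI (GANTC) and HpyCH4IV (ACGT); asymmetric enzymes would need
reverse-strand handling, a documented limitation. Fragments between
consecutive cuts carry the cutting enzyme's label on each end;
chromosome-terminal fragments are never "different-end". The report counts
fragments, different-end fragments, their total length, both restricted to
the 100–600 bp size-selection window, and the window's different-end bases
as a percentage of genome length. Cut finding is verified against an
exhaustive per-position motif scan in the tests.

## What the simulations do and do not show

The generator reproduces the statistical skeleton of a replicated F2 ddRAD
study — Mendelian segregation, Haldane recombination, dominant heterozygote
undercalling, unconditional or depth-driven missingness, a single additive
QTL — but not restriction-site polymorphism dropout, depth correlation
along the genome, multi-QTL or epistatic architectures, segregation
distortion hotspots, or reference-genome artefacts. Passing tests therefore
certify the algorithms under the stated error models, not performance on
any particular real library.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to keep Monte-Carlo
error acceptable: the correction benchmark uses 2 chromosomes × 1000
markers × 192 individuals; map-inflation checks use 51–500 markers over
20 seeds; threshold calibration uses 200 null scans at 200 permutations;
QTL recovery uses 200 replicates of the 19-chromosome genome at 100
permutations per replicate. The narrative analysis scripts use four
700-marker chromosomes.
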