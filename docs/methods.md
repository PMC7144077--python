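# Methods

## Coverage normalization and karyotype calls

Binned read counts (0-based half-open bins, default 100 kb; terminal
bins may be shorter and are retained) are divided by bin length and then
by the median per-bp depth over bins with at least one read. The median
is taken over *non-zero* bins deliberately: for an accession missing one
or two whole subgenomes, a global median would sit at or near zero and
destroy the depth scale. The result is unit-free and invariant to total
sequencing effort.

A chromosome is called present when more than `frac_present` (default
0.5) of its bins reach `depth_floor` (default 0.25) of the typical
depth. Per-subgenome depth is summarized as the median of
per-chromosome mean depths rather than the median over raw bins: at low
per-bin counts the raw-bin median sits on the discrete count lattice
(0, 0.5, 1.0, ... of the typical depth) and can jump a dosage ratio
across a decision threshold, whereas chromosome means are continuous.
The median across a subgenome's 6–7 chromosomes still resists a single
aberrant chromosome.

The ordered classification rules and their defaults:

1. present set within SG1 and at least 5 of its 6 chromosomes present →
   `DIPLOID_SG1`;
2. at least 12 of the 13 SG1∪SG2 chromosomes present, at most one SG3
   chromosome present, SG1/SG2 depth ratio < `ratio_hi` →
   `TETRAPLOID_SG1SG2`; ratio ≥ `ratio_hi` → `HEXAPLOID_TYPE2`;
3. all 20 present with max pairwise subgenome depth ratio < `ratio_hi` →
   `HEXAPLOID_REFERENCE`;
4. otherwise, SG3 read-share > `affinity_min` (default 0.5) →
   `DIPLOID_SG3_AFFINE`;
5. else `AMBIGUOUS` (a value, not an error).

`ratio_hi = 1.5` sits between the 1:1 dosage expected for a true
tetraploid and the ~2:1 expected when a cryptic, unrepresented subgenome
cross-maps onto its closest relative (the "Type 2" signature). The
SG3-affine class is affinity-based, not presence-based, because a
diverged SG3 relative maps diffusely across the genome rather than
cleanly onto seven chromosomes; the generator's default 57% SG3 read
share reproduces that behaviour. All thresholds are configurable and are
recorded in each call's `evidence` field.

Map inference assumes the hexaploid arose by stepwise hybridization
through the sampled lower-ploidy representatives: SG1 is the diploid's
presence set, SG2 the tetraploid's additions, SG3 the remainder. Up to
one discordant chromosome is tolerated (flagged `UNPLACED` with a
warning); more aborts with the offending chromosomes listed.

Anomaly screening compares each chromosome's (or scaffold's) median bin
depth with its subgenome's median, scaled by 1.4826 × MAD of the
subgenome's bin depths; entries above `z_threshold` (default 3) are
reported. Unanchored scaffolds carry a subgenome label in the map only
for this screen.

## Variant filtering and diversity

Filtering keeps loci with missingness ≤ 0.20, then minor-allele
frequency strictly > 0.01 (computed over all samples from non-missing
calls), then drops indels. Each predicate is locus-local, so the result
is order-independent and idempotent; the applied order is logged so the
record-count audit trail mirrors a raw → MAF+missingness → SNP-only
progression. Missing genotypes use a dedicated sentinel and never count
as hom-ref.

He = 1 − Σpᵢ² and PIC = 1 − Σpᵢ² − ΣᵢΣ_{j>i} 2pᵢ²pⱼ² are evaluated per
locus from the allele-frequency table; for biallelic loci PIC ≤ He with
maxima 0.375 and 0.500 at p = 0.5. Loci with zero calls report NaN.

## Distances, trees, ordination

Nei's (1983) D_A treats each individual as a per-locus allele-frequency
vector (0, 0.5, 1): D_A = 1 − (1/L) Σ_loci Σ_alleles √(xᵢyᵢ), with loci
missing in either member of a pair skipped and L adjusted; a pair with
no shared called loci is an error. Neighbor joining follows Saitou–Nei
with the Studier–Keppler Q-criterion; ties are broken at the lowest
(row, column) index so rebuilds are reproducible, and additive matrices
are recovered exactly (branch lengths may legitimately be negative on
non-additive input). PCoA double-centers the squared distance matrix
(Gower) and eigendecomposes; negative eigenvalues are reported but
excluded from the variance denominator, so variance fractions sum to 1
over retained axes. Newick serialization writes branch lengths to 6
significant digits; a single-leaf tree is written as the bare label.

## AMOVA and the ΦPT estimator

Differentiation uses distance-based AMOVA on squared Euclidean
distances over genotype codes (0/1/2), the codominant-genotypic
convention: SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within = Σ_pops Σ_{i<j∈pop}
d²ᵢⱼ/n_pop, with df (k−1, N−k) and the unequal-size coefficient
n₀ = (N − Σn²_p/N)/(k−1). ΦPT = σ²_among/(σ²_among + σ²_within), clamped
to [0, 1] with the raw value retained. Pairs with missing loci rescale
the distance sum by L/L_shared. Permutation p-values shuffle population
labels (seeded; the estimate itself is deterministic) and include the
observed arrangement in the numerator and denominator. The windowed scan
applies the same estimator to loci falling in fixed-width windows;
variant-free windows are emitted with a missing value.

The simulator draws subpopulation allele frequencies from the
Balding–Nichols model. For two populations with parameter F, the
among-population dosage variance is 4Fp(1−p) and the within-population
(HWE) variance 2p(1−p)(1−F), so the expected dosage-AMOVA
differentiation is ΦPT = 2F/(1+F); the generator inverts this
(F = φ/(2−φ)) to aim a requested ΦPT, and the estimator recovers the
targets 0.05 and 0.30 within ±0.03 at n = 60 and 2,000 loci.

## Minor alleles and admixture

Within each species group, an allele is *minor* when the fraction of
non-missing genotypes homozygous for it is below 5% but above zero; the
"above zero" clause excludes alleles simply absent from the group. A
locus enters the group's set when either allele qualifies; the catalog
reports the 3-set Venn partition, whose region counts sum to the union
by construction. Whether the criterion should count homozygous
individuals or allele frequency is genuinely ambiguous; the
homozygote-fraction reading is the default and an allele-frequency mode
is selectable. Admixture classification assigns a sample to its argmax
ancestry iff max Q ≥ 0.70 (boundary inclusive), else `ADMIXED`.

## Expression dominance

Analysis is on log2(TPM + 0.01); the offset matches the expression
floor, and the log scale makes calls invariant to rescaling the TPM
unit. The expression filter drops a triplet in a tissue when any of its
three homoeologs has every replicate below 0.01 TPM (a triplet needs
all three members). The balanced randomized-complete-block ANOVA
(subgenome 2 df, replicate r−1 df, error 2(r−1) df) has the same F
statistic as a one-way model with replicate as a random effect, so no
iterative mixed-model fit is needed; the implementation is vectorized
across triplets and was checked against statsmodels' OLS ANOVA. When
the omnibus p < α, the top subgenome is contrasted against each of the
other two with t-tests on the pooled error term (unadjusted, following
the raw p < 0.05 convention; Benjamini–Hochberg is not applied by
default); dominance requires the top mean to strictly exceed both
others and both contrasts to be significant — which is why the realized
per-subgenome false-dominance rate sits well below the omnibus α.
Degenerate inputs: zero error variance with unequal means decides by
means with p flagged 0; fully constant triplets are `NONE`. The
per-tissue χ² against 1:1:1 (df 2) is undefined (reported missing) when
no triplet is dominant, and the Discussion-style ratio metric is the
ratio of dominant-triplet counts between subgenome pairs.

## Synthetic generators: what they emulate, and what not

Coverage: negative-binomial bin counts (variance μ + αμ², default
α = 0.1; α = 0 gives Poisson) because GBS depth is overdispersed, with
1% bin dropout for restriction-site-free bins, class dosage profiles
over subgenomes, a 2× SG1 multiplier for Type 2, and a 57% SG3 read
share for the SG3-affine class. The default reference is scaled down —
twenty 2-Mb chromosomes of 20 bins each, with Csa11 at 3 Mb as a
"fusion-like" long chromosome to exercise length normalization — so the
suite runs in seconds; chromosome identity and the 6/7/7 partition
match the real karyotype. Genotypes: per-allele ancestry draws for
admixed samples; species-private minor alleles injected as loci with a
single hom-alt carrier in one group (group sizes > 20 keep the carrier
fraction under 5%), left fully called so truth stays exact. Q-matrices
for classification tests are drawn by rejection with a margin around
the 0.70 cutoff (assigned ≥ 0.75, admixed ≤ 0.65) so truth is
well-defined rather than circular.

Not emulated: linkage disequilibrium and recombination (loci are
exchangeable), sequencing error in genotype calls, allele-dosage
ambiguity of polyploid genotyping, reference bias, tissue-correlated
expression noise, and mapping artefacts beyond the dosage model.
Passing recovery tests therefore demonstrates the correctness of the
inference logic under the stated generative models, not robustness to
every artefact of real GBS or RNA-seq data.

## Numerical choices and limitations

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; identical seed + configuration gives byte-identical files.
* Multi-allelic VCF records are split into biallelic loci by default
  (genotypes carrying a different alt become missing at the split
  locus); a "drop" policy is selectable. Split loci share a position,
  so the container enforces sorted (non-decreasing) positions.
* ΦPT component estimates can be negative by sampling; the raw value is
  retained alongside the clamped one.
* The classifier's thresholds were chosen from dosage expectations, not
  fitted; accessions near a dosage boundary at very low depth resolve
  to `AMBIGUOUS` rather than a wrong confident class.
* Table-range caps for He (0.500) and PIC (0.375) are analytic maxima
  of the biallelic formulas, used as oracle anchors in tests.
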