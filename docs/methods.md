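# Methods

This note documents the statistical procedures implemented in `mutspectra`,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions a user should know
before trusting a result.

## Mutation types and the extraction pipeline

A mutation type is an odd-length ancestral k-mer plus a derived central
base, strand-collapsed so the central ancestral base is A or C (the
convention that lists the 1-mer classes as A>C, A>G, A>T, C>A, C>G, C>T).
Type counts are 6·4^(k−1): 6, 96, 1,536 and 24,576 for k = 1, 3, 5, 7.
Ordering is total and deterministic — central substitution first, then
lexicographic context — so serialized tables and external signature files
align. Three CpG policies exist: `merged` (plain spectrum), `separate`
(1-mer + CpG, a 7th class), `excluded` (minus-CpG). *Folding* further merges
X>Y with the strand-collapsed Y>X to remove sensitivity to ancestral-allele
misidentification; the orbit label is the smaller member label, making
folding idempotent. At k = 1 the fold relation yields 4 orbits
({A>C, C>A}, {A>G, C>T}, {A>T}, {C>G}).

Classification reads context from the **ancestral** FASTA (the rescaling
denominators refer to ancestral k-mers), requires the full k-window to lie
inside one accessible interval (chromosome minus the union of all BED
masks) with no N, and drops sites whose ancestral base matches neither
allele — a conservative alternative to probabilistic polarization, which is
out of scope here (the ancestral FASTA is an input). Variants shared among
individuals are attributed to one uniformly chosen carrier (seeded), so a
mutation never counts twice. The CpG-aware 1-mer classifier always reads a
3-mer window, so its site filter is marginally stricter than the plain
1-mer one at window edges. Target counts t_m use the identical window rule,
keeping every rate x_m/t_m internally consistent; a documented consequence
is that windows merely *touching* a masked base are excluded everywhere.

Filtering trusts the VCF FILTER column (PASS only) plus the masks; no
depth or genotype-quality refiltering is done — inputs are assumed
pre-filtered. Coordinates: BED 0-based half-open, VCF 1-based, internal
0-based.

## Normalization and compositional geometry

The pipeline order is fixed and recorded in each table's provenance:

1. **Rescale** to a shared reference composition:
   x⁽ʳ⁾ = x · (t_{m,ref}/T_ref)/(t_{m,own}/T_own). Outputs stay real-valued;
   only the next step re-integerizes. Types missing from the reference are
   dropped with a warning; a positive count over a zero own-target raises.
2. **Downsample** each row by a single multinomial draw; the default size is
   the minimum row total, i.e. the lowest-diversity sample sets the budget.
3. **Pseudocount** +1 in every cell (configurable) — applied uniformly, not
   only where zeros occur, so all rows receive the same regularization.
4. **CLR/ILR.** clr_i = ln p_i − mean_j ln p_j; scale-invariant, zero-sum.
   The ILR basis is the deterministic orthonormal Helmert contrast system in
   schema order (the basis is not canonical; any orthonormal choice yields
   identical distances, which is the only property used downstream).

Aitchison distance = Euclidean distance between CLR rows. Two properties are
verified in the test suite rather than assumed: ILR-Euclidean equals
CLR-Euclidean to 1e−9, and pairwise distances are invariant (1e−9) to which
reference composition the counts were rescaled to. That invariance is exact
only for the rescale → CLR chain; pseudocounting and downsampling break the
per-type multiplicative structure, which is why the invariance is stated —
and tested — at the rescaled stage.

## Phylogenetic-signal statistics

**Mantel test.** r is the Pearson correlation of upper-triangle entries;
the null jointly permutes rows and columns of one matrix;
p = (b+1)/(N+1), one-sided upper tail by default (the hypothesis is a
*positive* distance correlation). The attainable floor is 1/(N+1) — 1e−5 at
99,999 permutations. The phylogenetic matrix is square-rooted before
testing because divergence of a Brownian trait scales with the square root
of cophenetic distance. An exact variant enumerates all n! permutations for
n ≤ 8 and anchors the sampled estimator in tests. Tie handling counts
permutation statistics within 1e−12 of the observed value as ≥.

**Partial (phylogenetically aware) Mantel.** Both the spectrum and the
covariate matrices are regressed on the phylogenetic matrix (OLS over
off-diagonal entries); the residual matrices are then Mantel-tested against
each other. The observed statistic equals the classical partial correlation
r_xy·z. This residual-permutation construction is this package's documented
choice; other phylogenetically aware variants exist and are not reproduced
here.

**K_mult.** With C the Brownian tip covariance (C_ij = root-to-MRCA shared
path length) and a the GLS phylogenetic mean,

K_mult = [Σ(Y−a)ᵀ(Y−a) / Σ(Y−a)ᵀC⁻¹(Y−a)] / [(tr C − n/(1ᵀC⁻¹1))/(n−1)],

expectation 1 under Brownian motion; significance from tip-label shuffling
(999 permutations by default). A single trait reduces exactly to the
univariate Blomberg's K, which the tests verify against an independent
implementation of the univariate formula. Sampling noise on top of a
Brownian trait biases K_mult downward — visible in the worked example and
relevant when interpreting sub-1 values on real data.

**Covariates.** Scalar species covariates become |v_i − v_j| matrices.
Watterson's θ = S/(a_n·L) is provided for the diversity covariate.
Bonferroni thresholds α/m are used throughout for families of Mantel tests.
A caution from the Mantel literature carries over: correlating a spectrum
with another *trait* has a higher false-positive risk than testing
phylogenetic signal of one trait; the partial Mantel mitigates but does not
eliminate this.

**CLR-PCA** is a column-centered SVD with a sign convention (largest
loading positive) for determinism.

## Conditional context-dependence test

A k-mer spectrum inherits signal from its nested (k−2)-mer spectrum. The
null "extended context adds nothing" is materialized by control spectra: for
each species and each (k−2)-mer class, the class total is redistributed over
member k-mer types by one multinomial draw with the species' *genomic target
fractions* as probabilities. Nested marginals are preserved exactly, per
control, per species. Controls are built from the same count stage the
empirical Mantel consumes (rescaled/downsampled counts) and pushed through
the identical pseudocount → CLR → Aitchison → Mantel-r chain; the test
p-value ranks the empirical r among n_control = 5,000 controls (reducible;
the suite uses 99–199). Whether to randomize before or after rescaling is
genuinely open; randomizing at the consumption stage keeps the empirical
and control pipelines identical except for the randomization itself, which
is the property the test's validity rests on.

## Hypermutability scan

Per species, raw counts (no rescaling or downsampling — nothing is compared
across species). For each type: 2×2 table [[x_k, t_k−x_k], [x_b, t_b−x_b]]
where the background b is the central 1-mer class *excluding* the focal
k-mer, avoiding self-comparison; two-sided Fisher's exact p (sum of table
probabilities ≤ the observed table's — the convention matters and is
oracle-tested against exhaustive hypergeometric enumeration); Bonferroni
over the number of tested types. The *reported* fold enrichment uses the
full 1-mer rate, (x_k/t_k)/(x_1/t_1), matching how such scans are plotted.
The species-specific benchmark is the CpG>TpG rate over the **non-CpG** C>T
background rate — defined so a genome with CpG transitions at f× background
recovers exactly f — and "super-CpG" motifs are the Bonferroni-significant,
non-CpG types at or above it. Note the benchmark denominator excludes CpG
contexts while the per-type fold does not; with realistic CpG target
fractions the difference is small, and both conventions are stated here
because they diverge in CpG-rich toy genomes.

## Signature models

`SignatureModel(counts, signatures).fit()` maximizes the multinomial
log-likelihood Σ_t x_t log(Σ_s e_s S_st) over exposure simplices by EM
(update e_s ∝ Σ_t x_t e_s S_st / p_t), which is concave in the exposures —
no restarts needed. `fit(extract_novel=True)` adds one signature shared
across species, estimated by block EM (exposure updates alternating with
novel-signature updates from summed responsibilities) with 10 seeded random
restarts, keeping the best likelihood; the log-likelihood is non-decreasing
every iteration in both modes, and the suite asserts it. Maximum-likelihood
EM replaces the Bayesian machinery of existing signature-fitting tools
deliberately: it gives a deterministic contract on the same likelihood
surface. Cosine similarity between observed and reconstructed proportions
is reported as a *metric*, not the objective. On data generated without a
hidden component the novel signature is unidentifiable — it degenerates
onto a fixed signature (a warning fires at cosine > 0.999) rather than
shrinking its exposure to zero; interpret novel-signature fits together
with the reported cosine-to-fixed-signature diagnostics.

Reproductive-aging signatures come from parental-age regression
coefficients per non-CpG 1-mer class (CpG transitions are stripped from
data and signatures alike because they are depleted in polymorphism data
relative to de novo data): maternal_c ∝ m_{c,mat}, paternal_c ∝ m_{c,pat},
and young-parent_c ∝ y_{c,mat}(13) + y_{c,pat}(13) with y_c(a) = m_c·a + b_c
and puberty taken at 13 years for humans (configurable).
`reconstructed_signal_test` re-runs the CLR → Aitchison → Mantel chain on
reconstructed spectra to ask whether a signature model retains the
empirical phylogenetic signal — the discriminating question that cosine
similarity alone does not answer.

External signature TSVs may use either `ACA>AAA` or COSMIC `A[C>A]A`
labels, any strand; both are collapsed to the canonical form on read.

## Synthetic data: what it emulates and what it does not

The generator covers the statistical structure the analyses assume:
iid-composition genomes with a reference/ancestral substitution fraction
(default 1%) and random exclusion masks (default 10%); per-species k-mer
rate compositions evolving by Brownian motion in CLR space (independent
N(0, σ²·branch) increments projected to the zero-sum subspace; inverse CLR
by softmax), so expected squared Aitchison distance grows linearly with
cophenetic distance; VCFs whose SNPs occupy accessible positions matching
the sampled type's ancestral context (reverse-strand placements receive the
complemented derived allele), with exact per-type truth counts; planted
hypermutable motifs as rate multipliers; signature-mixture spectra; and
Brownian or exchangeable scalar covariates. Everything is deterministic
given a seed; reruns are byte-identical.

The default tree has 13 leaves in four clades with one long internal branch
to a two-taxon clade — the shape that makes clade-clustering behavior
(including an outlier clade on PC1) qualitatively reproducible.

Not emulated: linkage, demography, selection, GC-biased gene conversion,
sequencing error, or genotype uncertainty. Passing tests therefore show the
*procedures* are correct and calibrated under their stated models, not that
real data are free of the confounders the covariate tests exist to probe.
Two sampling caveats: SNP placement is without replacement within each
context's finite position pool, so requesting rates near a pool's capacity
compresses realized enrichments (the generator warns and resamples); and
planting a motif inflates its own 1-mer class rate, so realized fold
enrichment is below the nominal multiplier (a nominal 30× on a common 3-mer
realizes ≈ 9–11×).

## Problem sizes and defaults used by the test suite

Calibration and power checks run at deliberately chosen desk scales:
Mantel null calibration over 500 replicates at 199 permutations; nested-test
calibration over 500 replicates at 99 controls (the p-grid granularity,
1/(N+1), is well below the KS resolution at 500 samples); power checks at
50–60 replicates with 99 permutations; K_mult calibration over 250–300
Brownian replicates (Monte-Carlo tolerance ±0.1 around 1); exposure
recovery at 10⁶ counts; hypermutability recovery on a 120 kb genome at
k = 3. `scripts/acceptance.py` uses 300 replicates for the mean-K_mult
calibration. Defaults inside the library remain the full-scale ones
(5,000 controls, 999 K_mult permutations, pseudocount 1, downsample to the
minimum row total).

## Known limitations

- Exact Mantel enumeration is limited to n ≤ 8 labels (factorial growth).
- The Fisher scan loops over scipy's exact test; at k = 7 (24,576 types per
  species) a scan takes minutes, not seconds.
- K_mult assumes an invertible Brownian covariance; zero-length terminal
  branch pairs make C singular and raise.
- The partial Mantel is one of several "phylogenetically aware" constructions;
  results near the significance boundary should not be compared across
  packages without checking the construction.
- Novel-signature extraction is a point estimate with restarts, not a
  posterior; identifiability diagnostics (cosine to fixed signatures) are
  part of the result object for a reason.
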