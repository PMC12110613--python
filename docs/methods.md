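# Methods

`mutsig` implements a mutational-signature analysis pipeline for cancer
whole genomes: catalog construction, de novo signature extraction, exposure
attribution, per-sample profiling, pairwise interaction testing, and
stratified cohort comparison. This note records the models, the defaults
that matter, and the choices made where the design was genuinely open.

## Mutation catalogs

Somatic events are read from Simple Somatic Mutation (SSM) tab-separated
files in the ICGC dialect: 1-based inclusive coordinates, `-` for the null
allele, insertions anchored at the base after which they occur. Flanking
context comes either from embedded `context5`/`context3` columns or from an
indexed FASTA (pyfaidx). Rows with unparseable fields, non-ACGT alleles or
context, or context windows beyond chromosome bounds are dropped and
tallied in a skip report — never fatal. Multi-allelic or overlapping
records are counted independently; there is no left-alignment beyond the
stated anchoring convention and no phasing.

Three channel schemes are produced:

* **SBS96** — substitution in trinucleotide context, reverse-complemented
  onto the pyrimidine strand (`T[C>A]G`, 96 channels).
* **DBS78** — doublet substitutions collapsed (ref and alt together) onto
  the ten canonical reference doublets (78 channels).
* **ID83** — indels binned by length, affected base (1-bp events),
  repeat-unit copy number, and microhomology (83 channels).

ID83 conventions, stated explicitly because they are the part reference
implementations differ on:

* 1-bp events use the homopolymer run of the affected base *containing*
  the event (both flanks contribute), so classification is independent of
  where inside a run the caller anchored the event. Deletions count the
  deleted base (bins 1..6+); insertions count pre-existing copies
  (bins 0..5+). The base is complement-normalized to C/T.
* Events of length >= 2 count maximal tandem copies of the event unit on
  the forward strand extending 3' of the locus; deletions include the
  deleted copy.
* Deletions >= 2 bp with exactly one copy and flanking homology >= 1 bp are
  microhomology channels. Homology is the longer of (longest prefix of the
  deleted sequence matching the 3' flank) and (longest suffix matching the
  5' flank), capped at event length − 1; a full-length 5' match would be a
  tandem copy, not homology. Label digits follow the COSMIC ID83 set:
  0-based bins for homopolymer/repeat channels, homology length (capped at
  5) for microhomology channels.

All three classifiers are validated channel-by-channel against independent
brute-force oracles (exhaustive case lookup for SBS/DBS, naive string
scanning for ID) on 10,000 randomized records each.

## De novo extraction (KL-NMF)

A catalog `V` (channels × samples) is factorized as `V ≈ W H` with
`W >= 0` column-stochastic profiles and `H >= 0` exposures, minimizing the
generalized Kullback–Leibler divergence — the Poisson-likelihood objective
appropriate for counts. Multiplicative updates guarantee a non-increasing
objective; iteration stops at relative change < 1e-9 or 10,000 iterations
(both configurable). A floor of 1e-12 guards logarithms and divisions.
Initialization is uniform-random scaled to the data mean; every
factorization seed is derived from one user seed via a counter, so runs are
reproducible bit-for-bit.

Rank selection follows bootstrap stability: for each candidate rank the
catalog is resampled per sample (multinomial over channels, burden
preserved; the first replicate is the original catalog so the degenerate
single-bootstrap call reduces to a plain factorization), each replicate is
factorized keeping the best of `n_restarts`, and the pooled solution
signatures are partitioned into `rank` clusters by cosine distance
(k-means on L2-normalized profiles). Consensus profiles are cluster
medoids. The stability score is the **minimum per-cluster mean
silhouette** — the reproducibility of the *weakest* signature — rather than
the pooled mean: a rank one above the truth manifests as a single
irreproducible cluster whose collapse the pooled mean masks (measured on a
planted rank-3 cohort: min-cluster stability 0.79 / 1.00 / 0.00 / 0.00 at
ranks 2..5, pooled mean 0.82–1.00 throughout). The selected rank is the
largest with stability >= 0.8, falling back to the argmax (ties to the
smaller rank). Underfit ranks are typically also stable — merged signatures
reproduce across bootstraps — which is exactly why the rule prefers the
largest qualifying rank. Defaults: 20 restarts, 30 bootstraps.

## Reference matching and exposure refitting

De novo consensus signatures are assigned to a reference set (COSMIC-style
channels × signatures TSV) by greedy one-to-one matching in decreasing
cosine order; matches below `min_cosine = 0.85` stay unmatched and can be
expressed as sparse non-negative mixtures of reference signatures (NNLS,
components below `prune_threshold` dropped and the remainder refit, weights
renormalized).

Cohort attribution is per-sample NNLS of the count vector on the reference
profiles, with the same pruning loop (default threshold 0.01 of the
sample's burden, i.e. minor attributions are zeroed and the fit repeated
until stable). Absolute exposures are rescaled to sum to the sample's
burden; relative exposures are their per-sample shares. Zero-burden samples
yield an all-zero row and are flagged, not errored.

## Per-sample descriptors

Signatures pool into etiology groups before presence and dominance are
evaluated (APOBEC = SBS2+SBS13, HRd = SBS3, HRd-ID = ID6,
MMRd = SBS26/SBS44/DBS7, BERd = SBS30/SBS36, ROS = SBS18, NHEJd = ID8,
Aging = SBS1, plus SBS5, cAID = SBS85, ncAID = SBS9; unmapped signatures
are their own group). A group is *present* when its relative contribution
is >= 0.05 (inclusive) **and** it accounts for >= 10 mutations — reported
minimum observed contributions in breast cohorts (~0.04) imply a small
detection floor but none is published, so both knobs are config-exposed.
The first/second dominant groups are the two largest contributions (ties
broken lexicographically); a sample's *signature group* is its strongest
dominant that is not clock-like (SBS1/SBS5), or "Others" when both
dominants are clock-like. The "and/or" in the published Others rule is
resolved this way because it is the reading consistent with reported group
frequencies.

## Interaction testing

For each unordered pair of groups with nonzero presence margins, the
overlap `k` out of `N` samples with margins `n_a`, `n_b` is scored with the
exact hypergeometric distribution: `p_co = P(X >= k)`,
`p_ex = P(X <= k)`, both tails including `P(X = k)` (so `p_co + p_ex >= 1`),
summed in log space. The smaller tail nominates the candidate direction;
candidate p-values are Benjamini–Hochberg adjusted across all tested pairs
(default; `none` reproduces raw-p calling, matching reports that state no
correction) and the direction is kept when `q <= alpha = 0.05`. Pairs with
a zero margin are reported *untestable* rather than p = 1, avoiding
spurious exclusivity. A seeded permutation oracle (exhaustive for
N <= 12) backs the implementation in tests.

Because the distribution is discrete, the two-directional procedure has
size close to 2α (each tail separately is calibrated at ~0.05 for N = 100,
margins 30/30); calibration is therefore checked per direction.

## Stratified comparison

Per-stratum summaries report prevalence (100·present/N, printed to 2
decimals, matching cohort-report formatting), dominant-signature fractions,
and contribution statistics over present samples. Enrichment of
dominant-signature composition across strata uses the two-sided Fisher
exact test for 2×2 tables and, for larger tables, a seeded Monte-Carlo
exact test with fixed margins (`scipy.stats.random_table`, 10^5 draws,
statistic = table probability under the multiple hypergeometric null,
add-one p estimate) — chosen over the network algorithm for simplicity
with quantified error. Distribution comparisons (two-sided Mann–Whitney U
and Kolmogorov–Smirnov) consider only samples where the signature is
detected (nonzero contribution), matching density plots restricted to
nonzero counts. Kernel densities are Gaussian with Silverman's factor
(≈1.06·σ̂·n^(−1/5) in one dimension) on a grid spanning the data ± 3
bandwidths; constant samples raise a degenerate-bandwidth error.

HRd status partitions samples into exactly one of three classes:
bi-allelic BRCA1/BRCA2/PALB2 inactivation → HRd; otherwise HRD score < 0.1
→ non-HRd; otherwise (score >= 0.1, or missing without the flag) →
unassigned, and unassigned samples are excluded from HRd-stratified
comparisons. The HRD score itself (LOH/LST/TAI genomic scars) is consumed
as an input column in [0,1]; computing it is out of scope — there is no
copy-number model here.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
per-sample active signature sets (independent Bernoulli presence with
optional hard exclusivity and co-occurrence odds multipliers, honored by
rejection sampling with a 10^4 cap and an error naming the offending
constraint), Dirichlet relative exposures over the active set
(concentration 2.0), negative-binomial burden (default mean 1,000
mutations/genome at desk scale — real breast WGS genomes carry thousands —
dispersion 10), and multinomial channel counts from the mixture profile.
Every sample is resampled until at least one signature is active, so no
tumor is processless. Signature profiles are symmetric-Dirichlet draws
(concentration 0.1) rejected until all pairwise cosines are < 0.8, keeping
planted signatures identifiable. Annotations link a designated HRd
signature's activity to the bi-allelic flag and a high (>= 0.5) vs low
(< 0.1) HRD score.

From any catalog the generator synthesizes concrete SSM records whose
alleles and constructed flanking context classify back into exactly their
source channel — runs, repeats and homology are built to the bin and then
explicitly broken one position further — so catalog → records → catalog is
the identity for all three schemes. Contexts are generated sequence on a
synthetic chromosome ("chrS1"), not drawn from a real genome.

What the generator does **not** emulate: trinucleotide abundance of a real
genome, replication-timing/chromatin covariates of mutation density,
copy-number or structural variation, signature profiles with the spectral
shape of real COSMIC signatures, or inter-signature burden correlation.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated statistical model, not performance on real
tumors.

## Problem sizes used in checks

The bundled verification runs use a 200-sample cohort at ~1,000
mutations/sample with 3 planted signatures for extraction/refitting checks
(rank sweep 2..5, 4 restarts, 8 bootstraps), 2,000 simulated cohorts
(N = 100, margins 30/30) for interaction calibration, 200 cohorts for
exclusivity power, and 10,000 randomized records per scheme for
classifier/oracle agreement. The analysis scripts use a 200-genome cohort
with seven named signatures and planted HRd/ROS exclusivity.

## Known limitations

* Exposure refitting assumes the reference set spans the active processes;
  unmodeled processes bleed into the nearest reference signature.
* The bootstrap consensus clusters with k-means on normalized profiles;
  pathological geometries (two true signatures at cosine just under the
  rejection bound) can split/merge clusters before the silhouette flags it.
* The Monte-Carlo R×C exact test has sampling error ~(p(1−p)/10^5)^1/2;
  p-values near a decision boundary should be read accordingly.
* Presence calling is thresholding, not a per-sample significance test.
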