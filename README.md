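# mutsig

Mutational-signature analysis for cancer whole genomes: mutation catalogs
(SBS96 / DBS78 / ID83), de novo signature extraction by KL-NMF with
bootstrap rank selection, exposure refitting against a reference signature
set, per-sample signature profiles, pairwise co-occurrence / mutual
exclusivity testing, and stratified cohort comparison (tumor grade, HRd
status).

It is written for the analysis style used in breast-cancer signature
studies: somatic mutations from ICGC-dialect SSM files are classified into
COSMIC channel schemes and counted into a catalog `V` (channels × samples);
`V ≈ W H` is factorized into column-stochastic signature profiles `W` and
non-negative exposures `H` by multiplicative-update NMF under the
generalized Kullback–Leibler objective; per-sample relative contributions
define presence (contribution ≥ 0.05 and ≥ 10 attributed mutations),
first/second dominant signature groups and the per-tumor signature group;
presence of each signature pair is tested for deviation from independence
with the exact hypergeometric test, `p_co = P(X ≥ k)` and `p_ex = P(X ≤ k)`
for overlap `k` given the margins, with Benjamini–Hochberg control across
pairs; and strata are compared with Fisher / Monte-Carlo exact enrichment
tests, Mann–Whitney U, Kolmogorov–Smirnov and Kruskal–Wallis statistics and
kernel densities. A synthetic-cohort generator with full ground truth
(planted signatures, exposures, burdens, interaction structure, HRd
annotations) backs every stage with recoverable truth, so the whole
pipeline is testable without any controlled-access download.

## Worked example

The numbered scripts under `analysis/` run a complete study on a simulated
200-genome cohort with seven named signatures (APOBEC = SBS2/SBS13,
HRd = SBS3, ROS = SBS18, SBS8, clock-like SBS1/SBS5), hard HRd/ROS mutual
exclusivity planted in the generator, and HRd annotations tied to SBS3
activity:

```sh
python analysis/01_simulate_cohort.py    # SSM file, signatures, annotations, truth
python analysis/02_build_catalogs.py     # SSM -> SBS96 catalog (lossless round trip)
python analysis/03_extract_signatures.py # de novo NMF, rank sweep 5..9
python analysis/04_profile_exposures.py  # NNLS refit, presence, dominants, prevalence
python analysis/05_interactions.py       # hypergeometric pair tests + heatmap
python analysis/06_stratified_comparisons.py  # grade / HRd-status comparisons, KDEs
```

Selected output from a run (tables land in `results/analysis/`):

```
      stability  reconstruction_error
rank
5        0.9982                0.1390
6        0.7419                0.1037
7        0.9858                0.0677
8        0.0000                0.0662
selected rank: 7 (7 signatures planted)
```

Extraction picks the planted rank — stability (minimum per-signature
bootstrap silhouette) collapses the moment a spurious eighth signature is
asked for — and every consensus signature matches its planted source at
cosine ≥ 0.989. Refit exposures correlate with the simulated truth at
Pearson r ≥ 0.994 per signature, and the interaction step recovers the
planted antagonism from the pipeline's own presence calls:

```
group_a group_b  k        q direction
    HRd     ROS  1 0.001302 exclusive
planted HRd/ROS exclusivity recovered: True
```

HRd-status stratification then shows what it should: dominant-signature
composition differs strongly between HRd and non-HRd genomes
(Fisher/Monte-Carlo exact p ≈ 1e-5) while tumor grade, which the generator
assigns independently, shows none (p ≈ 0.5).

A `mutsig` command-line interface exposes the same steps
(`simulate`, `matrix`, `extract`, `refit`, `profile`, `interact`,
`stratify`, `report`, and `run` for a YAML-configured end-to-end pipeline
that writes a checksummed artifact manifest; fixed seed ⇒ byte-identical
outputs).

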