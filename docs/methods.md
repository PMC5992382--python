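# Methods

This note documents the models, conventions and parameter choices behind
`cryoclean`, in the order the pipeline runs.

## Read quality control

Reads are filtered by **expected error**, `EE = Σ_i 10^(−Q_i/10)` over the
per-base Phred scores — the expected number of erroneous bases under the
Phred model. A read is excluded when its length is below `min_length`
(default 245 nt) or when EE exceeds `max_expected_error` (default 1.0,
strictly: EE exactly 1.0 is retained); survivors are truncated to
`trunc_length` (default 245 nt). EE is computed **on the truncated prefix**
by default, so the quality contract refers to the bases that actually enter
downstream analysis and the 245-nt output length is self-consistent; the
whole-read alternative is available via `QcParams(ee_on_full_read=True)`.
Quality encoding is fixed to Phred+33. Paired-end merging, primer trimming,
chimera detection and OTU clustering are deliberately out of scope — the
pipeline ingests merged, primer-free reads and an externally built OTU table.

## Profiles

**Rarefaction** is a single multivariate-hypergeometric draw (subsampling
without replacement) to a common depth, deterministic given a seed. A single
draw, not an average over repetitions, matches how depth normalisation is
usually reported for this kind of survey; samples below the depth are dropped
with a warning. Typical depths are 15,000 (control-only analyses) and 30,000
(combined analyses).

**Taxonomy masking**: assignments with classifier confidence strictly below
0.80 are replaced by `unclassified`. With the usual single per-assignment
confidence the mask applies to the whole lineage; per-rank confidences, when
supplied, mask rank by rank. Organelle (mitochondrial/chloroplastic) OTUs are
flagged by case-insensitive substring match on "mitochondri"/"chloroplast"
anywhere in the lineage and removed before rarefaction, so organellar reads
never consume rarefaction depth.

**Collapsing** sums OTU counts per rank label; per-sample totals are
conserved, and a masked rank aggregates under `unclassified_<nearest resolved
ancestor>` (e.g. an unclassified genus within *Comamonadaceae* becomes
`unclassified_Comamonadaceae`). **Major-taxon selection** supports both the
`≥` and strict `>` comparators because both conventions (≥ 1.0 % of a sample;
> 0.1 % of a sample) are in common use; ties in the descending-mean ordering
break lexicographically for reproducibility.

## R-OTU decontamination

Absolute abundance is `relative abundance × qPCR 16S copies/μl`; the R-OTU
score is the ratio of its arithmetic means over controls and specimens
(zeros included). Conventions:

- control mean 0 → `r = 0` (never flagged);
- specimen mean 0 with control mean > 0 → `r = +∞` (always flagged — an OTU
  seen only in controls is the unambiguous contaminant case);
- removal is strict (`r > threshold`, default 0.01) and **global**: flagged
  OTUs leave controls as well as specimens;
- scores are computed on the rarefied, organelle-filtered table at the OTU
  level, and retention denominators are that table's counts;
- an empty sample reports retention 1.0 with an explicit `empty` flag rather
  than NaN, keeping reports machine-readable.

The method is a **single pass**: once contaminants are removed, control
profiles consist almost entirely of carried-over specimen material, so
recomputing scores on the cleaned table would by construction inflate every
remaining ratio. Idempotence therefore holds with respect to the original
score report (a second `decontaminate` with the same report removes
nothing), and that is the property the tests check.

Why the 0.01 cutoff is safe: for an endogenous OTU whose templates reach the
controls only by carryover of a fraction ε of the mean specimen pool, the
expected control mean is ε × (specimen mean), so its expected score is ε
itself, independent of the biomass ratio. The cutoff must simply sit well
above the plausible carryover rate; observed control compositions in
background-control designs put ε in the 10⁻⁴–10⁻³ range, an order of
magnitude or more below 0.01. This identity (`E[r_endog] = ε`) is frozen as
a test.

## Community statistics

All five comparisons are implemented directly (scikit-bio and scipy versions
serve as independent cross-checks in the test suite):

- **Weighted UniFrac**: `d(A,B) = Σ_b l_b |p_A(b) − p_B(b)|` over branches,
  where `p_X(b)` is the fraction of sample X's reads below branch b. The
  un-normalized ("raw") variant is the default — the historical default of
  the era's amplicon toolchain — with the normalized variant
  (`÷ Σ_b l_b (p_A(b)+p_B(b))`) behind a flag. Extra tree tips are pruned;
  missing tips are an error.
- **ANOSIM**: `R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4)` on mid-ranked pairwise distances (mid-ranks documented because
  tie handling changes R at small n); p by label permutation with the +1
  correction, or exhaustive enumeration for small n.
- **PCoA**: classical scaling (double-center −½D², `eigh`); negative
  eigenvalues are reported but contribute no axis, and proportions explained
  are taken over the positive eigenvalues.
- **UPGMA**: size-weighted average linkage, merge height = distance/2,
  lexicographic tie-break; heights are non-decreasing (ultrametric) and the
  dendrogram serialises to newick.
- **Mantel**: Pearson r of the upper triangles, simultaneous row/column
  permutation of one matrix, two-tailed on |r|.
- **Paired profile test**: two-tailed paired t over per-taxon abundance
  differences with k−1 degrees of freedom; all-zero differences give
  t = 0, p = 1. Raw proportions by default (arcsine and logit transforms are
  available but off), because the comparison of original vs pre-amplified
  libraries is conventionally reported on raw profiles.

Permutation p-values are exactly reproducible given (seed, permutations).

## The simulator

`simulate_experiment` draws, per group, an endogenous community from a
symmetric Dirichlet (concentration 1.0 — a flat prior giving realistically
uneven mock communities), and one shared contaminant community for all
controls (ambient contamination in one facility is a common pool; per-control
idiosyncrasies are not modelled). Template pools in copies/μl:

- specimen = `specimen_copies × endogenous + control_copies × contaminant`
  (specimens also breathe the ambient pool — this is exactly the situation
  in which proportional removal, rather than presence/absence exclusion, is
  the behaviour worth testing);
- control = `control_copies × contaminant + ε × (mean specimen pool)`, the
  carryover term modelling directed high→low-biomass cross-contamination
  during co-processing.

Measured qPCR is the true total times a mean-1 lognormal factor
(`qpcr_cv = 0.10`, a typical replicate-level qPCR dispersion); reads are
multinomial at `read_depth` (default 30,000), optionally distorted by
two-round PCR bias `w_i ∝ pool_i (1+e_i)^(c1+c2)` with cycles (28, 8) and
per-template efficiencies uniform in (0.9, 1.0].

Defaults: 4 specimens at 2,000 copies/μl vs 4 controls at 40 copies/μl (a
50× biomass contrast, the lower edge of the 50–100× range such designs
exhibit), 20+20 OTUs, 2 depth-stratum groups. The **carryover default is
ε = 5×10⁻⁴**, chosen so that controls carry ≈ 2.4 % specimen-derived reads
(`ε·S/(C+ε·(S+C))`) — matching the few-percent specimen-derived fractions
and sub-3 % post-removal control retention observed in real background
controls. Because `E[r_endog] = ε`, a carryover rate at the removal cutoff
itself would place every endogenous OTU on the decision boundary; such a
regime is not a faithful model of any working background-control design and
is deliberately not the default (it can still be configured explicitly).

What the simulator does **not** emulate: taxonomic realism of names,
chimera formation, per-base error profiles beyond what the EE filter needs,
and air-volume normalisation of control biomass (collected air volume enters
no formula; ambient contamination is a single pooled rate). Passing tests
therefore demonstrate correctness of the computations and recoverability of
truth under the stated statistical model — not robustness to every artefact
of real sequencing.

FASTQ emission tags each OTU with a deterministic SHA-256-derived sequence
so that emit → QC → tally is exactly invertible at zero failure fraction;
injected failures are split between too-short and low-quality reads.

## Pipeline

`run_pipeline` fixes the stage order (QC'd table in → organelle filter →
rarefy → decontaminate → profiles → statistics), writes every artifact as
TSV/newick, and records a manifest with the resolved configuration, one
derived seed per stochastic stage (expanded from a single master seed via
`SeedSequence`), and a SHA-256 checksum per output, so identical configs
yield bit-identical runs. ANOSIM runs automatically when the specimens span
at least two groups; Mantel requires an explicit second matrix via the
`stats` subcommand.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use the default design (8
libraries × 40 OTUs at depth 30,000, 10 seeds) for recovery checks;
oracle-equivalence checks run on exhaustive small instances (≤ 5 OTUs × ≤ 4
samples for R-OTU longhand; 6-tip trees for UniFrac; n ≤ 6 for exhaustive
ANOSIM and n = 5 for exhaustive Mantel), where enumeration is exact. These
sizes keep full validation in the order of seconds while every check remains
a from-scratch recomputation.

## Known limitations

- The R-OTU approach assumes DNA extraction/recovery efficiency is similar
  for a given taxon across samples; taxon-specific recovery bias shifts
  scores in ways qPCR scaling cannot correct.
- Absolute abundances inherit qPCR measurement error wholesale; the score is
  a ratio of means over few samples and is noisy for rare OTUs.
- Presence/prevalence-model classifiers (frequency-based contaminant
  statistics) are a complementary family of methods and are not implemented.
- BIOM-HDF5, SRA retrieval and upstream tools (clustering, chimera removal,
  classification, tree building) are out of scope; the pipeline consumes
  their text outputs.
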