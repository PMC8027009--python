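# Methods

This note documents the models implemented in `autozykit`, the choices made
where the design was genuinely open, and what the synthetic data generator
does and does not emulate.

## Inbreeding estimators

### Pedigree (F_PED)

Malécot kinship by the standard recursion with memoization; founders are
unrelated and non-inbred, and a single unknown parent contributes no
relatedness. `partition_by_generation` splits F_PED into a *recent* part —
F computed on the pedigree truncated `g` generations above the focal
individual — and an *ancient* remainder. Truncation is path-based: an
ancestor contributes to the recent part only through paths whose every link
lies within depth `g`, and when a loop's common ancestor is reached at
depths `da`/`db`, its own inbreeding is evaluated with the residual budget
`g − max(da, db)`. This makes the split deterministic and monotone in `g`
(recent F converges to the total as `g` grows past the pedigree depth).
Completeness at generation `g` is the fraction of the `2^g` ancestor-path
slots that are fully recorded.

### SNP-by-SNP estimators (F_HOM, F_UNI, F_GRM, F_ML)

All work on alternate-allele dosages with per-SNP frequencies; missing
genotypes are dropped SNP-wise from every sum so the estimators stay
defined under sporadic missingness. Frequencies default to the sample being
analysed; any external vector (e.g. a founder-generation reference) can be
passed instead. F_GRM defaults to VanRaden's first method (ratio of sums);
the per-SNP-weighted variant is available behind a flag because tools such
as GCTA weight SNPs equally — the two coincide when all frequencies are
equal (tested identity).

F_ML maximizes the two-component mixture likelihood

  L(F) = Σᵢ log[ F·P(gᵢ | autozygous) + (1−F)·P(gᵢ | Hardy–Weinberg) ]

with autozygous emissions (1−p)(1−ε)+ε(1−p)², 2p(1−p)ε, p(1−ε)+εp² for
hom-ref / het / hom-alt (alternate frequency p, error rate ε). The
likelihood is unimodal in F, so a bounded scalar search to xatol 1e-7 is
used, with both boundaries checked explicitly and estimates within `tol` of
0 or 1 snapped to the boundary; EM is provided as an independent
cross-check. Default ε = 0.001: non-zero so a heterozygote does not send
the likelihood to −∞ at F→1, small enough not to bias the interior
optimum.

### ROH scanner (F_ROH)

Maximal runs of homozygous genotypes, split wherever consecutive-SNP
spacing reaches the maximum gap, then filtered on SNP count, strict
physical length (> min length, measured first-to-last SNP as in PLINK) and
density (count ≥ length / 100 kb). With zero heterozygotes allowed — the
configuration used throughout — PLINK's sliding-window vote reduces to
exactly these maximal-run semantics, so no window machinery runs; a
heterozygote-tolerant mode is deliberately not implemented. Missing
genotypes are run-compatible up to a per-segment budget (default 0); a run
over budget is split at every missing site. Length classes are half-open
[2,5), [5,10), [10,∞) Mb so boundary values assign deterministically, and
per-class F_ROH sums exactly to the total.

### HBD hidden Markov model (F_HBD)

K HBD classes with fixed, strictly increasing rates (default 5, 25, 125,
525 per Morgan) plus a non-HBD class sharing the largest rate. Between
markers separated by d Morgans the chain stays with probability
exp(−R·d) and otherwise resets to a draw from the mixing coefficients π,
so expected segment length in class k is 1/R_k Morgans and a class-k
segment points to ancestors roughly 0.5·R_k generations back. Emissions
reuse the F_ML mixture components, which is what makes the one-class,
independent-SNP limit of F_HBD coincide with F_ML (verified to 1e-4 in the
tests). Chromosomes restart from π. Only π is estimated (per individual);
the M-step uses the expected *reset* counts of the full chain — the exact
Baum–Welch statistic for this tied parameterization — rather than marginal
state occupancy. π components are floored at 1e-12 and renormalized so
boundary collapse is allowed without degeneracy. The recursion uses
per-marker scaling constants; the forward scalings give the
log-likelihood, which is non-decreasing over EM iterations (asserted on
every fit in the tests). Missing map positions fall back to 1 cM/Mb.

The module also contains the model's own generative sampler. Segments are
recorded per draw of the event process (state ~ π, sojourn ~ Exp(R_state)),
so adjacent same-class draws are separate segments — this is the sense in
which mean segment length equals 1/R exactly; decoded-run lengths would be
upward-biased by self-transitions.

## Evaluation scores

AF classes are half-open (lo, hi] partitioning (0, 1] (20 classes by
default); MAF classes partition (0, 0.5]. Per-class scores are normalized
by the class's non-missing SNP count; a class with no SNPs is reported
missing, never zero. HML counts hom-alt genotypes at SNPs with alternate
frequency ≤ threshold — homozygosity of the *rare alternate* allele, not
hom-ref at low-MAF SNPs — optionally weighted by 1/AF and restricted to a
functional class or to private alleles. Windows are half-open
[k·1 Mb, (k+1)·1 Mb) from position 0. Regional homozygosity is excluded
where a window holds fewer than 5 array SNPs; regional HML additionally
where it holds fewer than 2000 dense-panel SNPs or fewer than 8 individuals
with a non-zero score (each exclusion names the failing rule). At the
generator's desk scale the dense panel has ~80 SNPs per 1-Mb window, so
analyses on synthetic data scale the WGS-count filter accordingly; the
filter defaults keep the full-scale values.

Correlations use pairwise-complete observations and Fisher-transform 95%
intervals with the fixed 1.96 multiplier. Perfect correlations are returned
flagged degenerate with a collapsed interval rather than raising.
Offspring-F prediction is implemented for the two modes with a defined
convention: genomic (half the VanRaden relationship of the parents, which
for an identity pair reduces to (1+F̂)/2) and pedigree (parental kinship).

## Synthetic data generator

The generator emulates the structure of a sequenced livestock pedigree
study: a founder population with realistic spectrum and LD, a genotyped
multi-generation pedigree with widely varying inbreeding, an ascertained
array panel, and functional annotation strata.

* **Founder pool.** Forward Wright–Fisher haploid pool (default 200
  haplotypes, 200 generations) over 10 chromosomes of 1 Morgan / 50 Mb
  (2 cM/Mb, piecewise-linear map). Recombination uses the Haldane (Poisson,
  no-interference) model — implemented exactly via per-interval toggle
  counts — deliberately matching the HBD model's exponential segment
  assumption so parameter-recovery tests are well-posed. Mutation adds
  Poisson(N·μ) singleton sites per generation (default μ = 20 per haplotype
  per generation), plus one seeding batch at generation 0; fixed and lost
  sites are pruned. This yields ~40k segregating sites with a
  low-frequency-heavy spectrum, LD from the finite pool, and
  age–frequency–privacy gradients in the directions seen in real data
  (rarer alleles are younger and more often private). Site density
  (~1 SNP/12 kb) is a desk-scale stand-in for true WGS density.
* **Private alleles.** A second population splits off 50 generations before
  the end of the burn-in and drifts without further mutation; alleles
  absent from a 100-haplotype sample of it are flagged private.
* **Pedigree.** 5 generations: 60 founders, two adult generations of 75,
  and 100 final offspring; 20% of matings are close (full-sib, half-sib or
  first-cousin, drawn evenly from the pairs available), the rest avoid
  shared parents. The genotyped cohort is the last two adult generations
  plus the offspring (250 individuals, mirroring a 145-parents +
  100-offspring sequencing design).
* **Gene dropping.** Founders receive two distinct labelled pool
  haplotypes; each meiosis draws Poisson(length) crossovers uniform in cM.
  Tract labels tile every chromosome exactly (asserted), so true
  autozygosity — the bp fraction where the two haplotypes carry the same
  founder label — is exact. Genotyping error, when configured, perturbs
  only emitted genotypes, never the truth. The default error is 0: post-QC
  array error rates (~1e-4) are negligible at this scale, and a clean
  default keeps ground truth crisp; tests that probe error behaviour set it
  explicitly.
* **Array ascertainment.** Evenly spaced thinning of sites with
  founder-generation MAF ≥ 0.05 to a target of 8000 — the desk-scale
  analogue of a commercial ~50K array panel, with marker spacing per Morgan
  in the same regime (roughly one SNP per 0.12 cM).
* **Annotations.** Functional classes are sampled with frequency/age tilts:
  deleterious missense concentrated at low frequency and young age,
  tolerated missense mildly tilted, synonymous neutral; an all-neutral
  switch removes the tilts (used as a null in the tests).

**What the generator does not emulate:** selection and fitness (no
phenotypes, no inbreeding-depression regression), variable recombination
maps, crossover interference, overlapping generations, sequencing/calling
artefacts beyond a uniform genotype-error rate, and coalescent-exact deep
history. Consequently, passing tests demonstrate estimator correctness and
the qualitative estimator orderings under these idealized conditions; they
do not calibrate absolute correlation levels for real cattle data.

## Known limitations and observed behaviour

* **F_HOM recovery is the tightest margin.** Because F_HOM weights all
  homozygosity equally, founder background IBD (real, but invisible to the
  founder-label truth) acts as noise; across generator seeds its
  truth-correlation spans ~0.83–0.94 while F_HBD/F_ROH sit at ~0.93–0.96.
  This mirrors the estimator's known character rather than a defect.
* **Regional F_PED is not near zero against noise-free truth.** With the
  default 20% close matings, F_PED varies widely (sd ≈ 0.10) and therefore
  predicts the *level* of regional true autozygosity even though it has no
  locus-specific information: its mean per-window correlation with regional
  truth is ≈ 0.4 (≈ 0.18 against sampling-noisy regional WGS
  homozygosity), well below the locus-aware F_HBD. A near-zero value
  requires the narrow pedigree-F spread and noisy regional scores of real
  data; the corresponding assertion in the end-to-end suite is left
  failing by design rather than loosened.
* The EM fits ~250 individuals × ~8000 markers × 5 states in ≈ 1 minute on
  one CPU (vectorized across individuals); problem sizes in the test suite
  and acceptance script were chosen so the full pipeline runs in minutes.
* `f_ml` is O(individuals × SNPs × ~40 likelihood evaluations); the
  regional layer excludes it, as its window-level likelihood surface at
  <10 SNPs is too flat to be useful.
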