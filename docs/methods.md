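# Methods

`methylseg` analyses whole-genome bisulfite sequencing data from a set
of closely related strains: it calls methylated cytosines, segments
each strain's methylome into methylated regions (MRs), tests regions
for differential methylation between strains (DMRs), groups strains
into epialleles, and quantifies population-level properties of the
resulting methylation variation.  This note records the models, the
parameters that matter, and the choices made where the design was
genuinely open.

## Data model

The atomic observation at cytosine *p* of sample *S* is the pair
(*x_Sp*, *C_Sp*): methylation-supporting reads out of total reads.
Each cytosine carries its sequence context — CG, CHG or CHH (H = A, C
or T) — because the three contexts are maintained by different
enzymatic pathways and have very different rate distributions.
Coordinates are 1-based inclusive internally (the allc convention);
BED output is 0-based half-open.  Symmetric CG positions are *not*
merged across strands: each cytosine is an independent observation.
Accessions are sequenced as replicate pools of siblings; wherever a
single rate per accession is needed, read counts are summed across
replicates.  Base-call quality is a per-record boolean supplied
upstream; this toolkit does not process raw reads.

## Beta-binomial model and the dispersion floor

Read counts are modelled as beta-binomial: the latent per-site
methylation rate is Beta(α, β)-distributed and reads are binomial
given the rate.  Maximum-likelihood fits work on (log α, log β) with
analytic gradients (L-BFGS-B).

α and β are bounded in [10⁻⁴, 25].  The lower bound lets degenerate
data (all-zero counts) pin the mean at the boundary.  The upper bound
is a *dispersion floor*: the fitted rate distribution can never have a
standard deviation much below ~6% at intermediate rates.  Two reasons:
per-cytosine rates within a genomic region always retain residual
biological and technical spread, so a pure-binomial collapse is not a
credible fit; and on small regions the unbounded precision MLE
frequently diverges, which inflates likelihood-ratio statistics and
makes the nominal chi-squared reference anticonservative.  With the
floor in place the pairwise region test is calibrated (null type-I
error ≈ 0.05 at p < 0.05 with 10 sites per context at depth 20,
measured by simulation in the acceptance suite).

## Methylated-site and DMP calling

A cytosine is methylated when its replicate-accumulated counts are
inconsistent with the false-methylation rate (FMR) — the apparent
methylation of the chloroplast, which is biologically unmethylated and
therefore measures bisulfite non-conversion plus sequencing error.
The test is a one-sided binomial tail P(X ≥ x | n, FMR); q-values are
Storey's, with sites called at FDR 5%.  Sites must be covered ≥3× with
good quality in at least half the strains to enter the analysis.

Differentially methylated positions (DMPs) between two accessions use
two-sided Fisher's exact tests on pooled counts at positions methylated
in at least one strain, after excluding positions whose two replicates
disagree (Fisher + 5% FDR per accession).  Mid-p corrections are not
used.  The multiple-testing correction is Storey's method applied per
strain-pair contrast; the correction scheme of the prior work this
scheme descends from is not fully restated in the source methods, so
the per-contrast choice is a documented approximation.

## MR segmentation HMM

A two-state (LOW/HIGH methylation) hidden Markov model runs along all
genome-wide cytosines of one strain, covered or not.  Emissions are
beta-binomial with separate parameters per state and context — six
distributions — because in plants all three contexts are informative
but on different scales.  Uncovered cytosines emit with probability 1
(uninformative) but still occupy chain positions and count toward gap
distances.

Training is Baum-Welch, at most 30 iterations, stopping when the
relative change in total log-likelihood falls below 10⁻⁴.  The M-step
for emissions is a posterior-weighted beta-binomial MLE.  Chromosomes
are independent chains sharing one parameter set, giving one
segmentation per strain.  Initialisation breaks label symmetry (LOW
mean 0.05, HIGH mean 0.7, self-transition 0.99); after training the
states are relabelled if necessary so HIGH is the more methylated
state, which makes the labelling identifiable.  EM guarantees the
log-likelihood sequence is non-decreasing; the test suite checks this
and checks posterior decoding against brute-force path enumeration.

Candidate regions are maximal HIGH runs of the posterior-decoded
path.  A run ends early wherever ≥50 bp pass without a covered
cytosine.  Regions are scored by the sum of contained methylation
rates (covered positions only; a zero-coverage rate is undefined).
Scores are tested against an empirical null: cytosine observations are
permuted across the position grid, the permuted genome is decoded and
segmented with the trained model, and all permuted segment scores are
pooled (the per-length versus pooled construction is not prescribed
anywhere; pooling is our choice and is noted here).  p =
(1 + #null ≥ score)/(1 + #null), Storey FDR at 5%.  Finally, boundary
positions with rates below 10% are trimmed (up to the first position
above 10%; the behaviour at exactly 10% follows the strict readings:
not trimmed, and trimming stops).  The default of 100 genome
permutations is seedable and configurable; the pipeline runs in the
tests use 20, which already gives a null pool of thousands of segment
scores on the simulated genomes.

## DMR calling

**Candidates.**  The start/end coordinates of all strains' MRs form a
breakpoint set; within each connected component of overlapping MRs,
every pair of breakpoints defines a candidate segment, kept if at
least one strain is HIGH across the whole segment.  Restricting
combinations to connected components is our reading of "every
combination of coordinates": cross-component combinations would be
both meaningless and combinatorially infeasible.

**Filters.**  (a) a region needs ≥2 strains with ≥10 cytosines covered
≥3× (replicate-accumulated); (b) regions reciprocally overlapping an
already-accepted region by ≥70% are discarded, scanning in genome
order; (c) a strain pair is skipped when both strains are LOW
throughout; (d) strains with fewer than half the maximum per-strain
covered-site count are excluded from the region.

**Pairwise test.**  For each admissible pair, three context-specific
beta-binomial distributions are fitted per strain (replicates as
independent observations) and three to the pooled counts.  The
statistic is LR = 2(ℓ₁ + ℓ₂ − ℓ_common) summed over contexts, referred
to χ² with 6 degrees of freedom; a context with no data in either
strain contributes nothing and drops the df by 2 (df = 2 per context
— two free parameters per beta-binomial — for the per-context
variant).  Before testing, a prefilter requires the intervals
μ ± 2σ of the two strains — fitted on counts accumulated over all
contexts — not to overlap; both the prefilter and the test must pass,
in that order.  Storey FDR across all pairwise tests at 1% defines
significant pairs.

**Grouping.**  Per region, strains are vertices and significant pairs
are edges; epialleles are the colour classes of a minimum vertex
coloring.  The search deepens iteratively from two colours, processing
vertices in descending degree order, and enumerates proper colorings
exactly (backtracking with first-use colour canonicalisation, exact up
to 16 strains, capped enumeration with a greedy fallback beyond).
Among minimum colorings the one minimising *grouping diversity* — the
mean over strains of the accumulated |strain mean − group mean| across
contexts — wins.  Strains with no edges join the group with the
nearest mean profile.  The diversity denominator is the number of
strains entering the sum; the one worked example in the source prints
a different denominator and a group mean inconsistent with its own
operands, so the prose definition is implemented and the printed
number is not forced.

**Group test, overlaps, hDMRs.**  Groups are re-tested with the same
machinery, treating all member strains' counts as replicates, with
df = 6(g − 1) for g groups.  Significant regions (Storey FDR 1%) are
DMRs; overlapping DMRs are resolved greedily by ascending grouping
diversity.  hDMRs are DMRs longer than 50 bp with a more-than-3-fold
rate difference in at least one context having ≥5 cytosines, and an
overall rate in the most methylated group above 20%.  A zero rate in
the lower group counts as infinite fold change, gated by the
minimum-rate condition.

## Population statistics

**Discovery curve.**  Non-ancestral (derived) methylation-state
frequencies follow a Beta(a, b) prior; the expected number of variable
positions discovered in n accessions is Δ(n) = N(1 − E[(1−f)ⁿ]), with
the expectation evaluated through the beta function.  N is never
hard-coded; it can be estimated by inverting Δ at an observed count.
The printed population total in the source is not derivable from its
printed inputs under this standard capture formula (the original
estimator lives in an external supplement), so the formula is exposed
and the discrepancy is not hidden.

**Homozygosity test.**  At a branched-reference variant site with
branch/reference read counts (r_b, r_ref), homozygosity predicts the
major haplotype carries ~95% of reads; the lower binomial tail of the
major count against Binomial(r_b + r_ref, 0.95) is the evidence
against a single haplotype (the test's sidedness is our choice — few
major-allele reads is the heterozygous-like signal).  Sites with ≤3×
coverage are missing data.  Storey FDR is computed jointly across all
variant-strain tests.  Variants are classified common / not present /
segregating / insufficient by the quoted rules, including the 2-fold
read-count rescue and the ≥7-of-13 informative-strain requirement.

**Mutant gain/loss.**  A site is methylated in wild type when both WT
samples are ≥10% and one is >20% methylated; lost when the mutant is
<10%; gained when at least one WT is <10% and the mutant is >20%.

**Overlap permutation.**  Two region sets within an MR-space universe
are both re-placed uniformly at random (lengths preserved, segments
chosen with capacity weights) and the observed count of set-A regions
touching set B is compared with the permutation distribution:
Z = (obs − mean)/sd plus a smoothed empirical p.

**Heritability.**  Per region, the phenotype is log(mean methylation
rate + 10⁻³) (the floor handles zero rates; the transform is otherwise
unspecified upstream).  The kinship matrix is the GCTA-style
standardised-genotype cross-product over segregating variants.  A
single-variance-component model y = μ + g + ε with cov(g) = σ²_g K is
fitted by REML after one eigendecomposition of K, profiling the
restricted likelihood over h² = σ²_g/(σ²_g + σ²_ε); the standard error
comes from the numerical curvature at the optimum.  Estimates are
clamped to [0, 1].

## Synthetic data

The generators mirror the model assumptions so that every stage is
testable without downloads: a two-state Markov path along geometrically
spaced cytosines (default persistence 0.95 ≈ mean segment length 20
positions), context proportions 15/15/70% (CG/CHG/CHH), beta-binomial
counts at Poisson depth (mean 18 per replicate, matching the intended
sequencing design), 13 strains with two replicate pools each.  HIGH
means default to 0.80/0.65/0.35 per context and LOW to 0.03.

Planted DMRs overwrite ancestral HIGH runs of ≥12 cytosines: a random
proper subset of strains switches to a low epiallele (rate 0.1) while
the rest stay at 0.8, uniformly across contexts; untouched HIGH runs
are recorded as planted negatives.  Planting is restricted to runs of
≥12 cytosines because the candidate filters require 10 covered sites —
a shorter region is outside the method's stated domain, not a miss.
In recovery scoring, a window counts as recovered (or falsely called)
when called DMRs cover at least half of it, so that 1-bp boundary
touches by adjacent true regions are not counted as false calls.

Epimutation noise flips single sites with probability
(1 − exp(−2 r_eff g))/2 per strain, r_eff = rate × (1 − reversion):
divergence saturates rather than growing linearly, which reproduces
the sub-linear accumulation of methylation differences relative to the
linear SNP clock.  Genetic variants accumulate as strain-private
Poisson draws (0.7 per generation).

For the pooling property, pooled groups are built from independently
diverged lines (no shared family divergence) and pools are "sequenced"
at per-individual depth by hypergeometric subsampling of the summed
counts — the property that pooling hides private epimutations is a
statement about sequencing pooled DNA at standard depth, not about
concatenating reads.

What the generators do *not* emulate: spatial coupling of CHH/CHG
epimutations through RdDM, context-dependent epimutation rates,
strand-asymmetric coverage, mapping bias near structural variants, and
bisulfite conversion failure beyond a flat false-methylation rate.
Passing tests therefore demonstrate the statistical machinery works
under its own model assumptions at desk scale, not that real-data
peculiarities are handled.

## Problem sizes used in tests

The test and acceptance runs use genomes of 1,500–4,000 cytosines, 13
strains, 20 score permutations, 2,000–5,000 null regions for LRT
calibration, and 50 phenotype replicates at n = 200 for heritability —
sizes chosen so the full pipeline exercises every code path in
minutes.  All generators and pipeline stages take explicit seeds and
are deterministic given them.

## Known limitations

- The exact multiple-testing scheme of the ancestor pipeline for DMPs
  is approximated by per-contrast Storey FDR.
- The permutation null for MR scores is pooled across segment lengths.
- The chromatic search is exact only up to 16 strains (beyond that a
  greedy coloring is used and flagged).
- Heritability assumes a single genome-wide variance component; no
  per-variant mapping is attempted.
- The discovery-curve population total depends on an externally
  defined estimator that is not reproduced here; only the standard
  capture form is provided.
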