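# Methods

This note documents the models, defaults and design choices behind
`treburden`, and what the synthetic-data tests do and do not demonstrate.

## Expansion calling

A locus-motif profile is the vector of per-sample repeat-length estimates
(bp) at one locus for one canonical motif; samples without a call are
absent, not zero — absence of evidence about an allele is not evidence of
a short allele. Motifs are canonicalised to the lexicographically smallest
string among all rotations of the motif and of its reverse complement, so
e.g. `GCA`, `CAG` and `CTG` name the same repeat; canonicalisation is
idempotent and strand-blind, which is why overlap operations ignore
strand.

Calling runs 1-D DBSCAN on the length vector. Core point: at least
`min_samples` points (self included) within `eps`; clusters: connected
core components plus border points; border points join their nearest core
deterministically (lower-valued core on ties). Expansion carriers are the
noise points whose length **strictly exceeds every clustered length** —
right tail only. A locus with no core points has no reference allele range
and yields no call. The bulk cohort caller uses an exact shortcut: every
value above the maximum clustered value is necessarily noise, so only that
ceiling is computed per locus; equality with the per-profile DBSCAN path
is asserted in the test suite, and the general `dbscan_1d` is checked
against a brute-force neighbourhood-expansion oracle.

Defaults (both overridable per run):

- `eps = max(50 bp, 3 × MAD of the locus length vector)` — 50 bp is a
  third of a read length, comfortably above baseline length noise.
- `min_samples = max(2, ceil(0.01 × n_with_call))`. The density threshold
  must exceed the carrier count of any single real expansion, otherwise
  two or more co-carriers with similar expanded lengths form their own
  small cluster and escape the noise label entirely. A 0.1%-scaled
  threshold does exactly that once cohorts drop to a few thousand samples
  (it degenerates to `min_samples = 2`), destroying sensitivity for
  multi-carrier loci; 1% of the cohort keeps rare expansions (≲1% carrier
  frequency by definition) below the core threshold while leaving the
  baseline cloud densely clustered.
- Per-sample QC before calling: samples whose genome-wide repeat-call
  count exceeds `median + 3 × IQR` are dropped (`k = 3` configurable).
- Minimum 10 samples with a call for a locus to be testable.

Rarity: an expansion is rare when strictly fewer than 0.1% of reference
panel samples carry it (carrier-based, matching the carrier semantics of
the whole method). CpG classification: the motif concatenated with itself
(circular scan) contains any of CG, GC, CGC, CGG, CCG, GCC, GGC, GCG.

## Annotation

All context assignments use ≥1 bp overlap on 0-based half-open intervals;
abutting intervals share 0 bp. Gene-part labels are non-exclusive (one
event may be exonic, intronic and splicing); each part gets its own burden
test. Splice regions are the first/last `N = 8` intronic bases of each
intron (configurable; there is no community-standard window for repeat
events, and the results of the splicing test should be read with that in
mind). UTRs are derived strand-aware from the CDS span of each BED12
transcript. Conserved base pairs are split into coding (∩ CDS-exon union)
and non-coding; the piecewise interval arithmetic is tested against a
per-base counting oracle. Promoters are not modelled as a gene part;
regulatory context enters only through opaque epigenomic BED tracks
(per-track burden = count of rare TREs overlapping the track).

Region-level enrichment (e.g. of repeat-containing regions in GC-rich or
conserved sequence) uses a base-pair 2×2 contingency table over the
genome, a 0.5 continuity correction when any cell is zero, and a 1-df
chi-square p-value.

## Burden statistics

Burden tests are logistic regressions of case status on a per-sample
aggregate: a count of rare TREs within the target annotation, or a
base-pair total for conserved-sequence burden (odds ratio then per bp).
Covariates: sex; principal components of the depth-normalised anchored
in-repeat-read matrix (counts rescaled by median depth / sample depth; PCs
computed on cases+controls only); and, for target-region tests, the
sample's global intergenic rare-TRE burden, which absorbs residual
genome-wide technical variation and sharpens target specificity. PC
selection keeps components nominally associated (per-PC linear p < 0.05)
with the genome-wide rare-TRE count, with an explicit override accepted.
On synthetic cohorts this rule is conservative: with no technical
structure planted, leading IRR PCs partly reflect the expansions
themselves, so adjusting for them absorbs real signal; the replicate
recovery runs therefore use sex-only covariates (the generator plants no
ancestry or batch structure — depth enters only through IRR
normalisation).

Inference is Wald (estimate ± 1.96 SE on the log-odds scale). Separation —
non-convergence, |β| > 10, or SE > 50 — triggers a Firth-penalised refit
(Newton iteration on the Jeffreys-corrected score
`U*(β) = X'(y − p + h(½ − p))`, `h` the weighted-design leverages),
flagged in the result; gene-set odds ratios in the tens make this fallback
a practical necessity, not an edge case. A singular penalised information
matrix (e.g. a burden carried by a single sample) reports an infinite SE
and p = 1 rather than a spurious interval. Benjamini–Hochberg correction
is applied within declared families (global, CpG strata, gene parts,
epigenomic tracks, gene sets, conserved bp), since corrections are only
meaningful within an analysis family.

Carrier excess: rare-TRE counts are regressed (OLS, pooled over cases and
controls; case status is never a covariate) on the confounders; a sample
is an adjusted carrier when its residual is ≥ 0.5 — at least one excess
expansion beyond its covariate expectation; there is no canonical mapping
from residuals to proportions, so the threshold is explicit and
configurable. Group difference is tested by Wilcoxon rank-sum on the
residuals (exact enumeration for ≤12 tie-free observations, otherwise
normal approximation with tie and continuity corrections; the
approximation is checked against an enumeration oracle to <0.01).

Constraint: one-sided rank-sum with the alternative that genes carrying
rare TREs have lower LOEUF-style scores (more constrained), optionally
restricted to a gene subset before testing.

## Meta-analysis and power

Fixed-effect inverse-variance pooling: `w_i = 1/se_i²`,
`β = Σw_i b_i / Σw_i`, `se = (Σw_i)^(−1/2)`, two-sided normal p. Cochran's
Q and I² are reported but never switch the model to random effects.

The power simulation draws control carriers ~ Binomial(n₀, p₀) and case
carriers ~ Binomial(n₁, p₁) with odds(p₁) = GRR × odds(p₀): the aggregate
frequency parameter is the control-group carrier probability and the
genotypic relative risk acts as an odds ratio on carrier status. Each
replicate is tested two-sided with the unpooled two-proportion Wald z on
the carrier-proportion difference. This statistic was chosen deliberately:
it is the test whose closed-form normal-approximation power the simulation
is validated against, and at the discovery design (1154/934, p₀ = 0.01,
GRR = 4.9, α = 1e-5) it reproduces the expected ≥80% power, whereas a
Wald test on the log-odds-ratio scale has markedly larger variance with
~9 expected control carriers and only ~50% power at the same design. At
small expected carrier counts the simulated power can exceed the
continuous closed form by a few points (binomial discreteness), so the
two are compared loosely there and tightly at large counts.

## Synthetic cohorts

The generator emulates the *output* of a catalog-free repeat profiler, not
reads: per sample × locus, a baseline length from a truncated normal
(mean 60 bp, SD 15 bp, floored at the motif length) and, for planted
carriers, `200 bp + Exponential(scale 100 bp)` — above the 150 bp
read-length detection envelope, so planted events are unambiguous
right-tail outliers at default calling settings. Anchored IRR counts are
Poisson with mean `depth × max(0, length − 150)/150`, giving the
depth-confounded matrix the normalisation and PC machinery operate on.
Carrier status is drawn per locus per sample with group-specific
frequencies; the default control-group frequency is 0.002 per locus —
with ~50 planted loci this yields control carrier proportions of a few
percent, the regime the method targets, and keeps the per-locus risk
ratio ≈ odds ratio so the logistic burden OR is directly comparable to
the generating OR. Planted loci are absent from the panel (rare by
construction) and placed inside transcripts, so the genic test carries the
signal and the intergenic test is null. A few decoy loci are expanded in
all groups at 0.5% so the rarity filter has true-common events to remove;
at ≳1% cohort frequency decoy carriers would be dense enough to form
their own DBSCAN cluster at default settings and never reach the filter,
which is why the decoy frequency sits below the core-point threshold.
Sample sizes default to the emulated discovery design (1154 cases, 934
controls, 2504 panel genomes).

One seed drives deterministically derived sub-streams per stage, so
identical configs are byte-identical regardless of which outputs are
materialised, and the planted truth (loci, carriers, generating OR) is
emitted for recovery tests.

What the synthetic data do **not** contain: ancestry or batch structure
(so PC correction is exercised mechanically, not adversarially), motif
interruptions or zygosity (the profile is a single aggregated length per
sample-locus), locus-specific length distributions, call missingness
correlated with length, and linkage between loci. Passing recovery tests
therefore demonstrates the statistical machinery is calibrated and
unbiased under the stated generative model — not robustness to real-data
artefacts.

## Problem sizes and replication settings

Replicate-based checks use 1000 cases / 1000 controls / 500 panel genomes
with 2000 loci and 50 planted expansion loci: 50 replicates per generating
OR ∈ {2, 5} for CI coverage, 200 null replicates for type-I control, and
10,000 Monte Carlo replicates for power — sizes at which the Monte Carlo
error of each reported rate is a small fraction of the margin being
checked. Sensitivity/false-positive characteristics are measured over 100
seeds at default generator settings with the locus count reduced to 120
(both are per-locus properties, so cohort size and carrier frequencies
stay at their defaults).

## Known limitations

- The expansion caller assigns at most one call per locus-motif and does
  not size genotypes, resolve zygosity, or handle motif interruptions.
- Rarity is carrier-based, not allele-count-based.
- No kinship or mixed-model correction; samples are assumed unrelated.
- Coordinates are taken as-is (one reference build; no liftover).
- The residual-threshold mapping from adjusted counts to carrier
  proportions is a reporting convention; different thresholds move the
  proportions (not the rank-sum p-value).
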