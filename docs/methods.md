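# Methods

## Dyad model and the RCP statistic

A CpG dyad is the pair of cytosines at one CpG position on the two strands
of a double-stranded molecule; its state is M (both methylated), U (both
unmethylated) or H (hemimethylated).  Writing f_M, f_U, f_H for the state
fractions and m = f_M + f_H/2 for the single-strand methylation level, the
Ratio of Concordance Preference is

    RCP = f_M f_U / (f_H/2)^2 = f_U (f_U + 2m − 1) / (1 − f_U − m)^2

The two forms are linked by the identities f_M = f_U + 2m − 1 and
f_H/2 = 1 − f_U − m.  Under independent placement of methyl groups on both
strands at level m, f_M = m², f_U = (1−m)², f_H = 2m(1−m) and RCP = 1; the
statistic is scale-invariant in the counts and anchored at 0 (complete
discordance) and ∞ (complete concordance).  A square-root variant
√(f_M f_U)/(f_H/2), a monotone transform with the same anchors, is
available as `variant="sqrt"`; all group-difference signs are invariant to
the choice.

Boundary conventions: counts with f_H = 0 return +∞, including the
degenerate all-M / all-U case where the formula is 0/0 — no discordant
evidence has been observed, and treating such replicates uniformly as
infinitely concordant lets the bootstrap detect and redraw undefined
∞ − ∞ differences rather than silently mixing conventions.  f_M = 0 or
f_U = 0 with f_H > 0 returns 0.  All-zero counts are an error.

### Solving for a target RCP

The generator inverts the statistic: given (m, target RCP = r) it solves
p_M + p_U + p_H = 1, p_M + p_H/2 = m and p_M p_U = r (p_H/2)², i.e. the
quadratic (1 − r) h² − h + m(1 − m) = 0 in h = p_H/2, taking the root in
[0, min(m, 1 − m)].  Every r ∈ [0, ∞] is feasible for m ∈ (0, 1); at
m ∈ {0, 1} only the degenerate targets 0 and ∞ are accepted.

## Conversion-error channel and its inversion

Bisulfite conversion misreads strands in two directions: an unmethylated C
escapes conversion with probability f (default 0.0039, estimated from the
linker's known-unmethylated cytosines) and a methylated C converts anyway
with probability q (default 0.017).  Treating strand errors as independent
gives a 3×3 column-stochastic matrix T from true to observed dyad
fractions, e.g. a true H dyad is observed M with probability f(1−q).
Correction solves T x = observed fractions exactly (the matrix is
well-conditioned for rates below 0.5), clips negative components to zero,
renormalises, and rescales to the observed total.  Tests check the
inversion against an independently written scalar forward channel to
1e−9.

## Hierarchical bootstrap

Group RCP distributions come from B = 20,000 bootstrap replicates (CLI
default; smaller B is used in tests and the demo for speed).  In each
replicate, individuals are resampled with replacement within each group;
within each sampled individual, molecules are resampled with replacement;
each individual's dyad counts are then rescaled to a common per-individual
total — the mean observed total for the group, with fractional counts
carried — so that every individual contributes equal weight; the rescaled
counts are summed, corrected for conversion errors, and turned into an
RCP.  The replicate difference is RCP(first group) − RCP(second group).

One-tailed p = the proportion of difference samples at or left of zero
(zeros count as left, the conservative direction); two-tailed p = twice the
smaller tail proportion, capped at 1.  Replicates in which a group has no
informative dyads, or both groups are infinitely concordant (∞ − ∞), are
redrawn and counted in the report; no pseudocount is applied by default,
with an optional Haldane-style +0.5 per state behind `pseudocount`.

Site-to-site correlation within a molecule does not bias the point
estimate (each dyad enters the counts independently) but does inflate
variance; resampling whole molecules inside individuals propagates exactly
that correlation into the bootstrap distribution.

## Read model and reconstruction

The synthetic read is top arm + linker + bottom strand read 5'→3'.
Reversing the right arm aligns it base-for-base under the top arm (the
"G-C" / "G-T" patterns used in dyad calling); reverse-complementing it
expresses the bottom strand in top coordinates, where the only legitimate
arm disagreements are top T vs bottom-complement C (converted top C) and
top G vs bottom-complement A (converted bottom C).  Strand realignment is
a global pairwise alignment under an asymmetric substitution matrix that
scores exactly those two ordered pairs as matches (match +1, mismatch −1,
gap open −3, extend −1), absorbing 1–2 nt PCR-slippage indels as gaps.
Dyad calling is reference-anchored: the top arm is aligned to the amplicon
reference with C→T tolerance, and each reference CpG is read off as the
(top C-position base, bottom G-position base) pair; gaps or unexpected
bases give the ambiguous state '.', which never enters counts.

Linker location uses infix edit-distance search with C≈T equivalences and
N wildcards over the UMI slot.  The edit budget (default 2) was fixed from
fixtures: 0/1,000 random 150-mers match at ≤2 edits while 1–2 nt slippage
inside the linker is still tolerated; at ≥4 edits random matches appear.
The chimera threshold (arm identity 0.8) separates the shuffled-arm
identity distribution (max ≈ 0.75 over fixtures) from genuine arms
(identity ≈ 1).  UMI duplicates collapse by per-site majority vote, ties
to ambiguous; conversion-control tallies (linker C positions retained vs
converted) are summed over duplicates.

Internal coordinates are 0-based half-open throughout; genomic positions
in reports are 1-based.

## Synthetic-data defaults and what they emulate

Defaults mirror the dyad-level study design the package targets: 6
individuals per group, 50 molecules per individual, 5 CpG dyads per
molecule (an ~100 bp amplicon; 8-dyad designs are a parameter away),
m = 0.5, conversion error rates 0.0039 / 0.017, and a constant-quality
FASTQ representation.  Dyads are drawn i.i.d. across sites within a
molecule, and hemimethylation lands on either strand with probability 1/2
(the statistic collapses the two orientations).  UMIs are drawn from
{A, G, T}: a cytosine in the barcode would be rewritten by conversion and
break molecule identity, so conversion-insensitive barcodes are used.  The
bundled linker is a fixture (two 10 nt arms around an 8 nt UMI slot), not
a published sequence.

Not emulated: PCR amplification bias, substitution sequencing errors,
within-molecule site correlation, restriction-site context, or primer
effects.  Passing round-trip tests therefore demonstrates correctness of
the reconstruction and inference machinery under the modelled error
channels, not performance on arbitrary real libraries.

The beta-matrix generator inverts the clock exactly: each sample's target
epigenetic age (chronological + group offset + Gaussian noise) is mapped
through the calibration transform and spread over the clock probes along
the coefficient vector (minimum-norm perturbation around beta 0.5),
erroring out rather than clipping if a beta would leave [0, 1].  The
bundled synthetic clock uses ten alternating ±1 coefficients (zero-sum, so
the score is a pure contrast) and intercept 0.

## Clock stage

A clock is any (coefficients, intercept, transform) triple loaded from a
CSV + JSON header.  The piecewise calibration about adult age A maps
age ≤ A to log((1+age)/(1+A)) and age > A to (age−A)/(1+A); its inverse is
applied after the linear score.  Missing clock probes: over 5% is an
error; at most 5% are imputed with the per-sample mean of available clock
probes (a warning is raised — with no access to training data, the
per-sample mean is the only neutral fill).  AgeAccel residuals come from a
pooled OLS of epigenetic on chronological age (per-group fits are not the
default: the residual definition is group-blind).  Group comparison uses
Welch's t-test by default (`equal_var=True` recovers Student's).  The
regression comparison is sequential: the group×age interaction tests slope
equality; the group main effect in the common-slope model tests intercept
equality.  The 2-CpG cell-fraction model is a clipped linear predictor
with user-supplied coefficients.

Raw beta values are consumed as given; no array normalisation or
training-data calibration is applied, so epigenetic ages from public
array data will differ from calculator pipelines that renormalise input
betas — comparisons of groups run through the same path remain valid.

## Determinism

Every stochastic stage takes an explicit seed.  The CLI derives per-stage
seeds from the global seed as crc32(stage name) XOR seed mod 2³¹, recorded
in the run manifest together with parameter values and output checksums;
reruns are byte-identical.

## Problem sizes

The test suite and demo run at reduced sizes chosen to keep the
statistical assertions well-powered: bootstrap B = 200–2,000 in tests
(20,000 remains the CLI default), 100,000 dyads for distribution-level
checks (3-binomial-SD bands), 20 independent pipeline runs for the power
check at 6 individuals × 50 molecules per group, and 300 simulations for
regression-test calibration.
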