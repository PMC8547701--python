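# Methods

## Problem and scope

Transposable-element (TE) copies accumulate in a host genome and are slowly
degraded, silenced and deleted.  Treating the estimated insertion age of each
extant copy as a survival time, this package models how attributes of the
copy (taxonomy, length, base composition, coding capacity, methylation,
expression) and of its genomic neighborhood (distance to genes,
recombination, chromatin accessibility, nucleotide diversity, subgenome)
predict survival — the "genomic niche" of each TE family.  The package
covers everything downstream of a structural TE annotation: it does not
discover TEs, cluster families, align sequences or build trees; annotations,
paired-LTR alignments, per-superfamily trees, count tables and browser-style
interval layers are its input boundary.

## Nesting resolution

TEs insert into one another, so intervals overlap.  Every annotated base is
assigned to exactly one copy — the latest-arriving copy covering it — by
painting copies over the chromosome in arrival order.  Arrival order is
operationalized from nesting topology: an inserted element arrived after its
host.  Copies that overlap without an explicit nesting link are ordered by
containment (the contained copy arrived later); a partial overlap with no
link is refused as unresolvable annotation noise rather than guessed at.
A copy left with fewer than `min_surviving_bp` (default 50) of its own bases
is flagged `dropped`: excluded from all feature tables and the model, but
retained in conservation accounting so that owned bp over all copies always
sums to the annotation's base coverage.  Both the surviving length
(`length_bp`) and the original span including nested insertions (`span_bp`)
are exposed and used as model features, since either can be read as "the
length of the TE".

## Age estimation

*LTR–LTR*: the two LTRs of an LTR retrotransposon are identical at
insertion.  Their Kimura two-parameter distance, computed with pairwise
deletion of gap/N columns, is `d = -½·ln((1−2P−Q)·√(1−2Q))` with transition
proportion P and transversion proportion Q.  Saturated pairs (non-positive
log argument) are reported and excluded rather than clamped.

*Terminal branch length*: each copy's leaf branch in its superfamily tree,
in substitutions/site, measures divergence from its closest relative in the
genome, and is the only per-copy age available for TIR elements and
Helitrons.

Conversion to years uses `T = d/(2μ)` for LTR–LTR (both LTRs mutate
independently after insertion) and `T = b/μ` for terminal branches, with
`μ = 3.3e-8` substitutions·site⁻¹·year⁻¹ (maize point-mutation rate) as the
default.  The divisor convention is a documented choice, configurable via
the `method` argument; raw divergences are always emitted alongside ages.
A helper trims sequences to 1000 bp for tree building (3′ terminus for
Helitrons, 5′ for LTR and TIR elements), mirroring how large superfamily
trees are made computationally tractable.

## Base composition

Methylatable cytosine contexts (CG, CHG, CHH; H ∈ {A, C, T}) are counted on
both strands — a forward scan of the sequence and of its reverse
complement — and divided by sequence length, so a palindromic CG counts once
per strand and densities lie in [0, 2].  Context windows containing N, or
truncated by a sequence end, are skipped.  The TG/CA proportion (overlapping
dinucleotides equal to TG or CA, divided by length−1) tracks historic
deamination of methylated CG sites; across families simulated with varying
deamination it is negatively correlated with CG-context density, as
expected.  For a disrupted copy, composition is computed over its owned
segments with counts accumulated per segment, so no window spans a segment
junction; the two 1 kb flanks are pooled the same way (weighted counting,
never concatenation).

## Genomic context

Distance to the closest gene ignores strand and uses half-open gap distance
(adjacent intervals are at distance 0; any overlap is 0 and sets
`within_transcript`).  Ties are broken by smaller gene start, then
lexicographic id.  The closest *syntenic* gene restricts the search to a
supplied id set.  A chromosome with no genes yields missing distances, never
zero.

The genetic map is fitted per chromosome with a least-squares polynomial
(degree 7 by default) whose derivative is constrained non-negative on a
dense grid (SLSQP); the fit is then verified on a 4096-point grid, and any
residual wiggle — or too few points — triggers a monotone piecewise-linear
fallback with a warning.  Positions are rescaled to [0, 1] before fitting
for conditioning.  Extrapolation clamps to the boundary cM values and is
flagged.  A TE's recombination rate is (f(end) − f(start)) divided by its
length in Mb.

MNase hypersensitivity, segregating-site density and subgenome assignment
are plain interval operations (count, clipped-overlap proportion, maximal
bp overlap with ties going to "none"); flank metrics pool both 1 kb sides
into a single value, matching the one-value-per-copy convention of the
feature table.

## Methylation profiles

Per-cytosine calls are aggregated into genome-anchored 100 bp bins per
context and tissue.  Each copy gets a 41-slot profile per (tissue, context):
the body mean over its owned segments plus 20 flanking 100 bp windows per
side anchored at the span boundaries, walking outward and clipped only at
chromosome ends (flank windows may cross neighboring TEs on purpose — the
flank is the actual genomic neighborhood).  The body mean weights windows by
their covered cytosine counts, so for grid-aligned regions it equals the
per-cytosine mean exactly; an unweighted mode would weight each window
equally regardless of cytosine content and is deliberately not the default.
Missing cells (no covered cytosines, or flanks off the chromosome end) are
imputed with the family mean of the same (tissue, context, slot), falling
back to the superfamily and then the global slot mean, with per-cell flags;
imputation never alters observed cells and preserves observed family means
exactly.

## Expression

Family counts (unique plus family-assigned multi-mapped reads) are converted
per replicate to reads per million of the library, averaged over replicates
per tissue, and divided by family size to give a per-copy RPM; families
composed of genic copies can be excluded, since their signal is
indistinguishable from host-gene transcription.  Median across tissues and
the tissue-specificity index `τ = Σᵢ(1 − xᵢ/x_max)/(n−1)` summarize each
entity; genes (already-normalized atlas values) flow through the identical
code path.  An all-zero vector yields a missing τ (coded −1 by the model
stage) rather than 0, since specificity is undefined without expression.
Library size means total mapped reads; it is an input column, so any other
definition can be supplied.

## Survival model

`TEAgeModel` assembles per-stage feature frames (each labeled with one of
nine categories: TE taxonomy / base composition / methylation & chromatin /
expression / encoded proteins, nearest-gene expression, regional base
composition, regional methylation & chromatin, regional recombination &
selection) into a single numeric matrix: missing cells coded −1,
superfamily and family integer-coded, family capped at the 31 largest
(ties by id) plus a pooled "smaller" level.  `fit()` trains a regression
forest — 1000 trees by default, `max_features = 1/3` per split (the
regression-forest convention) — on a uniform random 50% of copies and
returns a `TEAgeResults` carrying held-out MSE and variance explained.

Interpretation is computed on the held-out half for honesty:

- **Permutation importance**: each feature's column is shuffled (20 repeats
  by default), and the mean ΔMSE, its sd over repeats, the scaled importance
  (mean/sd) and the RMSE increase in kya are reported; zero-variance
  features get importance 0 with a flag.  Category importance is the sum of
  member features' mean ΔMSE, so categories sum to the total by
  construction.
- **Family correlations**: Pearson r of each feature with age within each
  family; features fixed within a family yield missing cells.
- **ICE curves**: for a grid of `n_grid` values spanning the central 95% of
  a feature's observed values, each copy's prediction with the feature
  substituted, reported as deviation from the copy's observed age, with
  superfamily-mean curves.  `ICEResult.slope()` estimates the marginal
  effect by least squares over the central half of the grid, because forest
  predictions flatten at the edges of the training support.

## Synthetic data

The generator emulates the study conditions at desk scale: 3 chromosomes of
250 kb, all 13 superfamilies with 2 families each, family sizes from a
truncated zipf (a = 1.8, max 20, minimum 2 — heavy-tailed like real family
size distributions), nesting probability 0.2 with a guaranteed chain of
depth ≥ 3, per-family mean ages lognormal around 180 ky with per-copy gamma
draws clipped at 1.2 My.  Copies are placed oldest-first (so any host is
older than its guest), sequences diverge from a family ancestor by
Binomial(L, μT) substitutions at distinct sites with ts:tv = 2:1 — exactly
the K2P model, making K2P recovery a true oracle test.  LTR elements carry
two identical LTRs in the ancestor, so pair divergence has expectation 2μT;
star trees carry terminal branches μT exactly.  Methylation windows are
binomial draws around family-level levels (CG ≈ 0.85, CHG ≈ 0.70,
CHH ≈ 0.08 in TEs; low background), with 5% of windows dropped to exercise
imputation; expression is negative-binomial with a "silenced" indicator for
large families; the genetic map is a normalized cumulative-gamma curve
(≈1.5 cM/Mb); domain hits decay with age via exp(−T/600 ky).

What the toy does *not* emulate: realistic karyotype or sequence
composition, indels and tandem repeats (alignments are gap-free, so the
pairwise-deletion path is exercised only by unit fixtures), solo-LTR
formation and deletion bias, read-level noise, population structure in the
variant layer, or feature-driven ages in the genome simulation (copy ages
are family-driven there; feature-driven ages with known effect shapes are
provided by the separate `generate_age_features` harness).  Passing tests
therefore demonstrate correctness of the computations and recoverability of
known signals, not biological realism of any particular estimate.

## Numerical choices and problem sizes

All internal coordinates are 0-based half-open; GFF3 is converted on read
and emitted 1-based inclusive, BED half-open, per their standards.  Every
random process takes an explicit seed (numpy Generator); dataset generation
and the full pipeline are byte-identical across reruns with the same seed.
Test and acceptance problem sizes are chosen for quick desk-scale runs: the
recovery harness uses n = 5000 copies, 3 causal + 47 decoy features, noise
sd 50 ky, 100-tree forests with 3 permutation repeats over 20 seeds; the
end-to-end check runs the full toy genome with 200 trees.  The oracle checks
(per-base nesting sweep, per-cytosine methylation means, closed-form K2P,
analytic map derivatives) are exact up to floating-point tolerance.

## Known limitations

Terminal-branch ages in the pipeline are read from input trees, not
re-inferred; with star-tree toy input they are exact, while real trees carry
alignment and inference error the package does not model.  The monotone
polynomial can legitimately fail on step-like maps and falls back to
piecewise-linear interpolation, which interpolates the data exactly but has
a discontinuous derivative.  Permutation importance on correlated features
shares credit in the usual way; no conditional-importance variant is
provided.  ICE curves are computed for numeric features only; categorical
level substitution is out of scope.
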