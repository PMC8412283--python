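# Methods

## The binding-affinity model

A bipartite RNA-binding-protein element consists of a left half-site, a
spacer of variable length whose bases are not read out, and a right
half-site.  The default element is the MEX-3 recognition element (MRE)
`(A/G/U)(G/U)AG N{0-8} U(U/A/C)UA`: four recognised positions per
half-site, spacer 0–8 nt.  For a fixed spacer length there are exactly
3·2·1·1 · 1·3·1·1 = 18 distinct perfect half-site combinations, a number the
test suite confirms by exhaustive enumeration of all 4⁸ octamers.

Site scoring assumes each recognised nucleotide contributes independently:
a penalty matrix assigns every (position, base) pair a free-energy penalty
ΔΔG°(i, b) ≥ 0 relative to the best-bound base at that position, and a
candidate site's total ΔΔG° is the sum over its recognised positions
(spacer bases contribute nothing).  The relative dissociation constant and
the reported affinity follow the Boltzmann relation

    K_rel = exp(ΔΔG° / RT),        affinity = 1/K_rel = exp(−ΔΔG° / RT).

ΔΔG° = 0 gives affinity 1 (binding equivalent to the best-bound control);
affinity decays toward 0 as penalties accumulate.  Note this is the
standard thermodynamic relation ΔΔG° = RT·ln(K_rel) solved for K_rel; the
direction is fixed by its endpoints (a perfect site must score 1, a heavily
mutated site near 0).

**Energy units.**  RT defaults to 1, making ΔΔG° dimensionless "RT units".
If a matrix in kcal/mol is supplied, set RT = 0.593 kcal/mol (25 °C).

**The default matrix.**  Experimentally derived penalty matrices for MEX-3
are not generally available, so the shipped default is consensus-derived:
allowed bases score 0 and disallowed bases score a flat `default_penalty`
(1.0 RT).  Under this matrix ΔΔG counts mismatches.  Arbitrary matrices
load from TSV (`position_index, A, C, G, U`); each row must be finite,
non-negative, and contain at least one zero.

**Scanning.**  Every start × admissible spacer combination is scored; per
start only the minimum-ΔΔG candidate is reported, with ties broken toward
the shortest spacer (smallest footprint; a `longest_spacer` tie rule is
selectable).  Sites with ΔΔG above `max_ddg` (default 3·RT, i.e. affinity
below exp(−3) ≈ 0.05, boundary inclusive) are suppressed.  The per-position
affinity track ("wiggle" profile) places each reported site's affinity at
its start coordinate by default; a `footprint` rule that paints the whole
site extent is available.  Catalog counting (`count_catalog_matches`) is a
different operation: it reports *all* perfect degenerate matches of each
catalog motif, overlaps and all spacer alternatives included, with no
per-start reduction — this is what deletion deltas are computed from.

## Deletion alleles

Deletions are named 1-based inclusive intervals; length = end − start + 1.
This convention is dictated by the allele arithmetic it must reproduce
(328–517 → 190 bp, 28–515 → 488 bp).  A catalog match overlapping the
deleted interval at all is classified *removed* — a match merely straddling
a boundary loses recognised bases and cannot survive.  Matches wholly
upstream keep their coordinates; matches wholly downstream shift left by
the deletion length.  The mutant sequence is then rescanned: matches not
present in the coordinate-remapped retained set arose across the new
junction and are reported as *junction-gained*, separately from retained
counts.  The invariant (retained ∪ junction-gained) = fresh mutant scan is
enforced by test on random UTR/allele/catalog triples.

## Germline profile statistics

Line profiles carry one intensity per axial pixel, distal tip → last
oocyte.  Binning partitions the pixels into `n_bins` contiguous runs whose
sizes differ by at most one; the leading `n_pixels mod n_bins` bins absorb
the remainder (deterministic and order-preserving; any remainder rule is
defensible, this one is fixed and documented).  20 bins is the default
(endogenous-reporter experiments); transgene experiments use 10.

Two-condition comparisons use a per-bin two-sample two-tailed
*pooled-variance* Student t-test (the named test; Welch is deliberately not
substituted).  Shared-control multi-condition comparisons run, per bin, a
one-way ANOVA across all conditions for overall significance, then
Fisher's LSD for each treated condition against the control — a t statistic
whose standard error uses the ANOVA pooled within-group mean square with
N−k degrees of freedom — followed by a Bonferroni adjustment that
multiplies each p-value by the hypothesis count m and caps at 1.  m
defaults to (treated conditions) × n_bins and is configurable; supplying a
smaller m triggers a warning rather than an error.  The ANOVA is run per
bin (the alternative — one global ANOVA across bins — would conflate axial
position with treatment).  With exactly two groups the LSD p-value equals
the pooled t-test p-value; the suite checks this identity numerically.

Zero-variance degenerate bins use a fixed convention: p = 1 when group
means agree, p = 0 when they differ, so identical data can never be called
significant.  Significance is adjusted p ≤ 0.05 throughout.  All p-values
are invariant under rescaling of the intensity axis (checked by test).

The nuclear/cytoplasmic statistic averages each animal's two proximal-
oocyte nuclear/cytoplasmic mean-intensity ratios, then compares groups of
per-animal ratios with the same pooled t-test.

## Fecundity and DE filtering

Brood counts are pooled across biological replicates (labels retained).
Mann–Whitney U is exact when n·m ≤ 400 and the pooled counts are tie-free,
otherwise the tie-corrected normal approximation is used; the two-sample KS
test uses the exact small-sample computation where SciPy provides it and
the asymptotic distribution otherwise.  The exact MW branch is validated
against full permutation enumeration, and the KS D statistic against a
brute-force ECDF supremum.

The DE filter applies the strict inequalities |log2FC| > 0.585 and
FDR < 0.05 — boundary rows are excluded, as the suite checks explicitly.
Upstream model fitting (dispersion, shrinkage) is out of scope; the filter
consumes any table with `gene_id, log2fc, fdr`.  Set overlap between two
experiments intersects up-sets and down-sets separately; sign-discordant
genes are flagged and never counted as shared.

## Synthetic data: what it emulates, what it does not

*UTRs* (`synth_utr`): i.i.d. background with configurable composition
(default uniform), default length 689 nt to match the motivating UTR.
Planted sites are written at fixed coordinates; rejection resampling
regenerates the whole sequence until the only perfect consensus matches
are the planted ones, making the ground truth exact.  With uniform
composition a 689-nt sequence contains ≈ 1.7 accidental perfect MREs in
expectation (per-start chance 18/4⁸ per spacer), so rejection succeeds
within the default 200 attempts at these lengths; far longer sequences can
exhaust the bound and raise a capacity error rather than silently emit
dirty truth.  Real 3'UTRs are A/U-rich and have composition structure the
generator does not model.

*Profiles* (`synth_profiles`): a three-segment piecewise-linear axial
baseline — distal-high (100 a.u.), pachytene-low (20 a.u. at 35% of the
axis), rising through the loop to the proximal oocytes (120 a.u.) — the
minimal shape with the qualitative distal-high/mid-low/proximal-rising
pattern of germline reporters.  Pixel noise is additive i.i.d. Gaussian
(sd 10 a.u., clipped at 0), 400 pixels, 15 animals per condition.
De-repression is an additive shift of `effect_size × noise_sd` on every
pixel of the chosen bins, using exactly the analysis bin geometry.  Real
profiles have correlated pixel noise, animal-to-animal amplitude variation
and axial length differences; a green recovery test therefore establishes
correctness of the testing chain under its nominal model, not robustness
to those artefacts.

*Broods* (`synth_broods`): negative-binomial counts (mean 250, size 10 —
an overdispersed spread typical of wild-type brood assays, SD ≈ 81), with
the treated mean shifted down.  Counts are discrete, so exact two-sample
test p-values are mildly conservative under the null; the calibration
check uses coarse bounds rather than asserting perfect uniformity.

All generators are pure functions of their spec including the seed, and
truth is emitted as machine-readable JSON alongside the data files.

## Statistical-calibration checks: design notes

The type-I error check runs 500 simulated null experiments × 20 bins
= 10,000 per-bin t-tests through the production code path (binning
included) and requires a rejection rate of 0.05 ± 0.01 at nominal 0.05.
The effect-recovery check plants a 3×-noise-SD shift in bins 8–12
(n = 15/group, 500 runs) and requires every effect bin flagged in ≥ 95% of
runs with ≤ 1 false-positive bin per run on average; note that at a 0.05
per-bin rate over 15 null bins, ~0.75 false positives per run are expected
by design, so complete absence of false positives is not a meaningful
requirement.

## Known limitations

- Positional independence is assumed; cooperative or multivalent binding
  (e.g. OMA-1 cluster effects) and RNA secondary structure are not
  modelled.
- The consensus-derived default matrix collapses all mismatches to one
  penalty; quantitative K_rel values are only as good as the matrix
  supplied.
- Junction-gained sites are detected but deliberately excluded from
  retained counts.
- Polyadenylation-site information is carried as an annotation only.
- The exact GLD-1 (GBM) and LIN-41 (LBM) motif definitions vary across the
  literature; catalogs are therefore user-supplied configuration, and no
  fixed GBM count is asserted anywhere.
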