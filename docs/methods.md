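# Methods

## Marker model and the ten-pattern classification

A marker is one TE insertion locus scored present/absent/unknown in each
lineage of a panel: four ingroup lineages (default Primates, Dermoptera,
Scandentia, Glires), an optional annotation lineage (Lagomorpha) kept out
of the four-lineage statistics, and one or more outgroup lineages.
Markers are treated as single-copy, homoplasy-free characters: no parallel
insertion and no precise excision.  A marker enters the statistics when at
least two ingroup lineages show presence and at least one shows absence;
its diagnostic pattern is then its ingroup presence set, necessarily one
of ten (six pairs, four triples).  A marker whose known states pass this
pre-filter but that carries an unknown ingroup state has an undetermined
presence set: it is counted separately as "partially informative" and used
only for gene-tree export, never in the ten-pattern table.  This keeps the
tabulated counts exact while still extracting quartet signal from
incomplete rows.

### The y-vector ordering

Count vectors are exchanged in a fixed "y-vector" order indexed by the
upper triangle of a 4x4 matrix (y11, y12, y13, y14, y22, y23, y24, y33,
y34, y44): off-diagonal y_ij is the pattern in which lineages i and j are
*absent* (presence = the complementary pair), diagonal y_ii the pattern in
which only lineage i is absent (presence = the complementary triple), with
lineage order (Primates, Dermoptera, Scandentia, Glires).  For the bundled
Euarchontoglires vector `16,12,9,9,16,5,13,55,132,94` this places 132 on
Primates+Dermoptera, 94 on Primates+Dermoptera+Scandentia, and 9 on
Dermoptera+Scandentia, consistent with every anchored tally; the ordering
is nevertheless configurable (`PatternCounts.pattern_order`) because the
assignment of the remaining conflict values to patterns is conventional,
and every statistic in the package that touches the headline conclusions
is insensitive to it (verified by test).

### The worked-example fixture

`example_matrix()` realizes the bundled tally as an explicit 361-marker
matrix: markers grouped by pattern, outgroup always absent, and lagomorph
annotation states arranged so that 299 are known of which 289 equal the
rodent state.  The arrangement (concordant first, then conflicting, then
unknown) is an arbitrary deterministic choice; only the tallies are data.

## Locus diagnostics

State calling works on per-locus alignments with the TE span annotated in
alignment columns (0-based, half-open; 1-based inclusive only at the
RepeatMasker boundary, where orientation `C` maps to strand `-` and the
parenthesized consensus remainder is read as the 3' truncation).

- **present**: at least 80% of TE-span columns carry A/C/G/T (the default
  `coverage_threshold = 0.8` tolerates small internal indels in real
  rows while rejecting fragments).
- **absent**: the span is a contiguous gap; the gap boundaries sit within
  3 nt of the annotated span, measured in ungapped consensus coordinates
  so alignment padding cannot inflate shifts; and both flanks remain
  alignable (>= 20 aligned bases at >= 60% identity to the column-majority
  consensus within 30 columns of the gap).  The flank requirement
  distinguishes true absence from a deletion spanning the region, which is
  deliberately called unknown.
- **unknown**: everything else (N-runs, partial rows, out-of-band shifts).

Because integration duplicates the target site, a taxon lacking the
element retains a single target-site copy and its gap is one TSD longer
than the annotated element.  Gap-boundary overhangs are therefore checked
against the mirrored columns on the other side of the element (the
retained copy); an overhang matching at >= 75% identity with at least half
its positions aligned is the TSD alignment ambiguity, not a shift.  A
planted boundary shift, by contrast, truncates the retained copy and is
counted in full — shifts of 4 nt and above can never be called absent.

TSD detection compares, for lengths 25 down to 4, the ungapped sequence
ending at the TE start with the sequence beginning at the TE end, and
accepts the longest pair with at most one mismatch (all three bounds
configurable; the range covers typical LTR and LINE1 TSD lengths).

Acceptance of a locus requires all four criteria (boundary agreement,
shared family, shared orientation, outgroup absence with at least one
known-absent outgroup taxon) plus the presence/absence pre-filter.

## The coalescent insertion model

The simulator runs the multispecies coalescent on the species tree
`(((a,b):tau1, c):tau2, d):root_stem` (coalescent units; one haploid
lineage per species).  Within each ancestral population, k lineages
coalesce at rate k(k-1)/2; survivors pass upward.  A marker is one
insertion placed uniformly at random on the gene-tree branch segments
lying inside the three ancestral populations (cherry stem, triple stem,
root stem), optionally reweighted per species-tree branch
(`branch_weights`, default uniform — no rate information is available to
prefer anything else).  Insertions above the root stem would be shared
with the outgroup and are therefore outside the insertable region;
insertions whose descendant set has fewer than two or all four lineages
fail the diagnostic pre-filter and are rejected and redrawn, which also
removes all terminal-branch (species-specific) insertions.  The only
noise channel is `missing_rate`, which masks states to unknown.

`pattern_probs` is the matching probability engine: the Rao-Blackwellized
form of the same draw (the per-replicate weighted length *fraction* per
descendant set, averaged over Monte-Carlo gene trees, then conditioned on
the ten informative patterns).  Both routines consume the identical
segment bookkeeping, and a property test checks that 50,000 sampled
markers match the probability engine within three standard errors.

What the simulator does not emulate: nucleotide substitution beyond
i.i.d. flank noise in planted loci, population-size variation along
branches, hybridization/introgression, precise excision, and parallel
insertion.  Green tests therefore certify the statistical machinery under
clean ILS, not robustness to those processes in real data.

## Statistics

**Three-lineage test.**  For triplet counts (n1 supporting the candidate
clade, n2 and n3 the alternatives), the tree-versus-polytomy p-value is
the exact binomial tail `P(X >= n1)` with `X ~ Binomial(n1+n2+n3, 1/3)`
(a hard polytomy makes the three resolutions equiprobable), computed via
`scipy.stats.binom` and cross-checked against a rational brute-force sum.
The hybridization screen is the exact two-sided binomial test of n2
against n3 at p = 1/2 (pure ILS is symmetric in the two conflict classes).

**Four-lineage test.**  The ten counts are modeled as a multinomial whose
cell probabilities come from `pattern_probs`.  For each of the fifteen
rooted topologies (twelve caterpillar, three balanced), the log-likelihood
is maximized over (tau1, tau2) on a precomputed probability grid (tau from
0 to 5, spacing 0.05 near zero widening to 0.5; root stem fixed at 1.0)
followed by Powell refinement on the bilinearly interpolated surface.
Monte-Carlo surfaces use 100,000 replicates per grid cell with a fixed
seed and common random numbers across cells; this size was set so that
surface noise is negligible relative to the likelihood-ratio statistic
(smaller surfaces visibly inflate the test, larger ones only cost time —
the suite verifies calibration directly).  The polytomy null refits the
winning topology with its cherry stem pinned to zero (tau1 = 0, tau2
profiled).  Because tau1 = 0 lies on the boundary of the parameter space,
the LRT null is the 50:50 mixture of a point mass at zero and
chi-square(1); and because a polytomy admits three competing resolutions
of the tested node, the mixture p-value is additionally Bonferroni
-corrected by a factor of three.  Without that correction the
topology-selection step makes the test anti-conservative (empirically
roughly three times the nominal size, as expected for three nearly
disjoint one-sided rejection events); with it, simulated size at
alpha = 0.05 is within +/- 0.02 of nominal (property test, 2000 null
replicates).  Hybridization is screened by two-sided binomial tests
between every pattern pair related by swapping the leaves of a cherry of
the winning topology, Holm-corrected (few, correlated tests).

**Branch lengths.**  The internal branch above a resolved triplet is
estimated by inverting the gene-tree discordance law
`(n2+n3)/N = (2/3) e^(-tau)`, truncated below at 0 and capped at 10
coalescent units when no conflicting markers are observed (the point
estimate diverges; 10 units corresponds to a discordance expectation
below 10^-4, i.e. indistinguishable from zero conflict at these sample
sizes).  The estimator is consistent for markers that tag the internal
segment of their gene tree (one marker per gene tree), which is how the
recovery test draws them; applied to length-weighted insertion counts it
is a first-order summary, which is how it is used for display on the
species tree, pair branches from the three within-triple pair patterns
and the triple branch from (triple, other triple containing the pair,
complementary pair).

## Tree inference

Each usable marker (>= 2 known presences) becomes a Newick gene tree with
the presence set as its only resolved clade and the other known-state
taxa at the root polytomy; unknown-state taxa are omitted.  For up to six
taxa all unrooted binary topologies are enumerated and scored by the
number of (gene tree, four-taxon subset) pairs whose induced resolved
quartet matches — the same objective a heuristic quartet species-tree
program maximizes at scale, solved here exactly, which keeps the pipeline
dependency-free at desk scale.  The tree is rooted on the declared
outgroup; the annotation lineage is excluded by default and joins only on
request, constrained solely by its marker states.  Ties are broken
lexicographically on the rooted Newick string and reported loudly, since
silent ties would corrupt bootstrap tallies.  The bootstrap resamples
markers with replacement (multinomially over marker classes), rebuilds
the winner per replicate, and reports per-clade recovery percentages;
it is bit-reproducible for a fixed seed.

## Numerical and interface choices

- All randomness flows from explicit integer seeds; derived seeds stay
  below 2^31.
- NEXUS output is a DATA block (datatype standard, symbols "01",
  missing ?) so external network/Bayesian tools can consume it; NEXUS
  input goes through dendropy.  PHYLIP follows a relaxed dialect
  (whitespace-delimited names of any length) because strict 10-character
  names are impractical for modern matrices.
- Matrix files carry no panel metadata, so readers assume the study
  layout: four ingroup lineages first, an annotation lineage fifth when
  six taxa are present, outgroup last; callers can always pass an
  explicit panel.
- Degenerate inputs fail loudly: empty matrices cannot be written, empty
  triplets and all-zero count vectors are rejected, a species tree with
  zero insertable branch length is an error.
- Problem sizes used by the verification suite — 10,000 gene trees for
  the discordance law, 2000 x 2000-marker null replicates for LRT
  calibration, 100 replicates for topology recovery, 5000 markers for
  branch recovery, 200 planted loci for diagnostics — were chosen as the
  smallest sizes at which the targeted tolerances (3 SE bands, +/- 0.02
  size, +/- 0.15 branch length) are meaningfully testable.

## Known limitations

- The four-lineage LRT's Bonferroni factor targets the three resolutions
  of the tested node; under a star tree in *both* internal branches the
  selection space is larger and the test may be conservative or mildly
  liberal there.  Calibration is verified at the tau1 = 0 boundary with
  tau2 positive.
- The exhaustive quartet stage is limited to six taxa by design.
- The three-lineage and four-lineage formulations are documented,
  statistically standard constructions on the published count data; other
  implementations of the same ideas may report different exact p-values
  while agreeing on all qualitative conclusions at these sample sizes.
- Locus diagnostics assume the TE span is annotated in alignment columns
  of the given MSA; no realignment is attempted.
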