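# Methods

## Enrichment model

ESTs are ranked by the mean TPM of one condition's replicates, or by the
ND/NR ratio of means; ties break by ascending EST id so rankings are
deterministic. Windows are floor-based: width W = ⌊0.10·N⌋, step
S = ⌊0.05·N⌋, starts 0, S, 2S, … while start + W ≤ N, which gives exactly 19
windows of 1,260 for N = 12,609 (and 19 windows for any N divisible by 20).
Ranks past the last window end are dropped by default; an `extend_last`
option widens the final window instead.

The enrichment statistic for k members of a pathway with background K/N
inside a set of w ESTs is fold = (k/w)/(K/N) and the upper tail
P(X ≥ k) of X ~ Binomial(w, K/N), i.e. sampling with replacement at the
background rate. This is the model that reproduces the worked top-10
figures exactly (175.1-fold, p = 4.72e-11 for 5/10 vs 36/12,609; 13.3-fold,
p = 0.0012 for 3/10 vs 284/12,609). A hypergeometric
(without-replacement) tail is available behind `model="hypergeometric"`; it
agrees with the binomial within ~1% on the moderate case but is ~25%
smaller in the extreme 1e-11 tail, where with/without-replacement models
genuinely diverge — the binomial is the default because it matches the
printed values.

The window screen excludes pathways with fewer than `min_pathway_size`
members *before* testing (study presets: 60 for level-ranked, 25 for
ratio-ranked lists) and corrects with Bonferroni over the full family
m = retained pathways × windows — the conservative reading when the
multiplicity universe is not stated; the chosen universe is recorded in the
result's metadata. A cell is flagged when fold > 2 and adjusted p < 0.05.
Top-set enrichment reports raw tails, matching how such hits are
conventionally quoted.

## Differential calls and EC aggregation

All change calls share one statistical kernel: a two-sided Welch *t*-test
on log2(level + 1) with per-group variances (n = 3 replicates is typical),
and a fold max(r, 1/r) with r the ratio of condition means. A pseudo-count
of ε = 0.01 substitutes for a *zero* mean rather than being added
throughout, so 8 vs 0 gives exactly 800 while 8 vs 2 stays exactly 4; this
keeps ratios finite without perturbing well-measured values. All fold
thresholds are strict (> t), so a fold of exactly 4 fails a 4-fold screen.
Degenerate all-constant input yields p = 1 when the means agree (and 0 when
they disagree, which only constant non-equal vectors can produce).

The Welch test is a deliberate simplification: the original
differential-expression screen used a negative-binomial framework, but
every enzyme- and lipid-level comparison is reported as a plain p-value on
n = 3, and an NB dispersion model is out of scope here; the choice is
embedded in every report's metadata. FDR adjustment is Benjamini–Hochberg,
applied table-wide, never per call. Two presets reflect the two published
screen variants: > 4-fold with BH q < 0.01, and > 4-fold with raw p < 0.05;
neither is privileged.

EC aggregation sums isoform levels replicate-wise (exact sums, so
conservation and single-copy linearity hold to machine precision), calls
the direction on the summed vectors at (1.5-fold, α = 0.05), and counts
members individually significant at the same member-level screen. Pathway
flux tables label ECs missing from the expression data `not found` rather
than guessing.

## Lipid grammar and remodeling analysis

Species parse from CLASS(C:D[n-x]/…) shorthand; chains require an even
carbon count ≥ 12 and D < C/2, and errors report the failing character
position. Mono-acyl classes (MGMG, LPC, LPE, LPG, FFA) take one chain,
diacyl classes two (sn1/sn2), TAG three with sn1/sn3 chemically
indistinguishable: terminal chains are canonicalized (sorted by carbons,
double bonds, omega) so string equality coincides with structural equality,
and parsing is idempotent under its own formatting.

Origin classification reads the sn2 chain of di-/tri-acyl glycerolipids:
16 carbons → prokaryotic (plastid-assembled), 18/20/22 carbons →
eukaryotic. The 20/22-carbon extension beyond the textbook 16-vs-18 rule is
needed because PC species carry 20:4/20:5 at sn2; those PUFAs arise from ER
elongation/desaturation, so the eukaryotic label is the only consistent
reading. Chains shorter than 16 carbons at sn2 are undetermined and
flagged; mono-acyl species and free fatty acids carry no positional
information and stay undetermined.

"Major species" of a class are all species when the class has ≤ 5, and the
top ⌈n/2⌉ by mean level over all samples when it has ≥ 10. The 6–9 species
range falls between the two stated cases; the same top-⌈n/2⌉ rule is
applied there and flagged as a rule-gap in the return value. Signature
tracing restricts sources (DGDG, MGDG, PG) to major species, requires the
source called down and the target up at the species screen (1.5-fold,
p < 0.05) unless direction filtering is turned off, and matches chains on
(carbons, double bonds) — omega labels are display annotations, since MS/MS
signatures are C:D pairs. The prokaryotic fraction of a class's increase
sums positive ND−NR mean deltas over prokaryotic species and divides by the
positive deltas over all species of the class; with no increasing species
the quantity is undefined and returned as `None` rather than 0.

Class-level calls sum member species replicate-wise (strata partition the
class sum exactly) with threshold presets 1.2 (the ">20%" whole-class
screen), 1.25 (origin-stratified and sn2-PUFA screens) and 1.5. Lipid
levels are accepted as already-normalized moles per million cells;
peak-area normalization is upstream chemistry and out of scope.

## Synthetic data

The expression generator draws baseline TPM log-normally (default natural-
log mean 1.5, sd 2.0 — a heavy tail so "most abundant" windows are
meaningful), assigns pathways of configurable size, forms EC groups with
copy counts 1 + Poisson(mean − 1) reproducing the ~4.4 copies/EC scale, and
applies condition effects on the log2 scale before multiplicative
log-normal replicate noise with a given CV (mean-preserving,
σ² = ln(1 + CV²)). Defaults mirror the study design: 12,609 ESTs, three
replicates per condition. The replicate CV is the one free parameter with
no published counterpart; 0.2 is a realistic bulk-RNA-seq choice, and tests
that probe boundary behaviour set it explicitly. Rank-band pathways are
placed by permuting the baseline values so members occupy rank positions
drawn uniformly inside the band — the value multiset is untouched, and the
recorded truth lists every window overlapping the band. The null generator
strips all planted effects and is used for type-I-error calibration
(family-wise window flag rate ≤ nominal over 200 seeds in the suite).

The lipidome generator builds ~80 species in the 12 observed classes from
the organism's eight major acyl chains, with class-specific sn2
composition: galactolipids mostly 16:X (MGDG keeps an ER-derived minority),
PC/PE 18–20:X, TAG split between the two strata. Remodeling is planted as
~2.6-fold source drops with matched DAG (~3.5-fold) targets or TAG targets,
and the whole-class TAG gain (default 5-fold, the level seen three days
after nitrogen removal) is distributed so a fraction `f_prokaryotic`
(default 0.7) of the net increase sits on 16:X-sn2 species. PC species with
PUFA at sn2 are planted down while the PC class rises — the acyl-editing
signature. What the generator does *not* emulate: compositional coupling
between classes, correlated replicate structure, ionization-mode biases and
missingness; passing tests demonstrate the algorithms recover planted
structure at realistic noise, not that real data meet these assumptions.

## Numerical and reporting conventions

Exact integer window arithmetic; binomial/hypergeometric tails via scipy
survival functions (validated against explicit mass summation to 1e-12 for
w ≤ 25); BH-FDR via statsmodels. Ranking and species tie-breaks are
lexicographic. Report tables are UTF-8, LF, tab-separated with '#'-prefixed
metadata headers embedding every threshold and the seed, so a bundle is
byte-reproducible from (config, seed). Cytometry keeps full precision
internally and rounds half-up only at the reporting layer (3 decimals for
densities: 1.2605 → 1.261); the density-reduction figure is reported as
computed (11.2% for 1.261 → 1.120) without reproducing any coarser
rounding. Test problem sizes (600–5,000 ESTs, 200 Monte-Carlo null
replicates) are chosen so calibration estimates have standard errors well
inside the asserted bounds while the whole suite runs in well under a
minute per module.

## Known limitations

The Welch-on-log2 kernel is not a count model and will differ from NB-based
callers near zero counts; subcellular localization of isoforms is not
modeled, so an EC's summed call can mask compartment-specific regulation
(the DGAT case — flagged by the per-copy counts, not resolved); the
trace matcher treats identical C:D chains as identical acyls, which MS/MS
cannot always distinguish either; PG tracing is retained as a source class
even though its decreasing species typically find no neutral-lipid home
(recycling/editing), so empty PG results are expected, not a bug.
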