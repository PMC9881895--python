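# Methods

## Screen preprocessing

Raw read counts (constructs x samples) are validated as non-negative
integers with unique construct ids and at least one reference-role sample
(plasmid or T0). Normalization adds a pseudocount (default 5) to every
cell and scales each sample so its mean count per construct equals a
fixed target (default 500). The fixed-mean reading is the only one that
makes normalized totals independent of sequencing depth; within-sample
relative abundances are preserved exactly. Log2 fold change is taken
against the reference sample, or against the mean of a reference set when
several reference samples exist (e.g. multiple T0 replicates).

Two-slot constructs are grouped as `gene_N` (target gene first, control
guide second), `N_gene`, `A_B` (two targets) or `control`. Each group is
then centered so its modal fold change is zero — centering is a
*subtraction*, since "setting a mode to zero" by multiplication is
ill-defined, and a shift preserves all within-group differences. Some
study designs instead anchor the whole table on a named negative-control
class; both schemes are exposed, and study-specific variants (reference
role, control class, gene-family exclusions) are declarative
configuration, not code branches.

The mode estimator is a Gaussian kernel density estimate with Silverman
bandwidth, evaluated on a fixed 512-point grid spanning the data range;
the argmax is the mode. The KDE is robust to the heavy left tail that
essential-gene constructs add to a fold-change distribution, which is why
it is preferred over a histogram mode. Groups with fewer than 10 values
are rejected by default (the estimate is unstable), though the minimum is
a parameter. On a handful of points the KDE's broad bandwidth can place
the peak a few hundredths off the majority value; tests of tiny examples
use a 0.1 tolerance for that reason.

Replicate averaging is the arithmetic mean per construct. A construct
missing from some replicate is an error in strict mode; lenient mode
averages over the available replicates and warns.

## Exact-match counting

Guide-array amplicons are counted by exact sequence match only: no
mismatch tolerance, no alignment, no reverse-complement search (amplicon
sequencing with custom primers fixes the orientation). The constant
anchor — the leading direct repeat expressed from the vector, or the
vector segment just 5' of it when the match should include the leading
DR — is located in each read, and the fixed-length slice following it is
compared against the expected spacers-plus-DRs concatenation. Anchoring
tolerates the 0–8 nt stagger regions introduced by the sequencing
primers. Every read increments at most one construct; unmapped reads are
counted and reported, never dropped, and the mapped + unmapped totals
always reconcile with reads processed. For the seven-guide library the
match body is 7×23 nt spacers + 6×20 nt DRs = 281 nt. Whether a "perfect
match" should span the leading DR as well is exposed as the
`full_array` / `array_body` mode rather than guessed.

## Genetic interaction model

The multiplicative null model states that independent fitness
perturbations combine additively in log2 fold-change space. SMF of a gene
is the mean fold change of its gene+control constructs, pooling both
singleton orientations (orientation-specific fits are possible upstream
by filtering the construct table, but pooling is the default). Expected
joint fitness is the sum of member SMFs; observed is the mean over all
constructs targeting the full set, in either gene order; dLFC = observed
− expected. Group spreads use the sample standard deviation (n−1), which
matters at the small construct counts typical per group and is what the
formula-chain oracle in the tests assumes.

The modified Cohen's D uses the four-formula chain given in the README.
All calling thresholds are strict inequalities (dLFC exactly −1 is not a
hit). Triples and quads are classified in threshold-only mode — the
expected fitness is still the sum of member SMFs, but no D is defined
because the "expected distribution" construction is specific to pairs.
`score_pair` degrades D to `None` (rather than failing) when every group
has zero spread, which only occurs in noise-free synthetic data.

Gene-level essentiality is the mean fold change over all arrays and
replicates for a target, with essential defined as mean fc < −1 (strict).
Precision-recall ranks targets ascending by fold change and evaluates
precision and recall at each rank over reference essential/nonessential
genes only; targets in neither set are ignored. This rank-by-rank
construction is implemented directly because library PR-curve routines
use score-threshold conventions that differ at ties; a library
average-precision computation serves as a cross-check in the tests.

## Meta-analysis

Each (platform, cell line) screen is one unit. A platform's weight is the
median Jaccard coefficient of hit sets over all unordered pairs of its
cell lines (with two cell lines, the single coefficient; with one,
undefined — an error). The Jaccard of two empty hit sets is defined as 0:
shared absence of hits carries no replicability evidence. A pair's
paralog score sums the platform weight over every cell line where it was
a hit and subtracts the weight over every cell line where it was tested
but missed; pairs tested by several platforms accumulate contributions
from all of them. Gold-standard candidates require score > 0.25 and hits
on at least two platforms, which suppresses pairs assayed by only one
technology.

## Seven-position array regression

Enumerating essential/nonessential assignments over 7 positions gives 128
arrays per pool; three pools with independent guide picks give 384.
Because fitness saturates when many essential genes are cut, the fit is
restricted to arrays with at most two essential guides (87 of 384). The
regression `y ~ Aβ` has no intercept: fold changes are normalized so
all-nonessential arrays sit at zero, making the baseline structurally
zero. By default one β is shared across pools (the coefficients describe
positions and genes, and each pool targets the same genes), with a
per-pool option; R² = 1 − SSE/SST is reported per pool over array-level
observations. Whether R² should instead be computed on knockout-class
means is genuinely open; the array-level definition is standard and
reproducible, so it is the default. Rank deficiency is detected before
fitting and reported with the names of the dependent columns.

## Library design

Percent identity between paralogs is directional (AB ≠ BA when protein
lengths differ); the mean (AB+BA)/2 and delta |AB−BA| summarize it. The
strict selection profile keeps pairs with mean identity in the inclusive
interval [30, 99] % ("between 30% and 99%" is read inclusively; the
endpoints are boundary-tested), delta < 10 %, and both genes
constitutively expressed (mean log-expression > 2, stdev < 1.5, units as
carried by the input table — CCLE-style log2(TPM+1) is assumed). The
relaxed profile removes the delta and variance filters, keeps the
mean-expression floor, and widens the family drop threshold from 10 % to
20 %. Family expansion anchors on each gene A, takes its top paralog B by
mean identity, adds any C with AB − AC strictly below the threshold, and
truncates to four members keeping the highest-identity companions (ties
broken alphabetically, so the output is independent of input order).
Families from different anchors are deduplicated exactly; nested families
(a pair inside a triple) can coexist, mirroring libraries that target
pairs and larger families as separate reagent classes.

Each target gets two four-spacer arrays. Pairs reuse the same four guides
in a fixed different order ([A1,B1,A2,B2] / [B2,A2,B1,A1]); singles use
the top four guides and their reversal; triples and quads use disjoint
guide ranks across arrays, with triples padded by a filler guide drawn
reproducibly under a seed (nonessential pool in the strict profile,
nontargeting in the relaxed one). The specific permutations are this
package's deterministic choice — the source libraries do not print
theirs — favouring reproducibility over fidelity to an unknown layout.

Oligos are assembled verbatim from the printed template segments: 5'
primer, BsmBI linker `cgtctcgAGAT`, four 20-nt spacers separated by the
three internal DRs, `TTTTTT` terminator, `GAATggagacg` linker, 3' primer.
The two dialects differ only in primers; their lengths are computed, not
asserted — 208 nt for the relaxed template and 212 nt for the prototype,
whose printed 3' primer is four bases longer. Spacer validation rejects
non-ACGT characters, internal BsmBI sites (uncloneable by golden gate)
and runs of ≥ 4 T (premature Pol III termination); these are design-rule
additions of this package. Parsing an assembled oligo recovers the
spacers exactly (round-trip property).

## Synthetic data

`simulate_screen_counts` draws reference counts negative-binomially
(Var = m + α·m², default dispersion α = 0.1, typical of pooled screens)
around a uniform depth, and endpoint counts around
depth · 2^(expected LFC + ε), with ε ~ N(0, σ²) per construct and
replicate (default σ = 0.3). The expected LFC of a construct sums the
efficiency-weighted SMFs of its targets plus any declared interaction
effect whose member set the construct fully covers; interaction effects
are attenuated by the product of member efficiencies, the simplest model
in which 80 % single-gene efficiency compounds to ~50 % joint triple
knockout. Depth normalization of a depleted library shifts all fold
changes upward by the mean depletion; simulated analyses therefore anchor
on control constructs (or a known-neutral gene) exactly as a real screen
would via mode-centering.

`simulate_pair_lfc` generates construct-level fold changes directly in
LFC space for calibration studies: five groups (both singleton
orientations per gene plus A_B), a configurable number of constructs per
group (default 3, the typical per-group reagent count in pairwise
libraries), Gaussian noise per construct×replicate, replicates averaged.
`simulate_multiplatform_hits` defaults to five platforms with recalls
(0.9, 0.7, 0.5, 0.3, 0.1) — evenly spaced over the range spanned by a
two-platform (0.9, 0.5) reference configuration — three cell lines per
platform, 500 tested pairs of which 50 are true synthetic lethals, and a
1 % false-positive rate. `simulate_7mer_lfc` applies per-position
attenuation multipliers to emulate late-position efficacy loss.

What these generators do *not* model: sequence-level read errors,
lentiviral bottlenecks, copy-number artifacts, guide-specific efficacy
beyond a per-gene scalar, or correlated noise between constructs sharing
a guide. Passing recovery tests therefore demonstrates correctness of the
estimators under the declared noise model, not robustness to every
artifact of real screens.

## Calibration results and a known limitation

Under the default pair-simulation conditions, the null (zero-interaction)
hit rate at dLFC < −1 with D > 0.8 is far below 2 %, and the
platform-weight ranking of five platforms matches their true recall
ranking in ≥ 95 % of simulations. Recovery of an injected dLFC of −2
within ±0.25 succeeds in about 85 % of simulations at the default
3 constructs/group, 2 replicates, σ = 0.3 — and this is a statistical
ceiling, not an implementation defect: the estimator's sampling standard
deviation under those conditions is σ·√(1/6 + 2/12) ≈ 0.17, giving
P(|error| ≤ 0.25) = 2Φ(1.44) − 1 ≈ 0.85. Reaching 90 % coverage at ±0.25
requires roughly twice the singleton measurements per gene (e.g. more
constructs per orientation or more replicates). The acceptance suite
asserts the 90 % figure and accordingly reports this single check as
failing; all other checks pass.

## Problem sizes

Calibration suites use 1,000 pairs for null calibration, 500 seeds for
parameter recovery, 100 simulations for the regression R² comparison, 200
seeds for ranking recovery and 1,000 random spacer quartets per dialect
for oligo round-trips — sizes at which every binomial confidence interval
is a small fraction of the margin being tested while the whole suite runs
in seconds.
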