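# Methods

This note documents the generative models, estimators and numerical
choices behind `wheatnam`, and what the synthetic-data tests do and do
not demonstrate about real data.

## The breeding scheme and its closed forms

The simulator executes, per nested population: F₁ = recurrent × donor;
BC₁F₁ = F₁ × recurrent; a configurable number of BC₁F₁ "streams"
(default 12) each selfed into 8 BC₁F₂; then single-seed descent for a
total of 4 selfings to BC₁F₅ (96 genotypes per population before
attrition). Uniform random dropout thins each population to a target
size (default 60); dropout is uniform because no loss mechanism beyond
a final average size is specified for such programmes.

Founders are fully homozygous. Each donor combines an A/B sub-genome
pattern drawn from a tetraploid parent pool (default 15) and a D
sub-genome pattern from a diploid pool (default 47); a pool pattern
differs from the recurrent parent at each marker with probability
`polymorphic_fraction` (default 0.5, a middle ground between closely
and distantly related donors). Dosage coding throughout: 0 = homozygous
recurrent (reference), 2 = homozygous donor, 1 = het, NaN = missing.

Meiosis is Haldane — crossovers as a Poisson process on the cM map, no
interference — because it is the simplest map-consistent model and
gives closed-form checks: recombination fraction ½(1 − e^(−2d/100)),
expected recurrent genome share 75% in BC₁ derivatives, and residual
heterozygosity ½·(½)^g of donor-polymorphic loci after g selfings.
cM positions are linearly interpolated from bp by default; a
per-chromosome cM profile can be supplied to emulate pericentromeric
recombination suppression.

Trait phenotypes are unit-level sums: mean + planted QTL effects ×
dosage + a polygenic value + block/row/column/scorer/lid effects +
residual, each random term drawn from its stated variance. The
polygenic value is built from a few hundred random markers (then
rescaled to the target variance) so that kinship computed from markers
genuinely predicts the background — an i.i.d. mode exists for cases
where that coupling is unwanted. Check varieties take fixed true
values: their role is purely to estimate spatial effects.

Trial layouts are augmented two-unit ("half-plot") designs: replicated
checks are dealt one-per-plot over a shuffled plot cycle (never the
same genotype twice in a plot), unreplicated entries fill the rest;
blocks are as equal as possible within the configured size range, with
row/column grids nested per block and a drilling-lid factor every 20
plots.

## Genotype QC

Markers are removed when het fraction > 10%, missing fraction > 10%,
or minor-allele homozygote count < 15; genotypes when het fraction >
10%. All thresholds are exclusive (a marker at exactly the boundary
survives). Het fractions use non-missing calls as the denominator so
the het and missingness filters stay decoupled; missingness alone never
removes a genotype. The cascade order is fixed (markers → genotypes →
duplicates → non-parental check → imputation) but each stage is
re-runnable on its own and reports its counts.

Duplicate detection computes all pairwise Pearson correlations between
genotype dosage vectors (pairwise-complete) and flags a pair by either
of two codified rules — absolute r > 0.99, or r above the
within-population mean + 6 sd — because "too similar relative to the
overall distribution" is otherwise a visual judgement. Both cutoffs are
configurable; when dropping, the member with more missing data loses
(ties: lexicographically later id). Constant rows are excluded and
reported.

The non-parental-allele check uses, per population, the markers where
the recurrent parent and the donor share a homozygous dosage: offspring
disagreeing there carry an allele neither parent could donate. The
default flag threshold of 5% disagreement tolerates residual
genotyping error while catching sample mix-ups; it is configurable.

Imputation is iterative random-forest classification (default 200
trees), markers visited by increasing missingness, stopping when the
number of changed calls rises between sweeps (the classic iterative-RF
criterion) or at `max_iter`. Predictors are capped at the 100 markers
most correlated with the target, which preserves accuracy in LD-dense
panels while bounding cost. Outputs stay in {0, 1, 2}; observed cells
are never altered; an out-of-bag error estimate is reported from the
first sweep.

## Marker positioning

Alignment-based placement takes the best hit per marker (bitscore,
then e-value, then alignment length, then subject name) and uses the
orientation-independent midpoint ⌊(start+stop)/2⌋. Correlation
transfer places an unplaced marker via its highest-R² placed partner
(floor R² ≥ 0.2 to block noise matches), adopting the marker's own hit
nearest to the partner's position on that chromosome — no fallback to
other chromosomes.

LD-bin repositioning groups markers into connected components of the
R² > 0.5 graph (components are order-independent and reproducible,
whereas the notion of a "bin" is otherwise underspecified). A marker
disagreeing with its bin's majority chromosome — strict majority,
i.e. more than half of the *other* members; plurality available as a
configurable fallback — is moved to the midpoint of its best hit on
that chromosome; with no majority, the highest-LD partner's chromosome
guides. Exactly two passes by default. Repositioning never unplaces a
marker, and within-chromosome bp errors are deliberately out of its
mandate. A summary statistic (mean adjacent-marker R² within
chromosomes) quantifies the map improvement that would otherwise be
judged from LD heatmaps.

## Trial mixed models

The REML fitter optimizes variance ratios γ_k = σ²_k/σ²_e on the log
scale (L-BFGS-B, bounds ±12 in log space ≈ [6e-6, 1.6e5]) with the
residual variance profiled out; ratios at the lower bound are reported
as zero variances. It was written directly against the covariance form
V = σ²_e(I + Σ γ_k Z_k Z_kᵀ) to give full control over backward
elimination and BLUE extraction with arbitrary crossed random terms;
the test suite verifies it against `statsmodels` MixedLM (variance
components and restricted likelihood agree to ~1e-3 relative).

Backward elimination drops, one at a time, the random term with the
largest χ²₁ LRT p-value above α = 0.10 (the default of the stepwise
tools commonly used for this). Fixed effects are unchanged during
elimination, so REML likelihoods are comparable. BLUEs use treatment
coding with the recurrent parent as reference when present; the
reported value is intercept + effect, i.e. on the response scale.
Half-plots are independent units — no plot-level random term by
default, though one is available. The scorer term enters only when more
than one scorer is recorded. H² = V_g/(V_g+V_e) from a refit with
genotype random alongside the retained design terms.

Group comparisons use Welch's unequal-variance t-test (two-sided), and
cross-trial trait correlations are pairwise-complete Pearson r with
two-sided tests, flagging cells with p > 0.05 for masking in displays.

## Association scan

The null model y = Qβ + u + e, u ~ N(0, K σ²_g), is fitted by REML
after rotating into K's eigenbasis, reducing the search to one
dimension (log variance ratio, bounded ±12, with explicit boundary
comparison so pure-genetic and pure-residual solutions are reachable).
Per-marker tests are GLS with those components held fixed — the
P3D/EMMAX approximation — which makes a scan one QR decomposition plus
one vector projection per marker and reproduces exact OLS when K = I.
Q is the nested-population factor as fixed dummies (first population
reference). Markers constant within every population are confounded
with Q and reported NA rather than tested. Scans run on imputed
matrices; missing dosages at scan time are not permitted.

Kinship is the centered cross-product W Wᵀ/m on a marker set skimmed
at |r| ≥ 0.8, so dense LD blocks do not dominate relatedness. Marker
preparation per trial: minor-homozygote count ≥ 15 in that trial's
genotype subset, then an exact-duplicate skim (|r| = 1).

M_eff uses the eigenvalue rule (each correlation-matrix eigenvalue
contributes I(λ≥1) + frac(λ)), computed per chromosome and summed;
eigenvalues are rounded at 1e-8 so a value of k − ε does not contribute
a spurious extra fraction. The estimator choice is recorded in scan
metadata so a permutation-based alternative can be swapped in. The
threshold is −log₁₀(α/M_eff). Inflation λ is the median association
χ²₁ over 0.4549.

## QTL calling

LD decay pools within-chromosome pairwise R² (subsampled per
chromosome above 200k pairs for memory), bins by 1 Mb, and fits
a·e^(−b·d) to the binned means; the window is ⌈crossing of the critical
R²⌉, with an error (rather than an extrapolated number) when the fitted
crossing lies beyond twice the observed distance range. Peak calling is
greedy highest-score-first with ±window suppression per chromosome
(ties: smaller bp, then marker id). Intervals extend through
consecutive significant markers but are confined to the suppression
window to prevent runaway intervals on dense significant stretches.

Cross-trial merging is single-linkage clustering within trait ×
chromosome × effect-sign groups at 3× the LD window — cross-trial peak
drift of 20–55 Mb for one QTL is common in this design, so a 1× window
would split genuine signals. The multiplier is configurable and every
merge is written to an audit log with its span, replacing the visual
inspection such decisions would otherwise need. Conflicting signs at
one position never merge and are flagged. Multi-QTL variance shares are
partial R² from dropping each peak out of a joint GLS model (same P3D
machinery), in percent of total phenotypic variance; collinear peaks
are pruned with a warning and reported NaN.

## Selection summaries

Descriptive only: per-background availability, selection counts and
percentages (one decimal), and 2×2 carrier-by-selection tables at a
marker, restricted to populations segregating at the locus. "Carrier"
defaults to homozygous donor allele (dosage 2) with a dosage ≥ 1
switch, since zygosity conventions differ. Donor contributions in
nested panels are unbalanced, so no inference is attached beyond the
explicit Welch t-tests.

## Problem sizes and what the tests show

The test suite runs everything on synthetic panels of 200–850 genotypes
with 150–1050 markers: large enough that the closed-form pedigree
expectations, REML parameter recovery, GWAS calibration (type-I error
and λ), 8%-variance QTL power, and repositioning recovery are all
measurable with comfortable margins, while a full run stays in minutes
on one core. The generator reproduces the design structure of a real
backcross NAM — nested relatedness, map-consistent LD, spatial trial
effects, check replication, missingness and dosage errors — but not
array-specific artifacts (probe cross-hybridization, cluster-calling
bias), segregation distortion, or genotype-by-environment interaction
across years. Passing tests therefore validate the estimators and
bookkeeping, not those data pathologies. Within-trial genotype subsets
for multi-trial studies are config-driven rather than reconstructed,
and lineage labels for diploid donors are user-supplied metadata, never
inferred.

## Known limitations

- The REML fitters use dense n×n covariance algebra: fine to a few
  thousand units/genotypes, not for biobank scales.
- P3D fixes variance components at the null estimates; for markers of
  very large effect exact per-marker REML would give slightly different
  p-values (the standard trade-off of this approximation).
- The exponential LD-decay fit is a summary, not a model of
  recombination-rate variation along chromosomes; windows are genome
  averages.
- Backward elimination uses χ²₁ LRT p-values, which are conservative
  for boundary variance tests; with α = 0.10 this mildly favours
  dropping weak terms.
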