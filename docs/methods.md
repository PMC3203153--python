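# Methods

## Design and scope

`mirreg` analyses a paired tumor/normal two-platform expression study:
every patient contributes one tumor and one adjacent-normal sample to both
an mRNA and a miRNA intensity matrix. The package is organised around the
statistics such a study needs at very small n (the reference design has
six pairs), where a consistency requirement across all pairs is a stronger
guard against false calls than any asymptotic test.

## Differential expression

**Detection filter.** A feature is retained if its detection flag is true
in at least one sample. Detection flags arrive as a separate boolean
matrix; a converter from detection p-values (p < 0.05 → detected) is
provided for platforms that report them, since detection criteria vary by
scanner software.

**Normalization.** Raw intensities must be strictly positive; they are
log2-transformed and each array (sample column) is centered on its median.
After centering every column median is exactly zero.

**Consistent-direction calls.** With per-patient differences
δ_p = tumor − normal on the centered log2 scale, a feature is *up* iff
δ_p > 0 for every patient and *down* iff δ_p < 0 for every patient. An
exact-zero difference in any pair breaks consistency (direction *none*):
the rule is deliberately strict, matching the idea that at six pairs a
single discordant patient is disqualifying. `mean_delta` is the mean of
the per-pair differences and is the Δe used downstream.

**SAM-style paired statistic.** d = mean(δ) / (se(δ) + s₀) with
se = sd/√n (sample sd, n−1 denominator). The fudge factor s₀ is the
configured percentile (default 5th) of the feature-wise standard errors —
a deliberate simplification of the original coefficient-of-variation
minimisation, chosen because the reference analysis used packaged SAM
with default settings and the percentile variant is transparent and
deterministic. At s₀ = 0 the statistic reduces to the one-sample t on the
differences. In the vectorized permutation path a zero-scatter feature
with nonzero mean maps to ±∞ (the noise-free limit outranks every finite
statistic); the scalar `sam_paired_d` treats that case as an error, since
a user computing a single d from degenerate data is more likely holding a
data problem than a noise-free limit.

**Permutation FDR.** The null is generated by sign-flipping the
per-patient difference vectors. When the requested permutation count
reaches 2ⁿ the 2ⁿ distinct sign patterns are enumerated exhaustively (64
patterns at n = 6, so the default 1,000 requested permutations always
triggers exhaustive enumeration there); otherwise patterns are sampled
with the configured seed. For a feature with threshold t = |d_obs|,

    q(t) = median_b #{j : |d_b,j| ≥ t} / #{i : |d_obs,i| ≥ t},

capped at 1. q-values are then monotonized by taking, for each feature,
the minimum plug-in estimate over all thresholds at or below its own |d|,
so q is non-increasing in |d|. Under a complete null this estimator is
strongly conservative (measured call fraction at q < 0.1 is ~10⁻³ across
seeds), which is the desired behaviour for a screen whose primary filter
is direction consistency.

**Reported percentages** use half-up rounding to two decimals
(`percent_of`), matching how published report tables print proportions.

## Regulation values and gene classes

For each direction-consistent ("variable") miRNA, r = Δe / t, where t
counts its predicted targets among the *detection-filtered* genes (not
only the differentially expressed ones — "expressed targets" means
expressed). Variable miRNAs feeding this statistic are the
consistent-direction lists, not the FDR-significant subset: the FDR layer
at six pairs passes almost nothing, and the classification is built on
the directional lists. For each differentially expressed gene,
R_g = Σ r over its variable regulators; no regulator → R_g null.

Classes: *others* iff R_g is null or |R_g| ≤ ε (default ε = 0, so exact
cancellation counts as null); otherwise *anti-correlated* when sign(R_g)
opposes the gene's own direction and *correlated* when it agrees.
Classification depends only on signs, so scaling all Δe by a positive
constant never changes a class. The three classes partition the
differentially expressed genes, and per-class up/down counts sum to the
direction totals — the internal-sum property any three-group summary
table must satisfy.

Multiple probes per gene are kept at probe level through differential
analysis; joins against target tables use any-probe semantics. Identifier
normalization (miRNAs lowercased, gene symbols uppercased) is applied in
every reader, making pair tables join reliably against expression
features.

## Target-set intersection

Predictor outputs are consumed as (miRNA, gene) pair tables; overlap is
plain set intersection with percentages of each side. The internal
algorithms of the predictors are out of scope.

## Promoter CpG classes

Within sliding windows (default 500 bp, step 1), GC fraction and the CpG
observed/expected ratio O/E = #CpG·L/(#C·#G) are computed with N positions
excluded from counts and effective length. HCG: some window has GC ≥ 0.55
and O/E ≥ 0.75; LCG: no window reaches O/E ≥ 0.48; ICG: the remainder.
These are the classical strong/weak CpG-island thresholds and are fully
configurable. Sequences shorter than the window are scanned as one
whole-sequence window with a logged fallback. The acronyms are read at
face value (H=high, I=intermediate, L=low CpG content) even though some
published prose swaps the parenthetical glosses of ICG and LCG; the
thresholds are unambiguous. Promoter extraction from a genome is out of
scope — sequences arrive pre-cut.

## Enrichment

Hypergeometric upper tail P(X ≥ O) over a universe of N annotated
measured genes, n the annotated gene-set size, C the term size, with
E = C·n/N and R = O/E (reported 2-decimal rounded). p-values are
BH-adjusted; terms with adjP < 0.001 (configurable) are flagged. The
universe is an explicit argument because published enrichment p-values
are only meaningful relative to a stated universe; annotation is treated
as flat (no GO-DAG propagation).

## qPCR

ΔCt = Ct_target − Ct_reference per sample (U6 for miRNA, GAPDH for mRNA
assays), ΔΔCt = ΔCt_case − ΔCt_control, fold = 2^(−ΔΔCt) (the standard
Livak sign convention). Replicate wells are averaged before ΔCt. Paired
designs use the paired t-test on ΔCt; independent designs use Welch's
test, with the control baseline for unpaired fold changes taken as the
mean control ΔCt. All-zero paired differences report t = 0, p = 1 with a
warning rather than a NaN.

## Synthetic data

The generator emulates a 6-pair paired design at a scaled-down feature
space — 1,200 genes and 80 miRNAs by default, preserving roughly the 1:2
up:down asymmetry of the motivating study (defaults: 5% genes up, 10%
down, 10% of miRNAs each way). Baselines are Gaussian on the log2 scale
(mean 8, sd 2 ≈ a log-normal intensity distribution), per-cell noise is
Gaussian with sd 0.1, planted features shift by 1.5 log2 units in every
tumor, and each variable miRNA represses a private block of 3–8 targets
by `repression_effect × Δe / t` in the opposite direction
(repression_effect default 2).

Two constructions keep the planted truth exactly recoverable at zero
noise, both worth knowing when interpreting tests:

* planted shifts are placed strictly within the upper (up) or lower
  (down) half of each array's baseline distribution, excluding the middle
  order statistics, so median centering is exactly neutral with respect
  to planted differences;
* each variable miRNA's target block is disjoint from all other planted
  sets, so every planted target has exactly one variable regulator.

Real data honour neither: highly expressed genes can fall, targets share
regulators, and array medians do drift with large expression changes.
Passing recovery tests therefore demonstrates correctness of the
*computation*, not robustness of the *design* to those confounders.
Detection is a fixed log2 intensity floor (default 2.0), with a planted
fraction (2%) of features placed far below it. Truth tables are emitted
as separate TSVs and never read by the pipeline.

Promoters are built per requested class (CpG-token insertion for HCG,
CpG depletion at two strengths for ICG/LCG) and verified against the
classifier at generation time; the annotation plants one term drawing
half its 80 genes from the planted up set.

All randomness flows from `rng_seed` through independent child streams,
so equal seeds give byte-identical output files.

## Numerical choices and limitations

* Exact-zero deltas, exact-zero R_g and E = 0 cases all have explicit
  conventions (none / others / error) rather than sign-dependent defaults.
* Probe→gene collapsing, unpaired designs, SAM's original s₀ optimizer,
  GO-DAG propagation and amplification-efficiency correction are out of
  scope.
* The permutation FDR is a median-count estimator without a π₀
  correction; it is conservative by construction.
* BH adjustment is not idempotent in general (e.g. [0.25, 1.0] adjusts to
  [0.5, 1.0], which adjusts to [1.0, 1.0]); the property tests assert
  order preservation and elementwise domination instead.
* Default problem sizes (1,200 genes, 80 miRNAs, 20-seed calibration
  panels) were chosen so the full suite exercises every stage at
  comfortable statistical resolution; all are configurable upward.
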