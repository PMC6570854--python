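# Methods

This note documents the statistical procedures implemented in
`leafspectra`, the assumptions behind them, the synthetic survey that
exercises them, and the design choices made where the problem was
genuinely open.

## Trait indices

Plot-level traits are means of leaf-level measurements (the package does
not process raw leaf measurements beyond SLA = area/dry mass and
LDMC = 1000·dry/fresh mass, mg g⁻¹; LDMC is reported in mg g⁻¹ because
that is the conventional unit even though the defining ratio is
dimensionless).

**PVI** min–max normalises a trait over the sampled units,
`(max−T)/(max−min)`: 0 at the observed maximum, 1 at the minimum.  Two
conventions deserve emphasis.  First, the orientation: PVI *decreases*
with the trait; it is implemented exactly in that printed form.  Second,
the scope of the extremes: a survey may score 300 plots against extremes
taken over its 66 populations, so `compute_pvi` accepts an
`extremes_from` reference separate from the scored units (values can
then leave [0,1] by construction).  The default scope is the supplied
table itself; the pipeline uses population (site) means as the
extreme-defining scope.  Extremes are observed sample extremes — no
trimming, no theoretical bounds.

**LPI/LTI** sum max-normalised traits within the production set
{leaf area, SLA, chlorophyll, leaf N} and tolerance set
{LDMC, leaf C, leaf C:N}.  Max-normalisation makes both indices
invariant to rescaling any single trait column, which the tests verify.
Leaf C:N is recomputed from leaf C / leaf N when absent; if supplied and
inconsistent beyond 1e-6 relative, the supplied column wins with a
logged warning.

**Δ** = (Vi−Vu)/(Vi+Vu) over a plot pair is antisymmetric and bounded
in [−1,1] for nonnegative inputs; it is undefined at Vi+Vu = 0 and the
library raises there.  (The *generator* defines Δ = 0 when a variable is
zero on both sides of a pair — absent on both sides means unchanged.)

## Model-II regression and the PVI ANOVA

Trait–trait and LPI–LTI relationships carry error on both axes, so they
are summarised with the standardized major axis: |slope| = s_y/s_x
signed by the Pearson correlation, intercept through the means.
Significance is the test of r = 0 (t, n−2 df), the conventional SMA
test.  Raw traits are natural-log transformed before fitting (a flag);
LPI and LTI, already normalised composites, are fitted untransformed.
No multiple-testing correction is applied across the 21 trait-pair fits
(a flag-free deliberate default matching common practice for these
descriptive fits).

Differences in phenotypic variation among the seven traits are tested
with one-way ANOVA and all-pairs Tukey HSD at α = 0.05 (the standard
all-pairs post-hoc choice), rendered as a compact letter display:
groups share a letter iff their difference is not significant.  For ≤ 12
groups the display is an exact minimum cover (search over maximal
mutually-nonsignificant sets by increasing family size); beyond that the
Piepho insert-and-absorb construction is used, which is always valid but
not guaranteed minimal.  If every observation is identical the F
statistic is defined as 0 with a single shared letter.

## Multimodel inference

Predictors are z-scored before enumeration so averaged coefficients and
signs are comparable across drivers; reported effects are therefore on
the standardized scale (the transform parameters are retained).  All
2^p subsets of the p = 16 drivers are fitted by OLS with intercept and
ranked by AICc with k = |subset| + 2 (intercept and residual variance
both counted).  Ties in AICc are broken by lexicographic subset mask so
output is deterministic.  Subsets violating n − k − 1 > 0 are skipped
with a logged warning rather than aborting; an exactly-fitting model
(RSS = 0) raises, since the Gaussian likelihood degenerates.

Akaike weights are computed over the full candidate set.  The 95%
confidence set is the smallest AICc-ordered prefix whose cumulative
weight reaches 0.95, including the crossing model.  Coefficients are
averaged over that set with renormalised weights using **full
(zero-substituted) averaging** — a predictor absent from a model
contributes 0 — because importance and effect direction are interpreted
jointly across the whole set; conditional averaging is available as a
flag.  Unconditional standard errors combine within-model variance and
between-model spread, `sqrt(Σ w_m [var(β|m) + (β_m − β̄)²])`, with
two-sided normal p-values on z = β̄/SE and significance stars at
0.05/0.01/0.001.

Importance(v) = Σ weights of models containing v ∈ [0,1].  Relative
contributions divide importance by the summed importance of all 16
drivers (so they total 100%); category totals sum members; per-capita
contributions divide a category total by its member count, making the
2-driver climate/diversity categories comparable with the 6-driver soil
and interaction categories.  The biotic/abiotic split is a configurable
mask; the default marks richness, evenness, bacteria, fungi, F/B and
the six Δ variables biotic (11) and MAT, MAP, pH, texture, nutrients
abiotic (5) — one consistent reading, not the only one.

The sweep is vectorised: subsets of equal size share one batched
Cholesky/solve over gathered sub-blocks of the (p+1)×(p+1) Gram matrix,
so the full 2^16 enumeration at n = 300 takes on the order of a second.

**Response choice.**  "Variation in a trait" is ambiguous between the
raw trait and its variation index; the pipeline uses the per-unit PVI of
each trait (an affine, orientation-reversing transform of the trait, so
subset ranking is identical and signs flip), and the per-unit LTI/LPI
ratio for the spectrum.  Both the 300-plot and the 66-population unit
scopes are supported (`scope` in `AnalysisConfig`).

**Texture** enters as a single continuous variable (sand fraction, %),
since a clay:silt:sand composition does not define a scalar; the
generator draws it directly.

## The synthetic survey

The generator emulates the survey design exactly: 22 locations × 3
sites; the first 51 sites (in location/site order) hold five plot pairs
and the remaining 15 hold three, giving 300 pairs.  Ten measured
drivers are drawn per pair from a multivariate Gaussian with
configurable means/SDs/correlation (defaults: MAT 16.5 ± 1.5 °C, MAP
1400 ± 250 mm, richness 8 ± 3 species, evenness 0.60 ± 0.12, pH
6.0 ± 0.7, sand 40 ± 12%, nutrients 50 ± 15 mg kg⁻¹, bacteria 60 ± 18
and fungi 12 ± 4 nmol PLFA g⁻¹, F/B 0.20 ± 0.05 — values a subtropical
lowland survey would call typical), clamped to admissible ranges
(nonnegative pools, evenness in [0,1], pH in [0,14], sand in [0,100]).
The correlation matrix covers these ten *drawn* drivers (identity by
default); the six Δ drivers are **computed**, not drawn: invaded-plot
values are uninvaded + a per-variable invasion shift (defaults: −2
richness, −0.2 pH, +5 nutrients, +6 bacteria, +2 fungi, +0.01 F/B) +
pair-level noise, and Δ follows from the pair.  Correlations involving
Δ variables therefore emerge from the pairing model.

Each trait is baseline + standardized drivers · effect column +
Gaussian noise, with nonpositive draws resampled (≤ 100 attempts, then
error).  Leaf C:N is derived as leaf C / leaf N so the table satisfies
the consistency invariant; the C:N column of the effect matrix is
consequently ignored.  The default effect matrix is sparse and
ecologically signed (moisture/nutrients → acquisitive leaves; warmth →
dense C-rich tissue) with magnitudes of roughly 0.3–0.7 residual SDs.
A single integer seed feeds a hierarchical stream (environment stage,
trait stage), so equal (design, model, seed) triples give bit-identical
bundles.

What the generator does **not** emulate: spatial autocorrelation (all
pairs are exchangeable draws; location labels are labels only),
non-Gaussian driver distributions, microbial community composition
beyond scalar PLFA-like totals, and measurement error structure within
plots.  Passing tests therefore demonstrate correctness of the
*estimators* under a known linear truth, not that real surveys satisfy
these assumptions.

## Numerical choices and determinism

CSV floats are written at 12 significant digits, making end-to-end
reruns byte-identical under a fixed seed and config; every report
carries a config hash and refuses to overwrite a directory produced
under a different one.  Constant driver columns contribute nothing to
trait generation (their z-score is defined as 0) but are rejected with
a named error in the analysis path, where a zero-variance predictor is
almost certainly a data error.  Batched subset solves raise a
singular-fit error on rank-deficient subsets rather than silently
pseudo-inverting.

## Problem sizes used in validation

The test suite and acceptance script validate the chain against an
independent brute-force per-subset refit at p ≤ 4, n ≤ 60 (tolerances
1e-8 to 1e-12), run the full 2^16 × n = 300 enumeration directly, and
measure driver recovery over 100 replicate surveys with four true
drivers of |standardized slope| ≥ 0.5 against residual SD 1 — sizes at
which the whole validation completes in a few minutes on one core.

## Known limitations

- The published survey's 16-variable environmental table is not
  publicly deposited, so the headline per-category percentages of the
  original study cannot be recomputed here; the replication tests that
  *are* possible (per-trait PVI means, the LPI–LTI fit) require the
  original leaf-trait deposit to be placed at `data/leaf_traits.csv`.
- Exhaustive enumeration is exponential in p; the engine is sized for
  p ≈ 16–20, not general feature selection.
- No mixed-effects or spatial error structures: plots within a site are
  treated as independent units, which overstates effective sample size
  when within-site correlation is strong.
- Full and conditional averaging disagree when the confidence set mixes
  models with and without a predictor; the default (full) shrinks weak
  effects toward zero by design.
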