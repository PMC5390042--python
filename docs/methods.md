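# Methods

## Bioassay classification

Antimicrobial activity: each species' replicate agar-diffusion inhibition
radii (cm) are averaged; the species is *active* iff the mean is ≥ 0.6 cm.
The tie at exactly 0.6 cm resolves to active (the rule is a ≥ threshold).
Raising the threshold can only shrink the active set (tested).

Cytotoxicity: viability is 100·mean(A_treated)/mean(A_control) from the
MTT absorbances. Per species and cell line, a two-group one-way ANOVA
compares treated replicates against the shared solvent-control replicates
(for two groups F = t² of the pooled-variance t-test, asserted
numerically). p-values are Benjamini–Hochberg corrected *across the
species of one cell line* at FDR α = 0.05, and a species is *cytotoxic*
iff the corrected call is significant **and** mean viability is below
100 %. The direction requirement keeps significant readings above the
control — hyper-proliferation — out of the cytotoxic class. Species with
zero variance in both groups have an undefined F; they are flagged and
never called significant. The grouping of the ANOVA (per-species contrast
vs. the control, correction across species) is a design choice of this
package: it is the only grouping that yields the per-species significance
call the downstream screen consumes.

## Feature table

Presence ⇔ raw intensity ≥ 10⁴ (boundary inclusive). Peaks present in
every species are discarded before screening: they carry no contrast
between classes and their kappa against any non-constant classification
conveys nothing (the filter is idempotent and its removals are recorded).
Missing intensity cells are coded 0 (absent), not imputed — the analysis
is presence/absence. The PCA overview centres each feature and divides by
the square root of its standard deviation (Pareto scaling, n−1
denominator), dropping zero-variance features with a warning; raw
intensities are the default input, with presence/absence available as an
option. Group overlays use a two-standard-deviation ellipse from the
mean and 2×2 covariance of each group's first two score coordinates;
groups with fewer than three members get no ellipse.

## Kappa screen

For a binary feature profile and a binary classification on n species,
the 2×2 table (a, b, c, d) gives κ = (p_o − p_e)/(1 − p_e) with
p_o = (a+d)/n and p_e = [(a+b)(a+c) + (c+d)(b+d)]/n². κ is undefined
(flagged, excluded from ranking) only when p_e = 1, i.e. both raters are
constant in the same direction. Per-feature significance uses a two-sided
Fisher exact test — exact and parameter-free at n ≈ 87 with sparse cells —
followed by Benjamini–Hochberg at α = 0.05; the test choice is
configurable in principle since the tier boundaries, not the stars, drive
candidate selection. Features are ordered by competition (min) rank: tied
values share the smallest rank of their block, so three features tied at
the top are all rank 1 and the next value is rank 4.

Tiers: strong κ ≥ 0.68, moderate 0.35 ≤ κ < 0.68, low otherwise. The
combined score κ̄_C = κ_AM − (κ_HaCaT + κ_IEC-6) is an unweighted linear
combination; a feature is selected iff κ̄_C ≥ 0.68 and κ_AM ≥ 0.68.

Identified compounds are compared between activity classes with a
two-tailed unpaired pooled-variance t-test on LC-MS intensities; features
annotated to the same compound are summed per species first.

## Boolean pair screen

All C(F,2) unordered pairs are evaluated under AND and OR. Per feature
block B, two Gram products against all features give the pairwise
intersection counts overall (|x∧y|) and within the active species
(|x∧y∧L|); all four contingency cells for both operators follow in closed
form (for OR via inclusion–exclusion). Counts are integers below 2⁵³, so
the float matrix products are exact and the blocked kernel agrees
*bitwise* with a naive per-pair loop (asserted on 19,900-pair instances).
Evaluation is streaming with O(B·F) memory; only pairs at or above a
report threshold (default 0.68) are materialised, while summary tallies
always cover every pair. *Outperforming* means strictly greater than the
best individual κ on the same inputs — strict inequality generalises a
data-specific cut-off. Pairs whose combined profile makes κ undefined
count as evaluated but never as strong or outperforming. Triples and
higher-order combinations are out of scope.

Maximising κ over ~F²/2 pairs inflates the best value relative to the
best of F individual features even for label-independent profiles; every
pair summary carries this selection-maximum caveat, and the package's own
null test confirms the effect.

## Fritz–Purvis D

On a rooted, strictly bifurcating tree, tips carry the trait (0/1), each
internal node the mean of its two daughters (post-order), and
d_obs = Σ |v_left − v_right| over internal nodes. Two nulls are simulated
on the same tree (independent substreams of one seed): random — tip
states shuffled; Brownian-threshold — a Brownian character (root 0,
variance = branch length, rate 1; the scale cancels through thresholding)
binarised at the quantile matching the observed prevalence (exactly k
ones). Then D = (d_obs − mean d_B)/(mean d_R − mean d_B);
p_random = P(d_R ≤ d_obs) (small ⇒ significantly more clumped than
random, i.e. D below 1), p_brownian = P(d_B ≥ d_obs). Monomorphic traits
are rejected; if the two null means coincide D is undefined and flagged.
Polytomies must be resolved first (`resolve_polytomies`, deterministic per
seed; new internal edges get length 10⁻⁸ so the Brownian null keeps
positive variance). Calibration on 64-tip Yule trees at prevalence 0.25
(200 replicates, 500 permutations) gives mean D ≈ 0.99 for random traits
and ≈ 0.00 for Brownian-threshold traits. Agreement with other
implementations (e.g. caper) to machine precision is not claimed; the
defining calibration properties above are what the tests assert.

## Synthetic studies

The generator emulates the target study design: 87 species, triplicate
bioassays, thousands of LC-MS peaks, ~20 % of species antimicrobially
active. Defaults (all overridable in `SyntheticConfig`):

- Trees: Yule pure-birth, unit rate — simple with realistic topology
  spread. Antimicrobial activity is laid on the tree with the
  Brownian-threshold mode (clade-concentrated, as a lineage-specific
  defence compound would be); cytotoxicity labels are random subsets
  (HaCaT ~2 %, IEC-6 ~25 % of species), so the two D outcomes of a
  study-like run differ qualitatively.
- Planted causal peak: presence equals the activity vector with
  independent per-species flips at `flip_noise` (default 0.05).
- AND pair: the active set is noise-flipped once; component A covers it
  plus one half of the inactive species, component B the other half —
  the intersection reproduces the flipped active set while each component
  alone is a weak rater (κ ≈ 0.3 at the default prevalence).
- OR pair: the flipped active set is split into two disjoint halves, one
  per component; the union reproduces it.
- Background peaks: independent Bernoulli(0.2). Any all-present column
  has one entry cleared so the ubiquitous-peak filter never fires on
  synthetic data.
- Intensities: log₁₀-normal, σ = 0.3, mean 10⁵ when present and ~300 when
  absent, clipped to the correct side of the 10⁴ threshold so the
  presence call is exact by construction; only the binarized value
  matters downstream.
- Bioassays: active radii ~ N(0.9 cm, 0.05 cm) truncated at 0, inactive
  ~ N(0.2 cm, 0.05 cm); absorbances ~ N(1.0, 0.05) scaled by 0.5 for
  cytotoxic species. The noise levels are package choices — studies of
  this kind report means, not dispersions — sized so that classification
  is reliable but not deterministic.

Every generator is a pure function of (config, seed); one seeded
generator per call, no global state. What the generator does *not*
emulate: chromatographic artifacts, adducts/isotopes, retention-time
drift, correlated peak families from shared biosynthesis, or
dose–response structure. Passing recovery tests therefore show that the
screens find the planted contrast structure under label noise — not that
real LC-MS matrices satisfy these independence assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run at 87 species × 2,000 features
(~2·10⁶ pairs per screen), 50 seeds for recovery rates in the test suite
and 10 in the script, and 100–200 calibration replicates at 500
permutations — sizes chosen so the planted-recovery estimates are stable
while a complete run stays in the minutes range on one CPU. The pipeline
fans a single config seed into per-stage substreams
(`numpy.random.SeedSequence`), so stages can be rerun independently and
two runs with the same config are byte-identical. Ranking ties are broken
only by the shared-min-rank convention; record orderings use stable sorts
with feature-id tie-breaks for reproducibility.

## Known limitations

- The pair screen's outperformance cut-off is recomputed from the same
  inputs; it is a description of the screen, not an inference procedure
  with controlled error rates.
- Fisher-exact p-values treat species as independent; phylogenetic
  pseudo-replication is measured (via D) but not corrected for in the
  screen.
- The combined score is an unweighted difference; no claim of optimality
  is made for the 0.68 tier boundary, which is a field convention for
  "strong" agreement.
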