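# Methods

## Problem and model

A cell-line panel (NCI-60-style) is screened against many compounds; each
(drug, cell) pair has a log10 molar GI50 — the concentration inhibiting
growth by 50%. Higher GI50 means more drug is needed, i.e. *resistance*;
this convention is fixed throughout. The same panel has one expression
profile per cell line on a log scale. The analysis asks, per drug: which
genes separate resistant from sensitive lines, and does forcing expression
of a candidate factor (an induction experiment) move cells toward the
sensitive expression state?

## Sensitivity grouping

Two published rules are implemented side by side and never reconciled:

* **SD rule** (default): resistant iff `gi50 ≥ mean + 0.8·sd`, sensitive
  iff `gi50 ≤ mean − 0.8·sd`, with the sample (n−1) standard deviation
  over the drug's present values. Cells with missing GI50 are excluded
  from the mean/SD and from grouping only. Fewer than 3 present values:
  the drug is skipped (sample SD undefined at n<3 in any useful sense).
* **Fold rule**: resistant iff the GI50 is at least `fold` (default 6)
  times the per-drug average. Applied on the log10 scale,
  `|Δlog10| ≥ log10(fold)`, i.e. fold change relative to the geometric
  mean — concentrations are multiplicative, and GI50s arrive as log10.

Downstream analysis keeps drugs with ≥ `min_group_size` (default 6) cells
in *both* groups. With a degenerate threshold (multiplier 0, or all values
equal) strict inequalities apply, so cells exactly at the mean stay
unassigned and the groups remain disjoint.

`rank_cells_by_gene` provides the complementary view (top-k / bottom-k
cells by one gene's expression, default k = 15), with ties broken by cell
identifier so the partition is deterministic.

## The v statistic

For a two-group contrast, each gene gets a two-sided Student's t-test
P-value (equal-variance by default, per the method's description; Welch
selectable) and the sign `s` of the mean difference. The signed summary is

    v = s · (1 − P)  ∈  [−1, 1].

The source analysis references this transform without typesetting the
formula; `v = s·(1−P)` is the unique simple form consistent with every
stated property (bounds ±1 as P→0, direction from the mean difference,
magnitude increasing with significance). This adoption is a design
decision of this package, flagged here deliberately.

Degenerate genes: zero variance in both groups with equal means gives
P = 1, s = 0; zero variance with unequal means gives the smallest positive
float (logged). P-values are clipped to (tiny, 1] so v never reaches ±1
exactly except in that degenerate case.

## q-values

Storey–Tibshirani estimator: π0(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0, 0.05, …, 0.90; a natural cubic spline through these points is
evaluated at λ = 1 and clipped to (0, 1]. q-values are the running minimum
of π0·m·p/rank from the largest p down. With fewer than 100 p-values the
spline is unstable, so π0 falls back to 1, making the q-values exactly
Benjamini–Hochberg (this equivalence is tested against statsmodels).
Note the correct direction of the resulting bounds: q_i ≤ π0·m·p_i/rank_i
(it is a minimum over genes with larger p) and q_i ≥ π0·p_i.

An induction signature is the same machinery applied to induced-vs-control
replicate columns, reporting the number of genes up and down at
P < 0.01 **and** q < 0.10 (both defaults configurable). At 3 replicates
per arm the t-test has 4 degrees of freedom; the joint P/FDR filter then
has low power for moderate effects — with unit noise the filter only
approaches complete recovery for standardized effects around 6. The tests
assert sensitivity/specificity against planted truth in that regime.

## Gene-set random expectation

For a candidate set of k genes and a drug signature, O = members with
p < α (default 0.05). `n_random` (default 10) same-size sets are drawn
uniformly without replacement from all signature genes (the tested set is
not excluded from the pool — with ~2000+ genes the overlap effect is
negligible); E = mean count over those sets. The comparison is a 1-df
chi-square on the {differential, non-differential} split,

    χ² = (O−E)²/E + (O−E)²/(k−E),

with an exact two-sided binomial test (success probability E/k) reported
as a cross-check and a `reliable` flag set to False when an expected cell
is < 1. Under an exchangeable null the measured rejection rate at nominal
0.05 is ≈ 0.055 over 1000 trials (the E estimated from 10 sets adds ~10%
variance to O−E, slightly inflating the statistic). The per-drug
"at least one set gene differential" report is the minimum member p, not
a separate statistic.

## REM construction

The response engineering module for a drug is the set of genes passing
both criteria over the resistant/sensitive cells:

1. group separation: t-test p < α (default 0.05);
2. GI50 tracking: Pearson correlation of expression with log10 GI50
   across the union of the two groups, two-sided p < α via the t-transform
   `t = r·√((n−2)/(1−r²))` (Spearman selectable).

Correlation is computed over the *grouped* cells only, not the whole
panel: the criteria describe the grouped cells, and the grouped-only
choice is switchable (`correlation_with_gi50` accepts any cell subset).
`v_rem` is signed resistant-minus-sensitive, so positive means higher in
resistant. No multiple-testing correction is applied inside REM
construction (the stated criteria are per-gene significance); group-test
q-values are reported alongside for transparency.

**Warning on the dual criteria:** for null genes the two test statistics
are strongly dependent (the group indicator and GI50 are correlated by
construction of the groups, ρ ≈ 0.95 for planted 3-SD tails), so the
probability that a null gene passes both is ≈ 0.7·α, not α². REM size on
null data is therefore bounded by ~5·α of the background, and the
false-discovery *proportion* of a REM is not controlled at α — callers
who need FDR control should filter on the reported q-values.

## Signature comparison

A factor signature is matched to a REM by Pearson correlation of the
paired v-vectors over the REM genes (whole-transcriptome correlation is a
diagnostic, not the headline). Calls at α = 0.001 (the evidence level the
original analysis reports): r < 0 → sensitization on induction, r > 0 →
sensitization on repression, otherwise no call. Zero variance in either
vector yields no call with a logged reason.

Because REM genes pass a significance filter, their v-values saturate near
±1; the correlation of two saturated v-vectors behaves like a
sign-agreement statistic. When shifts are generated with population
correlation c against a saturated v-vector, the expected estimate is
`1 − 2Φ(−|c|/√(1−c²))·sign(c)` — e.g. −0.893 for c = −0.85 — not c itself.
This bias is intrinsic to correlating bounded significance-transformed
vectors and is documented rather than corrected.

## Clustering and heatmaps

Two-dimensional unsupervised hierarchical clustering with average linkage
on the uncentered-correlation distance
`d(x,y) = 1 − Σxy/(√Σx²·√Σy²)` — the convention of the classic Eisen-lab
clustering tool the original analysis names. Distances are
pairwise-complete, so missing GI50 entries are tolerated; rows/columns
without ≥2 complete overlaps with every other are dropped with a log
message. Inputs are pre-sorted lexicographically before linkage so leaf
order is a pure function of the values. Rendered heatmaps paint missing
cells white.

## Synthetic data: what it emulates and what it does not

* **Dose–response**: per drug, a Gaussian core on the log10 GI50 scale
  (μ ~ U(−8,−5) log10 molar, σ ~ U(0.3,0.8) — typical screen ranges) with
  ⌈tail_fraction·n⌉ cells shifted ±tail_shift·σ (defaults 0.15 and 3).
  The Gaussian-plus-tails shape is the minimal model consistent with
  t-tests and the SD rule; the 0.8-SD classifier recovers ≥90% of planted
  labels at the defaults.
* **Expression**: background iid Normal(0, σ); each planted gene gets a
  mean shift ±effect in its drug's planted-resistant cells plus a term
  proportional to each cell's standardized GI50 (coupling effect/2), so
  planted genes are discoverable by both REM criteria.
* **Induction**: per-gene shifts `c·ṽ + √(1−c²)·sd(ṽ)·ε` rescaled to unit
  SD (log-scale fold changes of order one), plus within-arm replicate
  noise 0.25 — technical replicates vary much less than induction
  effects. Population correlation with the v-vector is exactly c.

Not emulated: probe-level artifacts, batch effects, missing expression
values, non-Gaussian heavy tails in expression, dose–response curve
fitting, or correlated gene modules. A green planted-recovery test
therefore establishes correctness of the statistical machinery under the
stated model, not robustness to real-array pathologies.

Default desk scale is 60 cells × 200 drugs × 2000 genes (the real screen
is ~60 × 1400 × 47k); the full pipeline at desk scale runs in well under a
minute, and all generators are deterministic given their seed.

## Numerical choices and edge cases

* Sample SD everywhere (ddof = 1); t-tests via scipy; Pearson p via the
  exact t-transform (matches `scipy.stats.pearsonr` to 1e−10).
* Sorting is always stable (mergesort) and ties break on identifiers.
* Output files use `%.10g` float formatting and sorted JSON keys, making
  pipeline runs byte-identical for fixed (inputs, config, seed).
* Genes with any missing expression value in a contrast are dropped from
  that contrast; missing GI50 drops the cell from that drug only.
* Matrix orientation is fixed (drugs × cells, genes × samples) and never
  guessed; mismatched identifiers fail loudly.

## Known limitations

* The v formula is an adopted reconstruction (see above), not a verbatim
  transcription of the source method.
* The REM false-discovery proportion is uncontrolled by design (see the
  dual-criteria warning); published headline counts (e.g. 1115/1400 drugs,
  59% significant set differences) depend on undeposited data and are not
  reproduction targets.
* The chi-square null test treats the random-set expectation E as known;
  with 10 random sets its estimation noise mildly inflates the statistic.
* Per-contrast (not global) FDR is used for the induction filter.
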