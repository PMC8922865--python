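# Methods

## Model and assumptions

The package dichotomizes a single sample's worth of non-negative continuous
variables into low-value background and a dominant high-value shortlist.
The only modelling assumption is about curve shape: sorted ascending and
plotted against integer rank, the values form a biphasic curve — a long,
slowly growing first phase and a short, rapidly growing second phase — and
the boundary between the phases is biologically meaningful (a small number
of high-value variables dominate the system). The method is purely
geometric and makes no distributional assumptions beyond that shape; it
should not be applied to curves that are visibly not biphasic (flat,
sigmoid, multimodal), and it expects the *complete* list of variables, not
one already filtered by another threshold.

Ranks are 1-based and the chord is fit through `(1, V_min)` and
`(N, V_max)`, so `m_B = (V_max − V_min)/(N − 1)` and `b_B = V_min − m_B`.
For data whose minimum is zero this gives `b_B = −m_B`, i.e. a chord of the
form `y = m x − m`.

## Distance computation

Three algebraically identical formulations are implemented:

* **Stepwise** (`segment_length_stepwise`): construct the perpendicular
  line through the curve point, intersect it with the chord, apply the
  Pythagorean theorem. Used as an independent oracle in tests.
* **Closed form** (`segment_length_closed`): the single-expression
  formula obtained by substituting the construction into the Pythagorean
  theorem, evaluated exactly as written. Also an oracle.
* **Simplified** (`distance_profile`): `|V − m_B R − b_B| / sqrt(1 + m_B²)`,
  the standard point-to-line distance. This is the production path: it is
  vectorised, avoids the intermediate cancellation of the other two routes,
  and shares one denominator across all ranks (which is what makes the
  argmax affine-invariant).

The three agree to better than 1e-12 relative error over wide random input
ranges (the acceptance script measures this at every run).

## Cutoff, ties and degenerate inputs

* The cutoff rank is the argmax of the distance profile. The shortlist is
  strictly above the cutoff: cutoff rank `k` out of `N` gives the `N − k`
  records ranked `k+1 .. N`. The cutoff record itself is *not* shortlisted;
  this off-by-one convention is load-bearing and pinned by tests.
* **Argmax ties** are resolved to the largest rank — the smallest, most
  stringent shortlist — and only exact binary equality counts as a tie;
  `tie_count` in the result reports how many ranks tied. Near-ties are not
  collapsed.
* **Value ties** in ranking are broken by identifier (lexicographic), so
  ranking is deterministic across runs, platforms and input orders.
* **Flat profiles** (all values equal) raise a degenerate-profile error:
  the chord is horizontal, the perpendicular construction is undefined, and
  a flat curve has no bending point. Profiles with fewer than 3 records
  raise a size error.
* A **perfectly linear profile** has all distances exactly 0; under the
  tie rule the cutoff lands on rank N with an empty shortlist and
  `tie_count = N`, which is the honest answer for a curve with no bend.
* Zero-valued records participate in the cutoff computation (they are part
  of the curve) but are excluded from the low-tail control list. A
  `--drop-zeros` CLI flag exists for users who want them gone; it is off by
  default.

## Stringency offset

The geometric cutoff is a reproducible reference point, not a sacred
threshold. `adjust_cutoff` shifts it by a signed fraction of N:
`k' = clamp(round(k + offset·N), 1, N)`, with the unadjusted rank always
retained as `reference_rank`. "Fraction of N" was chosen over "fraction of
the shortlist" or "fraction of k" because it is the only reading that is
symmetric, scale-free and bounded; it is an extension beyond the core
method and is labelled as such in the results. Rounding is half-away-from-
zero so the shift does not depend on the platform's banker's rounding.

## Truncation sweep

Low-abundance variables drop in and out of real datasets by detection
chance. The sweep removes the lowest-ranked records in fixed increments
(default 1,000 records; `--increment-frac` for small datasets), re-ranks,
re-fits the chord and recomputes the cutoff from scratch at each step — no
incremental shortcuts, and a test asserts each step equals an independent
fresh computation. Stability is judged on **shortlist identity as an
identifier set**, the biologically meaningful output; the per-step cutoff
identifier, original-coordinates rank and shortlist overlap fraction are
all emitted so rank-based or gene-based readings of stability can be
inspected as well. The sweep stops before the remainder falls below 3
records or becomes flat.

## Synthetic data

The generator produces the two simplest families matching the biphasic
description, with exact ground truth:

* **piecewise-linear** (default): slope `s1` up to the knee rank, slope
  `s2 > s1` after it. On these, the maximum distance from the chord to a
  convex two-segment polyline is attained at the junction vertex, so the
  cutoff recovers the knee *exactly* — the basis of the knee-recovery
  acceptance check.
* **piecewise-exponential**: `expm1(r·steps)` growth per phase, for curves
  whose bend is smooth rather than angular.

Defaults (`n = 16,353`, knee at rank 15,778, `s1 = 0.002`, `s2 = 1.0`,
noiseless) mirror the scale and knee position of a whole-transcriptome
consensus expression table, giving a 575-member shortlist and a chord slope
near 0.036.

Noise is additive Gaussian on the values *before* ranking — ranking is part
of the method under test — and negative values are clamped to zero,
consistent with abundance data. What the generator does **not** emulate:
count-based sampling noise, normalization artefacts, the heavy right tail
of real expression data within each phase, or correlated dropout. Passing
tests therefore demonstrate geometric correctness and robustness of the
pipeline, not performance guarantees on any particular real dataset.

### Noise characterization (regression baseline)

With additive noise at 5% of the second-phase amplitude (n = 5,000, knee at
4,500, 200 seeded replicates) the recovered cutoff stays within 2.5% of n
of the true knee in every replicate and within 1.5% of n in ≥ 95% of them;
localization within 1% of n in ≥ 95% of replicates requires noise at or
below about 2% of the phase-2 amplitude. These figures are frozen as a
regression baseline for this generator and say nothing about real data.

## Problem sizes

The test suite and acceptance script use synthetic profiles up to
n = 50,000 (knee-recovery sweep), the n = 16,353 default profile, and
truncation sweeps on profiles of 500–10,000 records — sizes at which every
check runs in seconds while still exercising transcriptome-scale
arithmetic.

## Known limitations

* The method assumes exactly one bend; on curves with several regime
  changes it reports only the globally farthest point from the chord.
* The cutoff depends on the two endpoint values through the chord, so a
  single extreme outlier at either end moves the chord and can move the
  cutoff. No outlier handling is applied — inputs are taken as given.
* Stability percentages from the truncation sweep are conditional on the
  removal being exactly the lowest-valued records; random dropout would be
  noisier.
* Duplicate identifiers are rejected rather than aggregated: an
  aggregation rule (sum, max, mean) would be a biological choice the tool
  has no basis to make.
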