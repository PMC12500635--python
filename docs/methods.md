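# Methods

## The Kano classification model

A Kano survey measures how a service item drives satisfaction by asking a
functional and a dysfunctional question about it, each on the five-level
scale 1 = Like, 2 = Take it for granted, 3 = Indifferent, 4 = Reluctant,
5 = Dislike. The pair of codes indexes a fixed 5×5 evaluation matrix
(rows = functional answer, columns = dysfunctional answer) whose 25 cells
hold exactly 1 O, 3 M, 3 A, 9 I, 7 R and 2 Q entries. The two Q cells are
the self-contradictory corners (Like/Like, Dislike/Dislike); the R cells
are the patterns where the respondent prefers the item absent.

Per item, the modal category over respondents is the item's attribute.
Two modelling choices are ours, as the modal rule alone is underspecified:

- **Tie precedence M > O > A > I > R > Q.** Misclassifying a must-be item
  is the costliest error for service planning, so ties resolve
  conservatively toward M; tied assignments are additionally flagged.
- **Instability flag.** An assignment whose top-two category margin is
  below 5% of the item's pair count (`unstable_margin`, tunable) is
  flagged so reports surface items whose attribute is effectively
  undecided at the realised sample size.

R and Q compete in the modal rule (they are excluded only from the
coefficient denominators, not from classification); an item whose mode is
R or Q is reported as such with a warning rather than silently reassigned.

## Coefficients, sensitivity, screening

With per-item counts A, O, M, I (R, Q excluded from numerator and
denominator):

- Better / SI = (A + O) / (A + O + M + I) ∈ [0, 1]
- Worse / DSI = −(O + M) / (A + O + M + I) ∈ [−1, 0]

An item answered only with R/Q patterns has an undefined coefficient; the
functions raise and the estimator surface reports the item as flagged
rather than imputing.

The sensitivity R = √(Better² + Worse²) ∈ [0, √2] is the Euclidean norm of
the item's position in the SI–|DSI| plane. Items are ranked by descending
R; exact ties (absent in realistic data) break lexicographically on item
id and are flagged. Screening uses two origin-centred quarter arcs with
the conventional radii 0.707 (≈ √2/2, element line) and 1.061 (≈ 3√2/4,
key-element line), stored exactly as the printed three-decimal constants
rather than the surd forms so that reported distances match published
practice; both are configurable. The perpendicular distance from a point
to an origin-centred arc is the radial difference, so the signed
`distance_to_key_line` is R − 1.061: positive means "right of the
key-element line", i.e. immediate-improvement priority. Zones are
exhaustive and exclusive: *key* for R > 1.061, *element* for
0.707 < R ≤ 1.061, *deferred* otherwise (boundaries closed on the inner
side).

Internal computation is in fractions throughout; two-decimal percent
rendering happens only at the reporting layer (JSON reports keep full
precision alongside).

The packaged 43-item instrument ships with its published attribute and
coefficient table (`data/table4_fixture.csv`, percent strings parsed to
fractions on load, content hash pinned in the tests). One known wrinkle:
the published per-item sensitivity for D2 prints as 91.50% while
recomputation from its printed two-decimal coefficients gives 91.48% —
the original computation evidently used unrounded inputs. Tolerances in
the tests (±0.0005 on fractions) absorb exactly this display-rounding
effect. A second wrinkle: the source prose lists item C6 under two
attribute groups; the fixture follows the printed table (C6 = A).

## Reliability diagnostics

Implemented from closed forms on a respondents × items score matrix
(listwise deletion of incomplete rows; sample n−1 variance convention,
which cancels in α):

- **Cronbach's α** = k/(k−1) · (1 − Σᵢ var(itemᵢ) / var(total score)).
- **KMO** = Σ r²ᵢⱼ / (Σ r²ᵢⱼ + Σ q²ᵢⱼ) over i ≠ j, with anti-image
  partial correlations qᵢⱼ = −Sᵢⱼ/√(SᵢᵢSⱼⱼ), S = R⁻¹. For k = 2 the
  partial correlation equals the correlation, so KMO = 0.5 identically —
  a useful analytic test point. Correlation matrices with condition
  number above 1e10 are rejected as singular.
- **Bartlett's sphericity** χ² = −(n − 1 − (2k+5)/6) · ln det R with
  df = k(k−1)/2, upper-tail p from the χ² distribution (requires n > k
  and a positive determinant).

Interpretation bands use left-closed intervals: α — below 0.6 revise,
[0.6, 0.7) acceptable, [0.7, 0.8) good, ≥ 0.8 excellent; KMO — below 0.7
inadequate, [0.7, 0.8) acceptable, [0.8, 0.9) good, ≥ 0.9 excellent. The
reference instrument's reported values (α = 0.905, KMO = 0.759,
χ² = 6830.828) are documentation metadata only: its raw respondent-level
data are not publicly deposited, so those numbers cannot be recomputed
here and are not test targets.

Which score enters the matrix is an assumption: the pipeline uses the
functional-question codes (one column per item). The module accepts any
wide numeric matrix if a different convention is wanted.

## The synthetic panel generator

No response-generating model accompanies the evaluation matrix, so the
generator is defined by inverting it. Each item carries a designed
substantive attribute (M, O, A or I; R/Q arise only through noise). A
noise-free respondent answers with a cell drawn uniformly from the cells
classifying to that attribute — 3 cells for M, 1 for O, 3 for A, 9 for I;
these sets partition the 16 substantive cells. With per-pair probability
`noise_rate`, each of the two codes is instead replaced by an independent
uniform draw over 1–5, which generates R and Q patterns at a controllable
rate. One `numpy` generator seeded per call; identical configurations
yield byte-identical panels.

Defaults follow the 5–10-respondents-per-item design heuristic (215–430
for 43 items); the CLI default of 240 respondents matches the realised
panel size typical for this instrument. The default per-pair noise of 0.1
is a deliberately moderate corruption level: high enough to exercise the
R/Q paths and the instability flags, low enough that modal recovery of
the designed attributes is near-certain at the default sample size
(measured in the test suite: all 43 attributes recover in ≥ 95% of seeds
at n = 240, noise 0.15, and mean recovery degrades monotonically as noise
grows toward 1).

What the generator does **not** emulate: inter-item correlation induced
by respondent-level traits (each item's answers are independent given the
design), demographic covariates, non-response, and ordinal
response-style effects. Consequently reliability statistics computed on
synthetic panels sit near their null values (α ≈ 0, KMO < 0.5) — passing
pipeline tests demonstrate the statistics' correctness on analytic cases,
not that synthetic data resemble a real instrument's correlation
structure.

## Numerical and interface choices

- Ranking sort is stable (mergesort) with an explicit item-id tie key, so
  output order is deterministic across platforms.
- Percent strings in fixtures tolerate the typographic minus (−) and are
  parsed exactly (two-decimal precision preserved through division
  by 100).
- The estimator layer follows the scikit-learn protocol (`fit`,
  `get_params`/`set_params`, trailing-underscore fitted attributes,
  `check_is_fitted`), so the components clone and compose with sklearn
  tooling; module-level functions remain thin wrappers for script use.
- The better–worse quadrant figure draws reference lines at 0.5 on both
  axes; this is a presentation convention only and no analysis depends on
  it.
- Problem sizes in the test suite (panels of 200–240 respondents, 5–20
  seeds per stochastic check) were chosen as the smallest sizes at which
  the checked properties are stable across seeds.

## Known limitations

- The modal rule ignores within-respondent consistency beyond the Q
  category; no respondent-level quality filtering is implemented.
- Weighted/fuzzy Kano variants, category-strength statistics and ordinal
  IRT response models are out of scope.
- The screening radii are treated as opaque conventional constants; no
  derivation is claimed for them.
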