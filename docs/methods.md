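# Methods

## The LDFN calculus

An LDFN ⟨(φ, ψ), (ϱ, σ)⟩ with exponent q ≥ 1 must satisfy ϱ^q + σ^q ≤ 1 and
φϱ^q + ψσ^q ≤ 1.  Since φ, ψ ≤ 1 the mixed constraint is implied by the
reference constraint; both are still checked independently (tolerance 1e-9,
with clamping of components within 1e-9 of [0, 1]) so that error messages can
name the inequality a caller actually wrote down.  All arithmetic requires a
common q across operands; mixed-q expressions are rejected rather than
coerced.

The score function ((φ−ψ) + (ϱ^q−σ^q))/2 gives grade and reference
differences equal say; ±1 is attained only by the crisp values (1,0,1,0) and
(0,1,0,1).  Ties are broken by accuracy ((φ+ψ) + (ϱ^q+σ^q))/2 and then
lexicographically, making `compare` a genuine total order — needed because
the pipeline's ideal-solution steps take per-cell argmax/argmin and must be
deterministic.  The complement swaps grades and swaps references, which
preserves both constraints, is an involution, and negates the score.

Hesitancy is defined as π = 1 − (φϱ^q + ψσ^q), the slack of the mixed
constraint.  It is the only natural candidate guaranteed to lie in [0, 1]
for every valid LDFN, and it is complement-invariant, which in turn makes
the entropy measure complement-invariant.

## Copula engine

All five families evaluate C(x, y) = ϑ⁻¹(ϑ(x)+ϑ(y)) from the generator; no
closed-form copula expressions are hard-coded, so every downstream operator
(binary laws, scalar laws, weighted aggregation) shares one numerical path.
Generators return +inf at 0 where the limit diverges, and the pseudo-inverse
clamps arguments beyond ϑ(0) to 0, which makes C(x, 0) = 0 exact and makes
crisp components absorbing under aggregation.  Two conventions depart from a
literal reading of the family table:

- **Clayton** uses ϑ(x) = (x^−λ − 1)/λ.  For λ > 0 this is a positive
  rescaling of x^−λ − 1 and induces the identical copula (generators are
  unique only up to a positive factor); for λ ∈ [−1, 0) the unscaled form is
  increasing and negative — not a generator at all — while the scaled form
  is valid and completes the family's stated domain.
- **Frank** uses ϑ(x) = −ln((e^{−λx}−1)/(e^{−λ}−1)); without the minus sign
  ϑ(1) = 0 holds but ϑ is non-positive and increasing.  Below |λ| < 1e-5
  the closed form degenerates to 0/0 and the engine switches to the λ → 0
  limit, the independence generator −ln x; continuity across the switch is
  tested.

Axioms (boundary conditions, 2-increasingness on a 20×20 grid, Fréchet
bound) are verified per family over a λ grid at 1e-9 tolerance.

## Aggregation operators

LDFWCA computes each output component as ϑ⁻¹ of a weight-convex generator
sum; zero-weight terms are skipped before the sum so that 0 · ∞ from a crisp
component cannot poison it.  Weights must sum to 1 within 1e-9 — callers
normalize explicitly.  The ordered variant (LDFWOCA) sorts inputs by
descending `compare` before applying position weights, which buys
permutation invariance; the hybrid variant (LDFWHCA) pre-scales each input
by cop_scalar(n·wᵢ) (a zero weight maps to the additive neutral (0,1,0,1))
and then applies the ordered operator.  These two constructions follow the
standard OWA/hybrid pattern; only the plain weighted operator has a stated
defining formula, so the variants are design choices documented here.

Verified operator laws: cop_scalar(n, L) equals the n-fold cop_add chain
(n ≤ 5, all families, 1000 seeded random values, deviation < 1e-8);
additivity cop_scalar(α+β) = cop_scalar(α) ⊕ cop_scalar(β); idempotency,
boundedness and componentwise monotonicity of LDFWCA; and the product-copula
reduction to the classical weighted average (< 1e-6 on 1000 seeded weighted
panels, with Clayton λ = 1e-6 standing in for the λ → 0 limit — the limit
converges at rate (λ/2)·Var(ln component), so the check samples components
on the 0.1–0.9 scale used by the benchmark's elicitation tables, where that
bound is below the tolerance).

## Distance and entropy

The generalized distance averages the four componentwise absolute
differences with prefactor 1/(4n) and applies the 1/Υ power; Υ = 1, 2, ∞
give Hamming, Euclidean and Chebyshev.  The weighted form defaults to the
literal convention that keeps the 1/(4n) prefactor **and** the convex
weights (`strict=True`), which double-normalizes: uniform weights then give
gdm/n^(1/Υ), not gdm.  The conventional 1/4-only form is available with
`strict=False` and is the one under which uniform weights collapse to the
unweighted distance.  The pipeline uses the literal form throughout so that
its numbers are self-consistent; switching conventions rescales DIS⁺ and
DIS⁻ by the same factor and therefore leaves every RCI, FC and ranking
unchanged for Υ-homogeneous weights — the choice matters only if distances
are compared across differently sized collections.

Entropy is the mean over elements of (1 − d(I, Iᶜ))·(1 + π)/2 with d the
single-element Hamming distance.  Crisp elements score 0, the maximally
fuzzy (0.5, 0.5, 0.5, 0.5) scores 0.75, and the measure is
complement-invariant.  The (1+π)/2 factor is applied per element (the
hesitancy subscript is on the element, and a collection-level π would make
single-element entropies depend on unrelated elements).

## Pipeline choices

- **Phase 3 runs per expert** by default, merging only at the final
  closeness FC = Σ w_k·RCI_k.  The collective variant (aggregate experts
  into one matrix with w_k before phase 3) is available via
  `collective_phase3=True`.  The per-expert route is the one whose published
  closing arithmetic is internally consistent (below).
- **RCI denominator** is DIS⁺ + DIS⁻ (the standard TOPSIS relative
  closeness); 14 of the 15 reported RCI values reproduce exactly under the
  sum and none under a product.
- **Criterion entropy** is the mean over alternatives of per-cell entropies
  of the expert-weighted aggregate's column; γ_j = (1−E_j)/(m − ΣE_j) with m
  the number of criteria (the count that makes Σγ = 1 for any shape).
- **PIS/NIS select existing cells** (per-column score argmax/argmin of the
  γ-rescaled matrix), not synthetic componentwise ideals, so distances are
  always to realizable profiles.
- **Degenerate cases**: an expert whose matrix coincides with all three
  ideals (e.g. a panel of identical matrices) gets closeness index 0.5 with
  a warning, so identical experts receive uniform weights; an alternative at
  zero distance from both PIS and NIS gets RCI 0.5 with a warning; final-
  closeness ties are broken by label order with a warning.
- **Defaults**: Clayton (family 2) with λ = 1 — the family in which the
  aggregation steps' closed forms are stated — and Hamming distance (Υ = 1);
  default reference parameters (0.5, 0.5) for pair-only inputs, the largest
  symmetric pair valid at q = 1, admitting every grade pair.

## The benchmark and what it can certify

The embedded case study (3 experts × 5 classifiers × 5 benefit criteria,
grades on a 0.1–0.9 scale, pair-only cells) exercises the full pipeline, but
its original run did not record λ, Υ, the score convention, or the origin of
the constant 0.302 reference components in its aggregated table, and several
of its intermediate tables contradict one another (a right-ideal entry that
is not among the candidate cells; one RCI and one FC entry inconsistent with
their own inputs).  End-to-end reproduction of the intermediate tables is
therefore not attempted.  What *is* reproduced, exactly at the reported
rounding, is the closing arithmetic that follows from printed inputs alone:
the third expert's weight (0.3452) from the closeness indices, P1's
per-expert relative closeness (0.697 / 0.695 / 0.308) from the reported
ideal distances, and the final closeness of P1/P3/P5 (0.562 / 0.515 /
0.590) from the reported weights and relative closeness.  Whether the
default configuration also puts P5 first, as originally reported, is logged
but not asserted (under Clayton λ = 1/Hamming the top pick is P1, with P5
second).

## Synthetic panels

`random_panel` draws reference pairs uniformly from the simplex
ϱ^q + σ^q ≤ 1 and grades uniformly subject to the mixed constraint (both by
rejection), with random benefit/cost senses — i.e. maximal-entropy valid
input, reproducible by seed.  Real elicitation data differ: grades cluster
on coarse scales (multiples of 0.1), references are panel-wide constants,
and criteria correlate.  Passing the property suite on such panels certifies
the algebraic contracts (validity closure, weight normalization, bounded
closeness, equivariance) on arbitrary valid input, not decision quality on
any particular domain.

## Problem sizes

Tests run on panels up to 5×5×3 (the benchmark's size) and Monte Carlo
batches of 10^3–10^4 values; the acceptance script uses the benchmark plus
one seeded 5×5×3 random panel.  These sizes are where the method is
intended to operate — expert panels are small by nature — and keep the full
suite under a few seconds.
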