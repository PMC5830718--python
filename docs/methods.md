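# Methods

## Decoding error and the uniformity criterion

A bin `[a, b]` holding `m` sorted members is decoded by the expected order
statistics of `m` i.i.d. uniforms, `a + (b−a)k/(m+1)`.  The decoding error
sum of squares is the expected squared reconstruction error

    DESS = m(b−a)²/(6(m+1)) + Σ_k [x_(k) − (a + (b−a)k/(m+1))]² ,

the first term being the summed order-statistic variances (the identity
`Σ_k Var[X_(k)] = m/(6(m+1))` scaled by `(b−a)²`).  Its exact mean under
uniformity is `(b−a)² m/(3(m+1))`.  The criterion used everywhere is
one-sided with multiplicative slack τ (default 0.25):

    satisfied  ⇔  DESS ≤ (1+τ) · (b−a)² m/(3(m+1)) .

One-sided because only a too-*large* DESS motivates subdivision; the exact
finite-m mean (not the 1/3 limit) removes small-m bias.  Bins with `m = 1`
or zero range (ties) have DESS 0 and always satisfy the criterion.
Boundaries default to the bin's empirical min/max.

**A calibration fact worth knowing:** DESS does not concentrate.  As
`m → ∞`, `DESS → 1/6 + ∫₀¹ B(t)² dt` in distribution (B a Brownian bridge),
a nondegenerate law with mean 1/3 and standard deviation ≈ 0.149.  The
τ = 0.25 band therefore passes a truly uniform bin with asymptotic
probability ≈ 0.86 — *independent of m* — and every downstream "recovers
exactly k bins" rate inherits that ceiling (measured ≈ 0.70–0.76 for
one-part and two-part recovery).  Detection of a true, wide gap is
unaffected (measured 100/100 on the canonical two-part mixture): extra
splits may occur, but the gap itself is always flagged.  Tests assert the
rates this package actually achieves, not idealised ones.

## Energy and the tree-guided search

The energy of a contiguous partition is `H = Σ DESS_j + L0·(B−1)`, charging
`L0` per interior boundary; gap spins carry no energy (gaps are decided
afterwards by the gap tests).  `L0` defaults to 0.1 × the root merge height
of the clustering tree and is compared against raw-scale DESS.  The search
walks the agglomerative tree (complete, average or ward linkage; single
linkage rejected) from the root in strictly decreasing merge height, ties
broken by leftmost segment.  A node is STOP-marked when its segment's DESS
is below `L0` or the uniformity criterion passes; otherwise its children
become active.  The STOP-marked segments are the bins (coarsest
histogram).  `refine()` optionally bifurcates any bin with DESS > L0 along
the stored branches; on the canonical two-part mixture at n = 12 the
refined histogram's energy is within 10% of the exhaustive optimum (worst
observed ratio 1.03 over 50 seeds).  An ad-hoc family with unequal part
widths ([0,1] vs [2,4]) shows the bound is family-dependent (worst ≈ 1.18):
the tree can only cut where branches exist.

1-D contiguity of every inter-node is asserted when the tree is built: for
the admissible linkages on the line, merges always join adjacent clusters.

## Gap confirmation

Extended boundaries come from the extreme order statistics: the expected
shortfall of the minimum/maximum of `m` uniforms is `(b−a)/(m+1)`, so
`â = x_(1) − r/(m+1)`, `b̂ = x_(m) + r/(m+1)`.  The default "extension" test
declares a gap when facing extended boundaries do not cross.  Note its
intrinsic operating characteristic: for two *contiguous* parts (no hole)
the shortfalls are asymptotically Exp(r/(m+1)), so "no gap" is concluded
with probability `P(E₁+E₂ ≤ 2μ) = 1 − 3e⁻² ≈ 0.594`, not ≈ 1.  The
"midpoint" alternative (re-check uniformity after forcing the shared
mid-point boundary) is slightly more lenient (≈ 0.68).  Both are exposed;
extension is the default for determinism.  Wide gaps (width ≫ r/(m+1)) are
detected essentially always.

## Phase 1 (entropy comparison)

Natural-log entropy; the ratio divides by the entropy of the treatment
sample sizes.  P-values are one-sided lower-tail (small entropy =
segregation), reported both as the raw proportion (exact zeros allowed) and
as the add-one estimate `(#{≤}+1)/(M+1)`.  Bin-level draws are simple random
samples without replacement from the pooled labels; the overall statistic
`Σ (m_k/n) H_k` uses full label permutations.  All sampling is driven by an
explicit `numpy` Generator seed, bit-reproducible.

## Phase 2 (authenticity)

The reference tree is built on row frequencies P (Euclidean distance,
complete linkage by default; the mimicked count matrices `n_j·P̂` row-
normalise back to `P̂`, so reference and mimics are compared on the same
scale).  Mimicked rows are `p + W/√n_j` with `W = G − p·ΣG`,
`G_k ~ N(0, p_k)` independent: `Cov(W) = diag(p) − p pᵀ` exactly, every row
sums to one exactly (to float rounding, ≤ 2 ulp), and zero cells stay zero.
Negative mimicked frequencies are retained — distances remain well defined
and the Gaussian law stays exact.  Rank-digits are ascending-height ranks of
the J−1 merges (ties by merge order).  Two branch indices are reported,
because "re-appears together" is ambiguous:

* **authenticity** — the smallest mimic branch containing the reference
  branch's leaves has rank-digit ≤ the reference rank-digit;
* **clade recovery** — the leaf set re-appears exactly as a branch.

The root's authenticity is 1 by construction.  Identical rows produce a
zero-height tree and a warning.

## Right-censored extension

Ties order events before censorings (the underlying laws are assumed
continuous; the convention only matters on discretised data).  Kaplan–Meier
is computed per ordered observation, `S = Π(1 − δ_(i)/(n−i+1))`; its jumps
are the redistribution-to-the-right masses and sum to `1 −` (residual tail
mass).  The censored histogram builds bins on event times only and
re-weights them by those masses.  The variance integral uses the plug-in
`n Σ δ_(i)/((n−i)(n−i+1))` over `(t_lo, t_hi]`, dropping the `i = n` term
(Greenwood-type guard); with no censoring it telescopes to
`F_n/(1−F_n)`, which is what makes `Σ#` reduce *exactly* to the
Brownian-bridge plug-in `F(t_i)(1−F(t_j))` on complete data.  Boundaries
beyond the last event trigger a warning and carry the last value forward.
Phase-2 rows are raw KM decrements or NA increments, *not* renormalised
(KM masses need not sum to one under heavy censoring; renormalising would
destroy the covariance scaling).  KM mimicking samples
`N(0, A⁻¹Σ#A⁻ᵀ/n_j)` through an eigen-decomposition with negative
eigenvalues clipped at 0 (they arise only from float rounding); the NA
basis has independent increments and is sampled directly.

## Synthetic data

`gen_gapped_mixture` draws i.i.d. from ordered, disjoint uniform parts —
exactly the generative model the histogram assumes; what it does *not*
emulate is smooth densities, heavy tails, or measurement rounding, so a
green recovery test establishes correctness of the search, not robustness
to model misfit.  `gen_censored` uses independent exponentials
(censoring probability `λ_C/(λ_T+λ_C)`; 2/3 at `λ_C = 2λ_T`, the heavy
regime of interest) with hooks for arbitrary samplers.  The 150-flower Iris
table ships as an in-repo CSV (public domain) so nothing is downloaded.

## Known limitations and an unreproducible published value

* The Iris worked values: with standardisation (ddof = 1) and the stated
  extension formula, the two published right boundaries reproduce to
  ≈ 0.010 and ≈ 0.015 absolute; the two published *left* boundaries
  (−0.5127225, −0.3240107) match no contiguous segment of the standardized
  sample under any of six extension-denominator variants and either
  standardisation divisor (exhaustive search over all segments).  They
  appear to stem from an unreproducible convention in the original
  analysis; the corresponding checks in `tests/test_acceptance.py` fail by
  design rather than being loosened.  The gap verdicts themselves (the
  non-crossing conclusions) reproduce exactly.
* The search is heuristic: energies are near-optimal along tree branches
  only (see above).
* No left truncation, interval censoring, or covariate adjustment.
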