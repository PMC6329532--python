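# Methods

## The model

The input to the statistics layer is a *binary ranked array*: `L` elements
ordered by descending direct-coupling score, `D` of them distinguished
(structural contacts under the active contact definition) and carrying
distance ranks `1..D` (1 = closest). Two independent questions are asked of
it.

**Where do the contacts cluster?** The initial-cluster model assumes the
distinguished elements fall with one rate before an unknown cut `X` and
another after it, against the null of a single uniform rate. For a cut at
position `X` with `d` distinguished elements at or before it, the
log-likelihood ratio is

    Λ(X) = ln Bin(d; X, d/X) + ln Bin(D−d; L−X, (D−d)/(L−X))
         − ln Bin(d; X, D/L) − ln Bin(D−d; L−X, D/L)

constrained to `d/X ≥ (D−d)/(L−X)` (a *depleted* head is never reported as
a cluster; Λ = 0 there). Cuts are only evaluated at distinguished
positions: moving a cut right past a run of '0's can only dilute the head,
so the tail probability is locally minimal at '1's. Likelihoods at nearby
cuts are strongly correlated; the density of effectively independent trials
grows roughly as the reciprocal of the cut's distance from either end, so
the selection objective is the flattened-prior form

    Λ(X) − ln(1/X + 1/(L−X)),

whose argmax is invariant to the density's overall scale. Ties resolve to
the smallest `X` (compact clusters, deterministic output). The raw
significance of the chosen cut is the hypergeometric tail
`P_a,raw = P[≥ d distinguished among X draws from L with D distinguished]`.

**Are the contacts inside the cluster the close ones?** Rank information is
deliberately excluded from cut selection and recovered by a ball-in-urn
statistic: the `d` best-ranked of the `D` distinguished elements are
coloured red, `R` counts reds among the `d` left-distinguished elements,
and `P_b` is the hypergeometric probability of at least `R` reds when `d`
balls are drawn from an urn of `D` containing `d` reds. Under the null the
ranking is independent of the positions, so `P_a` and `P_b` are independent
and combine exactly as `P_J = q(1 − ln q)`, `q = P_a,raw·P_b` — the tail of
a product of two independent uniforms.

**Multiple-cut correction.** The reported p-value is
`P = min(1, T_eff·P_J)` where `T_eff(L, D)` is the effective number of
independent cut trials implicit in the scan. Its surface,

    ln T_eff = −1.193 + 0.647·ln D + 0.0222·ln L   (clamped at T_eff ≥ 1),

was fixed once from shuffled-array nulls: on a 25-cell grid
(L = 200..10 000, D = 10..250, 2×10⁴ replicates per cell) we measured the
tail quantiles (at 10⁻² and 3×10⁻³) of `P_J` at the selected cut and fit
the implied trial counts by least squares in log space. Residuals are
within ±25%, a large part of which is quantile noise at that replicate
count; ±25% on `T_eff` is ±0.1 on an s-score, well inside the binomial
bands the calibration test uses. The dominant dependence on `D` (not on the
nominal number of positions `L`) reflects that only cuts at distinguished
elements compete, and that their tails are correlated. In the
"without P_b" mode the same `T_eff` multiplies `P_a,raw`; because `P_b` is
a discrete (hence conservative) p-value, a single correction cannot make
both modes exactly uniform — the calibration targets the joint statistic,
so the `P_a`-only mode runs slightly hot against its own null. Both raw and
corrected values are exposed in every report.

All tail probabilities are computed by log-gamma binomial coefficients and
log-sum-exp, so arrays of ~5×10⁴ pairs with p-values near 10⁻⁸⁰⁰ are exact
to double precision in log space; `P_b` uses exact integer/rational
arithmetic (the urn sizes are at most a few hundred).

## Building the array

Coupling scores arrive as pair lists (`evcouplings`: `i res_i j res_j
score`; `psicov`: score in the last column; `gaussdca`: three columns) or
as a raw ℓ×ℓ matrix (`ccmpred`), all 1-based; duplicates keep the first
occurrence with a warning, residue-letter conflicts with the query are hard
errors. Pairs with fewer than `m` intervening residues (`j − i − 1 < m`,
default m = 5) are removed; remaining pairs sort by descending score, ties
by `(i, j)`.

Distances are minima over sidechain atom sets: backbone N, CA, C, O, OXT
and hydrogens riding on N or CA are excluded; glycine's sidechain is its CA
plus attached hydrogens (HA2/HA3); a residue whose set comes up empty falls
back to CA alone; nonstandard residues keep all non-backbone atoms with a
warning. Hydrogens are used when the file provides them and are never
added; requesting the hydrogen-bond window (r_max = 2.6 Å) on a
hydrogen-free structure warns. Only the first coordinate model is read, and
disordered atoms resolve to the highest-occupancy conformer. With an
interface partner chain, a pair's trans distance is the minimum of the two
cross-subunit pairings `d(i_A, j_B)` and `d(j_A, i_B)`, and its effective
distance is `min(internal, trans)`.

A pair is dropped from the array entirely (L shrinks) if either residue is
unresolved or its effective distance lies below `r_min` (used by
distance-range analyses such as a 3–5 Å hydrophobic window); it is
distinguished if the distance falls within `[r_min, r_max]` (default
r_max = 5 Å). Ranks are by increasing distance, ties resolved to the
earlier array element.

Design points that were genuinely open and the choices made:

- `x = round(F·ℓ)` uses round-half-up; no rounding rule is conventional.
- `PPV = d_x/x` (fraction of the top-x pairs that are contacts), the
  standard usage; the alternative reading `d_x/D` (recall) is not used.
- `P_b` at a fixed cut uses the tally at that cut, keeping `P_F`
  self-contained.
- The Wilcoxon procedure drops zero differences, averages tied ranks,
  applies tie and continuity corrections in the normal approximation, and
  enumerates all sign assignments exactly for n ≤ 12. Scores are
  normalised by each analysis' post-filter array length `L` before
  testing. p-values far below 10⁻⁴ from the normal branch should be read
  qualitatively.
- τ's standard deviation is `μ/√(d−1)` with `μ = (d³−d)/12`; enumeration
  for d ≤ 7 confirms this is the exact population value. Exact p-values
  are enumerated for d ≤ 10, Gaussian (continuity-corrected) above. τ is
  reported for diagnostics only and never folded into `P_J`, since its
  independence from `P_a`/`P_b` is not established.

## Synthetic data

`make_fixture(n_res, theta, seed)` emulates the minimal structure of the
real problem: a chain laid down by a persistent random walk (step 3.8 Å,
the Cα virtual bond) confined to a sphere of radius `13·(n_res/60)^{1/3}` Å,
giving protein-like compactness with ~6–7% of well-separated pairs in
contact; one pseudo-sidechain atom per residue; contacts are pairs within
`r_max` with at least `m` intervening residues; coupling scores are
`theta·1[contact] + N(0,1)`. `theta = 0` is an exact null by construction.
What this generator does **not** emulate: the transitivity structure of
real coupling matrices (pairs {i,j}, {j,k}, {i,k} are correlated in real
MSAs), score heavy-tails, alignment depth effects, and multi-atom
sidechains. Passing the planted-signal and null tests therefore validates
the statistical machinery, not any claim about a particular DCA method on
real alignments; the column-permutation MSA null is provided for users who
can run a coupling method on the permuted alignments.

The shuffled-array null (`null_s_scores`, `calibration_curve`) permutes
element order with flags and ranks attached, preserving `(L, D)` — the
regime in which the theory should be exact. The calibration curve reports
`Ŝ(S) = −log10(fraction of null s-scores ≥ S)` with two-binomial-SD bands;
the shipped contract checks `S ∈ [2, 3]` at 10⁴ replicates (the band is
uninformative above `log10 n_rep − 1`); release-grade runs at 10⁵
replicates extend the check to S ≈ 4–5 and, on shuffled arrays, the
statistic has been exercised to S ≤ 8 elsewhere.

## Problem sizes and determinism

Default test and example runs use arrays up to L = 2000, D = 100 with 10⁴
null replicates and 60-residue fixtures — sizes chosen so the whole suite
runs in well under a minute of statistics plus ~20 s of calibration on one
core while leaving the binomial bands tight enough to be meaningful. All
stochastic entry points take an explicit seed (NumPy `default_rng`) and
record it in their outputs; identical inputs and seed give byte-identical
reports.

## Known limitations

- `T_eff` is an empirical surface, valid in the calibrated range
  (L ≲ 5×10⁴, D ≲ 500, D/L ≲ 0.2); far outside it the correction
  extrapolates log-linearly.
- Pairs of positions sharing a residue are treated as independent by the
  null; on real large alignments this approximation is known to leave
  s-scores slightly inflated, an effect this package can reproduce only
  qualitatively (it requires an external coupling run on permuted MSAs).
- The interface mode assumes a homo-oligomer (same numbering in both
  chains); hetero-interfaces are out of scope.
- Structures are consumed as given: no hydrogen placement, no altloc
  ensemble averaging, no B-factor weighting.
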