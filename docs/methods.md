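# Methods

## Setting and data model

A case–control GWAS with R cases and S controls summarises each SNP as a
2×3 genotype table: case counts (r₀, r₁, r₂) and control counts
(s₀, s₁, s₂) indexed by the number of minor alleles an individual carries.
Counting alleles instead of individuals collapses this to a 2×2 allelic
table with case row (r₁+2r₂, 2r₀+r₁) and control row (s₁+2s₂, 2s₀+s₁).
The association score is the allelic test statistic — the Pearson χ² of the
allelic table, equivalent to the Cochran–Armitage trend test under an
additive model, on 1 degree of freedom:

    Y_A = 2N[(2r₀+r₁)S − (2s₀+s₁)R]² / (R·S·(2n₀+n₁)(n₁+2n₂))

with nᵢ = rᵢ + sᵢ and N = R + S.

Assumptions carried throughout:

* **Controls are public.** Privacy protects the case group only; the
  control row (or the control allele frequency it is derived from) is fixed
  and known. Neighbouring databases differ by re-genotyping one *case*
  individual.
* **Hardy–Weinberg expansion.** When controls arrive as a minor-allele
  frequency p, the control row is S·((1−p)², 2p(1−p), p²). These cells are
  kept real-valued — nothing downstream requires integral controls, since
  all privacy-relevant moves act on the case row. An optional
  largest-remainder rounding (`round_preserving_sum`) is provided for users
  who want integer tables; it is off by default.
* **Common SNPs.** Minor-allele frequencies are assumed above 1%, so the
  derived control rows are polymorphic and every allelic margin on the case
  lattice is positive. Monomorphic tables return Y_A = 0 with a logged
  warning from the χ² scorer (the numerator is forced to zero whenever a
  margin is, so 0 is the continuous completion — a documented convention,
  not a canonical definition) and are refused outright by the Hamming
  scorer, whose geometry is undefined there.

## The Hamming distance score

Fix the control row and R. Case rows live on the integer triangle
{(r₀, r₁) : r₀, r₁ ≥ 0, r₀+r₁ ≤ R}; re-genotyping one case individual
applies one of six moves (±1 to one coordinate, or transfers between r₀/r₁)
— each changes the case major-allele count x = 2r₀+r₁ by −2, −1, +1 or +2.
Y_A depends on the case row only through x:

    Y_A(x) = 2N(xS − n₁₀R)² / (R·S·(x+n₁₀)(2N−x−n₁₀)),   n₁₀ = 2s₀+s₁

which vanishes on the equal-frequency line xS = n₁₀R and increases
monotonically away from it on either side. Given a threshold p-value p*
with χ²(1) critical value c, a table is *significant* when Y_A ≥ c (ties at
c count as significant, and Y_A is compared to c exactly in floating point —
both sides come from the same formula, so an epsilon would only blur the
contract). The significant region is therefore the complement of an
x-interval around the vertex, and the Hamming distance score is

    h(D) = −d   if Y_A(D) < c      (d = fewest moves to reach significance)
    h(D) = d−1  if Y_A(D) ≥ c      (d = fewest moves to reach insignificance)

so h ≥ 0 exactly for significant tables.

**Exact fast algorithm.** The fewest moves that change x by Δ from a row
with r₀ homozygous-major and r₂ homozygous-minor cases are

    down: max(⌈Δ/2⌉, Δ − r₀)        up: max(⌈Δ/2⌉, Δ − r₂)

Achievability follows by spending the −2 (or +2) moves first and finishing
with single steps; optimality because each move changes x by at most 2 and
changes x − r₀ (resp. x + r₂) by at most 1. The algorithm scans the integer
profile Y_A(x), x ∈ [0, 2R], locates the nearest significant (or
insignificant) x on each side, and applies the step formulas; this
reproduces the two-phase directional walks (decrease r₀, then r₁; or the
mirror) that define the score. Two conventions the geometry forces:

* For a *significant* table the only finite walk moves x toward the vertex
  x = n₁₀R/S; the opposite direction is ∞. (A directional description that
  decreased r₀ on both sides would walk away from the boundary on one of
  them, contradicting the monotonicity of Y_A(x); the equivalence sweep
  against the BFS oracle confirms the toward-the-vertex reading.)
* If *no* table in the space is significant, an insignificant table's
  distance is defined as 1 + min(d₁, d₂), where d₁ = r₀+r₁ and d₂ = R−r₀
  are the move counts to the triangle corners (0,0) and (R,0). If instead
  every table is significant (c below the minimum of Y_A over the space),
  a significant table has no boundary to cross and the scorer raises an
  error rather than inventing a value.

**Oracle.** `shortest_hamming_bfs` realises the definition literally by
breadth-first search over the triangle and is the independent check: the
test suite sweeps every table of every space for R = 2..12 across several
control rows and thresholds and requires exact agreement. The fast path is
O(R) per SNP; BFS is O(R²) states and reserved for verification.

**Sensitivity.** By construction |h(D) − h(D′)| ≤ 1 for one-move
neighbours; `empirical_sensitivity` verifies the bound — and that it is
attained — by exhaustive enumeration, and the acceptance script reports it.

## Release mechanisms

Both mechanisms release K of M SNPs under budget ε with score sensitivity s:

* **Laplace top-K**: perturb each score with i.i.d. Laplace(0, 2Ks/ε) and
  take the K largest perturbed scores. Ties break by ascending panel index
  (probability zero for continuous noise; the rule makes runs reproducible).
* **Exponential top-K**: K sequential draws without replacement with
  Pr(i) ∝ exp(ε·qᵢ/(2Ks)); a selected SNP's weight is set to exactly 0
  rather than its score to −∞, avoiding NaN arithmetic. Softmax weights are
  computed after subtracting the maximum exponent.

The factor 2K in both scales is taken as given — it is the budget split
across the K sequential releases; no alternative composition is offered.
For the Hamming score s = 1. For the χ² score no sensitivity is assumed:
it is a required input, and `empirical_chi2_sensitivity` (exhaustive over a
small space) / `panel_chi2_sensitivity` (one-move neighbourhoods of a
panel) provide empirical values. The panel-local value is *not* a certified
global bound; the CLI warns when it falls back to it. Raw per-SNP scores
are never serialised by default — they are not DP-protected outputs — and
`--debug` includes them only with a logged privacy warning.

`selection_probabilities` exposes the exact K=1 distribution, enabling the
analytic privacy audit in the tests: over every one-move neighbour pair of
a small panel, every probability ratio is verified ≤ e^ε with no sampling.

## Synthetic panels

`simulate_panel` emulates the shape of a challenge-style dataset (defaults
M = 5000, R = 201, S = 174). Per SNP: a population MAF p ~ Uniform(0.05,
0.5) — the lower bound safely above the 1% common-SNP floor so small panels
keep positive margins; an *observed* control MAF drawn Binomial(2S, p)/2S
and expanded under HWE into the control row (control frequencies in real
panels are finite-sample estimates, and without this noise the null
statistic would have mean S/(R+S) rather than 1); and a case row drawn from
the HWE trinomial at p — the minimal case model consistent with using HWE
for controls. Associated SNPs (the first n_assoc, recorded as ground truth
with their true χ²) shift the case frequency to p + effect, clipped into
(0.01, 0.99). One global seed spawns per-SNP substreams `[seed, i]`, so
growing M extends a panel without reshuffling earlier SNPs.

What the generator does **not** model: linkage disequilibrium, population
stratification, genotyping error, covariates — the statistic is single-SNP
and the tests exercise selection behaviour, not confounding. Passing tests
therefore show the mechanisms behave as designed on exchangeable,
independent SNPs; they do not certify utility on structured real cohorts.

Two engineered panels support the utility experiments:
`separated_panel` (M = 40, R = S = 200, 5 associated SNPs at effect 0.3)
produces Hamming scores split by dozens of integer steps between associated
and null SNPs — the regime where the Hamming-score exponential mechanism
dominates at small ε; `ranking_disagreement_panel` (M = 8, R = S = 60)
pairs a rare-allele SNP whose χ² tops the panel but whose significance
boundary is a few record moves away against common-allele SNPs with
slightly smaller χ² and larger Hamming scores, so the Hamming top-3 and the
χ² top-3 differ and the mechanism's utility plateaus at the overlap
fraction 2/3 as ε → ∞.

## Evaluation

Utility of a release is u = |S₀ ∩ S|/|S₀| against the true top-K by χ²
(ties by ascending panel index). `risk_utility_sweep` runs each requested
mechanism over a grid of ε × K (× p* for the Hamming score), default 200
repetitions per cell with per-repetition seeds derived via
`SeedSequence([base_seed, cell, rep])` — deterministic and independent of
iteration order — and reports mean ± sd. Default grid: ε ∈ {1, 2, 5, 10,
20, 50}, K ∈ {3, 5, 10}, p* ∈ {0.1/M, 0.01/M}. The numeric table is the
contract; the plot is cosmetic.

## Numerical choices

* Cross-formula χ² equivalences are asserted at 1e-9 (relative), absorbing
  float accumulation at N ≤ 10⁶; HWE rows conserve S to 1e-12.
* χ²(1) critical values come from the inverse survival function
  (`scipy.stats.chi2.isf`); the round-trip sf(c) = p* holds to 1e-10.
* All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; identical config + seed ⇒ identical release.
* Test problem sizes (R ≤ 12 for exhaustive sweeps, M ≤ 200 panels,
  200 repetitions per sweep cell) were chosen so the full suite exercises
  every property exhaustively where enumeration is the point and
  stochastically elsewhere, while remaining desk-scale.

## Known limitations

* The χ² sensitivity auditors are empirical; a user wanting a provable
  ε-guarantee with χ² scores must supply a certified bound.
* Single-invocation accounting only: composing multiple releases of the
  same panel is out of scope, as are Gaussian/Rényi variants.
* Genotype-level formats (VCF/PLINK) are out of scope; the data model is
  counts, and the panel TSV is the interface.
* The significance comparison Y_A ≥ c is exact in floating point; a table
  engineered to sit within one ulp of c could flip status across platforms.
  Generic data are unaffected.
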