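# Methods

This note records the models implemented in `safusion`, the defaults and
numerical choices, what the synthetic data generator does and does not
emulate, and the package's known limitations.

## The fusion-type null model

A fusion draws two non-homologous chromosomes from a karyotype; the null
hypothesis is that all such pairs are equally likely. Homologous fusions
(a chromosome with its pair partner, or X with Y) are excluded because
they would produce unbalanced gametes. For a male-heterogametic karyotype
the model has five structural parameters — diploid autosome count `Da`
(even by construction), male X count `Xs`, male Y count `Y`, and the
derived diploid numbers `Ds = Da + Xs + Y` (male) and `Dd = Da + 2·Xs`
(female) — plus the sex-bias parameter `mu_d ∈ [0, 1]`, the proportion of
fusions arising in the female germ line. Each sex contributes a pair-count
fraction; `mu_d` mixes them linearly, so every probability is affine in
`mu_d`.

Conventions worth stating explicitly:

- **Default `mu_d = 0.5`** wherever a value is not supplied: equal sex
  contributions. Under this default the simple-XY system satisfies
  `P(SA) = 4/(Da+2)` (provable algebraically for any `mu_d`, since the
  male and female branches coincide when `Xs = Y = 1`), giving the
  25%-floor thresholds at `Da = 14` (XY) and `Da = 22` (XXY).
- **XO is `Y = 0`**, not a separate code path: all `Y(Y−1)` terms vanish.
  A direct ordered-pair enumeration for an XO male (an X with no homolog)
  would give denominators slightly different from the printed
  `Ds(Ds−2)` convention; the single-formula convention is implemented.
- **The multi-X male denominator `Ds(Ds + Xs − 1)`** is implemented as
  the model states it. A naive non-homologous-pair enumeration does not
  obviously reproduce it for `Xs ≥ 2`; the closed form is treated as
  authoritative, and the pair-enumeration oracle in the tests is applied
  only to the simple XY/XX cases where the two derivations agree exactly.
- **ZW systems** are a pure relabelling (exchange the sexes:
  `Xs → Zd`, `Y → W`, `mu_d → mu_s`); the implementation mirrors the
  XY code bit-for-bit. **UV systems** force `mu_d = 0` (no diploid
  homogametic sex) and set both sex-chromosome slots to the common U/V
  count; unequal U and V counts are outside the model and raise.
- Probabilities are clamped into `[0, 1]` only within a few ulps;
  anything larger raises an internal-consistency error rather than being
  masked.
- Odd `Da` is rejected (autosomes come in homologous pairs). `Da = 0` is
  legal while the denominators `Ds(Ds−2)` and `Dd(Dd−2)` stay positive.

## The exact multinomial tail test

Given observed counts `(n_SA, n_AA, n_SS)` summing to `n`, the excess
test computes `P(X_SA ≥ n_SA)` under `X ~ Multinomial(n; p_SA, p_AA,
p_SS)`. Because the AA/SS split marginalizes out, this equals the
binomial tail `P(Bin(n, p_SA) ≥ n_SA)` — an identity, not an
approximation. Both forms are evaluated and must agree to 12 significant
digits; the explicit double sum has O(n²) terms and is cross-checked up
to `n = 500` (far beyond any realistic fusion tally), with the binomial
form alone used above that. Point masses accumulate in log space
(`gammaln`), so p-values far below 1e−5 are exact to double precision. A
`tail="lower"` flag gives the deficit direction `P(X_SA ≤ n_SA)`.

For the jumping-spider worked example the sex-bias value is not dictated
by the data; the 1e−5 bound holds under all-paternal fusions
(`mu_d = 0`, tail ≈ 5.2 × 10⁻⁶) but not under `mu_d = 0.5`
(≈ 6.2 × 10⁻⁵). Both values are computed in the tests and the README
uses the paternal-origin configuration; users probing sensitivity can set
the flag.

## The karyotype chain on a phylogeny

States are `(i, system)` with `i` the (even) male diploid chromosome
number and `system ∈ {XY, neoXY}`. Four transitions: AA-fusion `δ`
(`i → i−2`, system kept), fission `γ` (`i → i+2`, system kept),
SA-fusion `σ` (`(i, XY) → (i−2, neoXY)`) and reversion `ρ`
(`(i, neoXY) → (i, XY)`). Choices made where the model sketch is silent:

- Both fusion classes decrement `i` by 2: a fixed fusion merges two
  chromosome pairs, and diploid numbers move in twos.
- A neoXY lineage cannot SA-fuse again; it must first revert through
  `ρ`. Only the four listed arrows exist.
- Transitions that would leave the configured bounds `[min_i, max_i]`
  get rate zero (reflection by omission); defaults 6–12 with the root
  fixed at `(12, XY)`, both configurable, and a flat root prior is
  available.
- For the clade-level weighting, both `(i, XY)` and `(i, neoXY)` map to
  the karyotype `Da = i − 2, Xs = 1, Y = 1`: the neo-sex chromosome is
  counted as the sex pair, and no separate neoXY formula is used.

Likelihoods use Felsenstein pruning with per-node rescaling; transition
matrices are `expm(Q t)` cached per distinct branch length. Rates are
estimated by L-BFGS-B over log-rates in the box `[1e−8, 1e3]` with
multistart (one moderate fixed start plus seeded log-uniform draws); a
flag pins `ρ = 0` for sensitivity analysis. On degenerate (constant-tip)
data the likelihood surface is flat near zero and the optimizer may halt
marginally above the box floor; fitted chains there are substantively
static (well under one expected event on the tree).

Conditional stochastic maps are exact draws: node states are sampled
jointly root-to-tips from the pruning conditionals, then each branch path
is drawn conditional on its endpoints by uniformization (dominating rate
`Λ = max exit rate`, jump matrix `R = I + Q/Λ`; the jump count is drawn
from its endpoint-conditioned law, interior states form a Markov bridge
under powers of `R`, jump times are uniform order statistics, and virtual
self-jumps are discarded). When `Λ = 0` the path is constant by
construction, which covers the all-rates-zero case; powers of `R` are
cached and capped (4096) to bound memory. All stochastic stages accept
either an integer seed or a shared numpy `Generator`, so a single
top-level seed makes any run bit-for-bit reproducible.

## The clade report

Per map, the **expected** SA proportion is the time-in-state-weighted
mean of the closed-form `P(SA)` over occupied states, and the
**observed** proportion is `n_SA / (n_SA + n_AA)` over the map's fusion
events — the chain has no SS transition, so SS events never enter the
denominator. Fusion-free maps have an undefined observed proportion; they
are excluded from the observed distribution and counted in the report.
Intervals are equal-tail sample quantiles across maps (default 95%), and
`overlap` is a simple interval-intersection flag.

## The synthetic generator

`yule_tree` implements the standard pure-birth construction (two initial
lineages; each split waits `Exp(k·λ)` and divides a uniform lineage; a
final `Exp(n·λ)` stretch keeps tips off nodes), rescaled to unit depth by
default. Pure birth rather than birth–death: only tree shape and length
matter to the downstream machinery, and Yule is parameter-light and
seed-stable. `synthesize` composes a tree with a forward simulation of
the chain and returns the complete ground truth (rates, per-branch
history, event tallies, tip table).

Default geometry: 120 tips, unit depth, bounds 6–12, root `(12, XY)`,
rates `δ = γ = 1.0, σ = 0.5, ρ = 4.0` — a moderately sized clade in
which neoXY lineages are a minority of tips. What the generator does
*not* emulate: phylogenetic uncertainty (one fixed tree per dataset),
extinction, sampling bias, measurement error in karyotypes, hidden neoXY
states, and lineage-specific rate variation. Passing tests therefore
demonstrate internal correctness and statistical calibration of the
machinery, not robustness to those features of real data.

## Validation experiment sizes

The test suite's stochastic experiments use: pruning-vs-enumeration on 3-
and 4-tip trees (exhaustive oracle); 5 000 conditional maps on an 8-tip
dataset for the occupancy/marginal comparison; a 40-tip tree with 500
forward histories for the calibration check; a 60-tip dataset for the
σ = 0 separation experiment; and a 120-tip dataset for factor-of-two rate
recovery. For the calibration experiment the fusion split is matched to
the time-weighted null by a fixed-point iteration on pilot simulations
(σ/(σ+δ) = occupancy-weighted mean P(SA)); the reversion rate is set high
(ρ = 300) so neoXY sojourns are negligible and every fusion event is an
SA-fusion with probability exactly σ/(σ+δ), which is what makes the
matching exact rather than approximate. All experiments are seeded and
deterministic.

## Known limitations

- Unequal U/V counts, X–Y (homologous) fusions, and sex-chromosome
  turnover beyond the single `ρ` transition are out of scope.
- The exact test is exact but one-dimensional: it conditions on the
  total fusion count and tests only the SA margin.
- Rate estimation is maximum likelihood with a fixed or flat root; no
  Bayesian averaging over rates, and no MCMC.
- The chain's state space must contain all observed diploid numbers;
  tips outside the configured bounds are an error, not an extrapolation.
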