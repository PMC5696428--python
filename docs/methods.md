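# Methods

## Flight-time model

Flight (dry-period) durations `t`, in hours, follow one of four candidate
laws, each supported on `[a, ∞)` with `a = 30 s = 1/120 h`, the biological
lower limit below which a dry event (a scratch, a stretch) is not considered
a flight:

| family        | density on `t ≥ a`                                        | free parameters |
|---------------|-----------------------------------------------------------|-----------------|
| exponential   | `λ e^{−λ(t−a)}`                                           | rate `λ > 0`    |
| gamma         | `β^α (t−a)^{α−1} e^{−β(t−a)} / Γ(α)`                      | shape `α`, rate `β` |
| q-exponential | `(2−q) λ [1 + (q−1) λ (t−a)]^{1/(1−q)}`, `q ∈ (1, 2)`     | `q`, rate `λ`   |
| Pareto        | `(μ−1) a^{μ−1} t^{−μ}`, `μ > 1`                           | exponent `μ`    |

The lower limit enters the first three as a left shift and the Pareto as its
lower set point.  The q-exponential is a reparameterised generalized Pareto
(shape `ξ = (q−1)/(2−q)`, scale `σ = 1/((2−q)λ)`), recovering the
exponential as `q → 1` and approaching a pure power tail as `q → 2`; the
Pareto is the Lévy-flight step-length law.  All four are backed by frozen
scipy.stats distributions; sampling is inverse-CDF on seeded uniforms, so
records are bit-reproducible.

Reported location/spread summaries follow the fitted-table convention: the
gamma mean and variance are `α/β` and `α/β²` with the shift excluded;
`moments(include_shift=True)` gives the sampling-law moments.  Moments that
do not exist (Pareto mean for `μ ≤ 2`, etc.) are returned as `inf`.

## Observation model

A logger aggregates wet/dry state into intervals of length `τ`.  A flight of
duration `t` starting at a uniformly random phase `u τ` within an interval
covers

    j = max(floor(u + t/τ) − 1, 0)

completely dry intervals — the intervals containing take-off and landing are
wet-contaminated.  Marginally over phase, `K(j|t)` is a triangular tent on
`[jτ, (j+2)τ]` for `j ≥ 1` and `K(0|t) = clamp(2 − t/τ, 0, 1)`; `Σⱼ K(j|t) = 1`
identically.  Flights with `j = 0` never enter the record and are counted as
discarded.

With `S` the survival function and `I_m = ∫_{mτ}^{(m+1)τ} S(s) ds`,
integrating the kernel against the flight density gives the cell masses

    P(j) = (I_j − I_{j+1}) / τ   (j ≥ 1),       1 − P(0) = I_1 / τ,

so the observable-cell probabilities telescope to
`p(j|θ) = (I_j − I_{j+1}) / I_1`, which sums to one over `j ≥ 1` exactly.
Conditioning on `j ≥ 1` mirrors the generator's discard rule; it is the only
choice under which `Σ p(j|θ) = 1` over observable cells.

## Likelihoods

* **Exact (multinomial)**: `ℓ(θ|r) = Σⱼ dⱼ log p(j|θ)` over the record's
  occupied cells.  `p_obs` exposes the dense vector with residual tail mass
  lumped into the last cell; the likelihood itself uses the sparse per-cell
  form, so heavy-tailed records with astronomically large `j` need no dense
  allocation.
* **Naive**: each observed length is treated as an exact duration `j·τ` and
  the plain density is evaluated there.  Bins with `j·τ ≤ a` (possible at
  10–15 s resolution, where up to three bins sit at or below the 30 s limit)
  are relocated to `a + jτ/2` with a warning: at exactly `t = a` the gamma
  density diverges for shapes < 1, so the boundary bin is relocated along
  with the sub-limit ones to keep the naive method defined for every logger
  generation.

## Numerics

`I_m` has closed forms for every family (exponential: elementary; gamma: via
`∫₀ʸ Q(α, βz) dz = y Q(α, βy) + (α/β) P(α+1, βy)`; q-exponential and Pareto:
power-law antiderivatives, with logarithmic special cases at `ξ = 1`
(`q = 1.5`) and `μ = 2`).  The cell mass `I_j − I_{j+1}` is evaluated
cancellation-free: `expm1/log1p` second differences for the power-tailed
families, a `sinh²` form for the exponential, and beyond `j > 10⁴` the
asymptotic `τ² f((j+1)τ)` (relative error `~μ(μ+1)/12j²`).  Where the mass
underflows double precision entirely (a light-tailed family confronted with
heavy-tailed data), the log-mass is continued analytically as
`2 log τ + log f + 2 log[sinh(rτ/2)/(rτ/2)]`, so every family has a finite
log-likelihood everywhere and model comparison never divides by zero.
Masses are clipped at zero against roundoff; a distribution whose
observable mass `I_1` vanishes raises a degenerate-observation error.

Fitting maximizes the chosen likelihood by Nelder–Mead over unconstrained
coordinates (`log` for rates, shapes and `μ−1`; logit onto `(1, 2)` for `q`)
with 5 multistarts: one at moment-matched values (durations de-aggregated as
`(j+1)τ`, heavy-tailed families initialised from the weighted median) and
the rest jittered by N(0, 0.4²) in transformed space from a seeded
generator.  Convergence tolerance is 1e-8 on the objective, at most 600
iterations per start; the best converged start wins, and refits with the
same options are bit-identical.

## Model selection

`AIC = 2k − 2ℓ`, `BIC = k ln N − 2ℓ` with `N` the number of *recorded*
flights (the multinomial sample size).  Model probabilities use the
ΔBIC-stabilised form `p(Mᵢ) = e^{−ΔBICᵢ/2} / Σ e^{−ΔBICᵣ/2}`, immune to the
thousand-unit BIC gaps coarse loggers produce.  BIC ties break toward fewer
parameters, then lexicographic family name, making rankings deterministic
and order-invariant.

## Synthetic-data generator

`simulate_study` crosses the four families with scale targets
{0.5, 1, 5, 10} h — bracketing flight scales from well below to well above
the coarsest (1 h) interval — matching each family's location summary to the
target: mean for exponential and gamma, median for the Pareto (whose mean is
infinite at the exponents of interest) and for the q-exponential at the
default `q = 1.6` (mean infinite for `q ≥ 1.5`).  The gamma shape is held at
0.7 (sub-exponential, the regime the real fits fall in) and `q` at 1.6
(markedly heavy-tailed, distinct from both exponential and Pareto) across
levels, leaving one free scale parameter per family.  Defaults are 10
replicates of 3,000 flights per generator observed at 10 s and 1 h — 320
records, each of at most 3,000 flights after discards.

Two emulators exist.  The default assigns each flight an independent uniform
phase (the kernel above).  The timeline emulator builds the full alternating
wet/dry stream — exponential wet gaps, default mean `2τ`, every interval
overlapping any wetness marked wet, maximal dry runs extracted — and serves
as an independent cross-check; the two agree in distribution (total
variation < 0.01 at 10⁵ flights) whenever wet gaps keep flights separated.
The generator does not emulate battery or memory failure, clock drift,
duty-cycled sampling, behavioural state switching, or inter-individual
heterogeneity: passing tests show the inference machinery is correct under
the stated observation model, not that real records satisfy that model.

## What the observation process can and cannot hide

Computed by the identifiability studies (`analysis/02`, `analysis/03`) and
the acceptance suite:

* At 10 s sampling, exact-likelihood estimates recover all four families'
  parameters with median relative errors of a few percent at 3,000 flights,
  and the generating family attains the top average model probability.
* At 1 h aggregation with flight scales ≲ the interval, most flights are
  discarded and parameter errors inflate by an order of magnitude (gamma
  shape errors approach 100%); the naive likelihood degrades far more than
  the exact one.  Truncation at the 30 s limit measurably biases naive fits
  already at 30 s resolution.
* A structural property of this pipeline: uniform-phase aggregation of a
  shifted-exponential law yields an *exactly geometric* record at every
  interval (`I_j − I_{j+1} ∝ e^{−λτj}` by memorylessness), so
  exponential-generated data remain classified as exponential even at 1 h —
  coarse aggregation destroys parameter precision before it destroys this
  family's identifiability.  Conversely the reduced-scale study shows the
  sub-exponential gamma collapsing toward the parsimonious exponential at
  1 h: whatever distributional signature separates the families must survive
  aggregation, and whether it does depends on the family, not only on the
  interval.

## Real-data workflow

Wet/dry CSVs carry per-interval wet-segment counts (or a binary state
column); timestamps mark interval starts (0-based, half-open `[mτ, (m+1)τ)`
intervals) and must advance by exactly `τ` within a deployment — gaps,
reordering and mixed intervals are rejected with the offending line.
Flights are maximal runs of intervals with zero wet count; runs touching a
record boundary are censored — their true extent is unknown — and dropped
rather than truncated, since truncated lengths would deflate `d_j`
unpredictably.  No additional minimum-duration filter is applied to observed
flights: the 30 s limit enters only through the distributions' shift, so at
10–15 s resolution the sub-limit bins are retained and handled by the exact
likelihood.  Deployments sharing an interval pool by summing counts (pooling
and extraction commute).  `analyze_dataset` fits all four families exactly,
ranks by BIC, reports the gamma shape/rate/mean/variance summary, and builds
a Q-Q table (observed `j·τ` quantiles at plotting positions `(i−½)/N`
against fitted-law quantiles).

## Known limitations

* Confidence intervals are not produced; the likelihood machinery supports a
  numerical-Hessian Wald interval but none is asserted anywhere.
* The naive method's sub-limit bin relocation (`a + jτ/2`) is a pragmatic
  convention; naive fits at 10–15 s should be read with that in mind.
* The per-flight kernel assumes independent phases; the timeline emulator
  shows this is harmless for well-separated flights, but regimes with wet
  gaps shorter than an interval inherit phase correlations that neither
  likelihood models.
* Problem sizes in the test suite are chosen for sharp statistical checks at
  interactive runtimes: 3,000-flight records, 10–40 replicates per recovery
  cell, 10⁵-flight Monte-Carlo oracles on ≤ 20-cell partitions (where the
  empirical TV noise floor stays well under the 0.01 budget).
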