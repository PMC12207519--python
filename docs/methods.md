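# Methods

## Model

A unit of population mass *Q* is partitioned into *m* types; type *i*
has weight μᵢ > 0 (Σμᵢ = 1), plays strategy 1 with probability xᵢ and
strategy 2 otherwise. Strategy costs are linear in load:
C₁ = αQ·f and C₂ = βQ·(1−f) with f = M·X = Σμᵢxᵢ. One round of MWU
learning with per-type rate aᵢ gives

    xᵢ' = xᵢ / (xᵢ + (1 − xᵢ) exp(aᵢ (f − b))),    b = β/(α+β).

The rate aᵢ is the reparametrization a = Q(α+β)·log(1/(1−ε)) of the
per-round MWU multiplier ε ∈ (0,1); `epsilon_to_a`/`a_to_epsilon`
convert both ways, and the package treats a ∈ (0,∞) as the primitive
(so that unbounded rate scaling σ·A is well defined even though ε
saturates at 1). The states with f = b form the Nash set: a continuum
of fixed points on which both strategies cost Q(α+β)b(1−b).

**Normalization.** Since only b and the aᵢ enter the map, the default
is Q = 1, α+β = 1 (α = 1−b, β = b); Q, α, β stay settable and enter
only the cost series.

## Logit representation

The update is carried exclusively in logit coordinates
zᵢ = log(xᵢ/(1−xᵢ)), where it is the exact linear shift
zᵢ' = zᵢ − aᵢ(f − b). This is algebraically identical to the
multiplicative form but has two decisive numerical properties: it never
overflows (the multiplicative form computes exp(aᵢ(f−b)), which leaves
double range once aᵢ ≳ 700/|f−b|, well inside the regimes of interest
for fast learners), and it keeps every xᵢ strictly inside (0,1) for any
finite trajectory, so the open-cube invariant of the exact dynamics
holds by construction. A property test confirms agreement with the
literal multiplicative form to 1e−10 wherever the latter is
representable.

## Invariant curves and the reduced map

Through any base point y runs the curve y(s)ᵢ = yᵢ/(yᵢ+(1−yᵢ)eˢᵃⁱ)
(in logits: logit(y(s)ᵢ) = logit(yᵢ) − s·aᵢ). Because the MWU step
shifts all logits proportionally to the same scalar (f − b), each curve
is invariant and the restricted dynamics is conjugate to

    g(s) = s + M·y(s) − b,      g'(s) = 1 − Σ μᵢ aᵢ yᵢ(s)(1 − yᵢ(s)).

The explicit form of g is a commitment of this package (the conjugacy
is usually stated abstractly); it is validated operationally by the
oracle test ‖F(y(s)) − y(g(s))‖ < 1e−9 over random games and both
benchmark curves. All one-dimensional machinery is then exact rather
than approximate:

- **Equilibrium.** s ↦ M·y(s) decreases strictly from 1 to 0, so
  M·y(s) = b has a unique root s*; it is found with `brentq` on a
  geometrically expanded bracket (start [−1,1], double until the sign
  changes), tolerance 1e−14 in s, giving |M·y(s*) − b| < 1e−12.
- **Stability.** The equilibrium is linearly stable iff |g′(s*)| < 1,
  i.e. Σ μᵢaᵢyᵢ(1−yᵢ) < 2 (the sum is positive, so instability is
  always through g′ = −1, a period-doubling). `sigma_critical` solves
  Σ μᵢ(σaᵢ)yᵢ(s*(σ))(1−yᵢ(s*(σ))) = 2 in σ; the curve context is
  rebuilt per σ because the splitting itself depends on the rate
  vector.
- **Curve membership** (`curve_coordinate`) requires the per-type
  candidates (logit(yᵢ)−logit(xᵢ))/aᵢ to agree within 1e−8 relative in
  s units (configurable in `Tolerances`); disagreement returns a
  structured "not on curve" result (`None`), never a partial answer.
- **Periodic orbits.** Roots of gᵖ(s) − s by sign-change scan on a
  uniform grid (default 2000 cells) plus `brentq` polish; roots whose
  minimal period properly divides p are discarded, orbit duplicates
  merged at 1e−7. Tangent (even-multiplicity) roots can be missed by a
  sign scan; a finer grid narrows that window. A period-3 orbit of g is
  reported as a Li-Yorke chaos certificate (period three implies
  Li-Yorke chaos for interval maps); a positive Lyapunov exponent alone
  is only "numerically chaotic".
- **Lyapunov exponent.** Mean of log|g′(sₖ)| along a reduced orbit
  after burn-in, skipping |g′| < 1e−300. It can equivalently be read
  off a stored full-state orbit via g′ = 1 − Σμᵢaᵢxᵢ(1−xᵢ); on chaotic
  orbits the two routes decorrelate through roundoff and agree only
  statistically (the tests allow 0.05).

## Ergodic diagnostics

Summing g(s)−s = M·y(s)−b along an orbit telescopes, giving the exact
identity mean(fₙ) − b = (s_N − s₀)/N over any window, hence the Cesàro
convergence of the flow to b at rate range(s-orbit)/N — the bound the
acceptance run verifies on the chaotic benchmark. Cost averages follow
by linearity (mean C₁ = αQ·mean f exactly). The normalized
time-average social cost, mean social cost over its Nash value
Q²(α+β)b(1−b), satisfies the algebraic identity
1 + mean((fₙ−b)²)/(b(1−b)); it is therefore ≥ 1 always, with equality
exactly for an orbit constant at equilibrium. Per-type time averages
are computed and exported but carry no convergence guarantee — they
genuinely wander with σ, and a test asserts that they do while the
population average stays pinned.

Orbit classification works on any scalar series that is a homeomorphic
image of the reduced orbit (s itself, or the flow, which is strictly
monotone in s): terminal increments < 1e−10 → fixed point; a repeating
terminal segment with minimal period p ≤ 64 within 1e−8 (relative to
the series scale) → periodic(p); otherwise aperiodic.

## Benchmarks and the synthetic-population generator

- `example1`: m = 2, μ = (0.5, 0.5), A = (1, 3), b = 0.3,
  X₀ = (0.2, 0.6); σ-grid for scans 1400 points on [0.01, 14] (the
  source plots state the σ range but not the grid resolution; 1400 is
  this package's choice, giving 0.01 spacing); σ = 12.2 for the
  chaotic-regime cost experiment.
- `example2`: m = 999, μᵢ = 1/999, aᵢ = 1.2(5 + (i mod 31)),
  xᵢ = 0.0001 + (i mod 23)/24 with i running 1..999 **1-based** exactly
  as printed (a 0-based reading would shift every value); b = 0.3,
  burn-in 20000.
- `random_population(m, a_range, seed)`: μ ~ Dirichlet(1) (clipped
  below at 1e−6 and renormalized), aᵢ ~ U(a_range), x₀ᵢ ~ U(0.01,
  0.99), and — an addition beyond the two benchmarks, since a game
  needs one — b ~ U(0.15, 0.85) unless given. Same seed, same spec;
  every generated spec passes game validation by construction. The
  generator emulates heterogeneous rate/initial-condition populations
  only; it does not model noise in the update, finite populations, or
  nonlinear costs, so passing tests say nothing about those regimes.

The dynamics themselves contain no randomness; seeds exist only here.

## Horizons and problem sizes

Bifurcation scans retain T = 10³ samples per σ after 10⁴ burn-in;
social-cost summaries use 2·10⁴ burn-in (fixed burn-in is this
package's transient-elimination rule; the criterion is not adaptive).
Time-average checks run 10⁵ retained steps, where the telescoping bound
makes the Cesàro error ≤ range(s)/N ≈ a few × 10⁻⁵ — far inside the
5e−3 acceptance band. The test suite uses the same conventions at
reduced grid sizes (tens of σ values rather than 1400) since the
per-σ dynamics are identical and vectorized across the grid.

## Known limitations

- Only two strategies and linear costs; no continuum of types (the
  999-type benchmark approximates it), no finite-player (atomic) games.
- Curves degenerate as any aᵢ → 0; rates must be strictly positive.
- `sigma_critical` is the linear-stability threshold of the curve
  equilibrium, not the (larger) chaos threshold.
- The Li-Yorke certificate is sufficient, not necessary: failing to
  find a period-3 orbit on a given grid proves nothing.
- The scrambled-set definition of Li-Yorke chaos (lim inf / lim sup
  conditions on orbit pairs) is not machine-checkable and is not
  attempted; topological entropy is out of scope.
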