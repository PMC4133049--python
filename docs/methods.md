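# Methods

## Model

The package models cellular identity as an attractor network over N binary
transcription-factor (TF) states Sᵢ ∈ {−1, +1}.  The p natural cell fates
are stored patterns ξᵅ; they are the only biological input.  Because real
lineages are strongly correlated (related blood fates can share ~77% of
their binarized TF states), couplings are built with the projection
(pseudo-inverse) rule rather than the Hebb rule:

    A = ΞᵀΞ / N,   J = Ξ A⁻¹ Ξᵀ / N.

J is the orthogonal projector onto the fate subspace: J² = J, Jᵀ = J,
trace J = p, Jξᵅ = ξᵅ.  Consequently the basin energy H_basin = −½SᵀJS
satisfies H_basin ≥ −N/2 for every state with equality exactly on the fate
subspace — all stored fates are equally deep global minima regardless of
their mutual correlations, and distances are measured with the projection
a(S) = A⁻¹m(S) (the least-squares coordinates of S on the patterns), which
separates correlated fates where the raw overlap m cannot.

The full energy adds three control fields:

    H(S) = −½SᵀJS − b_opt·S − N c·a(S) − N a(S)ᵀ D m(S).

* `b_opt` (length N): per-TF experimental bias (viral overexpression /
  knockdown).
* `c` (length p): culture bias; its TF-level equivalent is
  b_cult = Ξ A⁻¹ c, chosen so −b_cult·S = −N Σ c_α a_α(S) exactly.
* `D` (p×p, generally asymmetric): developmental signal.  Convention:
  **rows index the target fate, columns the source** — D[target, source]
  > 0 opens a path from source to target.  This orientation is fixed by
  the requirement that a positive signal applied at the source pattern
  produces a field component along the target pattern (at S = ξ^src with
  near-orthogonal fates, the signal coupling J_dev = Ξ A⁻¹ D Ξᵀ/N
  contributes ≈ D[tgt, src]·ξ^tgt to the local field).  The energy term
  is the bilinear form −N aᵀDm; with off-diagonal D it breaks detailed
  balance by construction (a pseudo-landscape), matching its biological
  role of driving irreversible switches.

Predictivity is P = Ξ A⁻¹ (N×p), defined without a 1/N prefactor; it obeys
a(S) = PᵀS/N for every state, so a TF's predictivity is exactly its
leverage on each fate's projection and basin energy.  Rankings built from
it are invariant under global positive rescaling, so the prefactor choice
only sets an overall scale.

## Dynamics and the self-coupling convention

Updates are asynchronous Glauber: a uniformly random TF is resampled with
P(Sᵢ = +1) = e^{βh} / (e^{βh} + e^{−βh}).  Two field conventions appear in
the code, deliberately:

* `local_field(..., exclude_self=False)` (default) reports the full sum
  hᵢ = Σⱼ Jᵢⱼ Sⱼ + fields, for which h(ξᵅ) = ξᵅ exactly.
* The dynamics (Glauber, deterministic relaxation, attractor enumeration)
  use the **self-coupling-excluded** field (the projector has a nonzero
  diagonal, Jᵢᵢ ~ p/N).  With the diagonal excluded, the single-flip
  identity ΔH = 2Sᵢhᵢ is exact and heat-bath updates are exactly
  reversible with respect to e^{−βH} for symmetric J — the property the
  equilibrium validation checks (a long run at N = 10 matches the
  exhaustively enumerated Boltzmann distribution to total-variation
  distance < 0.05).  The two fields differ by Jᵢᵢ Sᵢ ~ p/N per spin and
  share all sign structure at the stored patterns, so fixed points are
  unaffected.

Zero local field resolves to +1 in sign updates, matching the z = 0 → +1
binarization tie rule.  Time is counted in single-TF updates (1 sweep = N
updates); no mapping to wall-clock biology is attempted.  Burst noise
flips a fraction (default 2%, the only burst constant reported for the
original basin-stability experiments) of randomly chosen TFs every
`burst_period_sweeps` (default 10) sweeps.  The default β = 4 puts the
dynamics deep in the ordered regime while leaving the bursts visible;
both are exposed in `DynamicsConfig`.  Dilution zeroes entries of J
independently (not in symmetric pairs), producing the asymmetric,
detailed-balance-breaking variant; the equilibrium guarantees then lapse
and stability is assessed empirically.  The equilibrium validation runs
2×10⁶ updates — twice the minimum that makes the Monte-Carlo
total-variation noise comfortably smaller than the 0.05 acceptance band.
Signal-switching runs disable bursts: the signal term is the object under
test, and no burst constant is reported for those experiments.

## Preprocessing

Expression values are positive and approximately log-normal, so each
array is reduced to order statistics: average ranks for ties, midpoint
percentiles (rank − ½)/G (the midpoint convention keeps quantiles finite
and is symmetric about the median; any percentile convention yields the
same binarization, which depends only on the median), standard-normal
quantiles, then re-standardization with the biased (1/G) variance so each
column has mean 0 and Euclidean norm √G.  Binarization maps z > 0 → +1,
z < 0 → −1, z = 0 → +1 (fixed tie rule).  Per-fate consensus is the
majority vote over replicates, exact ties broken by the sign of the mean
continuous score.  TFs constant across all fates are dropped (they carry
no identity information and would inflate every correlation), and
cross-platform queries always trigger restriction to the common TFs with
a full rebuild of A, A⁻¹ and J — a correlation matrix computed on one
gene set is not valid on a subset.

A correlation matrix with condition number above 1e8 is rejected with a
named error instead of silently regularized; `pseudo_inverse=True` is an
explicit escape hatch for exploratory use.  Energy offsets that are
constant in S (e.g. the projector diagonal term, Σ Jᵢᵢ/2) are ignored
throughout: only energy differences drive dynamics.

## Hybrid classification

For uniform random ±1 states, Var a_α = (A⁻¹)αα / N exactly; the
calibration samples 10⁴ random vectors (matching that closed form to a
few percent) and uses the pooled across-fates standard deviation as the
default noise scale, with per-fate thresholds behind a flag.  A query is
reported as a hybrid of every fate where |a_α| ≥ 2 pooled sd (sign
preserved — strong negative projections are informative too), with a
strong flag at 3 sd.  Odd-majority-vote mixtures of k fates project ≈ ½
onto each constituent for near-orthogonal panels (binomial expectation),
an order of magnitude above the 2-sd threshold at N = 1000, which is why
planted three-way hybrids are recovered exactly.

## Synthetic data: what it emulates and what it does not

Fate panels evolve along a lineage tree (star over a hidden root, or a
chain); each edge flips a fraction f of each sign class, so fates at tree
distance d correlate as (1 − 2f)^d.  Defaults: star, f = 0.4 (pairwise
correlation 0.04, a weakly correlated panel).  Patterns are balanced
(half the TFs on) and the flips preserve balance.  This is deliberate:
the pipeline's binarization is a median split, which assigns +1 to
exactly half of each array, so consensus patterns derived from real data
are balanced by construction.  An unbalanced planted pattern with on-count
excess e would necessarily miscall its |e| boundary genes (E|e| ≈ 13 at
N = 1000 for iid patterns, a ~1.3% error floor independent of
signal-to-noise); balanced planting removes that artifact and leaves only
genuine measurement noise.

Replicate expression is log-normal: log-expression = per-gene baseline
(sd 0.15) + (Δ/2)·ξ + Normal(0, σ), exponentiated.  Defaults Δ = 2,
σ = 0.5 (Δ/σ = 4).  The error budget for these defaults: a gene with
baseline b flips per replicate with probability Φ(−(1 + b)/σ·(Δ/2)⁻¹…),
i.e. Φ(−2(1+b)) here; integrating over the baseline distribution and the
3-replicate majority vote gives an expected per-entry consensus error of
0.33% (0.85% at baseline sd 0.25, which is why 0.15 was chosen), a 3×
margin under the 1% recovery contract.  Hybrid queries push
odd-majority-vote mixture states through the same noise model.

The generator does **not** emulate: platform/batch effects, probe-level
structure, correlated noise between genes, unbalanced or duplicated
replicate designs, or fates whose marker sets overlap asymmetrically.
Passing recovery tests therefore demonstrates the pipeline's correctness
under the stated noise model, not robustness to real microarray
artifacts.

## Validation problem sizes

The integration checks run at sizes chosen to exercise the claimed
regimes while staying desk-scale: 50 random panels with N log-uniform up
to 2000 (one pinned at N = 2000, p = 50) for the projector identities;
N = 10, β = 1, 2×10⁶ updates for the Boltzmann check; N = 1000, p = 10,
10% initial flips, 2% bursts, with intact and 20%-diluted couplings for
basin stability (reported as the median projection over the last half of
the run, so burst dips do not mask recovery); N = 500, p = 3 for signal
switching; N = 1000, p = 20 with 10⁴ draws for the null; N = 200,
k = 20, |set| = 2, 10⁵ permutations for the Monte-Carlo/hypergeometric
agreement (the study-scale closed form C(50,4)/C(1337,4) ≈ 1.7×10⁻⁶ is
evaluated exactly); N = 1000 panels for pipeline and hybrid recovery.

## Known limitations

* Attractor-network dynamics do not capture reprogramming *rates*:
  simulated spontaneous transitions are so rare that known protocols are
  not kinetically distinguished from random ones.  The package ranks
  candidates by landscape structure, not kinetics.
* The exact analytic form of spurious attractors for *correlated*
  patterns is unknown; `enumerate_attractors` labels odd-majority
  mixtures and reports everything else as `other`.
* Predictivity is correlational: a highly predictive TF may be a
  downstream marker rather than a causal driver.
* Noise-modulating factors (raising the effective temperature rather than
  biasing specific TFs) are outside the model; they would enter through
  β, not through the fields.
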