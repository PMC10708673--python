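# Methods

## Charge sequences

Sequences live on the charge sites of a chain of N monomers, one site every
p-th monomer starting at the first (ceil(N/p) sites; 68 for N = 202, p = 3 —
the convention consistent with a 44 + 24 composition on the canonical PA
chain).  Site symbols follow a stationary symmetric two-state Markov chain:
the first symbol is uniform, each later site repeats its predecessor with
probability s (the *stay probability*).  The marginal at every site is then
uniform — the process is unbiased — and block lengths are geometric with
mean L = 1/(1−s).  "Uncorrelated" means s = 1/2 (L = 2), "blocky" s = 3/4
(L = 4); L parametrizes the public interfaces, s the internals.  PE sites
take 0/1 and Q is the number of charges; PA sites take ±1 and Q is the
absolute majority-minus-minority difference.  Sub-ensembles are selected by
exact net-charge equality.

**Block-length estimation.**  The naive pooled ratio (total sites / total
runs) is biased low on finite chains because the last run of every sequence
is censored by the chain end: for 68 sites it gives ≈ 1.97 and ≈ 3.83
instead of 2 and 4.  An interior-runs-only mean is *also* biased (interior
runs must complete before the boundary, which truncates long runs; measured
≈ 3.82 at s = 3/4).  The default estimator is the inverse pooled flip rate,
L̂ = Σ(sites−1)/Σ(flips): adjacent-site pairs are i.i.d. Bernoulli(s)
stays, so the estimator is exact in expectation ratio at any chain length.
Both the bias of the naive ratio and the exactness of L̂ are verified in
the tests by exhaustive enumeration of all 2^10 ten-site sequences weighted
by their chain probability.  `average_block_length(..., estimator="naive")`
exposes the raw ratio.

## The n-pearl energy landscape

States are (x, y) pairs of excess masses and charges under Σx = Σy = 0.
The energy keeps each pearl's surface term m^⅔ and self-energy q²/m^⅓
scaled by χ; strings and inter-pearl interactions are neglected, and pearl
order along the chain is not represented (states are reported mass-sorted
descending).  A pearl of zero mass and zero charge contributes nothing —
this makes the simplex vertices evaluable and matches the χ → 0 limit — and
zero mass with nonzero charge is a domain error (a charged point has
infinite self-energy).

**Charge equilibration.**  E is a positive-definite quadratic in the
charges, so the unique stationary charge split at fixed masses is
q_i* = m_i^⅓/Σ m_j^⅓ (Lagrange multiplier on Σq = 1), giving the reduced
landscape E_eq(m) = Σ m^⅔ + χ/Σ m^⅓ − 1 − χ.  Eliminating the charges is
exact for locating *all* stationary points of the full landscape (the
quenched-charge `energy()` remains available for scoring simulation
frames).  The closed form is cross-checked in the tests against a generic
numerical constrained minimizer on 100 random instances.

**Extrema.**  Stationary points form two-group families: n_l large pearls
of mass a and n_s = n−n_l small pearls of mass b.  Pairwise stationarity
gives the branch condition χ(b) = 2S²/(a^{−⅓} + b^{−⅓}) with
S = n_l a^⅓ + n_s b^⅓.  The solver works in u = b^⅓, where
χ(u) = 2S²u/(1 + u a^{−⅓}) is regular both at the vertex (u = 0, χ = 0)
and at the symmetric point (χ = n exactly): Brent root-finding in u then
resolves the χ → 0 vertex limit to ~10⁻²⁶ in mass, far below the 10⁻⁶
verification tolerance, which the large-pearl-mass variable cannot reach at
double precision.  χ_c is the maximum of χ(u) over the branch, found by
bounded scalar optimization; for n = 2 the expansion
χ(u) = 2 − (16/9)u² + O(u⁴) shows the maximum sits at the symmetric end, so
χ_c = n exactly and no asymmetric two-pearl state survives past the
transition — whereas the one-large-pearl branch for n ≥ 3 folds at
χ_c(3,1) ≈ 3.0225, χ_c(4,1) ≈ 4.0754.  Between χ = n and χ_c two solutions
coexist; `find_extremum(..., branch="upper")` returns the weakly asymmetric
one created at the χ = n bifurcation.

**Stability.**  Classification uses the numerical Hessian of the full
(x, y) energy in an orthonormal basis of the 2(n−1)-dimensional constraint
subspace (central differences, step adapted to the smallest pearl mass);
eigenvalues beyond ±10⁻⁹ (scaled by the Hessian norm) count as signed,
in-between as degenerate.  States with a pearl mass below 10⁻⁸ are reported
"degenerate" rather than misclassified through a singular curvature.  The
analytic per-mode 2×2 block at the symmetric point has determinant
(4/9)χ n^⅔ (χ−n), so the smallest eigenvalue changes sign at χ = n; the
numerical `stability_transition` reproduces this to better than 10⁻³.

## Simulation model

Single chain, implicit solvent, infinite dilution, no counterions or salt.
FENE bonds (k = 30 kT/σ², R₀ = 1.5σ); full unshifted Lennard-Jones between
all pairs with cutoff 2.5σ — ε_LJ = 1.5 kT is the "rather poor" PE default,
1.0 kT the "marginally poor" PA default; bare Coulomb λ_B z_i z_j/r with
λ_B = 3σ; Langevin friction γ = 1/τ at kT = 1.  These are the
community-standard bead-spring choices for necklace studies; every constant
is overridable, and the analysis layer does not depend on them.  The
integrator is BAOAB (half kick, half drift, exact Ornstein–Uhlenbeck
velocity refresh, half drift, half kick) at dt = 0.005τ (dt ≤ 0.01τ
enforced); with γ = 0 it reduces to velocity Verlet and conserves energy to
the expected O(dt²), which the tests check, along with equipartition and
force/energy consistency by finite differences.  Pair sums are direct
O(N²) in a numba kernel — at N ≈ 200 this is faster and simpler than
neighbor lists and keeps forces exactly consistent with energies.
Divergence (a bond reaching R₀, or non-finite coordinates) raises an error
naming the step; protocol runs attach the partial trajectory.

Initial states are either a straight chain or a freely jointed random walk
with a 0.8σ overlap-rejection rule.  Stretched starts are used for the
charged-chain production runs: the necklace then forms by the physical
pinch-off route, whereas random-walk starts frequently trap a metastable
single globule at these run lengths.

## Pearl detection and necklace observables

A monomer is *dense* when it has at least n_dense = 3 non-bonded neighbors
(chain distance ≥ 2) within r_c = 1.5σ; pearls are connected components of
dense monomers under the same contact graph, kept at min_size = 4; leftover
monomers in contact with exactly one pearl are re-attached to it, the rest
are strings/tails.  Bonded neighbors never count, so a taut string (whose
only ≤1.5σ contacts are its bonded neighbors) has zero density everywhere.
The defaults are a declared convention — the underlying studies do not
specify their criterion — and planted-fixture recovery is exact for
r_c ∈ [1.3, 1.7]σ.  On PA chains the per-pearl charge is the signed sum
projected onto the chain's majority sign, so Q_p + Q_s = Q holds with the
majority-minus-minority net charge.  When the pearls carry no net charge
the y_i are undefined (NaN) and such states are skipped by the histograms.

Densities of states are 50×50 histograms over the data's bounding box,
normalized by the peak bin to a [0, 1] scale.  For two-pearl (x, y)
histograms the range is centered on the origin and the 180°-rotated
histogram is added before normalization — equivalent to binning each
state's mirror partner (−x, −y) with the mirrored binning rule — so the
point symmetry imposed by the sum-zero constraints is exact by
construction, including for points on bin edges.  Dwell times are maximal
runs of n(t) times the sampling interval; runs touching either end of the
series are censored and excluded from means.  Switching events carry the
post-change simplex location and its nearest vertex by Euclidean distance.

## Planted fixtures

`make_necklace` builds necklaces from explicit plans.  Pearls are balls
traversed by a single continuous path: a center bead, concentric shells at
spacing dR carrying area-proportional bead counts as pole-to-pole spirals,
a radial exit, and protruding pole-cap beads at both ends.  Both the shell
spacing and the in-shell spacing are capped at 1.05σ, which keeps every
pearl internally connected down to r_c = 1.3σ, and the pole caps push the
first string monomer beyond 1.7σ from every non-bonded pearl bead — so the
planted decomposition is recovered *exactly* across the whole supported
detection band, and all bond lengths stay below the FENE R₀.  The default
density (0.8 monomers/σ³) mimics a collapsed melt-like droplet so fixtures
and simulation frames exercise the same thresholds.  The smallest buildable
pearl is 12 monomers; optional Gaussian jitter is limited to 0.1σ.
Synthetic n(t) series are exact by construction.

## Scaled-down production runs

The test suite validates the simulation-level claims at desk scale: blocky
PE sequences at Q ∈ {16, 22, 28, 34} (three quenched sequences per Q,
stretched starts, 600τ equilibration + 300τ production sampled every 10τ)
plus one neutral-chain run.  At this scale the qualitative necklace physics
is reproducible — neutral collapse to a single globule, monotone growth of
the mean pearl number with Q, strings and small pearls overcharged relative
to their mass share, short-lived small pearls — but quantitative lifetimes
and the full density maps are not: they would need two to three orders of
magnitude more sampling and depend on force-field constants that are a
declared convention here.  Quenched sequence-to-sequence variability is
large (individual Q = 22 sequences range from a single globule to a
three-pearl necklace), so the trend tests pool frames across sequences and
use a cluster bootstrap over runs for sign claims.  Note that the larger
pearl in a two-pearl state is *undercharged relative to its mass share*
(mean y − x < 0); its absolute excess charge y is typically slightly
positive, exactly as the charge-equilibrated model predicts
(y* = m^⅓-share − 1/n > 0 for the heavier pearl).

## Known limitations

No explicit counterions, added salt, or screening; no annealed
(pH-regulated) charges; single chains only; pearl order along the chain and
string energetics are outside the energy model; the pearl-detection
thresholds are a convention, and lifetime statistics inherit that
ambiguity.
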