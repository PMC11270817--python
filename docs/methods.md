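# Methods

## Problem

`flowfe` estimates reduced free-energy differences Δf (in units of k_BT) and
configurational entropy differences Δs (in units of k_B) between
non-overlapping metastable states of a single global potential-energy
surface, using only locally ergodic sample sets from each state.  Because the
states share no configurations, classical overlap-based estimators cannot be
applied directly; instead one invertible map per state transports its
Boltzmann distribution onto a common uniform reference box, where every pair
of states overlaps by construction ("targeted" reweighting).

## Model

Each state i is the restriction of the global reduced potential u to a region
of configuration space defined by a fixed, deterministic cluster rule
(nearest well group, lowest-index tie-break).  Its restricted potential is

    u_i(r) = u(r)            if assign(r) = i
    u_i(r) = u(r) + 10^20    otherwise,

so the Boltzmann weight of misassigned configurations is exactly zero during
reweighting; this enforces consistent integration limits for the state
integrals f_i = −ln ∫_i e^(−u) dr and measurably speeds up estimator
convergence (the package tests this variance reduction directly).

The per-state model q_i is the push-forward of a uniform base p_0 on
[a,b]^D (ln p_0 = −D ln L, L = b − a) through an invertible map 𝒯_i:

    ln q_i(r) = −D ln L + ln |det J_{r→z}(r)|.

q_i is normalized by construction, which makes the *absolute* reduced free
energy accessible.  The generalized work function is

    φ_i(r) = u_i(r) + ln q_i(r),

fixed by the identities 1 = ⟨q⁻¹p⟩_q and 1 = ⟨p⁻¹q⟩_p for a normalized q:
when q_i = p_i exactly, φ_i ≡ f_i is constant.

### Estimators

With data samples r ∼ p_i ("MD" origin) and model samples r ∼ q_i ("BG"
origin), the six estimators are

* AVMD / AVBG: f ≈ ⟨φ⟩ over data / model samples — exact only in the
  perfect-map limit; their divergence from the others is an overfitting
  diagnostic, not a production estimator.
* EXPMD: f = ln ⟨e^{+φ}⟩_p; EXPBG: f = −ln ⟨e^{−φ}⟩_q (one-directional
  exponential reweighting; log-sum-exp throughout).
* BAR: the root of the two-distribution mixture identity
  Σ_pooled 1/(N_p + N_q e^{φ(r)−f}) = 1, solved by monotone bisection
  bracketed by the two EXP estimates (tolerance 1e-10).  The solution is
  invariant to a common rescaling of N_p, N_q.  A model-side mixture-share
  diagnostic (< 1e-6 at the root) rejects no-overlap problems.
* MBAR: the K-state self-consistent equations on *remapped* potentials
  u_{k→i}(r_k) = u_i(𝒯_{k→i}(r_k)) − ln γ_{k→i}(r_k), where
  𝒯_{k→i} = 𝒯_i ∘ 𝒯_k⁻¹ composes two maps through the base box and γ is its
  Jacobian determinant.  Solved by log-sum-exp self-consistent iteration to
  1e-13; gauge fixed at f_1 = 0.  Only data-origin samples enter by default
  (base-box samples could be added as a K+1-th state but are not).

Uncertainties: AV uses the standard error of the mean; EXP a first-order
delta method computed in log space; BAR and MBAR the standard asymptotic
covariance of the self-consistent mixture estimator,
Θ = Wᵀ(I − W N Wᵀ)⁺W, evaluated in its K×K reduced form through the SVD of
the N×K weight matrix.  During development the analytic BAR/MBAR errors were
checked against seeded bootstrap resampling (agreement within ~5%).

### Entropy decomposition

From f_i = ⟨u_i⟩_{p_i} − s_i it follows that Δs_ij = C_ij − Δf_ij with
C_ij = ⟨u_j⟩_{p_j} − ⟨u_i⟩_{p_i}.  Throughout the package Δf_ij denotes
f_j − f_i (and Δs_ij = s_j − s_i), which is the sign convention this identity
forces.  The energy means come straight from the data and are independent of
the maps; the two error terms are propagated in quadrature (they are treated
as independent, a first-order approximation since Δf is estimated from the
same data).

## Flows

The trainable map is a stack of rational-quadratic spline coupling layers
(default 4 layers, 16 bins, 2×64 tanh conditioner), each strictly monotone on
[a,b] with both endpoints fixed.  Layers are oriented in the normalizing
(r→z) direction; sampling inverts each bin's rational-quadratic analytically
(stable quadratic root plus two Newton polish steps, restoring ~1e-9
round-trip accuracy through a 4-layer stack).  Masks alternate between the
even and odd coordinate subsets; in one dimension every layer is an
unconditional spline carried by the conditioner's bias path.

All parameters are initialized so every layer is the identity (uniform knots,
unit derivatives via a softplus offset, zero final conditioner layer), hence
training starts exactly at q = p_0 and early-training diagnostics are
interpretable.  Out-of-domain configurations get ln q = −∞ (zero density)
rather than being clamped, preserving normalization.  The whole log-density
path is double precision.

Gradients of the maximum-likelihood loss
L_ML = −(1/N) Σ ln q(r_n) are computed by hand-written reverse-mode
differentiation through the spline, the knot parameterization (softmax
widths/heights with a 1e-4 minimum bin fraction, softplus derivatives) and
the conditioner; the implementation is NumPy throughout and is verified
against central finite differences in the test suite (relative agreement
~1e-6).

## Training protocol

Adam (learning rate 0.001, default moments), minibatches of 1000 examples
drawn without replacement via epoch-wise seeded shuffling (partial final
batches dropped; data sets no larger than one batch are used whole).  Every
50 batches (first at 50) an evaluation callback receives the current model;
the full study evaluates all six estimators on the training split, the
validation split and 1000 freshly drawn model samples at every event.
Optionally, at a configured batch the training and validation splits are
swapped and the parameters, optimizer moments and epoch cursor are reset to
their initial state, so the second half of training replays the protocol
with the roles of the two splits exchanged.  Training is bit-reproducible
from the config seed.  A divergent batch (infinite loss) aborts with a
diagnostic rather than being skipped.

## Synthetic systems

The 3D toy system is six isotropic harmonic wells (soft-min combination,
smooth and finite on the unit box) grouped two per state into three 2-modal
metastable states.  Defaults: stiffness k = 100 (σ = 0.1) at the corners of
a side-0.5 cube centred in the box, so all pairwise separations are 0.5 =
5σ (the non-overlap requirement), with energy offsets (0, 0.5), (1.0, 1.5),
(0.75, 0.25) making the three state free energies distinct and the wells
within a state unequally populated.  Ground truth is midpoint-rule
quadrature (f_i stable to <1e-3 under doubling the default 128³ grid;
quadrature is refused above 3 dimensions).

Data sets are generated by a Metropolis random walk restricted to the state:
proposals whose cluster label differs from the target are rejected, the
step size adapts to ~40% acceptance during burn-in (1000 steps) and is then
frozen, and samples are thinned (stride 5).  Because a local random walk
cannot cross between two narrow wells 5σ apart, 10% of proposals are
symmetric between-well translations r → r + (c_other − c_near), making the
chain ergodic over the whole 2-modal state — the locally-ergodic-data
premise of the protocol.  Gaussian-mixture systems with closed-form
f_i = −ln Σ_c mass_c, exact direct samplers, and exact Gaussian-CDF maps
provide the analytic end of the test spectrum.

What the synthetic systems do not emulate: molecular dimensionality (tens of
degrees of freedom), roto-translational invariance, internal-coordinate
representations, anharmonic mode coupling, and correlated time series from
real dynamics.  Passing tests therefore demonstrate the correctness of the
estimator machinery and the qualitative train/validation phenomenology, not
the adequacy of any particular flow architecture for molecules.

## Assessment study

The reference study (reproduced by `flowfe assess-toy` and
`scripts/acceptance.py`) uses 1000 training + 1000 validation points per
state, 2000 training batches with the swap-and-reset at batch 1000, and
evaluations every 50 batches; these sizes keep the full study within a few
minutes on one CPU while clearly exhibiting both behaviors of interest
(validation-side convergence, training-side overfitting).  Coverage is the
fraction of post-burn-in events (first 10% excluded) whose estimate lies
within two analytic standard errors of the quadrature truth; by design this
operationalizes "remaining converged around the ground truth".  The
overfitting report gives, per state, the batch maximizing AVMD on the
validation split (early-stopping heuristic), flags validation-side BAR/MBAR
error-bar series that grow in trend over the last half of training (slope >
0 and terminal/initial ratio > 1.2 — the ratio guard avoids flagging
constant series through floating-point slope noise), and the
train-vs-validation gap series.  The energy-sanity fraction reports the
share of model samples within 100 k_BT of the potential minimum.

## Numerical choices and edge cases

* Penalized energies (≥1e18) are treated as +∞ in every weight path to avoid
  overflow while the reported values keep the 1e20 convention.
* Model samples outside their state or the domain: excluded (with count
  reported) from AV averages, but kept — at exactly zero weight — in the
  denominator of EXPBG and in BAR/MBAR, where they are legitimate draws
  whose integrand vanishes.
* MBAR refuses problems whose state-overlap graph is disconnected (named
  components in the error) or whose sample rows are nowhere finite.
* The master seed fans out to per-stage seeds through
  `numpy.random.SeedSequence.spawn`; every stage (sampling, per-state
  training, per-event model draws) has its own child, so traces are
  byte-identical across reruns.
* Cluster ties (exactly equidistant centers) resolve to the lowest well
  index via `argmin`.

## Known limitations

* The asymptotic BAR/MBAR covariance assumes independent samples; MCMC
  autocorrelation in the toy data slightly inflates true errors relative to
  the analytic bars.
* AV/EXP error bars are first-order delta-method estimates and understate
  the error when the weight distribution is heavy-tailed (exactly the
  overfit regime they are meant to flag).
* The entropy error bars ignore the correlation between C_ij and Δf_ij.
* Spline flows with very large parameter excursions develop sub-grid density
  spikes (minimum bin width 1e-4·L); quadrature normalization checks are
  meaningful for moderate parameter scales such as those reached by
  training.
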