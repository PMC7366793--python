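# Methods

## Muscle model

Muscles are modelled as Hill-type actuators with a rigid tendon: the tendon
is fixed at its slack length `lts`, so the fiber state follows directly from
the musculotendon kinematics and the model is stateless. With the
constant-thickness pennation assumption (sin α · l_fiber = sin α₀ · l₀), the
fiber length is l_fiber = √((lmt − lts)² + (l₀ sin α₀)²) and
cos α = (lmt − lts)/l_fiber. The force of a muscle is

    F = f_max · (a · fL(l̃) · fV(ṽ) + fPE(l̃)) · cos α

with normalized fiber length l̃ = l_fiber/l₀ and normalized fiber velocity
ṽ = vmt·cos α/(vmax·l₀), lengthening positive. The normalized curves are
pluggable; the defaults are

* active force–length: Gaussian exp(−((l̃−1)/0.45)²), fL(1)=1;
* force–velocity: 0.318·asinh(8.149·ṽ) + 1 clamped at 0, smooth and
  monotone with fV(0)=1, ≈0.11 at ṽ=−1 and ≈1.9 in fast lengthening;
* passive: 0.05·(exp(8(l̃−1))−1) for l̃>1, else 0.

`UNIT_CURVES` (fL=fV=1, fPE=0) exists purely so that analytic oracles in the
tests have closed forms. The exact curve shapes are a modelling choice — any
smooth non-negative set works — and all solvers exploit only the structural
fact that, for fixed kinematics, force is *affine* in activation:
F = gain·a + passive. `lmt ≤ lts` anywhere raises a degeneracy error naming
muscle and frame; passive force can be disabled globally (`passive_enabled`).

Joint moments are the linear image of forces through the signed moment-arm
Jacobian, Q[j,k] = Σᵢ r[j,k,i]·F[j,i]; r > 0 means the muscle produces a
positive moment about that DOF.

## Static optimization (SO)

Each frame solves min Σ aᵢ² subject to Q^MT(a) = Q^ID and 0 ≤ a ≤ 1. With
the affine force map the constraints are linear, so each frame is a strictly
convex QP with a unique solution; it is solved by SLSQP with analytic
gradients, constraints row-scaled by the per-DOF maximum |Q^ID| over the
trial, default residual tolerance 1e−6 (relative). Frame 0 takes the best
feasible result over five seeded uniform-random initial guesses; later
frames warm-start from the previous optimum (activation varies smoothly
within a gait cycle, and convexity guarantees warm and cold starts agree).
A frame whose constraints cannot be met within bounds raises an
infeasibility error carrying the best residual; an optional reserve mode
(off by default) replaces the hard equalities with a quadratic penalty,
mimicking reserve actuators. Because the constraints are equalities, SO's
moment-tracking VAF is 100% up to round-off on any feasible trial — a
structural property, not a fit.

## Synergy optimization (SynO)

Activations are constrained to a_{f×m} = C_{f×n_s}·V_{n_s×m}, each column
of C a clamped cubic B-spline with p = round((f−1)/5 + 1) control nodes
(half-up rounding; uniform interior knots over the trial duration; the
degree drops to p−1 when fewer than 4 nodes exist). The cost over all
frames j, DOFs k and muscles i is

    J = Σ_j [ β Σ_k ((Q^MT_jk − Q^ID_jk)/max_t|Q^ID_k|)²
              + Σ_i (a_ij² + λ_ij (a_ij − 1)²) ]

with β = 100, λ_ij = 1e5 when a_ij > 1 and 0 otherwise. The normalizer is
the per-DOF maximum absolute inverse-dynamics moment over the whole trial
(falling back to 1, with a warning, for an identically zero DOF).
Activations are non-negative by construction (non-negative spline basis,
nodes and weights), so only the upper bound needs the penalty; values above
1 are penalized, never clipped.

Design variables are the n_s·(p+m) stacked nodes and weights, with linear
equalities Σᵢ V_sᵢ = 1 per synergy (making the C/V factorization unique) and
zero lower bounds. The problem is non-convex; it is solved by SLSQP with the
closed-form analytic gradient (available because moments are affine in a)
from five seeded random feasible starts — V rows drawn from a flat
Dirichlet, nodes uniform on [0, 1] — keeping the lowest-cost feasible
solution. Seeded random multistarts replace a genetic-algorithm seeding
stage sometimes used for this problem; both only supply initial guesses to
the same gradient solver, and seeded starts are deterministic and portable.

## SO-NMF

`fit_nmf_l1` factors the non-negative SO activation matrix into H (f×n) and
W (n×m) by Lee–Seung multiplicative updates on ‖a − H·W‖_F, with each W row
rescaled to unit sum after every iteration and the scale absorbed into H — a
reparameterization that leaves the cost exactly unchanged (an L2 row norm is
available but non-default). Convergence: relative Frobenius-error change
below 1e−6 or 500 iterations; best of 10 seeded restarts. Reconstructed
activations a* = H·W are pushed back through the muscle model to obtain
reconstructed forces and moments; since the factorization never sees joint
moments, the reconstructed moments track Q^ID strictly worse than SO's exact
ones whenever n is below the effective rank of the SO solution.

## EMG processing

Envelope extraction rectifies each channel, low-pass filters it with a
zero-phase forward–reverse Butterworth (default 5th order, 15 Hz cutoff;
the magnitude response of the pass is the squared one-pass response), clips
filter undershoot at zero and normalizes by the per-channel maximum over the
record. An equivalent singular-spectrum-analysis path embeds the rectified
channel in a Hankel matrix with window length 250 samples and reconstructs,
by diagonal averaging, from the eigentriples whose left singular vector has
its dominant frequency at or below the cutoff. Component selection by
frequency (rather than by cumulative singular-value energy) is what makes
the SSA path behave like the low-pass filter: broadband noise spreads its
energy over many eigentriples, so energy thresholds retain it, while the
frequency rule discards it. All-zero channels are returned as zeros and
flagged rather than divided by zero. Envelopes are linearly interpolated
onto the motion time base before any comparison.

## Evaluation

* VAF = 100·(1 − Σ(q_ref−q_est)²/Σ q_ref²), the uncentered form standard in
  the synergy literature (a mean-centered variant sits behind a flag);
  applied per DOF and averaged for summaries; undefined for an all-zero
  reference.
* Lagged Pearson r: the maximum *signed* r over integer-sample lags within
  ±100 ms, computed on the overlapping samples at each lag, ties broken
  toward the smallest |lag|. A positive lag means the second series lags the
  first — EMG lags activation by the electromechanical delay. Signed
  maximization (not |r|) matches the use of r to compare activation shapes.
* Activation similarity: mean over muscles of the squared zero-lag Pearson
  correlation between two activation matrices, skipping constant columns.

`build_comparison_report` assembles tidy per-DOF VAF, per-channel r and
per-n r² tables across SO, SynO and SO-NMF.

## Synthetic data

The generator emulates one gait cycle of solver inputs as smooth periodic
functions of cycle phase:

* moment arms: per muscle–DOF Fourier series (≤4 harmonics, amplitudes
  decaying as 1/h) around a signed constant term; each muscle spans 1–3
  DOFs; magnitudes stay below 0.12 m (lower-limb moment arms rarely exceed
  ~8 cm; the scale is a choice, not a fit to any subject);
* musculotendon lengths: lts + l₀·(1 ± 15% over two harmonics), which keeps
  the rigid-tendon geometry non-degenerate; velocities are the exact
  analytic derivative, so kinematic consistency is limited only by the band
  limit of the parameterization;
* Hill parameters: f_max ∈ [300, 2500] N, l₀ ∈ [5, 13] cm, lts ∈ [12, 35]
  cm, α₀ ∈ [0, 0.35] rad, vmax = 10 l₀/s — generic adult lower-limb ranges;
* ground truth: n_true Gaussian-bump synergy activation profiles (centers
  spread over the cycle, widths 8–14% of the cycle, small 0.02 baseline)
  times unit-sum non-negative synergy vectors, scaled so the peak activation
  is 0.85 — inside the bounds, so the truth is strictly feasible for SO;
* inverse-dynamics moments: produced from the true activations by the same
  muscle-model code path the solvers use, so SO's equality constraints are
  feasible by construction and SynO's cost at the truth has zero tracking
  error;
* EMG: per-channel delayed (positive delay = EMG lags activation),
  crosstalk-mixed, rectified copies of true activations resampled to the
  EMG rate, with additive Gaussian noise on the envelope scaled to a
  fraction of channel amplitude. Raw interference-pattern EMG is *not*
  modelled — the pipeline consumes envelopes.

When the plant is supplied, each ground-truth synergy vector is built as the
non-negative part of the minimum-effort activation pattern for a random
direction in moment space (muscles weighted by moment-arm × force gain,
multiplicatively jittered, normalized to unit sum). This mirrors the
motor-control view of synergies as task-effective muscle groupings, and it
is what makes the planted structure *identifiable*: effort-penalized moment
tracking can only recover synergy vectors that are near-optimal for the
effort term. With arbitrary (e.g. flat-Dirichlet) synergy vectors the
optimizer legitimately finds lower-cost solutions whose vectors differ from
the truth; that fallback remains available for generating generic feasible
trials.

All generators are pure functions of their seeds (identical seed →
bit-identical arrays).

### What passing tests do and do not show

The synthetic trials are smooth, periodic, noise-free in the plant, exactly
forward-consistent, and have exactly low-rank ground-truth activations.
Real gait data have soft-tissue artefact, model-scaling error, inconsistent
inverse dynamics (no activation pattern reproduces the moments exactly
without residuals), and at best approximately low-rank activations.
Passing the recovery and exactness tests therefore validates the
*algorithms* — constraint handling, gradients, factorization, metrics — not
the fidelity of any subject-specific musculoskeletal model.

## Numerical choices

* SO: SLSQP ftol 1e−14, max 300 iterations per frame, constraint tolerance
  1e−6 relative to the per-DOF moment scale; one retry from the clipped
  least-squares point before declaring a frame infeasible.
* SynO: SLSQP ftol 1e−10, max 400 iterations, equality drift removed by a
  final row renormalization of V; solutions with constraint violation above
  1e−6 or negative variables below −1e−8 are discarded as infeasible starts.
* NMF: ε = 1e−12 guards in the multiplicative updates.
* Problem sizes in the test suite: full study dimensions (m=43, d=6, f=101)
  for the SO exactness check, where a trial solve takes well under a second;
  m=10–12, f=41–51 for the SynO recovery and trend studies, sizes at which
  the five-start solves finish in seconds while preserving every structural
  property under test.

## Known limitations

* No activation dynamics (excitation→activation ODE) and no compliant
  tendon; both matter for fast movements, less so for gait-speed analyses.
* The SynO landscape is non-convex; five random starts find consistent
  optima at the tested sizes, but larger problems may need more starts.
* Moment arms are inputs, not derived from a geometric path model, so
  moment-arm/length consistency (∂lmt/∂q = −r) is not enforced.
* EMG synthesis adds envelope-level noise only; crosstalk mixes envelopes,
  not interference signals.
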