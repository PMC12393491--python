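# Methods

This note records the models, conventions, and numerical choices behind
`capdyn`, the open design decisions it settles, and what the synthetic
cohorts its tests run on do and do not emulate.

## State extraction

Frames are points in R^N. Subject series are z-scored per ROI across
time with the population (1/T) standard deviation; the correlation
distance is invariant to this choice, so it is fixed purely for
bit-reproducibility. Constant ROIs are zeroed with a warning rather
than rejected, so one degraded region cannot abort a cohort run.

The clustering is PAM k-medoids (greedy BUILD + swap) under
d = 1 − Pearson r. Because the correlation of two frames is the dot
product of their centered unit-norm versions, all pairwise distances
are inner products of an N x T frame factor; the BUILD and swap sweeps
are chunked matrix products, with the full T x T table cached up to
T = 10,000 (in float32 above T = 3,000, where the ~1e-7 absolute
rounding is negligible against distances of order 1; small instances
stay float64 so toy problems match exhaustive enumeration exactly).
The swap phase evaluates every (candidate, medoid) exchange per pass,
re-verifies proposed swaps exactly before applying them, and asserts
monotone descent of the objective each step.

BUILD is deterministic, so running it once per restart would make
restarts redundant: restart 0 uses BUILD and the remaining restarts use
seeded random medoid draws. The returned solution is the restart with
the minimum total within-cluster distance; `restart_rule="max"` exists
for compatibility with a maximum-inertia reading, but inertia
minimization is the default because it is the standard objective.
Empty clusters (possible only through duplicate frames chosen as two
medoids) are re-seeded to the farthest frame and logged. Final states
are relabelled so medoid indices are ascending — label identity is
otherwise arbitrary.

Downstream analyses use cluster-mean centroids (the "non-binary state"
patterns); the medoid frames remain available on the solution object
for workflows that require states to be observed volumes.

### K selection

Per k in a contiguous scan (default 2..17 at full scale; the upper end
comes from the smallest k with k² exceeding the ~286 frames of a
10-minute TR 2.1 s scan, k = 17):

- explained variance EV(k) = 1 − Σ d(t, medoid(t))² / Σ d(t, grand medoid)²,
  with the grand medoid minimizing the total squared distance, so
  EV(1) = 0 and EV(T) = 1 by construction. The squared-distance form is
  one of several monotone variants; it is declared here and used
  consistently.
- variance gain EV(k) − EV(k−1), with taper threshold 0.01;
- mean medoid silhouette s = (d₂ − d₁)/max(d₁, d₂) over frames
  (0/0 defined as 0);
- fraction of subjects with at least one absent state (default
  admissible ≤ 0.25);
- maximum pairwise centroid correlation (default ≤ 0.5).

`select_k` returns the smallest k passing all criteria, logging every
decision; when no k passes, the best-compromise k (highest silhouette
at admissible absence) is returned flagged non-conclusive. Split-half
stability clusters random half-splits of the frame cloud and matches
centroids by Hungarian assignment on the Pearson correlation matrix —
assignment rather than greedy matching keeps the bijection
deterministic and order-independent.

## Temporal dynamics

Dwell time is the mean maximal-run length times TR (seconds); states a
subject never visits are reported missing (NaN), not zero, to avoid
biasing group means. Fractional occupancy is the percentage of frames
per state. Transition probabilities discard self-transition frame
pairs and divide each i→j switch count by the **total** switch count
(joint convention). Under the row-conditional alternative, every
subject's exit probability is identically 1/(K−1), which makes
between-subject exit/enter contrasts impossible; the joint convention
is therefore the default, with `normalization="row"` available. All
sequence metrics are computed strictly per subject; cohort label
vectors are cut at subject boundaries first.

The permutation null shuffles the **order of runs** (preserving the
run-length multiset and occupancies) rather than frames, because the
transition statistic conditions on run structure; adjacent same-state
runs merge naturally under permutation. p = (1 + #{null ≥ obs})/(1 + n).
Because the statistic is discrete, these p-values are valid
(super-uniform) but conservative, not exactly uniform — the test suite
checks validity, not uniformity. Sequences with fewer than 3 runs have
no permutable order and are skipped with a flag.

## Phase-randomized surrogates

Per ROI: FFT, random phases e^{iθ} on positive frequencies (mirrored
conjugate on negative; DC and, for even T, the Nyquist bin stay real —
the Nyquist bin gets a random sign), inverse FFT. This preserves each
ROI's amplitude spectrum, hence mean, variance and full
autocorrelation, to machine precision. "Independent" mode draws phases
per ROI and destroys spatial co-activation — the structure the
clustering feeds on — which is the appropriate null for cluster
quality; a "locked" mode (one shared phase draw) preserves zero-lag
cross-correlation for analyses that need it. Surrogates are generated
per subject before concatenation so subject boundaries match the real
pipeline. The real-vs-null comparison reruns the identical clustering
pipeline on each surrogate cohort and reports silhouette and
within-cluster-variance differences with permutation-style p-values.

## Control energies

The connectome W (symmetric, nonnegative, zero diagonal) is stabilized
as A = W/(λ_max(W) + c) − I with c = 1, placing the spectrum in
[−2, 0). The offset convention is absolute (the prevailing
continuous-time form in the network-control literature); note it is not
invariant to rescaling W unless c is rescaled with it — the ratio
identity a_norm(sW, sc) = a_norm(W, c) is what holds exactly, and c is
exposed in the config.

The optimal control problem — minimize
∫₀ᵀ (x−xf)ᵀS(x−xf) + ρ uᵀu dt subject to dx/dt = Ax + Bu, x(0) = x0,
x(T) = xf, with defaults ρ = 1, S = I, B = I (uniform full control
set), T = 1 — is solved via the Hamiltonian system: u = −Bᵀp/(2ρ)
closes a linear state/costate ODE with constant forcing, propagated
exactly by one (2N+1)-dimensional matrix exponential; p(0) comes from a
linear solve against the terminal condition. A condition number above
1e12 on the boundary block raises (target unreachable in the horizon),
and every result is gated on ‖x(T) − xf‖ ≤ 1e-6·(1 + ‖xf‖). Energies
are trapezoid integrals of u_i² over 1001 uniform samples by default
(the solve itself is step-free; only the quadrature depends on the
grid, converging as O(dt²) — energies change < 0.01% between 1001 and
2001 steps). Energies are in arbitrary units and scale quadratically
with state magnitude; states enter in raw z-units by default with a
unit-norm rescaling option.

State-to-state energies fill a K x K matrix (generally asymmetric);
diagonal self-maintenance energies are computed but excluded from the
exit/enter means, which average the off-diagonal row (exit) and column
(enter) per state. Exit > enter classifies a state sink-like (local
minimum of the landscape); depth_rank orders states by mean(exit,
enter) ascending. An independent cross-check discretizes the same
problem as a sparse KKT quadratic program over piecewise-constant
controls (tests/_oracles.py); solver and oracle agree to ~1e-5
relative on small systems, far inside the 0.5% test band.

## Statistical layer

Group contrasts are pooled-variance (Student) t-tests
(df = n_a + n_b − 2, so 38 + 38 gives df = 74; paired df = n − 1, so
53 pairs give df = 52). Symptom models are OLS of the outcome on the
clinical score with sex (0/1), medication (0/1) and age (years,
uncentered) as covariates; per-group fits and a pooled
group-interaction variant are both provided. Rank deficiency raises
with the collinear columns named. Multiplicity control is BH step-up
or Bonferroni over a family declared by the caller — comparison
families are configuration, not hard-coded.

## Synthetic cohorts

The generator emits, per subject: a 1-based Markov state sequence
(initial state from the stationary distribution, avoiding burn-in
bias), BOLD frames equal to the active state's centroid plus AR(1)
Gaussian noise ε_t = φ ε_{t−1} + η_t started from its stationary law
(marginal variance noise_sd²/(1−φ²)), a modular weighted connectome
(log-normal weights, denser/heavier within network modules, connected
by construction with regeneration on the rare disconnected draw), and
clinical scores equal to a group baseline plus a linear coupling to the
subject's realized fractional occupancy of a designated state plus
Gaussian noise.

Defaults mirror the target study design: 38 + 38 subjects, N = 85 ROIs
over 8 resting-state networks (VIS/SOM/DAT/VAT/LIM/FPN/DMN/SUB), 286
frames at TR 2.1 s, K = 4 planted states built from fixed network sign
designs (pairwise correlation < 0.3), AR coefficient 0.45, unit
innovation SD (signal and noise of comparable scale), self-transition
probability 0.75 (dwell ≈ 8 s). The patient group's planted deviations
destabilize state 3 (self-transition 0.65, heavier 2↔3 switching) and
weaken 1↔4 transitions; clinical coupling defaults to 0.5 score units
per occupancy percent on the depression/anhedonia columns with noise
SD 2.

AR(1) noise is a minimal stand-in consistent with an
autocorrelation-matched null — it is not a claim about the spectral
content of real BOLD. The generator also does not emulate
hemodynamics, motion artifacts, inter-subject spatial variability of
the state patterns, or realistic tractography; passing tests therefore
demonstrate correctness and calibration of the *method* under its own
assumptions, not performance on real scans.

## Test and acceptance scales

The unit suite runs on small cohorts (8 + 8 subjects x 120 frames x 40
ROIs for the shared fixture). The acceptance checks use: 38 + 38
subjects x 60 frames x 85 ROIs (T = 4,560) for state recovery and K
selection over k = 2..8 at 10 restarts; 20 random systems of N ≤ 3 for
the control oracle (800 segments); the full N = 85 connectome for the
terminal gate over all 16 state pairs; 10,000-frame chains for Markov
recovery; 100 surrogate seeds for spectrum/autocorrelation checks; 20
seeds of real-vs-null comparisons; 2,000 replicates for t-test
calibration and 60 for OLS sign recovery. These sizes are the
package's test-scale choice; the recovery and calibration bands are
properties of the method, and the full-scale configuration (286 frames,
k = 2..17, 50 restarts) remains available through the config/CLI.

## Known limitations

- PAM is a local search; global optimality is verified only on small
  instances (and holds there), while large instances rely on restarts.
- The energy landscape depends on the stabilization constant c and on
  state scaling; both are exposed, and cross-study comparisons should
  fix them.
- Joint transition probabilities couple all pairs within a subject
  (they sum to 1), so per-pair group tests are not independent; the BH
  family correction treats them as a family, nothing more.
- Clinical coupling in the generator is linear with Gaussian noise;
  calibration results do not speak to heavy-tailed or censored score
  distributions.
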