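# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `allokin`, in the spirit of a methods appendix.

## Reaction model

The reaction coordinate is a single torsion angle ω (degrees).  Its
potential is a sum of cosine dihedral terms

    V(ω) = α · Σ_n (V_n/2) [1 + cos(n ω − γ_n)]  +  background terms,

with the standard double well given by one term (n = 2, V₂, γ = 180°):
minima at 0° (cis) and 180° (trans), barrier height V₂ at ±90°.  The
scaling factor α ∈ (0, 1] multiplies only the dihedral term, emulating
barrier-reduced ("modified") potentials; optional background terms are
never scaled and stand in for the molecular environment (they produce
asymmetric well depths).  Angles are wrapped to [−90°, 270°) so both
wells and the studied barrier at ≈90° are interior; the symmetry-related
pathway through 270° is outside the modelled range.

Constants: k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, T = 300 K
(k_BT = 0.59616 kcal/mol) unless overridden.

## Overdamped dynamics

The generator integrates the overdamped Langevin equation with
Euler–Maruyama:

    ω ← ω − β D (dV/dω) Δt + sqrt(2 D Δt) η,   η ~ N(0, 1),

with D in deg²/s.  A construction-time guard requires the per-step RMS
displacement sqrt(2 D Δt) < 1°; the desk experiments use 0.8°
(D = 10⁸ deg²/s, Δt = 3.2 ns), for which the residual discretization
bias in equilibrium statistics is ≲0.3% of k_BT.  Trajectories are
bit-reproducible from the seed; child streams (windows, replicas,
bootstrap) are derived through `numpy.random.SeedSequence` spawning.

Harmonic restraints use U = ½ k (Δω)² with a minimum-image angular
difference; the equipartition variance k_BT/k is the unit test for this
convention.

Escape replicas start at 180° and terminate at the first saved sample
whose wrapped angle crosses the transition-state threshold (one event
per replica).  Because the synthetic double well is symmetric, the trans
well would have two equivalent saddles (90° and 270°); a reflecting wall
at 270° (default, removable) closes the second pathway so escape is the
single-saddle process that the one-pathway Kramers model and the
real reaction describe.  The save stride in the rate experiments is kept
short (≈1.6° RMS displacement between samples) so that sample-resolution
detection approximates true first passage to the threshold.

## Free-energy estimation

WHAM iterates the standard self-consistent equations over window
free-energy shifts until the maximum shift change falls below the
tolerance (default 10⁻⁶ kcal/mol); windows must overlap into a single
connected component.  Default binning: 80 uniform bins on
[−31.5°, 208.5°], half-open assignment; empty bins are flagged NaN and
never interpolated, and profiles are anchored to min A = 0.

Errors come from a Monte Carlo bootstrap (default 10 trials, seed 1234):
each trial resamples every window at its decorrelation stride (random
phase, then sampling with replacement), and the per-bin error is the SD
across trials.  The decorrelation time is twice the 1/e autocorrelation
decay lag of ω(t).

Wells are the profile minima within ±45° boxes around 0° and 180°; the
transition state is the maximum strictly between them.  Barrier heights
are bin differences with errors combined in quadrature.  Curvatures are
twice the quadratic coefficient of an inverse-variance-weighted parabola
fit around each stationary point.  The default half-window is 10°
(≥4 bins at the default binning); the Kramers desk experiment widens it
to 20°, where the quadratic remains a ≲3% approximation to the cosine
profile and the curvature noise drops ~3-fold — without this the
transition-state curvature sign is not resolved at the experiment's
sampling depth.

## Barrier-scaled extrapolation

For profiles measured at several α, a first-order cumulant expansion
gives A(ω; α) ≈ A₀(ω) − (1−α) B(ω) per bin.  Profiles are first
superposed by matching values at the bins nearest 0° and 180°, where the
scaled term vanishes; a per-bin regression of A on (1−α), weighted by
inverse bootstrap variances (unweighted fallback for noiseless inputs),
yields A₀ as the intercept with its standard error and −B as the slope.
Higher cumulants are omitted by design.  In the 1-D generator the
relation is exact, so any deviation from a directly sampled α = 1
profile is purely statistical; note the long lever arm (from 1−α ≈ 0.7
to 0) amplifies per-bin noise into intercept errors roughly 15-fold,
which the reported errors reflect.

## Survival kinetics

Events are first crossings of the transition-state angle at sample
resolution, one per replica; replicas that never cross are
right-censored at their final time.  S(t) is the Kaplan–Meier
product-limit estimate with 95% exponential-Greenwood confidence
intervals (via lifelines), evaluated on a uniform grid.  Rates come from
confidence-interval-weighted exponential fits: for one component, a
weighted linear regression of ln S on t through the origin with weights
1/(CI half-width of ln S)²; for mixtures Σ A_i exp(−k_i t) with A_i,
k_i > 0 and Σ A_i = 1, deterministic multi-start nonlinear least squares
weighted by 1/(CI half-width of S)².  The effective rate is the
amplitude-weighted mean Σ A_i k_i / Σ A_i.  Model size can be selected
by small-sample AICc with the weighted SSR floored at machine precision
(so exact fits are ranked by parameter count alone).

## Kramers regression

For each reduced barrier the pipeline collects ΔG‡, the well and barrier
curvatures, and the fitted rate.  One convention matters: the survival
analysis measures *arrival at the transition state*, whereas Kramers'
expression describes *completed* well-to-well transitions; for diffusive
dynamics the committor at the saddle is ½, so the transition rate is
half the TS-arrival rate.  The desk experiment applies this factor when
building regression points and validates the extrapolated rate against
the completed-transition oracle (0.5/MFPT); omitting it would bias D_eff
up by ≈2× — the size of the acceptance band.

The regression fixes the slope at −1/k_BT: the intercept
c = ln(β D_eff/2π) is the inverse-variance-weighted mean of
ln(k_i/ω₀ᵢω_bᵢ) + βΔG‡ᵢ, with point variances from first-order
propagation of the rate, curvature and ΔG‡ errors.  ω₀, ω_b are square
roots of the absolute curvatures — the only dimensionally consistent
reading with D in deg²/s.  Extrapolation evaluates the Kramers
expression at the target ΔG‡ (obtained here by direct umbrella sampling
of the unscaled potential) with the fitted D_eff.

Error propagation throughout is first-order (delta method):
s_f² = Σ (∂f/∂x_i)² s_i².  It agrees with Monte Carlo within a few
percent for ≤10% relative input errors; it under-covers for strongly
nonlinear forms at larger errors.

## Collective-mode detection

Frames are rigid-body superposed (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on the masked atoms,
defaulting to the mean structure as reference.  Multiensemble PCA
diagonalizes the pooled covariance of the masked Cartesian coordinates;
the functional PC maximizes |Pearson ρ| between per-frame projections
and the window reference ω among the top 10 PCs (the best-correlated PC
is often not PC1).  PLS-FMA (scikit-learn PLS1, no scaling) regresses ω
on the coordinates; the functional mode is the unit-normalized
coefficient vector, and the component count n maximizes the mean
test-fold correlation under seeded 10-fold cross-validation (grouped
leave-window-out folds are available because random frame folds share
window structure).  With n equal to the data rank PLS reproduces
ordinary least squares, which is tested.

## Synthetic study conditions

All desk experiments fix D_true = 10⁸ deg²/s, Δt = 3.2 ns, T = 300 K,
49 umbrella windows (−30°…210°, 5° spacing, k = 0.01 kcal mol⁻¹ deg⁻²,
window i+1 seeded from window i's final state), 150 000 steps per window
saved every 10 steps, and bootstrap errors with 10 trials.

* WHAM recovery: V₂ = 8.4 kcal/mol, α = 1; compared with the binned
  Boltzmann free energy by quadrature on bins with ≥100 samples after
  removing the free additive constant.  This fixture alone runs 400 000
  steps per window: window-shift noise accumulates as a random walk
  along the 49-window chain, and the longer production keeps the
  accumulated drift well below the per-bin target accuracy (window
  lengths are convergence-driven, as in the real protocol).
* Extrapolation: V₂ = 6 kcal/mol with a one-fold background of
  1 kcal/mol (asymmetric wells), α ∈ {0.25, 0.30, 0.35}, against direct
  sampling at α = 1.
* Kinetics: 4 kcal/mol barrier, 100 replicas capped at 3.2 mean
  first-passage times (≥90 events), single-exponential fit against the
  finite-difference MFPT oracle with identical boundary conditions.
* Kramers: barriers 4/5/6 kcal/mol on V₂ = 12 with 60/40/24 replicas
  (counts chosen so the full suite stays inside a practical runtime at
  ~2×10⁷ integrator steps/s; the rate SE at the deepest barrier is
  ≈20%, well inside the factor-2 band), extrapolated to V₂ = 12.
* Modes: 50 atoms, 10 windows × 50 frames.  The mixed fixture couples a
  random unit mode at 0.02 Å/deg (≈1.5 Å SD over the window ladder)
  under five orthonormal noise modes of 1.5 Å SD and 0.3 Å isotropic
  jitter — noise variance above signal, so leading PCs mix directions
  and the functional PC underperforms PLS-FMA.  The one-mode fixture
  (no orthogonal noise modes) is used for cross-validated dimension
  selection: with correlated high-variance noise present, a second PLS
  component genuinely improves test correlation by repairing
  weight-estimation noise, so the CV argmax legitimately exceeds the
  generative dimension there.  A zero-coupling twin provides the null.

## What the synthetic data does and does not emulate

The generator reproduces the structure of the real analysis — biased and
unbiased sampling on a scaled-barrier torsional landscape, censored
escape kinetics, ensembles whose collective mode tracks ω — with exact
ground truth for every recovered quantity.  It does not emulate:
position-dependent or memory friction (D is constant, so Kramers'
overdamped form is exact up to the harmonic-saddle approximation);
multidimensional reaction pathways or recrossing corrections; the
1-D reduction makes the cumulant extrapolation exact, whereas in a real
system higher cumulants contribute; and pseudo-structure ensembles carry
no physical stereochemistry.  Passing recovery tests therefore validates
the estimators and their error models, not force-field realism.

## Known limitations

* Rate-fit errors treat Kaplan–Meier grid points as independent; they
  are optimistic (the D_eff error inherits this through the weights).
* The comparative report's error digits follow strict first-order
  propagation of the stored table values; one published comparative
  error digit (the trans→cis phosphorylation barrier increase) differs
  in its error decimal from this arithmetic.
* WHAM assumes uncorrelated samples within bins; correlation is handled
  only through the bootstrap's decorrelation stride.
* The CV component count is the strict test-correlation argmax; on
  near-flat CV curves it is noise-sensitive (no parsimony rule is
  applied, matching the stated selection procedure).
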