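# Methods

This note documents the models, estimators, defaults and numerical
choices behind each `phrelay` stage, what the synthetic generators do and
do not emulate, and the known limitations.

## Units and conventions

Lengths in nm, times in ns, temperature in K, energies in kJ/mol, forces
in kJ/(mol·nm). Frames are 0-based; the time of frame *i* is
*i*·Δt with Δt the frame interval. The Boltzmann constant is taken as
k_B = R/1000 = 0.008314 kJ/(mol·K); free-energy conversions use
R = 8.314 J/(K·mol). All stochastic components take explicit integer
seeds (numpy `default_rng`); identical seeds give bit-identical outputs.

## Featurization

Trajectory I/O, superposition and RMSD go through mdtraj; positions are
always held in nm. Geometry-derived features are computed directly from
positions so the criteria are fully under this package's control:

- **Hydrogen bond**: present in a frame iff donor–acceptor distance
  ≤ `d_cut` (default 0.35 nm) and the H–donor–acceptor angle at the
  donor ≤ `angle_cut` (default 30°). This is the common geometric
  convention in MD analysis; source studies rarely state their criterion,
  so both cutoffs are configurable and echoed in outputs. A donor
  without a resolvable hydrogen is an error — there is no silent
  heavy-atom fallback.
- **Side-/main-chain tokens**: `"K257s"`-style selectors map to side
  chain (non-backbone heavy atoms plus hydrogens bonded to side-chain
  N/O/S) or main chain (N, H, C, O).
- **Pooling**: occupancies and population fractions pool frames with
  equal weight across replicas; histograms are computed per replica
  first and averaged. These are two deliberately different conventions —
  fractional populations are per-conformation statements, histogram
  bands quantify replica-to-replica variability.
- **Bootstrap band**: percentile interval over `n_boot` = 1000 resamples
  of *replicas* (not frames), respecting within-trajectory correlation.
  With ~10 replicas the percentile interval is known to undercover its
  nominal level slightly (≈91% observed coverage for a nominal 95% band
  in the test-suite simulation); the band is clipped to bracket the
  point estimate. A single replica yields a mean with the band flagged
  unavailable rather than a fake zero-width interval.

## PCA and tICA

PCA diagonalizes the pooled covariance of mean-centered features;
fitting both protonation ensembles jointly gives one comparable space,
and the explained-variance ratios sum to 1 by the trace identity.
Rank-deficient covariances drop their null directions with a warning.

tICA solves the generalized eigenproblem C(τ)v = λC(0)v. The lagged
covariance is symmetrized (forward + backward averaging), which forces a
real spectrum on finite data at the cost of a small bias for
non-reversible processes. C(0) is regularized by εI with
ε = 10⁻⁶·trace/dim so collinear features (duplicated distances are
routine) stay well posed; the regularization changes eigenvalues of
informative components by < 10⁻⁶ in the duplicated-feature test. For a
reversible process λ_i estimates the autocorrelation exp(−τ/t_i), so
t_i = −τ/ln λ_i.

Free-energy surfaces are 2D histograms converted to F = −kT ln p with
the minimum shifted to 0; empty bins are masked as +∞, never
interpolated. Difference densities p_A − p_B require a shared grid;
`compare_ensembles` histograms both ensembles on the union support.

## Common-nearest-neighbor clustering

Points a and b are density-connected iff both lie within r of each other
and their r-neighborhoods share ≥ n_c members (neither a nor b counts).
Clusters are connected components of this relation; components smaller
than `min_members` become noise (label −1). The neighbor search is an
exact KD-tree — no approximate search, so the production path can be
checked for *exact* label agreement against the O(n²) brute-force
reference on every input. Labels are deterministic: clusters numbered by
decreasing size, ties broken by smallest member index. There are no
default parameters; r and n_c depend entirely on the projected space and
must be supplied.

## Core-set Markov models

Core sets (one per non-noise cluster, or explicit intervals for 1D model
systems) are filled by milestoning: a frame outside every core inherits
the last visited core, frames before the first visit are discarded
(causal assignment, no backward fill). Transition counts use a sliding
window at lag τ and never cross replica boundaries. The reversible
estimator symmetrizes counts, C′ = (C+Cᵀ)/2, then row-normalizes —
simpler than iterative reversible MLE and adequate at these data sizes
(the iterative estimator is a noted extension hook). The estimate is
restricted to the largest strongly connected component of the directed
count graph. Detailed balance, a real sorted spectrum with λ₁ = 1, and
πT = π hold to 10⁻⁸ by construction.

Implied timescales t_i = −τ/ln λ_{i+1} are tabulated over a lag ladder;
a process is flagged converged when its relative spread over the upper
half of the ladder stays within a tolerance (default 20%). Negative or
complex eigenvalues beyond tolerance yield an undefined (NaN) timescale
for that lag and an unconverged flag.

## Rupture detection and cohort statistics

The opposing force in a constant-velocity pulling run rises roughly
linearly until the coordination bonds break, then collapses. The
detector smooths with a centered moving average (default window 0.1 ns),
takes the smoothed argmax as the candidate rupture, and accepts it only
if the smoothed force later stays below `drop_fraction`·max (default
0.5) continuously for ≥ `sustain_ns` (default 0.5 ns). A monotone ramp
returns `detected = False` rather than raising. The published analyses
locate the maximum visually; this rule is our operationalization, and
all three knobs are echoed in outputs. With window 0 and noiseless input
the rupture force equals the exact trace maximum.

Cohorts are summarized as notched boxes: quartiles by linear
interpolation (the convention is stated in the output, because tools
disagree), notch half-width 1.57·IQR/√n (a 95% CI on the median),
outliers beyond 1.5·IQR from the quartiles, whiskers at the extreme
non-outlier points. Median differences between conditions carry a
percentile-bootstrap CI. Undetected traces are counted separately and
never enter force statistics.

## Unfolding kinetics

Events are classified from feature series with a persistence window
(default 1 ns) to suppress single-frame excursions: the RMSD criterion
fires at the first time the long-loop Cα RMSD exceeds 0.2 nm and stays
above it; hydrogen-bond criteria fire at the first sustained break of
the named bond. Visual criteria cannot be automated and are accepted
only as externally supplied annotations. Trajectories with no event are
right-censored at their end time (the study design caps runs at 220 ns).

The rate estimator is the censored exponential MLE
k̂ = n_events/(Σ event times + Σ censoring times), which reduces to
1/mean for fully observed data. Its standard error is k̂/√n_events
(Fisher information), and the half-life t₁/₂ = ln 2/k̂ carries the
delta-method error t₁/₂/√n_events. A least-squares fit to the decay
curve is offered for comparison with graphical fits. A
Kolmogorov–Smirnov distance of event times to the fitted
(censoring-truncated) exponential is reported as a
deviation-from-single-exponential diagnostic; intermediate-state or
multi-exponential models are out of scope.

## Ensemble pKa aggregation

PROPKA 3.1 is strictly an upstream tool — this package parses its
summary output (one file per frame) and never computes pKa from
structure. Coupled carboxyl pairs (protonated dyads) carry two
alternative values: in alternative *a* the first group protonates and is
stabilized by the second, in *b* the roles reverse; labels are preserved
from file order, never inferred. Per residue we report mean ± SD over
all frames and over coupling frames only, the coupling percentage, and
the fraction of the distribution inside a critical window (default
[6, 7], the extracellular-to-endosome range). "Reaches into the
window" is operationalized as window mass > 1% (configurable), since the
qualitative phrase needs a threshold.

## ITC thermodynamics

Binding free energies use the 1 M standard state: ΔG = RT ln K_d with
K_d in mol/l, so K_d = 105 μM at 300 K gives −22.9 kJ/mol. Displayed
values are rounded to one decimal, half away from zero; full precision
is kept internally. The pH sensitivity is ΔΔG = ΔG_pH6 − ΔG_pH7,
antisymmetric under swapping the pair, with first-order error
propagation (σ_ΔG = RT·σ_Kd/K_d) combined in quadrature. One printed
literature value (the remeasured wildtype at pH 7, K_d = 113 μM, printed
−22.6) differs from the computed −22.67 → −22.7 at one-decimal rounding;
this is a rounding ambiguity on the source side and is not matched.

The titration model is the single-site isotherm (Hill coefficient 1)
with exact ligand conservation: after each injection the bound
concentration solves the quadratic
[MX] = ½(b − √(b² − 4·n·M_t·X_t)), b = n·M_t + X_t + K_d, with the
well-mixed displacement bookkeeping (each injection of volume v dilutes
cell contents by 1 − v/V₀). Heats difference the bound amounts,
correcting for displaced complex, in μcal. The fit is Levenberg–
Marquardt on per-injection heats with the stoichiometry fixable to 1;
the Wiseman parameter c = n·[cell]/K_d below 5 sets the low-c flag and
marks ΔH as unreliable (flat-thermogram inputs likewise).

## Synthetic generators: what they emulate, what they do not

The generators reproduce the *statistical* structure of the study's data
under known truth: metastable exchange (overdamped Langevin in model
potentials), force ramps with planted ruptures, censored exponential
unfolding, one-site titration heats, scheduled hydrogen-bond occupancies
emitted by a hidden Markov chain, and Bernoulli-coupled pKa records.
They do not emulate force-field physics, solvent, real protein
free-energy surfaces, multi-exponential unfolding, ITC baseline drift,
or PROPKA's structural pKa model. Passing tests therefore demonstrate
that the estimators recover known truth under the stated noise models —
not that any particular biological conclusion transfers to real
trajectories.

The Langevin sampler is Euler–Maruyama,
dx = −∇U/γ·dt + √(2kT·dt/γ)·ξ, with stationary density ∝ exp(−U/kT).
A step size with dt·max|U″|/γ ≥ 0.1 is rejected up front. The
independent timescale oracle discretizes the same one-step dynamics on a
uniform grid (≥ 500 bins), row-normalizes the propagator and reads the
slowest relaxation off the second eigenvalue, t = −dt/ln λ₂ — a route
that shares no code with the Markov-model stages it checks.

Default study conditions mirror the source design: 40 pulling traces per
condition with 5% force noise and a 150 kJ/(mol·nm) planted cohort
offset; 30–60 unfolding trajectories censored at 220 ns with half-lives
218 and 93 ns; low-c titrations (c < 5); coupling fractions 0.74/0.56.
The double-well validation system uses a 5 kT barrier at ±1 nm,
γ = 1 kJ·ns/(mol·nm²), dt = 5·10⁻⁴ ns, and 8 replicas × 5·10⁵ steps
(2 μs total, ≈ 280 slow relaxation times, ≈ 500 interwell transitions) —
enough sampling that the slowest implied timescale carries a few-percent
statistical error against the oracle's 7.08 ns.

## Numerical choices and edge cases

- Tie-breaks: cluster labels by size then smallest member index;
  interval cores resolve overlaps toward the nearest center.
- Degenerate inputs fail loudly with the offending name: unresolvable
  atom selectors, missing hydrogens, single-frame RMSF, all-noise
  clusterings, zero-event survival data, non-positive K_d,
  lag ≥ trajectory length (listing the replicas).
- Statistical checks on serially correlated chains use
  effective-sample-size corrections: the tICA eigenvalue comparison uses
  n_eff = n/(2t*) in its standard error, and the stationarity χ² test
  thins beyond the slowest relaxation time read off the grid oracle.
- The demo pipeline writes a provenance block (config hash, seed,
  package version); two runs with the same config and seed are
  byte-identical in every numeric artifact (wall-clock log entries
  excepted).

## Limitations

Reversible MSM estimation by count symmetrization is biased for
strongly non-equilibrium counts; Bayesian error bars, HMMs, PCCA+ and
transition-path analyses are out of scope, as are Jarzynski/Crooks
work-based free energies, Bell–Evans loading-rate models, kernel or deep
embeddings, multi-site/cooperative binding models and raw thermogram
peak integration. DSSP secondary structure is ingested, never computed.
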