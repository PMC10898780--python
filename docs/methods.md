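# Methods

## Phase extraction

BOLD matrices (nodes × volumes) are demeaned per node and band-passed at
0.008–0.08 Hz with a second-order Butterworth filter applied forward–backward
(`sosfiltfilt`, odd reflective padding). Zero-phase filtering matters here:
any phase distortion would propagate directly into the Hilbert phases that
every downstream measure consumes. The effective magnitude response is the
squared design response; tests verify the pass/stop behaviour against the
designed filter's own frequency response. Nodes with identically zero signal
have no defined phase; they are flagged (`PhaseField.degenerate_nodes`)
rather than silently emitted as zeros. Each node is demeaned but not
z-scored before the Hilbert transform — rescaling a signal does not change
its analytic phase, so z-scoring would be a no-op for every phase-based
measure.

## Local order parameter and turbulence measures

The kernel `C_np = exp(−λ r_np)` includes the self-term (`C_nn = 1`), and the
weighted phase average is normalised by the kernel row sum, so the modulus R
is a convex combination of unit vectors and lies in [0, 1] by construction.
All standard deviations (amplitude turbulence, node-level metastability) are
population (divide-by-N) moments, computed with the numerically stable
two-pass formula; the moment-difference form `⟨R²⟩ − ⟨R⟩²` loses ~8 digits to
cancellation on near-constant fields.

Scale grid: λ from 0.01 to 0.30 mm⁻¹ in steps of 0.03 (10 scales, 9
transitions). The cascade-flow lag Δt is one sample (one TR); the
cross-scale correlation is computed per node and then averaged over nodes,
with zero-variance nodes excluded and counted. Information transfer bins
pairwise R–R temporal correlations into 50 equal-width distance bins inside
the inertial subrange and fits log(corr) on log(bin midpoint); pairs with
non-positive correlation are excluded from the log fit and counted. The
inertial subrange defaults to 10–100 mm — the window between the shortest
centroid separations and the longest distances the synthetic brain supports —
and is configurable everywhere it appears.

## Hopf whole-brain model

Stuart–Landau oscillators in Cartesian form, coupled diffusively through the
connectome, integrated by Euler–Maruyama. Defaults: dt = 0.1 s, burn-in 20 s
(discarded), additive Gaussian noise of std ν·√dt per step on both
components with ν = 0.01, initial state drawn as 0.1·N(0, 1), and the real
part x decimated to the target TR by stride. The resting baseline is
a_n = −0.02 for all nodes — just below criticality, so that the perturbation
range [−0.02, 0] spans baseline-to-critical. Intrinsic frequencies come from
the periodogram peak inside 0.008–0.08 Hz (`estimate_frequencies`); the
synthetic generator draws them uniformly in 0.04–0.07 Hz, the band where
resting-state spectra typically peak. A state-magnitude guard (10⁶) converts
numerical blow-up into a diagnosable `IntegrationDivergedError`.

An exact-arithmetic caveat: explicit Euler at dt = 0.1 s carries an O(dt)
amplitude bias; the closed-form limit-cycle checks (radius √a, period 2π/ω
to 1e−3) therefore run at dt = 0.002 s. For the statistical measures the
default step is ample — halving dt changes FC profiles by far less than one
noise realisation does.

The connectome follows the exponential distance rule with decay 0.18 mm⁻¹.
When an empirical SC is supplied it is divided by its maximum, symmetrised,
and each pair keeps the larger of the EDR prediction and the empirical
weight ("long-range exceptions"); the diagonal is zeroed and ignored by the
diffusive coupling.

Many replicates (grid points × repetitions, or perturbation trials) are
integrated as one batched tensor; a batch of 100 60-node runs of 145 volumes
takes about a second, which is what makes desk-scale grid searches and the
directional cohort checks affordable.

## Fitting the global coupling

FC(r): node time courses are z-scored, Pearson correlations computed for all
pairs, and averaged in 30 equal-width distance bins over the inertial
subrange. The structure function is the affine transform S(r) = 2(1 − FC(r)).
The fitting error is the Euclidean distance between FC(r) vectors over
shared non-empty bins — defined on FC rather than S since the affine map
leaves the argmin unchanged.

The empirical profile is the **group-averaged** per-subject profile. At the
desk scale used throughout (T = 145 volumes), a single subject's FC(r) is
far too noisy to identify G; averaging 6–12 subjects makes the error
landscape usable.

The sweep simulates `reps` repetitions per grid value and averages their
errors; the working point G* is the grid argmin, ties to smaller G. By
default the sweep uses **common random numbers**: repetition r shares its
noise realisation across every grid value, so the correlated part of the
Monte-Carlo error cancels when grid values are compared. This is a pure
variance-reduction device for the argmin — each repetition remains an
unbiased simulation — and can be disabled (`crn=False`). At the desk scale
(60 nodes, grid step 0.1, 5 repetitions) CRN roughly doubles the fraction of
seeds that recover a known generative G within two grid steps. Diverged
repetitions are dropped and counted; a grid value whose repetitions all
diverge aborts the sweep with an error.

Desk-scale defaults (60–100 nodes, grid 0–2 step 0.1, 5 repetitions) keep a
full sweep under two seconds; the full-scale protocol (1,000 nodes, step
0.01, 100 repetitions) is expressible through the same interface but is
cluster-scale work.

## Perturbation protocol

Each trial redraws every node's bifurcation parameter uniformly in
[−0.02, 0] and simulates perturbed and unperturbed systems with **paired
noise** (identical Wiener increments and initial state) by default. Pairing
makes the zero-width protocol exactly null (χ = I = 0 to the last bit, a
test anchor) and sharply reduces trial-to-trial variance; independent seeds
are available (`paired_seeds=False`) and are verified in tests to be
strictly noisier. Both runs are reduced to R at scale λ_s (default 0.01,
the largest spatial scale, where group contrasts are strongest) via the same
bandpass→Hilbert→local-order path as the empirical data. χ averages the
per-trial, per-node time-mean difference over trials then nodes; I is the
across-trial population dispersion of that difference per node, averaged
over nodes. The printed definition of I is ambiguous between a variance and
its square root; the std reading is the default and
`capability_moment="var"` preserves the alternative. Both measures share one
cached set of trial simulations.

## Simulated attack

Overlap tables are patient × node fractions in [0, 1] (lesioned voxels in
the node ÷ node voxel count, or the analytic sphere–sphere equivalent in the
synthetic generator). The attack threshold is τ = mean + k·SD (population
SD) over the **positive** overlap values pooled across patients and nodes;
a node is attacked for a patient when its overlap ≥ τ (inclusive tie rule).
Node disconnection factors — 0 (binary) or 1 − frequency/n_patients
(weighted) — combine into pair entries by the minimum of the endpoint
factors, so a pair with both endpoints attacked is not double-penalised
(`pair_combine="product"` gives the multiplicative alternative). The mask
multiplies the connectome elementwise; symmetry and nonnegativity are
preserved, and a weighted mask at full lesion frequency reproduces the
binary mask exactly.

## Synthetic-data generator

Geometry: centroids uniform inside two mirrored axis-aligned ellipsoids
(semi-axes 35 × 42.5 × 30 mm, centres at x = ±40 mm), spanning ~150 mm
left–right and producing pairwise distances of roughly 3–150 mm — the range
the spatial-scale grid is annotated with. Seven RSN labels come from a
seeded spatial k-means, so networks are contiguous as in real parcellations.
Node volumes partition the total brain volume log-normally (σ = 0.3) around
brain_volume/N, giving equivalent-sphere radii near 11 mm at N = 60 and 6 mm
at N = 400.

Lesions are spheres whose centres sit at randomly chosen parcel centroids;
node overlap is the analytic sphere–sphere intersection over the node's
equivalent-sphere volume, summed over foci and clipped to [0, 1] (a
voxelised brute-force oracle cross-checks the closed form in the tests).

Cohorts: control-like subjects are simulated at G_control = 1.6 on the
intact EDR connectome; injury-like subjects at G_injury = 0.9 on a
connectome attacked with the weighted 1.5 SD mask from a synthetic lesion
cohort. Defaults emulate a typical resting-state acquisition — 145 volumes
at TR = 2 s — and subject i of both groups shares a noise sub-seed so group
contrasts are paired by subject index. Every generator is deterministic
under a fixed seed.

**What the generator does not emulate.** Synthetic BOLD comes from the same
model family later fitted to it, so parameter-recovery results demonstrate
the estimator's consistency, not the Hopf model's adequacy for real fMRI.
Spherical lesions with centroid-centred foci produce an overlap distribution
whose positive bulk is broad (mean ≈ 0.3, SD ≈ 0.33); consequently
thresholds at 3–4 SD exceed the saturation value 1 and yield empty attack
sets, whereas irregular real lesions have a much thinner tail and retain
small attack sets at high thresholds. The 1.5 and 2 SD sets — the
practically relevant ones — are stable and nonzero. There is no head
motion, physiological noise, hemodynamic convolution, or spatial smoothing;
passing tests show the measures behave correctly on model data, not that
they are robust to those artefacts.

## Statistical toolbox

The Kolmogorov–Smirnov distance, Benjamini–Hochberg step-up adjustment and
the top-quantile node tally are implemented directly (with scipy/statsmodels
cross-checks in the tests); Pearson p-values and Wilcoxon rank tests delegate
to scipy.stats, and ANOVA/ANCOVA run through a thin statsmodels OLS adapter
that records the formula, covariates and sample size with its output. The
top-quantile rule is strictly-greater-than the linear-interpolation
empirical quantile, so an all-tied input selects nothing — the documented
degenerate case.

## Problem sizes in the test suite and acceptance script

Oracle and closed-form checks run on ≤ 20-node instances. Parameter
recovery uses a 60-node geometry, 12-subject empirical groups, grid 0–2 in
steps of 0.1 and 5 repetitions, over 10 seeds per generative G. The
directional cohort check uses 6 subjects per group, sweeps with 3
repetitions and 20 perturbation trials, over 10 cohort seeds. The
acceptance script runs one 60-node, 10-per-group cohort plus a 400-node
lesion cohort. These sizes were chosen so the whole suite completes in
about a minute on one CPU while every statistical check retains a
comfortable margin.
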