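# Methods

This note records the measurement conventions, generator models, numerical
choices and known limitations of `morphoelec`, in the spirit of a methods
section a user could cite when reporting results produced with the package.

## Electrophysiological feature extraction

A cell's recording is a *step family*: one sweep per current amplitude
(−60…+200 pA in 10-pA increments, 500-ms step, −65 mV holding), optionally
plus a zero-current sweep. All features derive from the sampled membrane
potential; the injected current is known from the protocol, not measured.

**Spike detection.** dV/dt is computed by centered finite differences
(one-sided at the trace ends). A spike threshold is the first sample of an
upward crossing of the slope criterion (default 10 mV/ms), refined by
linear interpolation in the derivative back to the exact crossing; the
threshold voltage is the trace value interpolated at that time. A crossing
is accepted as a spike only if the *first* local voltage maximum within the
following 10 ms lies at least 2 mV above the threshold voltage; a 2-ms
refractory lockout suppresses duplicate crossings within one transient.
Using the first qualifying local maximum (rather than the window's global
maximum) keeps dense trains from assigning one spike's tip to its
neighbour. The spike tip itself is refined to sub-sample precision with a
local cubic-spline upsampling (±4 samples, 50× oversampling) where the
amplitude matters (first-spike shape features).

**Windows and fits.** Baseline is the mean of the 100 ms before step onset
and steady state the mean of the final 100 ms of the step. Sag is steady
state minus the minimum during the −60 pA step, reported ≥ 0 mV. Input
resistance is |ΔV_ss|/20 pA on the −20 pA step. τ comes from an
unweighted least-squares single-exponential fit to the −20 pA onset
relaxation, from 1 ms after onset to the step end (`scipy.optimize.curve_fit`,
initialized at 20 ms). The f-I "initial linear section" is operationalized
as the first three positive-rate current levels from rheobase (fewer if
unavailable; the slope is missing below two points), fitted by ordinary
least squares. The AHP trough is searched from the first rheobase spike's
peak to 100 ms after its threshold crossing, truncated at the next spike's
threshold; the AHP half-width is the time between the two interpolated
crossings of the level half the AHP amplitude below threshold, and the
recovery crossing may legitimately fall beyond the 100-ms trough window.
Adaptation index is the second-half over first-half spike count of the
maximal step (missing when the first half is silent); the ISI coefficient
of variation needs at least three spikes there. Sweeps with spikes before
step onset are excluded from the rheobase search; spikes during
hyperpolarizing steps mark the passive features missing.

Missing values are always explicit (NaN plus a reason string), never
silent zeros; the liquid-junction potential is deliberately not corrected.

**Recording QC.** A recording passes when both access-resistance readings
are < 25 MΩ and within 20 % of each other, the offset current drifts < 10 %
and stays < 100 pA in magnitude, and the resting potential is ≤ −40 mV.
The offset-current bound is interpreted as a magnitude bound; an
alternative reading (a signed bound at −100 pA) exists and would only
differ for cells requiring depolarizing holding current.

## Morphometry

SWC trees are validated (single soma-type root, no cycles or orphans,
positive radii). Neurite length sums parent–child Euclidean segments over
non-soma nodes; surface area sums frustum lateral areas π(r_p + r_c)·slant,
with a segment leaving the soma treated as a cylinder at the child's radius
so the soma surface itself is excluded. Branch order: a primary process
(emerging from the soma) has order 0; both daughters at a bifurcation
advance one order; a single-child continuation keeps its order. Soma nodes
are included in the convex-hull point set (the hull encloses *all* points
of the arbor); degenerate (coplanar) arbors yield missing hull features
rather than a 2-D fallback.

Root angles are evaluated at points placed every `resample_step` (default
1 µm) along each segment, measured from the segment's proximal node; points
coincident with the soma are skipped. The tangent is oriented root-ward so
a straight radial neurite scores 0 everywhere, and the von Mises–Fisher
concentration is fitted with the mean direction fixed at angle 0 using the
closed-form estimator κ̂ = r̄(3 − r̄²)/(1 − r̄²), clamped to [0, 10³], with
r̄ ≤ 0 mapping to 0 and at least 10 angles required. The closed form tracks
the exact maximum-likelihood solution of coth κ − 1/κ = r̄ to a few percent
over the physiological range (verified in the test suite); κ̂ applied to
arbor-derived angles carries a small (< ~5 %) upward bias from the
geometric correlation of consecutive segments. Sholl intersections count
sign changes of (distance-to-root − shell radius) along resampled paths at
10-µm shells.

## Cohort statistics and classification

Sample statistics use the n−1 denominator throughout. Rank-sum p-values are
exact (full enumeration) when both groups have n ≤ 10 and use the
tie-corrected normal approximation otherwise; no multiple-testing
correction is applied, so each feature is tested at p < 0.05 on its own.
Rank-sum tests use pairwise-complete values; PCA, UMAP and LDA drop
incomplete rows, with the count reported. PCA retains components with
> 1 % explained variance. UMAP runs with n_neighbors = 15, min_dist = 0.1,
Euclidean metric and a fixed seed (the reference implementation's defaults,
exposed as parameters). The Fisher discriminant uses the pooled
within-class covariance with an always-on Tikhonov term 10⁻⁶·tr(Σ)/p·I
(numerically inert when the problem is well-conditioned, and it keeps the
rank-one leave-one-out downdates safe); reported weights are absolute
standardized coefficients. The separation score is leave-one-out accuracy
under the equal-prior midpoint rule, computed with Sherman–Morrison scatter
downdates (verified against naive refits) so a 1000-permutation null is
cheap.

## Synthetic generators

**Composed traces (exact tier).** Sweeps are assembled from analytic
segments: exponential step relaxations carrying the programmed input
resistance and τ; a Gaussian sag trough (centre 350 ms, σ 20 ms) on the
−60 pA step; and stereotyped spikes. A spike's rising flank is specified by
its slope profile — the slope crosses the 10 mV/ms detection criterion with
constant acceleration (20 mV/ms per ms over ±0.3 ms) exactly at the
programmed threshold voltage, rises along a half-cosine to the upstroke and
decays along a quarter-cosine to zero at the tip; the falling flank is a
half-sine slope profile. Threshold, amplitude and half-width are embedded
exactly; because amplitude, width and both slope extrema cannot be chosen
independently, the two slope extrema are rescaled jointly (preserving their
ratio, solved by bisection) and the realized values are recorded as ground
truth. The constant-acceleration window makes finite-difference detection
with linear interpolation land on the programmed threshold point to
< 0.01 mV. AHPs descend along a half-cosine to the programmed trough at
the programmed latency and recover along a half-cosine whose duration is
solved so the half-amplitude level is recrossed exactly one half-width
after the first crossing. Per-step spike counts realize the rate targets
under the quantization rate = 2 × count; counts, the 10-pA rheobase grid
and the maximal-step half-counts use unbiased stochastic (dithered)
rounding so cohort means match calibration in expectation, and the
rate-derived ground truth (f-I slope, maximum rate, adaptation, CV) is
recomputed from the programmed spike times. Composed sweeps default to
40-kHz sampling; the slope extrema are the one feature class whose
curvature maxima remain resolution-limited, hence their 10 % recovery
tolerance.

**AdEx (mechanistic tier).** A standard two-variable adaptive exponential
integrate-and-fire model (forward Euler, 0.05-ms step, exponential argument
capped, spike reset at 0 mV, all sweeps integrated in lockstep) with a
holding current solved so −65 mV is the pre-step fixed point. Cohort
targets map to parameters through a simple monotone heuristic
(g_L = 1/R_in, C = τ·g_L, V_T = threshold, b = 2·AHP amplitude,
τ_w = AHP width); calibration is therefore approximate, and the feature
values the extractor measures on the simulated traces are recorded as the
realized ground truth. Only the composed tier backs exact-recovery claims.

**Trees.** Growth starts from a soma at the origin with `n_primary` trunks
in uniform random directions; tips elongate in 1-µm segments whose
directions are von Mises–Fisher about the current soma-to-tip direction
with concentration κ_gen; branch events are pre-scheduled along the length
budget (a dithered count placed uniformly over the first 85 % of growth) so
branch-point totals are exactly calibrated; growth is confined to an oblate
spheroid (equatorial radius `max_extent`, axis ratio `z_scale`) with a few
re-draws then a reflection at the boundary. Total length equals the budget
to within two segments, and length/count ground truth is exact
bookkeeping. Hull sphericity is controlled jointly by the flattening and
the fill density; the group values of `max_extent` and `z_scale` were set
by a one-time calibration scan so cohort sphericity approaches the profiled
means (≈ 0.54 flat/mouse-like, ≈ 0.67–0.73 full/macaque-like).

**Calibration.** `data/calibration.yaml` profiles three groups (mouse
cholinergic, mouse non-cholinergic, macaque cholinergic) as truncated
normal distributions per feature, with cohort sizes 48/46/46 recorded and
31/44/52 reconstructed and a combined-complete subset of 27 + 46
cholinergic cells carrying both modalities. Features without a published
group summary carry the package's own plausible choices; in particular the
three lineage-shared intrinsic features are chosen as sag, input resistance
and ISI CV, and the macaque values for features reported only as
qualitative contrasts follow those contrasts. Truncation bounds encode
physical plausibility (positive rheobase, spike widths achievable at the
protocol sampling, AHPs completing within the step), and jointly
constrained draws (latency + AHP span inside the 500-ms step; the implied
neurite radius between 0.08 and 2 µm) are rejection-resampled with a
logged cap. Cells whose sampled firing leaves a feature undefined (e.g.
< 3 spikes for a CV) are genuine members of their cohort; the fixture
replaces only as many as needed to fill the combined-complete subset, and
logs it.

**What the generators do and do not emulate.** They reproduce the
protocol's timing, the feature definitions' geometry, group-level means,
SDs and cohort sizes, and the missing-data structure of low-rate cells.
They do not add measurement noise, electrode artefacts, channel noise or
non-stereotyped spike-shape variability within a cell; trees have constant
radius per cell, no somatic geometry beyond a point and no compartment
labels. Passing recovery tests therefore demonstrates the correctness of
the measurement conventions and pipeline plumbing — not robustness to
recording noise, which users should assess on their own data.

## Problem sizes and determinism

Every generator is a pure function of (parameters, seed). The test suite
exercises: 100 composed cells across the three profiles for exact
recovery; 17 trees per κ level in {5, 15, 50} for concentration recovery
(the mean estimate per level is compared at 10 %, since single-tree
estimates carry ~5 % sampling error); 1000 null and 200 effect replicates
at the profiled 48/46 group sizes for rank-sum calibration; the full
two-species fixture for the classification benchmark (1000-label-shuffle
null); and 20 fixture seeds for the group-comparison pattern, in which the
features flagged in a majority of seeds are counted. Reduced-size fixtures
(`size_factor`) back the I/O and CLI tests.

## Known limitations

* Slope extrema (upstroke/downstroke) are resolution-limited at realistic
  sampling rates; treat differences of a few percent as within measurement
  error.
* The κ̂ estimator assumes a unimodal, soma-oriented angle distribution;
  arbors with mixed centripetal/centrifugal sections compress toward 0.
* The rank-sum normal approximation is used above n = 10 per group; exact
  p-values for mid-sized groups would require permutation.
* UMAP coordinates are only meaningful for a fixed seed and parameter set;
  distances between runs are not comparable.
* The AdEx tier's calibration heuristic is monotone but coarse; it is a
  realism check, not a quantitative emulation.
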