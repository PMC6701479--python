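# Methods

This package re-implements an integrative analysis for a flexible,
natively asymmetric multidomain dimer of the KAP1/TRIM28 type: model-free
SAXS analysis, elastic-network flexible fitting of coarse-grained bead
models to scattering data, clustering of the fitted ensemble in
collective-variable space, single-molecule TIRF dwell-time kinetics, and
one-set-of-sites ITC. Everything runs end to end on synthetic data
produced by the in-package generators, with planted ground truth carried
alongside every dataset.

## Coarse-grained structural model

Proteins are represented one bead per residue at the CA position. A
model carries per-bead protomer (chain A/B) and domain labels; domain
metadata (residue ranges, rigid/flexible flags) lives in a CSV sidecar
next to the CA-only PDB, because PDB has no domain column. Residue
ranges are 0-based and half-open; all lengths are in Å; consecutive
beads in a chain are pseudo-bonded at the ideal CA–CA distance of
3.8 Å, and a model is "topologically valid" when every pseudo-bond is
shorter than 4.5 Å.

The synthetic dimer is an antiparallel dumbbell: a straight coiled-coil
(CC) rod whose ends carry compact terminal modules (RB1B2 surrogates,
default radius 25 Å — the compact size of a ~150-residue domain) whose
centres of mass sit exactly the rod length (default 160 Å) apart; each protomer continues through a 200-residue
random-coil linker to a compact mobile module (PHD-Br surrogate, radius
18 Å). Folded domains are built as ball-winding spirals so each domain
is a connected 3.8 Å-step chain, and each CC strand leaves its module
through a short junction arc onto the rod axis so the two antiparallel
strands run side by side — this keeps the dimer's elastic network
connected no matter where the mobile domains are placed.

Bead masses carry the residue-equivalent weight of the region each bead
represents (defaults: 150 residues per terminal module, 207 per CC
strand, 220 per mobile module, 1 per linker bead). Masses double as
scattering weights in the Debye calculator, so the folded domains keep
their realistic share of the total scattering mass relative to the
disordered linkers even though they are built from fewer beads. With
uniform unit masses everything reduces to the plain unweighted forms.

Linker growth is a Brownian bridge: each 3.8 Å step mixes an isotropic
random direction with the direction to the far anchor, weighted by how
taut the remaining chain is; steps that bring non-consecutive beads
below 2.0 Å are resampled, and the chain restarts if it fails to land
within one bond of the far anchor. Free (single-anchor) growth is a
plain self-avoiding random walk whose mean end-to-end distance follows
ideal-chain statistics (~3.8·√N Å).

### What the generator does not emulate

Real folded domains are not spherical shells of beads; the surrogate
geometry reproduces overall sizes, separations and mass ratios, not
internal architecture. Consequently, model-free quantities computed on
the synthetic constructs (Rg ≈ 64 Å, Rgc ≈ 12 Å, Dmax ≈ 200 Å for the
RBCC surrogate) are compared against coordinate-level oracles computed
on the same beads, not against values measured on the real protein,
whose extended RING/B-box arms stretch its experimental length and
Dmax well beyond a compact-module dumbbell. Passing tests therefore demonstrate
the correctness of the analyses, and that the pipeline recovers planted
ground truth under realistic noise — not that the surrogate is a
faithful structural model of the real protein.

## SAXS toolbox

**Debye calculator.** I(q) = Σᵢⱼ fᵢ(q)fⱼ(q)·sinc(q·rᵢⱼ) with Gaussian
bead form factors fᵢ(q) = mᵢ·exp(−(q·w)²/2), w = 3 Å by default. Pair
distances are binned at 0.5 Å so the double sum collapses to a
histogram contraction; at q ≤ 0.6 Å⁻¹ the binning error is orders of
magnitude below profile noise. There is no hydration shell or
excluded-volume term: absolute χ² values against real beamline data
would differ from a full-featured calculator, but nothing in the
pipeline's logic depends on that.

**Guinier fit.** ln I vs q² over the widest low-q window satisfying
qmax·Rg ≤ 1.3, grown upward from 8 points, with a 5% runs test on the
residuals as the linearity diagnostic; Rg = √(−3·slope).

**Rod (cross-section) Guinier.** ln(q·I) vs q² in an intermediate-q
window starting beyond q·Rg ≈ 2 and capped at q·Rgc ≤ 1.3;
Rgc = √(−2·slope). Because the crossover out of the overall Guinier
regime oscillates, the window start is scanned as well; among
comparably wide linear windows the earliest is preferred (linear
stretches at higher q measure the bead form factor, not the rod
cross-section).

**Dimensionless Kratky.** (q·Rg)²·I/I0 vs q·Rg; a compact globular
particle peaks at (√3, 3/e ≈ 1.104), and the helper flags
"globular-like" when the curve's maximum falls within 10% of that
point.

**P(r) inversion.** I(q) = ∫₀^Dmax p(r)·sinc(qr) dr is solved on a
201-point r-grid by Tikhonov least squares with a second-difference
smoothness penalty and clamped endpoints p(0) = p(Dmax) = 0. The
regularization weight is scaled by tr(AᵀA)/tr(DᵀD) and chosen by an
L-curve corner search unless given. Derived values: Rg² = ∫r²p/2∫p,
I0 = ∫p. Automatic Dmax selection scans a grid (1–4 × Guinier Rg by
default) and returns the smallest Dmax whose inversion (i) reproduces
the data — back-transform reduced χ² within 10% (plus a small absolute
slack for noise-free profiles) of the best candidate's — (ii) has a
negative-lobe fraction below 1%, and (iii) has a terminal 5% that
decays monotonically to ~zero — the numerical form of "let P(r) decay
smoothly to zero". The fit-quality condition is what rejects truncated
supports, which can still look smooth and positive; if nothing
qualifies the best-scoring candidate is returned with a warning.

**χ² comparison.** The computed profile is interpolated onto the
experimental grid (σ in quadrature), scale c and offset b minimizing
Σ((c·I_calc + b − I_exp)/σ)² are found in closed form, and χ² is
reduced by N − 2.

## Elastic-network flexible fitting

**Network.** Springs connect all bead pairs within a 12 Å cutoff at
uniform unit stiffness (absolute stiffness only scales eigenvalues, not
mode directions); rest lengths are the current distances. A
disconnected network is an error naming the component sizes.

**RTB modes.** The 3N×3N Hessian is projected onto rigid motions of
blocks — each rigid domain one block, each linker bead its own
(translation-only) block. Per-block bases are orthonormalized by SVD
with rank pruning (a collinear block has no rotation about its own
axis), so the projected problem is a standard symmetric eigenproblem,
solved dense below ~300 DOF and by shift-invert Lanczos above.
Rigid-body modes are identified by overlap with the global rigid-motion
subspace rather than by eigenvalue magnitude, because genuinely soft
linker modes can fall below any magnitude threshold; a connected 3-D
model always yields exactly 6. Eigenvectors map back to per-block
screw generators (v, ω) through the pseudo-inverse of the block's
rigid-motion generator.

**Nonlinear deformation.** A mode step of amplitude a moves each block
by the finite screw motion of its (v, ω): rotation by |ω|·a about the
axis through the block centre offset by (ω×v)/|ω|², plus the parallel
translation a·(v·ω̂)ω̂. This reduces to the linear displacement at small
a (the deviation is O(a²)) and preserves rigid-block internal geometry
to machine precision at any amplitude.

**Topology regularization.** After each accepted move, steepest descent
on harmonic restraints toward the reference structure's 1-2 bond
lengths and 1-3 distances (the pseudo-angle surrogate; only pairs whose
middle bead is flexible, since rigid-block internals cannot drift).
Rigid blocks move only as rigid bodies (net force → translation, net
torque → small rotation). The step size adapts by backtracking;
iteration stops when the largest bond deviation is below 0.1 Å or
after 500 steps.

**Fitting loop.** Each iteration recomputes the 60 slowest modes on the
current structure, evaluates the finite screw deformation of every mode
over a geometric amplitude grid ±w·2^k (k = 0..4), w scaled per mode so
the largest trial displaces the most mobile block ≈ 15 Å, and takes the
single lowest-χ² trial. The move is accepted only if χ² — evaluated
after regularization — strictly decreases, so accepted-step χ² is
monotone by construction. The loop stops early after 5 consecutive
iterations with improvement < 10⁻³, and also as soon as χ² reaches 1.0:
descending below the statistical noise floor only fits the particular
noise realization and lets the structure drift. On rejected iterations
the amplitude scale anneals (halves, down to 1/16) so late iterations
probe fine moves; it doubles back on acceptance. When no trial improves on the first
iteration and χ² stays high, the fit is flagged non-converged but the
model is still returned. Iteration/stall caps replace wall-clock
limits. The 15 Å trial scale was chosen so a mobile domain can traverse
the full placement range within the iteration budget while the finest
trial (w) still allows ~1 Å refinements.

## Ensemble analysis

For each fitted model the collective variables are (dA, dB): the
distance from each protomer's mobile-domain COM to the COM of the
*nearest* terminal module. Because protomer labels are arbitrary in a
homodimer, clustering operates on the swap-symmetrized point set (each
point plus its mirror (dB, dA)): a 2-component full-covariance Gaussian
mixture with deterministic farthest-point seeding then yields a mirror
pair of centers — the model class is exactly mirror-symmetric for a
homodimer, so the small estimation asymmetry EM leaves is projected
out by averaging each component with the swap image of its partner —
plus Mahalanobis distances per model, density-level member
sets (e.g. the 10% level or the 300 closest models per center) and a
pooled 1-D two-Gaussian fit whose separation statistic is
|μ₁ − μ₂|/pooled σ. The 1-D bimodality flag additionally requires the
two-component model to beat a single Gaussian by BIC, because EM can
always split one Gaussian into two overlapping halves. The exact
clustering recipe behind the original analysis is not published in
detail; this symmetrized mixture is the package's documented stand-in
and reproduces every reported readout (mirror centers, density levels,
closest-member sets). A BIC-based sweep over k is available but the
headline outputs fix k = 2.

## Single-molecule kinetics

Traces are uniformly sampled intensity series (20 Hz default). Event
detection: baseline = trace median, threshold = baseline + k·MAD
(scaled by 1.4826; k = 3 default), with the thresholded state computed
on a short running median (3 frames by default) that bridges
single-frame noise dropouts inside events. Detected events are then
step-refined on the raw trace — edges snap to the half-amplitude
crossing, which erodes far less often than the k·MAD level — and
summarized by their mean raw level. Events need at least 2 frames;
boundary-truncated intervals are flagged and excluded from kinetic
fits. Raising k can only remove well-separated events (a noisy long
event split in two can transiently raise the count).

Dwell fitting operates on the empirical survival S(t) = P(T ≥ t) of the
pooled durations, evaluated at frame multiples. Because simulated (and
real) durations are floored to the frame grid, the survival of recorded
durations at frame multiples equals that of the underlying continuous
durations, so this evaluation grid removes discretization bias; losing
sub-frame events only rescales mixture amplitudes, which the fitters
undo analytically (the reported A₁/A₂ refer to the underlying mixture).
Dissociation: least squares of A·e^(−t/τ₁) + (1−A)·e^(−t/τ₂) with
A ∈ (0,1) via a logistic parametrization and τ₁ < τ₂ by convention;
bootstrap over intervals gives CIs, and the fit falls back to (and
flags) a mono-exponential when τ₂/τ₁ < 2 or the A₂ CI includes zero.
A frame-binned maximum-likelihood alternative (``method="mle"``, same
mixture conditioned on surviving the first frame) is available and
agrees with the survival fit within a few percent on simulated data.
Association: mono-exponential dark-time fit, k_on = 1/(τ_dark·[ligand]),
with a warning when R² < 0.9.

Intensity analysis normalizes per-event levels by their median, fits a
two-Gaussian mixture at nominal 1× and 2× levels, counts observations
above the level midpoint as 2-dye, and inverts the binomial labeling
model — among visible binders with dimer fraction f and per-protomer
labeling probability p, the 2-dye fraction is f·p/(1 + f(1−p)), so
f = f₂/(p − f₂(1−p)). This inversion is the package's documented
formula; the original report does not spell out its mapping.

The trace simulator draws alternating dark (exponential, rate
k_on·[ligand]) and bright (two-exponential mixture) intervals in
continuous time, assigns each binder dimer/monomer identity and
per-protomer labels binomially, floors intervals to the frame grid
(sub-frame events vanish from the trace but stay in the returned ground
truth) and adds Gaussian camera noise of sd = 1/SNR. An optional
``stuck_fraction`` of traces emulates immobilized molecules that are
bright from the first frame until a single-step dye bleach; the
detector flags such traces (one start-truncated event followed by
permanent dark) as ``bleach_suspect`` so they can be excluded, the way
stepwise-bleaching peaks are excluded from real analyses. Beyond that
single on/off level the simulator does not model dye photophysics
(blinking, multi-step bleaching) or image-plane effects; analysis
starts at extracted traces.

## ITC

The one-set-of-sites forward model uses the displaced-volume
convention: each 2 μl injection into the 300 μl cell displaces an equal
volume of the pre-injection average composition; total concentrations
update, the bound concentration solves the quadratic equilibrium, and
the injection heat is ΔH·V₀·(bᵢ − bᵢ₋₁·V₀/(V₀+dV)). Defaults mirror a
19-injection experiment at 15 μM cell / 170 μM syringe, 25 °C.

Fitting: a straight-line heat-of-dilution baseline is *initialized*
from the last 3 injections and then refined jointly with (N, Kd, ΔH)
in the nonlinear least squares — freezing it at the tail estimate would
fold residual post-saturation binding heat into the baseline and bias
Kd low; with the joint refinement the noise-free round trip is exact to
optimizer tolerance. Kd is fitted as log₁₀Kd. ΔG = −RT·ln(1/Kd) with
R = 1.98 cal mol⁻¹ K⁻¹ and ΔS = (ΔH − ΔG)/T. The first injection is
kept for ideal synthetic data; a discard-first flag exists for real
isotherms. A c-value below 1, or an isotherm whose heats show no
saturation transition, triggers a flat-isotherm warning (parameters
poorly determined).

## Noise models and defaults

SAXS noise is Gaussian with σ(q) = a·√(I(q)·I(0)) — the √I shape of
counting statistics — with a = 0.01 (1% relative error at I(0)) as the
default study condition; by construction the true model scores χ² ≈ 1
against such data. Trace noise is white Gaussian at SNR 10 by default;
ITC noise is Gaussian with sd equal to 1% of the first-injection heat.
All generators take a seed recorded in output metadata, and every
pipeline run archives its resolved configuration, so reports are
regenerable bit-for-bit.

## Problem sizes

The default replay profile used by the tests is the desk scale: 50
randomized starts × 40 fitting iterations × 60 modes on a ~700-bead
dimer (two 200-bead linkers plus coarse folded domains), 101-point
q-grid over 0.0025–0.6 Å⁻¹. The full-scale protocol (1,000 starts ×
100 iterations) is a configuration change, not a code change. Kinetic
recovery uses 5,000 bright and 2,000 dark dwells; ITC recovery uses 100
replicates of the 19-injection isotherm.

## Known limitations

- The Debye calculator omits hydration-shell and excluded-volume
  terms; χ² against real (as opposed to synthetic) data is therefore
  not directly comparable to full-featured calculators.
- Greedy single-move descent can stall in local minima; individual fits
  from unfavourable starts may keep χ² well above 1, which is why the
  ensemble stage filters on final χ² before clustering (mirroring the
  original protocol, where only a fraction of starts converged).
- The screw-motion NMA implements the rigid-block formalism in
  principle, not as a bit-compatible clone of any particular tool.
- Event detection assumes a stable baseline; slow drifts would need
  detrending upstream.
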