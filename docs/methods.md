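# Methods

This note documents the models implemented in `corralfcs`, the choices made
where the procedures left freedom, and what the synthetic data do and do not
establish.

## The physical picture

Membrane receptors such as LYVE-1 diffuse laterally in the plasma membrane,
but their long-range mobility is restricted by the submembranous actin
cortex.  Two distinct restriction modes are modelled:

* **transient trapping** — reversible immobilisation by binding to
  near-immobile objects (clusters, complexes), and
* **corral (hop) diffusion** — the picket-fence picture in which the actin
  meshwork divides the membrane into compartments that a molecule leaves
  only occasionally.

Spot-variation FCS discriminates these modes by measuring the apparent
diffusion coefficient D at several observation-spot diameters d (STED
microscopy shrinks the spot from the confocal ~250 nm down to ~50 nm).

## Monte-Carlo simulator

A 2-D random walk of `n_molecules` point emitters inside a circular arena
(diameter 3,000 nm), with per step (dt = 0.001 ms at full scale):

1. **Trap/release.**  With probability `p_trap` (5e-5 per step) a free
   molecule becomes trapped — its diffusion coefficient switches from
   `D_free` = 0.4 um^2/s to `D_trap` = 1e-10 um^2/s, practically immobile —
   and a trapped molecule is released with the same probability, giving a
   50% trapped fraction at equilibrium and geometrically distributed dwell
   times.
2. **Displacement.**  A Gaussian step with per-axis variance 2 D dt.
3. **Arena wrap.**  Steps leaving the arena re-enter antipodally (the exit
   point is mapped through the centre, overshoot preserved).  On a circular
   boundary this preserves uniform density, which a rectangular torus wrap
   cannot.
4. **Corral test.**  If the endpoint lies in a different Voronoi
   compartment than the start, the move is accepted with probability
   `p_hop`, otherwise the molecule remains at its pre-step position.
   `p_hop` = 1 therefore means unrestricted passage and lower values mean
   stronger confinement.

The corral mesh is the Voronoi tessellation of a homogeneous Poisson point
process clipped to the arena.  "Mean seed distance" is read as the mean
nearest-neighbour distance of that process (0.5/sqrt(lambda)), so a 50-nm
spacing gives an intensity of 1e-4 seeds/nm^2, about 700 compartments, and
a mesh size — defined as sqrt(mean compartment area) — of ~100-110 nm.

Compartment membership during the walk is resolved on a rasterized
nearest-seed label grid (1-nm pixels).  Exact nearest-seed lookup per
proposed move would dominate the runtime; at the simulated step size
(~1 nm per step) the grid is equivalent up to sub-pixel quantisation of
the boundary position.  The walk itself runs in a numba-compiled kernel
with an inline xorshift64 generator and Box-Muller normal deviates, seeded
deterministically, so identical configurations reproduce bit-identical
trajectories.

The fluorescence readout evaluates, at each sampling time (default every
0.01 ms), the sum over molecules of a Gaussian detection profile
`exp(-4 ln2 r^2 / d^2)` of FWHM d centred on the nominal spot position,
times a per-molecule brightness (default 1 count/molecule/sample).  Poisson
shot noise is optional and off by default so oracle tests see the noiseless
expectation.

Unwrapped coordinates (cumulative accepted displacements, ignoring the
arena re-entry teleport) are recorded on request for mean-square-
displacement analysis; rejected corral crossings contribute zero
displacement.

### Scaled-down conditions

Tests and examples default to 50 molecules, 2-s acquisitions and
dt = 0.002 ms (`test_preset`); the full-scale conditions (200 molecules,
15 s, dt = 0.001 ms, 10 repetitions) remain available as `paper_preset`.
Statistics-hungry checks pool 10 repetitions and, where corral geometry
matters, five observation-spot positions spaced 600 nm apart — the
simulation analogue of measuring several membrane regions per cell.

## Correlation analysis

The fluctuation autocorrelation G(tau) = <dF(t) dF(t+tau)>/<F>^2 is
computed two ways: a direct FFT-based estimator at every sampling lag
(the oracle path, exactly symmetric under time reversal) and a multi-tau
correlator (Schätzel scheme, 16 points per octave, signal binned by 2 per
level) for production use; the two agree within 1% at shared lags for
smooth correlation functions.

Photobleaching correction crops the first 5 s of a trace (configurable
5-10 s) and flattens residual decay by local-mean ratio normalisation,
F'(t) = F(t) <F>/<F>_16s.  The local mean is an order-1 Savitzky-Golay
smooth over the 16-s window — identical to a centred moving average in the
interior, a least-squares line at the trace edges.  (A truncated-window
moving average leaves a several-percent edge-induced trend; the
polynomial edge handling removes it.)  The ratio form (not subtraction)
preserves the relative fluctuation amplitude on which the FCS amplitude
1/N depends.  Scanning-FCS line carpets are
processed per pixel with the pixel index carried in provenance.

## FCS model fitting

Correlation curves are fitted with the one-component two-dimensional
diffusion model

    G(tau) = (1/N) (1 + tau/tau_D)^-1 + O_f

by least squares (lmfit), with the amplitude 1/N and transit time tau_D
bounded positive and the offset free, over 0.5-4,000 ms by default
(clipped to available lags).  Initialisation: tau_D from the
half-amplitude lag, N from the first-lag amplitude, O_f from the tail.
Weights are uniform by default; no weighting scheme is prescribed for
the reference procedure.

Repetitions of one protocol are averaged lag-by-lag before fitting
(`average_curves`); fitting each short, noisy repetition separately and
averaging the resulting D values inflates the mean because D ~ 1/tau_D is
convex in the fitted transit time.

Populations of per-curve transit times are summarised by a log-normal
model fitted in three representations — binned density (Freedman-Diaconis
bins), empirical cumulative, and Gaussian moments.  The density and
cumulative fits are carried out in standardized log space,
z = (ln tau - mu)/sigma, which makes all three medians exactly
equivariant under rescaling of the samples.  Each form yields a median
exp(mu); the consensus median is their geometric mean, and a disagreement
flag is raised when any two forms differ by more than 20%.  No combination rule is prescribed for
the reference procedure; the geometric mean is symmetric and scale-
equivariant.

Transit times convert to diffusion coefficients either geometrically,
D = d^2/(8 ln2 tau_D) (1 nm^2/ms = 1e-3 um^2/s), or through an instrument
calibration pair, D = D_ref tau_ref / tau_D.  The two are kept separate
because measured confocal transit/diffusion pairs (e.g. 50 ms at
0.14 um^2/s) imply an effective focal geometry different from the nominal
250-nm FWHM; the calibrated form reproduces the printed values exactly.

## STED spot calibration and the diffusion law

Spot diameters at each depletion power are calibrated on a freely
diffusing reference (supported lipid bilayer) via
d = FWHM_conf sqrt(tau_STED/tau_conf), FWHM_conf = 250 nm; replicate
measurements at one power are averaged before the ratio, and entries with
tau_STED > tau_conf are flagged unphysical but retained.

The diffusion law D(d) pools fits per spot size (mean ± sd) and is
classified by the ratio rho = D(d_min)/D(d_max):

* free      |rho - 1| <= 0.2
* trapped   rho < 0.8   (apparent D falls at small spots)
* hop       rho > 1.2   (apparent D rises at small spots)
* ambiguous when the standard error of rho straddles the decision
  threshold.

The ratio of the extreme spot sizes is used rather than a fitted slope:
with 4-5 spot sizes it is robust and matches how D(d) plots are read.

### What the simulations show about the two signatures

The trapping signature is strong and robust: with the full-scale trapping
parameters the apparent D at 50 nm falls to roughly a third of its 250-nm
value, because trapped episodes (mean ~20 ms) dominate the short transits
through small spots.

The hop signature is conditional in a way worth recording.  A corral mesh
comparable to or larger than the smallest spot does **not** produce a
rising D at small d under this fitting protocol: the slow corral-escape
component then contaminates the small-spot fit and the law looks trapped
or flat.  The classic meshwork signature (negative intercept of tau(d^2),
hence D rising as d shrinks) emerges when the mesh is well below every
spot used — the transit across each spot then averages many corral
crossings — and the hop-suite fixtures therefore use a fine mesh (~33 nm)
with hindered crossing rather than the 110-nm mesh of the trapping
conditions.

A related artefact limits where "apparent D" means macroscopic mobility
at all.  When the spot is at or below the corral scale and crossing is
strongly hindered, the correlation decays quickly to the intra-corral
plateau and the free offset absorbs the plateau; the fitted transit time
then *shrinks* below its free value and the apparent D is inflated —
spectacularly so in short acquisitions, and enough to invert orderings
even in longer ones.  For this reason the p_hop-monotonicity property
(apparent D nondecreasing in p_hop, the behaviour the full-scale
simulation study reports across spot sizes) is asserted on pure-hopping
ensembles with 6-s acquisitions at spot sizes above the mesh
(250/150/100 nm), over p_hop in {0.05, 0.2, 1}.  Below the mesh the
statistic reads out intra-corral diffusion plus the plateau artefact, and
no monotonicity in p_hop should be expected of it.

## FRAP

Recovery curves are preprocessed by pointwise background subtraction,
optional division by an unbleached control acquisition (removing slow
acquisition bleaching), normalisation to the prebleach mean (2 frames by
default), and a time origin at the first post-bleach frame.  The model is

    F(t) = A1 (1 - e^-(t-t0)/tau1) + A2 (1 - e^-(t-t0)/tau2)

with amplitudes bounded nonnegative and components relabelled so
tau1 < tau2; t0 is fixed to the first post-bleach frame unless floated.
The printed form of this model carries a typographical "(1 - t0)" argument
which is time-independent and cannot describe a recovery; (t - t0) is the
only reading consistent with a recovery curve.  Times are unit-agnostic:
the quoted component recovery times (~2-3 and ~15-20) conflict with a
1 frame/s protocol if read as milliseconds, so the synthetic generator
uses the printed numerals in the trace's own time unit and only the
dimensionless amplitude fractions are compared quantitatively.
`frap_tau_to_D` provides the uniform-disk orientation estimate
D = r^2/(4 tau) and is documented as an approximation, not a calibrated
measurement.

## Bead counting

Fields of fluorescent beads are segmented by: threshold to binary (Otsu by
default, fixed value supported) -> Euclidean distance transform of the
mask -> Gaussian smoothing of the distance map (sigma 1 px) -> regional
maxima with a minimum separation (default 5 px, of the order of the bead
radius) -> marker-controlled watershed on the inverted distance map within
the mask -> removal of objects below 0.25 pi min_distance^2.  Smoothing
the distance transform rather than the raw image respects the stated
binary-then-Gaussian order while keeping maxima well defined; smoothing a
binary image directly and re-thresholding would be ill-posed.  The count
equals the number of retained labels; touching beads are split provided
their centres exceed the marker separation.

## Numerical and degenerate-input choices

* All internal units are nm, ms and um^2/s; converters live at the I/O
  boundary only.
* Voronoi cells are clipped to a 256-gon approximation of the circular
  arena (area error ~2.5e-5 relative); a single-seed mesh degenerates to
  the whole arena, and fewer than 3 seeds raises a degenerate-mesh error.
* Nearest-seed ties are broken by lowest seed index (KD-tree convention).
* Zero-mean traces cannot be normalised by <F>^2 and are rejected; a
  constant trace correlates to exactly zero.
* Noiseless model fits are driven to machine tolerance (xtol = ftol =
  1e-14) so round-trip tests can assert 1e-6 relative recovery.
* Seeds below 2^31 are drawn from a numpy Generator per repetition; the
  simulation kernel scrambles them through splitmix64.

## What passing tests do and do not show

The synthetic data obey the fitted models by construction (plus controlled
noise), so parameter-recovery tests validate the estimators, not the
biology.  The simulator omits photophysics (blinking, dye bleaching),
3-D membrane topography, anomalous diffusion and detector afterpulsing;
real sFCS traces carry all of these.  Bead images are uniform disks with
Gaussian read noise — real fields add uneven illumination and out-of-focus
light.  Agreement of the pipeline on these inputs therefore establishes
correctness of the computations under the stated models, and the
acceptance checks establish that the full-scale study conditions reproduce
the published summary numbers (mesh size, free-diffusion recovery, FRAP
fractions, calibrated conversions) within their tolerances.
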