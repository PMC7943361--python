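# Methods

## The model

Tissue electrophysiology is described by the monodomain equation

    dv/dt = div( D grad v ) + I_ion(v, h) + I_stim,

with the modified Mitchell–Schaeffer (mMS) two-variable reaction

    I_ion = h v (v − v_gate)(1 − v) / τ_in − v / τ_out,
    dh/dt = (1 − h)/τ_open   if v < v_gate,
          = −h/τ_close       if v ≥ v_gate.

`v` is the nondimensional transmembrane variable, `h` the recovery gate.
The cubic source vanishes at `v = 0`, so rest is a true fixed point; the
excitation threshold `v_gate` plays the role written `h_min` elsewhere.
Default cell parameters are τ_in = 0.3 ms, τ_out = 6 ms, τ_open = 120 ms,
τ_close = 80 ms, v_gate = 0.1 — a standard atrial operating point; all are
overridable per node.  τ_out is not part of the personalization set and is
held at its literature-typical default.

One threshold convention is used everywhere: activation, local activation
time (LAT), and action potential duration (APD) are measured at
v_thr = 0.1 (equal to `v_gate`), with linear interpolation between samples.
This choice is natural for a nondimensional two-variable model and is
consistent with the gate dynamics that give τ_close its effect on APD;
APD90-style conventions would differ only by a near-constant offset.

## Personalization mappings

Two parameters carry the spatial heterogeneity and are mapped analytically
from the restitution targets:

* **Conductivity from CV_max.**  In a reaction–diffusion medium the planar
  wave speed scales as √D.  The slope of CV = s·√D is calibrated once per
  (cell parameters, grid spacing) by measuring the speed in a 1-D cable at
  three reference conductivities; the mapping is D = (CV_max/s)².  The
  scalar entry point adds one fixed-point correction from a direct cable
  measurement and verifies the round trip to 5 %, raising a diagnostic
  error for speeds that the discretization cannot represent.  Calibrating
  at the simulation's own dx makes the mapping absorb the (well-known)
  grid-induced slowing of under-resolved fronts.
* **τ_close from APD_max.**  The plateau APD — the APD of a single beat
  from full rest — is monotone and very nearly affine in τ_close.  The
  scalar mapping inverts it by Brent root finding against the single-cell
  integrator; whole fields use an affine calibration fitted at three
  τ_close values (they agree to well under the 5 % round-trip contract).

The remaining parameters (v_gate, τ_open, τ_in) stay global; an optional
per-case scalar refinement by coordinate descent on validation RMSE is
provided, because their per-node identifiability from LAT/ERP data alone is
not established.

ERP serves as the APD_max surrogate (configurable offset δ, default 0).
For the mMS cell the capture threshold tracks the plateau APD closely, so
the identity surrogate is accurate at this operating point.

## Discretization

Sheets use a 5-point finite-difference Laplacian, triangle meshes a
mass-lumped linear-FEM cotangent Laplacian.  Heterogeneous conductivity
enters per edge as the harmonic mean of the nodal values, which preserves
wave-speed behaviour across parameter gradients.  Boundaries are zero-flux.
Time stepping is forward Euler with operator splitting; before any work the
step is checked against the Gershgorin bound of the assembled diffusion
operator combined with the reaction bound dt ≤ 0.1·τ_in.  Defaults are
dt = 0.02–0.025 ms at dx = 0.25–0.75 mm; halving dx and dt changes the
plane-wave speed by < 3 % (tested).

Two numerical details matter in practice.  First, substrate patches get a
cosine taper over the outer 20 % of their radius: hard parameter
discontinuities cause numerically induced wave breaks.  Second, after an
episode terminates, v and (1 − h) decay exponentially toward rest and
eventually transit the subnormal floating-point range, which stalls the
arithmetic units by ~50×; deviations below 1e-30 are therefore flushed to
rest exactly at every sampling step.  This is twenty-plus orders of
magnitude below any physiological signal and keeps runs bit-deterministic.

## Stimulation protocols

Stimuli are additive sources on dv/dt (default 1 ms⁻¹ for 2 ms) over a node
set.  Provided constructors: single pulse, S1–S2 trains, burst pacing
(default 20 beats; desk-scale runs use 8–10), and the cross-field spiral
construction (S1 plane wave, S2 over the lower half during the
repolarization tail).  Twelve pacing sites are laid out as 3 sites in each
of 4 corner zones on sheets — the sheet stand-in for the 3-sites-per-
pulmonary-vein layout; on meshes the zones are seeded from bounding-box
corners.

Tissue ERP is measured by bisection over an S2 grid, re-using the
conditioning-train state for every probe; capture means a fresh upstroke
beyond a 5 mm radius (distinguishing propagated capture from local graded
response) on the S2 beat only.

## Induction outcomes and frequency analysis

Episodes are classified by when activity ends relative to the horizon.
The clinical-scale taxonomy (non-triggering < 1 s, early-terminating 1–3 s,
then self-terminating, sustained iff still active at the 80 s horizon)
is scaled proportionally to the desk-scale horizon: the two interior
thresholds sit at fractions 1/80 and 3/80 of the horizon.  These two
thresholds partition [0, horizon) gap-free (property-tested); the 40 s
figure sometimes quoted for late terminations is a reporting boundary
inside the self-terminating bin, not a category boundary.  Analysis windows
exclude the post-pacing transitory (scaled analogue of discarding the first
500 ms).

Activation frequency is the reciprocal of the mean inter-upstroke interval
pooled over 9 farthest-point probe nodes, in 500 ms windows; windows with
fewer than two intervals report a no-estimate marker.  The settling time is
the first window that is within 10 % of the mean frequency over the final
reference span and stays within tolerance thereafter.

Sustained runs are subdivided by their phase-singularity tracks:
macro-re-entry (single persistent track, trajectory bounding radius
< 5 mm), meandering rotor (single persistent wandering track), or
fibrillation-like (time-median simultaneous PS count ≥ 2, or no persistent
track).  These are explicit, testable proxies for a taxonomy that is
usually applied visually; sustained activity with no detected singularity
is reported as re-entry around an anatomical obstacle.

## Phase mapping and the tethering label

Because both state variables are available in simulation, the phase is
taken directly in the state plane: θ = atan2(h − h*, v − v*) with origin
(0.5, 0.6), which the re-entrant loop encircles (a diagnostic warns
otherwise).  No Hilbert-transform surrogate is needed.  A singularity is a
±2π winding of θ around an element, computed as the sum of wrapped phase
differences around the node loop — exact on analytic vortices at any
resolution from 11×11 up (tested).  Singularities are linked greedily into
tracks by nearest-neighbour matching with equal chirality and a 5 mm jump
limit.

PS density accumulates each record's dwell time (one sample interval) onto
its host element's nodes, smears it with a mass-preserving Gaussian kernel
(σ = 2 mm; mass preservation, not kernel shape, is the binding contract),
and normalizes by node area and window length — the surface integral times
the window equals total PS dwell exactly.  The density window defaults to
the final 1/16 of the run, the scaled analogue of aggregating from 75 s of
an 80 s episode.  The tethering label marks nodes whose density strictly
exceeds mean + 1 sample SD over nodes (an area-weighted variant is
available by flag; with equal-area interior nodes the two coincide).

## Synthetic cohort

Clinical per-patient data of this kind are not shareable, so the generator
produces the statistical structure the analysis assumes: CV_max/APD_max
fields equal to a base value modulated by a unit-SD Gaussian random field
(white noise smoothed at a 10 mm correlation length), with one substrate
patch in which CV_max is scaled down and APD_max shifted down.  Cohort
defaults mirror the observed substrate contrast — background CV_max
160 cm/s with patches reaching ~60 cm/s (cv_scale 0.35–0.5), APD_max
180 ms shortened by 20–50 ms in the patch, 5 % field noise — and case
surface areas are drawn uniformly over 259–440 cm², the span of the
packaged cohort table.  Ground-truth masks for classifier-recovery tests
come from explicit rules (the patch core; CV below threshold; CV below
threshold AND surface above threshold).

Virtual electrode tables place 14 sites (configurable — clinical counts
range from ~14 per protocol to 42–100 per case) by farthest-point
sampling, take LATs from forward simulation plus Gaussian noise, and take
each site's refractory period from the single-cell capture threshold at
the local parameters (the tissue-level bisection agrees to within ~15 ms
but costs two orders of magnitude more compute).

What the generator does not emulate: anatomical geometry (pulmonary veins
exist only as labelled pacing zones), fibre orientation, wall thickness,
endo–epicardial dissociation, fibrosis imaging, and measurement artefacts
of mapping systems.  Passing tests therefore demonstrate method
correctness on fields with the assumed statistical structure, not clinical
performance.

## Desk-scale experiments

Clinical-scale runs (80 s of activity over ~300 cm² at 160 cm/s) are not
reproducible on a workstation; the bench uses scaled experiments whose
wavelength-to-domain ratio admits re-entry.  The standard operating point
is CV_max 30 cm/s, APD_max 80 ms, τ_open 65 ms on a 5×5 cm sheet
(wavelength ≈ 2.4 cm): a cross-field S2 at 167 ms initiates a spiral that
sustains for the full 2 s horizon with a single dominant PS track.  The
localization experiment plants a patch (cv_scale 0.5, APD −20 ms, radius
10 mm) at a seeded position in the central region; the tethering mask's
density-weighted centroid falls inside the patch in ≥ 8 of 10 seeded
trials.  The pipeline demo burst-paces 10 beats at 130 ms from corner
zones on ~5.5 cm sheets with a stronger patch (cv_scale 0.3–0.4) biased
toward the right half; induction is site- and seed-dependent there, which
is itself the expected physiology — not every pacing site induces.

## Classifier

Per-node rows (CV_max, APD_max, optionally case surface area) are labelled
by the tethering mask.  The SVM uses an RBF kernel (C = 10, γ = "scale" by
default; a small (C, γ) grid searched by 3-fold CV on the training split is
available), class weights inverse to frequency (tethering tissue is well
under a percent of nodes at clinical scale), and standardization fitted on
the training split only.  Splits are point-wise stratified 70/30 by
default with a grouped leave-cases-out variant by flag, and reports carry
plain and balanced accuracy, sensitivity, specificity, F1 and the
confusion counts (recomputable to 1e-12).  For tractability the negative
class is capped at 20:1 against positives and training at 40 000 rows.
The noise-robustness experiment perturbs held-out features with zero-mean
Gaussian noise of SD equal to a fraction of the per-feature training SD.

KDE summaries use a Gaussian kernel with bandwidth equal to the sample SD
of the values (zero-variance samples fall back to a minimal bandwidth with
a warning).

## Problem sizes

The test-bench sizes were chosen as the smallest that exhibit the physics:
single-cell integrations at dt = 0.02 ms; 1-D cables of 60 mm at
dx = 0.25 mm for calibration; 2-D sheets from 21×21 (unit tests) to
101×101 nodes (spiral experiments); cohorts of 6–10 synthetic cases at
dx = 2–3 mm for classifier recovery; pipeline demos with 1–2 cases, 2–4
pacing sites and 2.5–4 s horizons.

## Known limitations

* The analytic mappings are calibrated per grid spacing; conductivities
  mapped at one dx are not transferable to another without recalibration.
* Forward Euler caps dt at the diffusion bound; very fast tissue
  (D > ~4 mm²/ms) at fine grids is expensive.  No implicit or adaptive
  stepping is provided.
* The pattern taxonomy thresholds (r_stable = 5 mm, 50 % persistence) are
  declared proxies; different choices shift labels between macro-re-entry
  and meandering rotor for borderline trajectories.
* Burst-pacing inducibility at desk scale is sensitive to patch placement
  and noise seed; the suite treats inducibility per run as an outcome, not
  a guarantee.
* Meshes are supported throughout the solver and IO, but the scaled
  experiments and the acceptance bench run on sheets.
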