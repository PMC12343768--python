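# Methods

This note records the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Sequences and coordinates

All user-facing coordinates are 1-based inclusive, matching how domain
boundaries are reported in the literature. Sequences are restricted to
the 20 canonical amino acids; X/B/Z are rejected with a position-level
error rather than silently mapped, because every downstream statistic
depends on exact composition. IDRs come either from explicit regions
(published boundaries are trusted as given, with no length filter) or
from a disorder mask, where maximal True-runs are kept only if strictly
longer than `min_len` (default 30 residues). Running a disorder
predictor is out of scope; masks are inputs.

Residue groups: pos {K,R}, neg {D,E}, pol {S,T,N,Q,C,H}, hyd
{A,I,L,M,V}, aro {F,W,Y}, pro {P}, ala {A}, gly {G}. Histidine is polar
for grammar purposes but joins the positive pool in the design
algorithm (see below); both conventions are standard and they serve
different purposes, so they are kept side by side.

## Charge profiles

For window length L (5 for sequence-level plots, 31 for smoothed
per-protein profiles), each full window scores fracPos − fracNeg, and
each residue receives the mean over all full windows containing it.
Residues near the termini therefore average fewer windows; no padding
is used. With L equal to the sequence length the profile collapses to
NCPR everywhere, which the tests exploit as a closed-form limit.

## Patterning statistic and nulls

The delta statistic (README, "Charge patterning") uses window sizes
{5, 6} averaged — the conventional blob sizes for charge-patterning
descriptors of disordered regions. Windows with no X∪Y residue
contribute sigma = 0 rather than being skipped, so delta is defined for
sparse compositions; a sequence with no X∪Y residue at all raises an
undefined-statistic error that generators and reports propagate or flag
explicitly. "Segregation of X alone" scores X against the complement of
X.

The null is the uniform permutation of the full sequence, default
10,000 shuffles, seeded. The z is (delta_obs − mean_null)/sd_null; a
degenerate null (sd = 0, e.g. homopolymers) reports z = 0 with a flag
rather than NaN. For whole-report computation one permutation set is
drawn per IDR and shared across all patterning features — the null is
feature-independent, and this makes a ~35-feature report roughly
35-fold cheaper with identical statistics. Exhaustive enumeration at
n ≤ 10 confirms blocky ≥ alternating for every composition tested, and
that for balanced two-group compositions the contiguous arrangement is
the global maximizer of delta. For unbalanced or filler-containing
compositions the exact maximizer can differ from the contiguous layout
(the windowed statistic rewards spreading surplus residues); the
`blocky_arrangement` helper is therefore documented as "fully
segregated", not "maximal".

Composition features (20 amino-acid fractions, 8 group fractions, FCR,
NCPR) are z-scored against an IDRome background (per-feature mean/SD
over a background IDR set, ≥2 members required; zero-SD features are
flagged degenerate). The full report carries ~30 composition and ~36
patterning features; the display convention keeps features with
|z| ≥ 1 in at least one IDR. The feature list approximates published
grammar-feature panels but is configurable; reproducing any specific
published 90-feature list is a non-goal.

## Well-mixed-charge design

Within each IDR region independently, charged positions (excluding
anchored negatives) are refilled by alternating draws — next unused
negative, then next unused positive, in N→C extraction order, negative
first — and the surplus pool drains in extraction order once the other
is exhausted. Processing regions independently is a deliberate choice:
it makes per-IDR net charge conservation exact by construction, which
the validator then asserts as an integer identity. The alternation
phase (negative first) and surplus handling are the documented
defaults for an inherently ambiguous verbal rule; they are
deterministic, so the seed argument only matters if a stochastic
tie-break mode is ever enabled. The validator checks composition
identity, per-IDR net charge (K/R = +1, D/E = −1, H = 0), anchored
positions, and identity outside the regions (the proxy for "structured
domains unaltered"), and reports delta and shuffle-null z for both
sequences.

## Interaction maps

The map is deliberately mean-field: epsilon of a window pair is the
average pair weight, order-independent within windows, full windows
only, stride 1, axes labeled by 1-based window starts. The default
matrix is a simplified potential — opposite charges −1, like charges
+1, aromatic–aromatic −0.7, cation–π −0.5, all else 0 — chosen so that
the sign structure (attraction between opposite charge blocks,
repulsion between like blocks) is transparent and auditable; any
force-field-derived 20×20 symmetric matrix can be supplied as TSV, and
results with such a matrix will differ in scale. The per-residue
attractive vector averages min(epsilon, 0) over all cells whose window
contains the residue, so repulsive cells do not dilute it. Transpose
symmetry holds to floating-point rounding (the two orientations sum in
different orders); tests assert it at 1e-12.

## Dwell times

Dwell = (last frame − first frame + 1) × frame interval, gap-inclusive:
the tracker closes gaps of up to 2 frames, and a molecule is presumed
bound across a blink. Tracks with fewer than 2 detections are dropped
as unlinked detections. Oversized gaps and duplicate (track, frame)
rows are hard errors — they indicate a broken upstream table, not data.

The survival function is the right-continuous complement
S(t) = P(dwell > t), reported at t = 0 and each unique dwell; S reaches
0 at the largest dwell, and that point is excluded from log-domain
fitting. The bi-exponential fit runs on log₁₀ S with equal weight per
unique dwell time by default, which keeps the rare long tail (dwells
up to ~80 s) from being swamped by the sub-second majority; raw-S
fitting is available by flag. Initialization reads τ_ns from the 0.5
crossing of the curve (median dwell), τ_s from the 0.1 crossing, and
A = 0.7; bounds keep A in (0,1), and label swap is resolved by ordering
τ_ns < τ_s. Fits with τ_s/τ_ns < 1.05 are flagged degenerate
(effectively single-exponential data). No photobleaching correction is
applied to dwell times — a known caveat, as bleaching truncates long
dwells; the simulation twin shares this property, so recovery tests
are internally consistent.

Population bins: < 1.2 s (non-specific) and the overlapping specific
bins ≥ 1.2 s, ≥ 7 s, ≥ 10 s. Fold changes are mean(condition)/
mean(control) per bin across experiments, compared by two-sided
equal-variance t-test (Welch available by flag).

Expression gating: bounds are the 1st/99th percentiles (linear
interpolation) of wild-type nuclear intensities; fixed-stain
intensities are mapped to the live scale by corr_fix = mean(live)/
mean(fixed) before comparison, and values exactly on a bound are
excluded (strict inequalities, a documented convention).

## Cluster quantification

Each seeded spot is fit on an 11×11 patch (radius 5) with an
elliptical Gaussian plus constant offset; fits with non-positive
amplitude or sigma outside [0.5, 5] px are rejected. The integral is
the model-minus-offset sum over the 2σ ellipse (a raw-pixel variant is
available by flag); "2σ" pins down the loosely defined "area of the
fit" and captures 1 − e⁻² ≈ 86.5% of the flux. Molecule counts divide
by the unitary intensity, the median integral of isolated single
molecules measured with the same procedure — because calibration and
measurement share the 2σ convention, the truncation factor cancels.

At low signal-to-noise (per-pixel noise comparable to the unitary
intensity) a free-center, free-sigma fit latches onto noise maxima and
inflates amplitudes by tens of percent; for that regime the fitter can
pin sigma to the PSF width calibrated from the single-molecule data
and bound or pin the sub-pixel center at the detector seed. The clean
calibration → constrained measurement protocol is what the recovery
tests and the acceptance script use for noisy scenes; noiseless fits
keep all parameters free. Even so, single-spot counts at 15 molecules
under noise = unitary carry ~35% statistical scatter — only averages
over spots are meaningful there, and counts below ~10 molecules at
that noise level are unreliable (fits are rejected or strongly
biased).

Phase decomposition per nucleus: dense = summed integrals of clusters
with ≥ 10 molecules per nuclear pixel; dilute = mean intensity outside
the union of all cluster 2σ ellipses; total = mean over the mask.

## Recruitment pipeline

Filters (conjunctive, with a per-rule rejection ledger): track starts
at frame 0; spans ≥ 10 frames (18 min at 2-min sampling); per-track
mean area within [0.45, 1.55] a.u. (area units are opaque; the cutoffs
are taken as given); nucleus-localized. The correction model
a·e^(−t/τ) + c is fit to the pooled control-arm partner mean after
scalar background subtraction — the offset c is included because a
plain mono-exponential cannot absorb a camera offset, and fitting the
pooled mean (not per-track) keeps the correction low-noise. Corrected
series = raw − background − model(t); applying the model to the
control itself leaves residuals at zero, which is asserted as the
pipeline's self-consistency check. The correction removes non-specific
recruitment and the bleaching of the baseline; bleaching of the
induced signal itself is not divided out (matching the source
procedure), which slightly depresses late time points.

Gating keeps tracks whose baseline-subtracted YAP channel at 16 min
(nearest frame within one interval) reaches the threshold (250 a.u.
for the Halo-tag readout; 750 a.u. for the SNAP-tag readout). Pooling
intersects the track time grids, subtracts each track's value at the
first shared time point, and reports mean ± SEM; difference curves
subtract two pooled means on their shared grid. t = 0 is acquisition
start; inducer addition at ~2 min is metadata, not a time shift.

## Synthetic-data generators

All generators are seeded and bit-reproducible, and each returns
machine-readable ground truth.

**Dwells** are drawn from the two-exponential mixture (defaults
A = 0.7, τ = 1.2 s and 7 s — the measured non-specific/specific
chromatin-binding constants; the mixing weight is an assumption, since
the fitted fast fraction is not part of the emulated measurements),
rounded *up* to whole 150 ms frames (a molecule present for any part
of a frame is detected; mean bias +dt/2), and truncated at the 80 s
longest observable dwell, kept on the frame grid. Track tables place
each dwell as a run of consecutive frames with optional ≤2-frame
blinks (repaired to respect the tracker's gap-closing limit, so
first/last frames — and hence spans — are exact) and single-frame
noise detections.

**IDRs**: random sequences at a requested group composition (remainder
drawn from G/S), optionally driven toward a target delta by seeded
greedy position swaps; IDRome-style backgrounds draw per-sequence
compositions from a Dirichlet around disorder-like residue
frequencies (P/S/Q/E/K/G enriched, hydrophobics and aromatics
depleted) with lengths 40–300. These backgrounds have realistic
composition variance but no phylogeny, no length–composition
correlation, and no real proteome structure — composition z-scores
against them exercise the machinery, not mouse-proteome biology.

**Cluster scenes**: flat background plus isotropic Gaussian spots
whose full-plane integral is molecules × unitary, plus Gaussian read
noise. No Poisson shot noise, no PSF asymmetry, no spot overlap
(a warning fires below 3σ spacing) — recovery tests on these scenes
validate the fitting and calibration conventions, not robustness to
real optical artifacts.

**Recruitment**: a phenomenological ODE on a 2-min grid (RK4 at 0.05
min; drives are piecewise-constant),

    Y' = k_on·1{t ≥ t_rap} + k_fb·M − d_y·Y
    M' = k_med_on·Y − k_med_off·M
    P' = k_pol_on·M − d_pol·P − k_neg·R·P
    R' = k_rna·P − k_rna_decay·R      (k_rna = 0 after the DRB time)

with Mediator feeding back positively on YAP recruitment and
accumulated transcript R suppressing Pol2 (delayed negative feedback →
adaptive response). The decay terms d_y and d_pol are required for
bounded steady states. No rate is a measured value; the defaults
(per-minute: k_on 100, k_fb 0.01, d_y 0.1, k_med_on 0.05, k_med_off
0.2, k_pol_on 0.02, d_pol 0.05, k_neg 0.01, k_rna 0.02, k_rna_decay
0.01) were chosen once to produce the qualitative regimes the pipeline
must distinguish — YAP plateau ~1000 a.u. within ~30 min, a sustained
Mediator-like partner, an adaptive Pol2-like partner peaking near
40–60 min and settling well below half its peak — with realistic
amplitudes relative to the 250 a.u. gate. Observed channels add a
constant baseline (non-specific partner level 200 a.u., YAP baseline
100 a.u.), per-track log-normal amplitude (CV 0.1), per-frame Gaussian
noise (SD 10 a.u.), and multiplicative bleaching e^(−t/600 min) —
mild bleaching appropriate to low-excitation spinning-disk imaging at
2-min intervals. Control arms have k_med_on = k_pol_on = 0
(fluorophore-only constructs: baseline and bleaching, no response).

## Problem sizes

Defaults throughout are desk-scale choices: 10⁴ dwells × 20 replicates
for parameter-recovery statistics, 300-member synthetic IDRomes and
2,000–10,000 shuffles for grammar nulls, 25-spot scenes × 4 replicates
for cluster recovery, 40 + 40 tracks per recruitment simulation. These
sizes give sampling errors comfortably below the effect sizes under
study while keeping any single analysis under a couple of minutes.

## Known limitations

- The grammar feature panel approximates, but does not reproduce, any
  specific published feature list; z-scores are comparable within this
  package only.
- The default interaction matrix is a sign-structure caricature;
  quantitative epsilon scales require a real force-field matrix via
  TSV, and the window-pair normalization (per-pair mean) may differ
  from other implementations.
- Dwell times are not bleach-corrected; absolute τ_s is a lower bound
  in bleach-limited regimes.
- The recruitment ODE is phenomenological; its rates are not fit to
  data and should not be interpreted biophysically.
- Passing tests on the generators demonstrates correctness of the
  analysis conventions under the stated noise models, not performance
  on real microscopy (segmentation errors, drift, aberrations, and
  shot noise are all out of scope).
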