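# Methods

`microcolony` analyses experiments in which *E. coli* grows through a
confined, non-fluidic microchannel (60 µm wide, ~4 µm deep) towards a set of
gold microelectrodes, while an automated platform records three parallel
readouts: micrographs of each channel segment every 10 min, three cyclic
voltammograms (CV) every 30 min, and one 25-point impedance spectrum (EIS)
every 30 min.  The scientific object of interest is the *colonization
event*: the moment the bacterial front covers the electrode-enabled active
area and establishes electrical contact between the microelectrodes.

## Variance statistics and changepoint detection

Every raw record is reduced to one scalar per acquisition: the unbiased
variance (denominator M−1) of its M values — 201 currents for a CV sweep,
25 |Z| values or 25 phase values for an EIS spectrum.  Before colonization
the microelectrodes have no electrical contact and the response is dominated
by stray and capacitive effects, so this variance is small and stable; the
faradaic peaks and impedance collapse that follow colonization change it by
close to an order of magnitude.

The variance-versus-time series is min–max normalized to [0, 1] (a constant
series maps to all zeros and is flagged degenerate), and a single step
change is located by minimizing the segment-length-weighted log population
variance

    J(k) = (k−1)·log var(V₁…V_{k−1}) + (n−k+1)·log var(V_k…V_n)

over 1-based split indices k ∈ [3, n−1], each segment keeping at least two
points.  Segment variances are floored at 1e−12 before the logarithm so
noiseless fixtures stay finite; ties break toward the smallest k (earliest
event).

The change ratio R — post-segment mean over pre-segment mean — is computed
on the **raw** variance series with the k found on the normalized series.
Normalization maps every series onto the same range, so a ratio computed on
normalized values cannot distinguish a physically large step from a small
one; on raw variances a quiet control run gives R ≈ 1 while a colonization
event gives R ≫ 1 on current variance and R ≪ 1 on impedance variance.
(The normalized variant remains available through an argument.)

## Image pipeline

Per frame: collapse to luminance and stretch to full dynamic range; detect
the two channel borders as the two highest-scoring near-parallel
(≤ 5°) straight-line Hough peaks on a Canny edge map (0.5° angle
resolution); rotate the channel to horizontal about the weighted centre of
the enclosed band and crop to the interior plus a 4-px margin, refining the
crop anchor against the darkest rows because Hough offsets are
bin-quantized; segment texture by thresholding the local intensity variance
(5×5 window) at the 70th percentile of the reference (first) frame's
distribution, one frozen threshold per image set.  The colonized percentage
is 100 × foreground/total pixels.

Growth phases: the offset is the median of the pre-growth plateau; the lag
phase ends when the curve first exceeds the offset by 3 percentage points;
the stationary phase starts at the first frame after the rise whose
increment drops below 0.5 pp/frame; colonization duration is their
difference.  Both anchors are frame-aligned, which introduces a positive
bias of up to one frame interval in the recovered duration (a 65-min
traversal at 10-min frames is typically reported as 70 min); all margins
are configurable.

Because an empty channel still shows its borders and static optical
artifacts as texture, the segmented baseline is non-zero (≈30% with the
default generator settings); the offset estimate reports it explicitly.

## CV analytics

Sweeps are grouped before/after the detected event.  At each of the 201
potential points the across-sweep current variance is computed; strict
local maxima of that curve are primary peak candidates, and local maxima of
|σ²/σ²′| and |σ²′/σ²″| (central differences, denominators floored at 1e−15
and floored points excluded as candidates) supply secondary candidates
where the primary survey is inconclusive.  Candidates are clustered per
polarity by 1-D single linkage with a 50 mV gap; each cluster is
represented by its highest-|i| member, and the strongest anodic/cathodic
representatives form the redox pair.  Peak change ratios divide the mean
|current| across after-event sweeps at the peak's grid index by the mean
|current| across before-event sweeps at the same index.

The anodic current is positive (oxidation) and the forward sweep is the
increasing-potential half.  The formal potential is the midpoint of E_pa
and E_pc; referencing against the ferro/ferricyanide couple vs. Ag/AgCl
uses correction = 0.241 V − measured formal potential.

## EIS analytics

The simplified equivalent circuit is R_elec in series with C_belec parallel
to (R_b + CPE), with Z_CPE(ω) = 1/(Q·(jω)^n).  R_elec is the microsystem
series resistance, C_belec the bacteria–electrode interface capacitance,
R_b the bacterial charge-transfer resistance, and the CPE models the
non-uniform accumulation of adsorbed species.  A full two-Randles-cell
topology with a capacitive inter-electrode bridge is implemented for
documentation and limit checks; it reduces to the simplified model when the
electrode double layers vanish, and all quantitative fitting uses the
simplified model.

Fitting minimizes the modulus-weighted complex residual
Σ|Z_model−Z_data|²/|Z_data|² with positive parameters in log space and n
through a logit onto (0, 1], using Levenberg–Marquardt from a small grid of
starting points (the data-derived auto-init plus R_b·{1,10,100} ×
n∈{0.6,0.8,0.95}); the lowest-residual solution wins.  Noiseless
simulate-and-fit round trips recover all five parameters to machine
precision in both circuit regimes.

Identifiability is regime-dependent.  In the pre-colonization (blocking)
regime the interface capacitance shunts the open faradaic branch: the CPE
contributes well under 1% of the measured signal, and under 1% relative
noise the (Q, n) pair degenerates toward an ideal capacitor while R_elec,
C_belec and (more weakly) R_b stay identifiable.  Epoch summaries of
per-spectrum fit trajectories therefore use medians, and the fit-quality
assessment (median per-parameter error below 5%) is performed on the
epoch-mean spectrum of the colonized regime — the same averaged-epoch
fitting the monitoring protocol uses — where all five parameters meet the
bound.

## Event staging

A channel shows a *step* when its changepoint improves the no-split cost by
at least n·log 4 — precisely the improvement an artifact-free linear drift
can achieve, so smooth trends never flag — and its raw change ratio leaves
a band around 1 (current and impedance: [1/2, 2]; phase: [1/1.1, 1.1],
because a genuine colonization moves the phase variance only to ≈0.7–0.8 of
its pre-event level).  Colonization = concurrent steps on all three
channels with current R ≫ 1 and impedance/phase R < 1; control = no steps;
early electrode damage = two stepping channels without the faradaic
signature (current variance drops rather than rises); damage after
colonization = a colonization followed, in the post-event tails, by a
current-variance decrement together with a phase-variance increment.
Image concordance reports the signed offset between the electrochemical
event and the image-derived stationary onset, flagging offsets beyond
2.5 h.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (scenario, seed) and emit their ground
truth alongside the data.

**Images.** A 300 µm segment at 4 px/µm: two 2-px dark border lines 240 px
apart, background with Gaussian sensor noise (σ = 2 grey levels), bacteria
and artifacts as clipped-Gaussian granular texture (amplitude 45), a front
entering at a configurable arrival time and traversing the segment in
3900 s, plus Poisson-seeded scouting colonies ahead of the front.  The
static artifact field is calibrated, disk by disk, until the
texture-visible area (drawn region plus the 2-px halo a 5×5 local-variance
window responds in) of an empty frame is 30% of the analysis crop.

**CV.** Triangular sweeps −0.5 → 0.5 → −0.5 V at 50 mV/s, 201 points per
cycle (10 mV half-sweep step): a capacitive box (±2 nA by sweep direction),
an ohmic slope (20 nA/V), and 0.1 nA stray noise.  At the event, Gaussian
faradaic peaks (width 45 mV) appear at E_pa = 139.8 mV and
E_pc = −204.55 mV — abruptly at 80% of steady state, as electrical contact
is established — then stabilize over 2 h, with 10% per-sweep amplitude
scatter; steady-state peak currents are 8.29× (anodic) and 6.07× (cathodic)
the pre-event current magnitude at those potentials.  Electrode damage
multiplies subsequent currents by a factor decaying to 0.3.

**EIS.** Spectra evaluated from the simplified circuit at 25 log-spaced
frequencies (200 Hz–50 kHz) with 1% complex Gaussian noise proportional to
|Z|.  Parameters interpolate log-linearly from the pre-colonization regime
(R_elec 15.96 kΩ, C_belec 0.919 nF, R_b 5.71 MΩ, Q 31.4 nS·sⁿ, n 0.774) to
an after state that keeps the colonized-regime spectral shape but is
impedance-scaled, in closed form, so the across-frequency |Z|-variance
drops to exactly 0.15× its pre-event value.  Early damage steps the series
resistance ×5 with no faradaic change; damage after colonization raises the
series resistance ×5 and the bacterial charge-transfer resistance ×10,
degrading the established contact and raising the phase variance.

What the generators do **not** emulate: optics (no point-spread function,
no illumination gradients, no focus drift), electrochemical physics
(no Butler–Volmer kinetics or diffusion; the CV waveform is a descriptive
model of exactly the features the analysis consumes), temperature effects,
biological variability in growth rates, or agar degradation.  Passing
recovery tests therefore demonstrates that the *analysis* is correct and
well-calibrated under the study's statistical structure, not that it is
robust to every imaging or instrumentation pathology of real hardware.

## Numerical choices and problem sizes

Changepoint segment variances floored at 1e−12; derivative-ratio
denominators at 1e−15; circuit fits use xtol=ftol=gtol=1e−14 with at most
2000 function evaluations per start; rectification pads out-of-bounds crops
with the background median.  Monitoring sessions used throughout testing
are 30 h (61 EIS spectra, 183 CV sweeps) with the event at 6 h; recovery
statistics use 20-seed batches (50 for fit-error medians; 25 per class for
the staging confusion panel), sizes chosen so every suite completes in
minutes on one CPU while keeping the Monte-Carlo error well inside the
assessed tolerances.

## Known limitations

The between-segment lag and segment-overlap utilities assume the generator's
left-to-right growth geometry; the full-circuit topology is a documented
modelling choice, not fitted; CPE parameters should not be interpreted from
single-spectrum fits in the blocking regime (see identifiability above);
and the staging thresholds, while configurable, are calibrated against the
synthetic study conditions rather than learned from data.
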