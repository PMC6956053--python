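# microcolony

Automated analysis of bacterial colonization in confined, non-fluidic
microsystems.  When *E. coli* grows along a 60-µm microchannel towards a set
of gold microelectrodes, three readouts change together the moment the
bacteria cover the electrode-enabled active area and establish electrical
contact: time-lapse micrographs show the advancing front, cyclic
voltammograms (CV) develop anodic/cathodic faradaic peaks, and impedance
spectra (EIS) collapse.  This package implements the full analysis chain for
such experiments — for microbiologists and bio-electrochemists running
long-term electrode-colonization monitoring — together with seeded synthetic
data generators that make every stage testable without instrument data.

## What it computes

Every raw record (a 201-point voltammogram, a 25-frequency spectrum) is
reduced to its sample variance σ²ₙ = 1/(M−1) Σ|xᵢ−μₙ|²; the variance-vs-time
series is min–max normalized to Vₙ ∈ [0, 1] and the colonization event is the
single changepoint

&nbsp;&nbsp;&nbsp;&nbsp;k̂ = argmin_k (k−1)·log var(V₁…V_{k−1}) + (n−k+1)·log var(V_k…V_n),

qualified by the change ratio R = mean(x_k…x_n)/mean(x₁…x_{k−1}) of the raw
variances.  Around that core:

- **imaging** — channel border detection (straight-line Hough), rotation and
  crop rectification, percentile texture segmentation, and extraction of the
  lag / exponential / stationary growth phases from the colonized-area curve;
- **cvpeaks** — per-potential current variance, primary and secondary redox
  peak surveys, 1-D peak clustering, peak change ratios, formal potential and
  Ag/AgCl referencing;
- **eisfit** — constant-phase-element and equivalent-circuit models
  (Z_CPE = 1/(Q(jω)ⁿ); R_elec + C_belec ∥ (R_b + CPE)), complex nonlinear
  least-squares fitting, parameter trajectories, per-frequency variances;
- **monitor** — fusion of the CV-current, |Z| and phase variance channels
  into colonization / control / early-damage / post-colonization-damage
  calls, cross-checked against the image-derived growth curve;
- **synthdata** — seeded generators for image stacks, CV sessions and EIS
  sessions with the statistical structure the analysis assumes, each
  returning its ground truth;
- **io** / **cli** — CSV session formats, TIFF stacks with JSON sidecars,
  and a `microcolony` command (`simulate`, `analyze-images`, `analyze-cv`,
  `analyze-eis`, `fit-circuit`, `classify`, `report`).

## Worked example

Simulate a paired 30-h monitoring experiment with a colonization event
injected at 6 h, then stage it:

```python
from microcolony.synthdata import generate_paired_sessions
from microcolony.monitor import stage_experiment

cv, eis, truth = generate_paired_sessions("colonization", seed=7)
result = stage_experiment(cv, eis)
print(f"label: {result.label}")
print(f"event time: {result.event_time_s / 3600:.1f} h")
for name, ev in result.evidence.items():
    print(f"  {name:9s} change ratio {ev.change_ratio:7.3f}  step={ev.step}")
```

prints

```
label: colonization
event time: 6.0 h
  current   change ratio   4.226  step=True
  impedance change ratio   0.157  step=True
  phase     change ratio   0.738  step=True
```

The current variance jumps (R ≈ 4) as faradaic peaks appear, the impedance
variance collapses to ≈0.16× its pre-event level, and the phase variance
drops moderately (≈0.74) — the three-channel signature that separates a true
colonization from electrode damage (which steps only two channels, without
the current-variance rise) and from a quiet control run (no steps).  The
event is recovered at the injected 6 h.

The same flow from a shell:

```sh
microcolony simulate --kind cv  --seed 7 --event-h 6 --out run/
microcolony simulate --kind eis --seed 8 --event-h 6 --out run/
microcolony classify --cv run/cv.csv --eis run/eis.csv --out run/label.json
```

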