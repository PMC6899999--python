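# kymodwell

Single-molecule kymograph analysis of how long kinesin motors reside at
microtubule ends, paired with a stochastic simulator that generates
synthetic two-channel TIRF kymographs with known ground truth.

## The problem

Kinesins that regulate microtubule dynamics (e.g. the depolymerase MCAK,
a kinesin-13) recognise the microtubule end and stay there for seconds,
whereas purely translocating kinesins such as kinesin-1 walk over the end
and leave almost immediately. The standard readout is the **microtubule
end-residence time** measured from TIRF kymographs: movies of single
GFP-labelled motors on immobilised, GMPCPP-stabilised, rhodamine-labelled
microtubules, imaged at 2.7 Hz, are resliced into time × position images
in which moving motors appear as diagonal traces and end-bound motors as
vertical traces at the microtubule end.

Scoring such kymographs involves thresholding both channels against
background, defining the microtubule end as the final above-threshold
pixel column of the rhodamine channel, segmenting discrete fluorescence
events in the GFP channel (events are discrete when separated by at
least one non-event pixel in time or space), classifying each event
(translocating / static / discarded crossing), and converting frame
counts into durations. Every one of those steps has failure modes that
are invisible without ground truth. This package therefore implements
both the measurement chain and a generative simulator, so that each
stage can be validated by parameter recovery.

## Model

A motor variant is characterised by a small set of kinetic parameters:

* landings: Poisson process with rate `λ·L` (λ per μm per s, `L` the
  microtubule length), uniform landing positions;
* translocation: constant speed `v` (nm/s) toward the plus end, with
  detachment hazard `v/ℓ` so run lengths are exponential with mean `ℓ`;
* end residence: on reaching the plus-end pixel, an exponential dwell
  with mean `τ_end`, stationary at the tip, then detachment;
* static binders (e.g. MCAK, which does not translocate): exponential
  lattice dwells `τ_lat` in place; landings within one pixel of the plus
  end bind the terminal site and draw from `τ_end`.

Durations are estimated from frame counts. A motor seen in `k` frames at
the end was bound for roughly `(k − ½)·Δt` (the default convention; `k`
and `k − 1` are options), and at the dataset level the package also
provides the memoryless inversion `τ̂ = −Δt / ln(1 − 1/k̄)`, which removes
frame-quantisation bias entirely for exponential dwells.

Variant panels default to published single-molecule measurements for the
rat kinesin-1 motor-domain construct rkin430-GFP, its α4-helix point
mutants (G262K, N263E, S266R, the triple mutant, S266A) and MCAK —
e.g. WT: 810 nm/s, 3.06 μm runs, 0.46 s end residence; S266R: 1.41 s;
MCAK: 2.03 s. Distributions are compared by two-sample
Kolmogorov–Smirnov tests and fold changes of mean end residence with
bootstrap confidence intervals. Basal ATP turnover is fitted as the
ordinary least-squares slope of an ADP-production timecourse divided by
the enzyme concentration.

## Worked example

```python
import kymodwell as kd
from kymodwell.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    panel={"WT": kd.DEFAULT_PANEL["WT"], "S266R": kd.DEFAULT_PANEL["S266R"]},
    imaging=kd.ImagingParams(n_frames=1500),
    n_microtubules=12,
    seed=1,
)
report = run_pipeline(cfg, "demo_out")
```

This simulates 12 microtubule movies per variant (1500 frames at 2.7 Hz,
160 nm pixels), renders and then re-measures them, and writes TIFFs,
per-event CSVs and a JSON report. With the seed above the report
contains:

```
WT     n_end_events=65  end_residence_mean_s=0.464  velocity_mean_nm_s=803.2
S266R  n_end_events=35  end_residence_mean_s=1.561  velocity_mean_nm_s=672.0
S266R vs WT: ks_D=0.422  ks_p_value=6.1e-04  fold_change=3.36 (95% CI 2.26-4.82)
```

i.e. the measurement chain recovers the generative end residences
(0.46 s and 1.41 s) within sampling error, finds the S266R distribution
significantly different from wild type, and reports the roughly
three-fold increase in end residence that distinguishes an
end-recognising motor from a purely translocating one.

The same stages are available from the shell:

```
kymodwell run --config panel.yaml --out results/ --seed 1
kymodwell simulate --config c.yaml --out sim/ --seed 1
kymodwell analyse --in sim/WT --out events.csv
kymodwell stats --events events.csv --out summary/
kymodwell atpase --in timecourse.csv --kinesin-um 1.0
```

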