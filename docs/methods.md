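# Methods

## Generative model

The simulator realises the simplest kinetic model consistent with
single-molecule motility assays on stabilised (non-dynamic)
microtubules. Landings are a homogeneous Poisson process along the
microtubule (`landing_rate` per μm per s; default 0.005, chosen so that
events are sparse and crossing traces are occasional, as in real
single-molecule assays where the motor concentration is deliberately
kept low). Translocating motors move plus-ward at constant speed with a
constant detachment hazard, giving exponential run lengths. A motor
that reaches the plus end switches to an exponential end dwell and is
stationary at the tip until it detaches. Non-translocating motors
(`fraction_static`) dwell exponentially in place; a static landing
within `end_zone_um` (default 0.16 μm, one pixel) of the plus end binds
the terminal site and draws from the end dwell instead — this is how an
end-recognising depolymerase such as MCAK is represented without
simulating depolymerisation itself.

When imaging geometry is known, the end dwell starts on entry into the
plus-end pixel column rather than at the geometric tip. The terminal
site is not resolved below pixel size, and starting the dwell clock at
column entry makes the generative dwell coincide with what end-column
occupancy can measure; the sub-pixel discrepancy is at most one pixel
of travel (~0.2 s at 810 nm/s would otherwise leak into short dwells).

Rendering follows the acquisition conditions of the assay: frames at
2.7 Hz (`frame_interval = 1/2.7 s`), 160 nm pixels (typical EMCCD TIRF
at 100×; the pixel size is configurable), a rhodamine channel with
uniform microtubule intensity (partial coverage at the end columns) and
a GFP channel with one Gaussian spot of width `psf_sigma` (default
1 px) per bound motor per frame, both with additive Gaussian background
noise. A motor contributes to frame `k` iff it is bound at the frame
midpoint; there is no motion blur. Spots are additive, which produces
genuine crossing events for the exclusion rule to catch. Events still
bound at the movie end are marked censored in the ground truth.
Microtubule lengths default to uniform 4–8 μm in a 120 px image, so
that background columns remain the majority and median/MAD background
estimation stays valid.

Deliberately not modelled: microtubule dynamics, depolymerisation,
photobleaching (dwell truncation therefore comes only from the movie
end), multi-motor interactions other than additive intensity, and 2-D
movie synthesis. Passing parameter-recovery tests on these synthetic
data therefore demonstrates correctness of the measurement chain under
the stated model, not robustness to bleaching, drift or dense traffic.

## Measurement chain

Thresholds are `median + k·1.4826·MAD` (robust SD), default `k = 3`,
computed per channel. The microtubule extent is the longest
above-threshold run of the time-averaged rhodamine profile; the
outermost run columns are the end pixels. Because the end columns are
only partially covered by the microtubule, their intensity relative to
the interior recovers the end position to sub-pixel precision; this
"tip" position anchors end-occupancy scoring.

GFP pixels above threshold within the extent form the event mask.
Discrete events are its 8-connected components (diagonal contact does
not separate events, matching the rule that events are discrete only
when separated by at least one non-event pixel in time or space).
Components smaller than `min_event_pixels` (default 2) are treated as
noise. A component with two or more disjoint pixel runs in any frame
row is a crossing that cannot be attributed to a single molecule; it is
classified `discarded-crossing` and carries no measurements.

Per-frame positions are intensity-weighted centroids over a fixed
window (default ±2 px) around the brightest component pixel in that
row. A fixed window avoids two biases of centroiding the thresholded
footprint itself: selection jitter from dim edge pixels toggling across
the threshold, and an inward pull at the microtubule end where the mask
is clipped at the extent while the PSF tail spills past it.

An event is translocating when it spans ≥3 frames, its centroid steps
are unidirectional (|step| ≤ 0.5 px counts as a pause; no sign
reversals) and its net displacement is ≥2 px; velocity is the |OLS
slope| of centroid position versus time excluding end-occupied frames,
and run length the net centroid displacement, censored when the run
terminates at an end or movie boundary. All other well-formed events
are static lattice binders.

End occupancy is scored per frame as the centroid lying within
`end_margin_px` (default 0.4 px) of the sub-pixel tip, one-sided since
nothing lies beyond the end. Because one discrete trace is one
molecule, a single off-frame inside an end run is treated as centroid
noise and bridged (`end_gap_frames = 1`); runs touching the movie
boundary are censored and excluded from summaries. The end-residence
time of an event is its maximal consecutive end-occupied frame count
converted to seconds.

## Durations from frame counts

An exponential dwell of mean τ sampled at frame midpoints Δt apart is
seen, conditional on being seen at all, in `1 + Geometric(1 −
exp(−Δt/τ))` frames. Hence `k·Δt` overestimates short dwells badly
(≈ +45% at τ ≈ Δt) and `(k−1)·Δt` underestimates them. The default
per-event convention is `(k − ½)·Δt`, whose residual bias is
`Δt²/(12τ)` — under 6% for τ ≥ 0.46 s at 2.7 Hz; `k` and `k_minus_1`
remain available as `duration_convention` for comparison with other
software. For dataset-level estimates,
`dwell_mean_from_frame_counts` inverts the geometric mean count,
`τ̂ = −Δt / ln(1 − 1/k̄)`, which is free of both the quantisation and
the detection-conditioning bias.

Known residual biases of the full chain, measured by ground-truth
matching at the default study conditions: mean end residence recovered
within ±8% across generative dwells 0.46–2.03 s (events that collide at
the end are discarded as crossings, removing slightly more long dwells
than short ones); velocity within ~2%; and lattice-terminated run
lengths about 5% short, because the first and last partial frames of a
run are unobserved. Run-length summaries additionally exclude runs that
reach the end, which on short microtubules truncates the observable run
distribution — recovery of the generative mean run length should be
checked on long microtubules with the end out of reach.

## Statistics

Per-variant summaries report n, arithmetic mean and SEM = SD/√n of
uncensored end-residence times, with histograms binned at one frame
interval (the time quantisation of the measurement). Two-sample
Kolmogorov–Smirnov tests compute the exact supremum ECDF difference and
an asymptotic p-value from the Kolmogorov distribution at effective
size `n₁n₂/(n₁+n₂)`; at the sample sizes involved (~250 per variant)
the asymptotic approximation is adequate (measured null rejection rate
0.042 at nominal 0.05) and exact small-sample p-values are not
attempted. Fold changes are ratios of means with seeded bootstrap
percentile 95% CIs (default 10⁴ resamples, seed 12345). Pearson
correlation with a two-sided p reproduces "no relationship" checks such
as velocity versus end residence; it is reported as undefined for
zero-variance input. No multiple-testing correction is applied across
variant pairs (raw KS p-values are reported).

ATP turnover fitting assumes zeroth-order kinetics in ATP: at 2 mM ATP
over ≤30 min the consumed fraction at the relevant rates stays below a
few percent, so [ADP](t) is linear and the rate is slope/[enzyme]. The
fit refuses timecourses where ADP exceeds 50% of the initial ATP. No
Michaelis–Menten analysis is performed. The synthetic timecourse
template is 7 points at 5 min spacing, 1 μM enzyme, 2 mM ATP.

## Pipeline and reproducibility

`run_pipeline` simulates, analyses and summarises a panel of variants,
then compares each variant's end-residence distribution against the
reference (default WT) by KS and fold change, and writes a JSON report
validated against the schema in `src/kymodwell/schema/`. The master
seed spawns independent per-variant streams (numpy `SeedSequence`), so
a fixed seed reproduces every TIFF, CSV and the report byte-for-byte.
Stage timings go to logging only, keeping the report deterministic.

Problem sizes in the shipped tests and acceptance script (tens of
microtubules per condition, 1500–2000 frames per movie, 10²–10³
statistical replicates) are chosen so that Monte-Carlo standard errors
are several-fold smaller than the tolerances being checked.

## Open choices

Where the assay description leaves parameters open, the package fixes
them as follows: landing rate 0.005 events/μm/s (sparse single-molecule
regime), microtubule lengths uniform 4–8 μm, pixel size 160 nm, spot
amplitude 8× the background SD (detection recall >0.99; the chain is
validated down to signal-to-background 5). The "±" on published end
residences is reported here as SD/√n of the raw durations; both
microtubule ends are measured and events are attributed per end, with
polarity known in simulation. Lattice residence of the static binder
defaults to one third of its end residence, reflecting the roughly
three-fold end-over-lattice preference reported for kinesin-13
depolymerases.
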