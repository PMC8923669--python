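# Methods

`fearpeth` analyses event-aligned electrophysiology and behaviour from
auditory cued fear conditioning in the ventrolateral periaqueductal grey
(vlPAG): single-unit peri-event time histograms (PETHs) and their
response statistics, tetrode cluster-quality gating, auditory
event-related potentials (ERPs), freezing/extinction quantification, and
the repeated-measures correlation that links neural response size to
freezing.  Because raw in-vivo recordings of this kind are rarely
shareable, the package pairs every analysis stage with a synthetic
session generator that reproduces the statistical structure the analysis
assumes, so the whole pipeline is testable end to end.

## The conditioning protocol

A session is laid out on one clock starting at 0 s: optional habituation
tones, then acquisition — the conditioned stimulus (CS, a 10 s tone)
paired 7× with an unconditioned stimulus (US, 0.5 s footshock) — then a
single extinction session of 35 unreinforced CS+ presentations in five
blocks of seven.  In the delay paradigm the US starts at tone offset; in
the trace variant a 1 s stimulus-free interval separates them.  Early
extinction (EE) is trials 1–14, late extinction (LE) trials 21–35.
Inter-tone intervals are drawn uniformly from a configurable range
(default 60–120 s; the underlying study does not report its ITI
distribution, so this is a package convention).  Trial indices are
1-based within each phase to match the "trials 1–14" convention.

## Unit-level analysis

**PETHs.**  Spike counts are binned at 40 ms relative to tone onset or
offset (bin k covers `[t0 + kΔ, t0 + (k+1)Δ)`), averaged across the
selected trials (all, EE, LE, or single blocks).  Each unit's
trial-averaged histogram is z-scored against the mean and *population*
SD of its 5 s pre-tone-onset baseline; the baseline is treated as the
full reference distribution, hence divide-by-n.  Offset-aligned
histograms reuse the pre-onset baseline statistics of the same trials,
because the 5 s before tone offset lie inside the tone.  A zero-variance
baseline marks the unit degenerate; it is excluded from response
analysis and counted in the report.  z-scoring is applied to the
trial-averaged PETH (one z series per unit per phase), not per trial.

**Response detection.**  A significant response is one or more
consecutive 40 ms bins at least 2 baseline SDs from the baseline mean
(either sign) within the first 500 ms after the aligned event.  500 ms
is not a whole number of 40 ms bins; the search window includes every
bin whose start precedes 500 ms (bins 0–12, the last covering
480–520 ms).  Direction comes from the earliest qualifying
same-direction run.  With the default single-bin criterion the
*per-unit* false-positive rate under a Poisson null is large — each null
bin crosses ±2 SD a few percent of the time, and there are 26 searched
bins per unit — which the null-calibration tests measure directly.
Raising `min_consecutive_bins` suppresses it sharply; the
high-specificity setting (4 consecutive bins) is used where exact
per-unit typing must be guaranteed, e.g. in cohort-recovery checks.

**Typing.**  Excitatory responses at onset and/or offset → type 1
(subtypes onset_only / offset_only / both); no response → type 2; both
an excitatory and an inhibitory response across the two alignments →
type 3 (biphasic); inhibitory only → type 4.  Units are typed from
all-trials PETHs and re-measured on EE and LE.

**Response metrics.**  Area is the trapezoidal integral of the z series
over the first 1 s after the event with unit spacing per bin (arbitrary
units; 25 bins → a constant z of 1 integrates to 24).  Peak z is the
unit's z at the bin where the cohort-average type 1 response peaks
(when a cohort is available), else at the unit's own largest-|z| bin.
Peak counting treats a peak as a maximal run of consecutive
supra-threshold bins (the published "(non-consecutive) bins" phrasing is
ambiguous; per-bin counting is available via `per_bin=True`).  Units
with a supra-threshold run starting after 500 ms are flagged and
excluded from peak summaries; this late scan is confined to the 1 s
response-analysis window, because scanning the full 5 s post-event span
would exclude essentially every unit through chance crossings alone.
The maximal-peak latency histogram divides the first 500 ms into five
100 ms bins and reports the percentage of units whose largest positive
z falls in each.

**Cohort bookkeeping.**  Counts and percentages per type and subtype;
percentages are rounded to one decimal, half away from zero.  Subtype
percentages are relative to the type 1 count.

## Cluster quality

Sorted units pass the single-unit gate when L-ratio < 0.35, isolation
distance > 15 and the fraction of interspike intervals under 2 ms is
below 1% (all strict; boundary values fail).  With D² the squared
Mahalanobis distance of a spike to the cluster (cluster mean, members-
only covariance with divide-by-(n−1)), L-ratio is
`Σ_noncluster (1 − CDF_χ²,df(D²)) / n_cluster` with df = the number of
features, and isolation distance is the n_cluster-th smallest D² among
non-members (undefined, and the unit rejected, when non-members number
fewer than members).  The ISI criterion is read as a refractory-
violation bound — intervals *shorter* than 2 ms — since rare long
intervals would describe no physiological unit.  The module is
feature-agnostic: energies, peaks or principal components per wire all
work, as the metrics are affine-invariant.

## ERPs

LFP traces are zero-phase band-pass filtered at 1–32 Hz (Butterworth,
applied before averaging), averaged across the selected trials aligned
to tone onset or offset, and summarised by: onset latency — the first
post-event time at which the mean departs from the pre-event baseline
mean by at least 2 baseline SDs for 5 consecutive samples (our own
construct; the source study does not report its latency rule, so values
such as specific millisecond latencies are not treated as recoverable
targets); peak latency — the first local extremum of the deviation at or
after onset; and peak-to-peak amplitude — max minus min of the
post-event mean.  A flat or sub-threshold trace leaves the latency
metrics undefined rather than raising.  Per animal, the channel with the
largest mean peak-to-peak response is selected (ties → lowest index) and
used for all phase comparisons.

## Behaviour

Freezing is the percentage of a half-open window covered by freeze
intervals; CS+ windows are the tone presentations and each ITI window
runs from tone offset to the next tone onset (or session end).  Epoch
durations summarise bout structure: baseline uses the last five freeze
and last five move epochs starting before the first extinction CS+;
EE the first five of each starting at or after it; LE the first five
starting at or after the tone onset of extinction trial 22.  Epochs are
attributed by start time and never split; fewer than five available
epochs yields a mean over what exists plus a shortfall flag.  The
extinction rate is the ordinary least-squares slope of freezing % over
extinction trials 1–21 (the first three blocks).  Rears and 22 kHz
ultrasonic vocalisations enter as annotated point events and are counted
in half-open windows.

**Repeated-measures correlation.**  For two variables measured
repeatedly within subjects (here: per-block response area and per-block
freezing %, blocks of seven tones, sessions as subjects), the model
`y = subject intercepts + common slope · x` is fitted by least squares;
`r_rm = sign(slope) · sqrt(SS_slope / (SS_slope + SS_residual))`, with
`df = n_observations − n_subjects − 1` and the p-value from the F test
of the slope on (1, df).  The implementation is independent of, and
agrees to machine precision with, `pingouin.rm_corr`.  Onset-response
area pairs with CS+ freezing; offset-response area with ITI freezing.

## The synthetic generator

Every generator is a pure function of (spec, events, seed); one master
seed is split into fixed per-component sub-streams, so adding a unit
never perturbs the behaviour or LFP streams.

**Spike trains** are inhomogeneous Poisson: a baseline rate (default
5 Hz) with rectangular event-locked transients — excitatory templates
multiply the rate by (1 + gain) inside a window of `response_width_s`
starting `response_latency_s` after the event, suppressive (type 4)
templates multiply it by a gain in (0, 1).  The rectangle is the
simplest shape for which superposition (excitation) and thinning
(suppression) are exact.  Transient gain scales by
`(1 − extinction_decay_per_block)^(block−1)` across extinction blocks;
per-trial Gaussian latency jitter is shared across a trial's sub-peaks.
`n_subpeaks > 1` splits the offset transient into that many sub-peaks
separated by 1.5 widths of silence.  A 2.5 ms absolute dead time is
pruned after generation: a pure Poisson train violates the <1% sub-2 ms
ISI purity gate about half the time, which no accepted sorted unit
would.  The muscimol-like unit preset (temporal dispersion after
cerebellar-nucleus inactivation) uses three 0.08 s sub-peaks with 0.03 s
per-trial jitter: wide per-trial jitter alone (e.g. 0.1 s) smears the
trial-averaged histogram into a single broad bump and produces *fewer*
distinct peaks, the opposite of the dispersion it must emulate.

**Behaviour** is a two-state freeze/move semi-Markov process with
exponential holding times.  The move→freeze hazard is multiplied, and
the freeze→move hazard divided, by a modulation factor while a
conditioned tone and its following interval are "hot"; the factor decays
per extinction block.  `epoch_duration_scale` divides both hazards,
lengthening both bout types without changing the freezing fraction (the
muscimol-like behaviour preset sets it to 3).  Defaults
(hazards 0.08 / 0.25 s⁻¹, modulation 3.0, decay 0.35 per block) were
chosen once so the stationary freeze fraction reproduces the reported
levels — ≈74% during EE tones falling to ≈31–36% in LE — and are not
revisited.  Rears and USVs are Poisson points confined to movement.

**LFPs** per channel are sums of event-locked kernels plus white
Gaussian noise.  A kernel is one full sine cycle of peak-to-peak
amplitude A starting `latency_s` after the event and peaking at
`peak_latency_s`, so injected onset and peak latencies and amplitude are
exactly recoverable on noiseless traces; kernel amplitude decays per
extinction block (default 15%, matching the reported ≈35% EE→LE drop of
the offset ERP).

**Cluster features** are Gaussian clusters plus a broad background
(label 0), the fixture source for the quality metrics.

What the generator does *not* emulate: bursting or oscillatory spike
structure, spike-field coupling, non-stationary baselines, video- or
audio-level behaviour (annotations are taken as given), and any
biophysical neuron or volume-conduction model.  Passing tests therefore
demonstrate correctness of the *analysis* under the stated statistical
assumptions, not robustness to every property of real recordings.

## Numerical and design choices

- Threshold 2.0 SD (the methods-text value), not the 1.96 drawn in
  figure significance lines; configurable.
- Strict inequalities at every quality-gate boundary.
- Trapezoidal areas use unit bin spacing (arbitrary units).
- Population SD for PETH baselines; sample SD (n−1) for cluster
  covariances and across-unit SEMs.
- Ties in best-channel selection go to the lowest channel index.
- Report percentages round half away from zero to one decimal; all
  computation is full precision until report time.
- The run manifest records config hash, seed and package version but no
  timestamp, so identical (config, seed) runs are byte-identical.
- Problem sizes in the test-suite and acceptance simulations use an
  extinction-only protocol with 20–30 s ITIs: PETH/behaviour statistics
  depend on trial structure, not ITI length, and the shorter sessions
  keep the suite quick.  The analysis drivers under `analysis/` use the
  full delay protocol with 60–120 s ITIs.

## Known limitations

- The detection criterion's per-unit false-positive rate at the default
  single-bin setting is intrinsic to the published rule; cohort
  summaries on synthetic data therefore contain chance-typed units, just
  as the criterion would produce on real nulls.
- Group-comparison statistics (t, Mann–Whitney, ANOVA, chi-square) are
  out of scope; standard libraries serve that need downstream.
- Raw-waveform spike sorting, video freezing detection and acoustic USV
  detection are out of scope; their outputs are the package's inputs.
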