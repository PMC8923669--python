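# fearpeth

Event-aligned analysis of single-unit, field-potential and behavioural
data from auditory cued fear conditioning — built for systems
neuroscientists studying how midbrain structures such as the
ventrolateral periaqueductal grey (vlPAG) encode the onset and offset of
a conditioned tone, and how that encoding relates to fear behaviour
across extinction.

The package implements, as a tested reusable pipeline:

- **Peri-event time histograms** (40 ms bins) z-scored to a 5 s
  pre-tone baseline: `z_k = (c̄_k − μ_base) / σ_base`, one series per
  unit per trial subset (all trials, early extinction EE = trials 1–14,
  late extinction LE = trials 21–35).
- **Response detection and unit typing**: a significant response is ≥ 1
  consecutive bin with |z| ≥ 2 within 500 ms of tone onset/offset;
  units are typed 1 (excitatory; onset / offset / both), 2 (none),
  3 (biphasic), 4 (inhibitory).
- **Response metrics**: trapezoidal area of z over the first 1 s
  (arbitrary units), peak z at the cohort-average peak time, counts of
  supra-threshold peaks and the 100 ms maximal-peak latency histogram.
- **Cluster-quality gating** for tetrode sorting: L-ratio
  `L/n_C = Σ_noncluster (1 − F_χ²,df(D²)) / n_C` < 0.35, isolation
  distance (the n_C-th smallest non-member Mahalanobis D²) > 15, and
  < 1% refractory (< 2 ms) interspike intervals.
- **Auditory ERPs**: 1–32 Hz zero-phase band-pass, trial-averaged
  potentials aligned to tone onset/offset, onset/peak latency and
  peak-to-peak amplitude, best-channel selection.
- **Behaviour**: per-trial freezing % during CS+ and inter-tone
  intervals, freeze/move bout durations around protocol anchors, the
  extinction-rate slope over trials 1–21, rear/USV counts.
- **Repeated-measures correlation** between per-block response area and
  freezing %, `r_rm = sign(b)·√(SS_slope/(SS_slope+SS_res))` with
  df = N − n_subjects − 1 (verified against `pingouin.rm_corr`).
- **A synthetic session generator** — inhomogeneous-Poisson spike
  trains with event-locked transients and per-block extinction decay,
  semi-Markov freeze/move behaviour with CS-modulated hazards, ERP
  kernels in noise, and Gaussian sorting-feature clusters — so every
  stage is testable without any recording on disk.

See `docs/methods.md` for the full model descriptions and design
choices.

## Worked example

Simulate a small control cohort and run the whole pipeline:

```python
from fearpeth.session_io import parse_config
from fearpeth.pipeline import run_pipeline

config = parse_config({
    "protocol": {"n_acquisition_trials": 0, "iti_range_s": [20.0, 30.0]},
    "groups": [{
        "condition": "control", "n_sessions": 6,
        "units": [{"template": "type1_both", "count": 3,
                   "onset_gain": 6.0, "offset_gain": 6.0}],
        "behavior": {},
    }],
})
results = run_pipeline(config, seed=1)
print(results.behavior_summary[["freezing_cs_EE", "freezing_cs_LE"]].mean())
print(results.rmcorr[["pairing", "r_rm", "df", "p_value"]])
```

prints

```
freezing_cs_EE    76.444601
freezing_cs_LE    40.318294
dtype: float64
                    pairing      r_rm  df       p_value
0    onset_area~cs_freezing  0.839411  23  1.566400e-07
1  offset_area~iti_freezing  0.829678  23  2.929516e-07
```

Freezing during the conditioned tone falls from ≈76% in early
extinction to ≈40% in late extinction (the conditioned response
extinguishes), and within animals the per-block unit response area
tracks the per-block freezing percentage (positive `r_rm` with
df = 30 observations − 6 sessions − 1 = 23): larger tone-evoked vlPAG
responses accompany more freezing, block by block.

## The analysis project

Numbered drivers under `analysis/` reproduce a study-style workflow on
the synthetic cohort defined in `analysis/cohort_config.yaml` (six
control sessions and four cerebellar-inactivation-like sessions under a
delay protocol):

```bash
python analysis/01_simulate_sessions.py     # sessions → scratch/sessions/
python analysis/02_run_pipeline.py          # report tables → results/report/
python analysis/03_condition_contrasts.py   # EE vs LE, control vs inactivation
python analysis/04_neural_behavior_correlation.py
```

The pipeline is also scriptable through a CLI
(`fearpeth simulate|analyze|report`, each taking `-c config.yaml`,
`--seed`, `-o outdir`).

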