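# erptopo

Topographic ERP analysis from stimulus onset to articulation, for overt
speech-production (picture-naming) experiments.

## The problem

In overt-production paradigms the interval of interest — from picture onset
to articulation onset — has a different length on every trial and for every
participant (production latencies typically span 700–1100 ms). Fixed
stimulus-locked epochs miss late phonological/phonetic encoding on slow
trials; fixed response-locked epochs misalign early processes. Worse, when
one processing stage simply lasts longer in one condition, every later
period of stable scalp topography is *shifted*, and a fixed analysis window
turns that shift into a spurious duration difference of the *following*
topography.

`erptopo` implements the combined-epoch approach: stimulus-aligned and
response-aligned ERPs are concatenated per trial/subject/condition according
to the production latency RT, with the overlapping signal removed from the
response-aligned side, so the analysed window covers exactly
[0, RT − offset]. On top of that it provides the standard global topographic
toolkit:

- **GFP** (global field power): the spatial standard deviation
  `GFP(u) = sqrt(mean_i (u_i − ū)²)` of the average-referenced map `u`;
- **DISS** (global map dissimilarity):
  `DISS(u,v) = sqrt(mean_i (u_i/GFP(u) − v_i/GFP(v))²)` ∈ [0, 2], with
  `DISS² = 2(1 − r)` for the spatial Pearson correlation `r`;
- **TANOVA**: a paired randomization test on the per-timepoint DISS between
  condition grand-average topographies (subject-wise condition swaps);
- electrode-/timepoint-wise **paired t-tests** with the ≥5-adjacent-
  electrodes / ≥20 ms / α = 0.01 extent criterion;
- **microstate segmentation** by atomize-and-agglomerate hierarchical
  clustering (AAHC), with cross-validation and modified Krzanowski–Lai
  model-order selection, ≥20 ms temporal smoothing, and GEV accounting;
- **back-fitting** of the group templates to individual ERPs, yielding map
  duration (ms) and GEV per subject × condition × template, compared with
  Wilcoxon signed-rank tests;
- a **synthetic-study simulator** with planted microstate schedules,
  per-subject/trial latency jitter and spatially correlated noise, whose
  stimulus- and response-aligned epochs are cut from one continuous signal
  (so combination is exactly invertible).

## Worked example

The canonical overlap-removal arithmetic (stimulus epoch 500 ms, response
epoch 500 ms ending 100 ms before articulation):

```python
>>> import erptopo as et
>>> et.combined_window(850, et.CombineSpec(500, 500, 100))
CombinedWindow(resp_keep_start_ms=-350.0, resp_keep_end_ms=-100.0, removed_ms=250.0)
```

For an 850 ms latency, 250 ms of the response-aligned epoch duplicate the
stimulus-aligned epoch and are removed; the retained response window is
−350..−100 ms and the combined ERP covers 0–750 ms.

The headline windowing contrast (`python examples/05_backfit_windows.py`),
on a simulated 18-subject study where condition B lengthens microstate E by
40 ms (shifting map F and the RT equally):

```
fixed 300-500 ms window (stimulus-locked):
  map E (lengthened)  A  127.2 ms  B  162.0 ms  z = -3.71  p = 0.0002
  map F (following)   A   72.0 ms  B   37.2 ms  z = +3.71  p = 0.0002
combined window (300 ms to articulation-100):
  map E (lengthened)  A  125.2 ms  B  163.3 ms  z = -3.72  p = 0.0002
  map F (following)   A  155.1 ms  B  155.2 ms  z = -0.13  p = 0.8954
```

In the fixed window the *unchanged* map F appears 35 ms longer in condition
A — pure truncation artifact. Over the combined window F is identical across
conditions and only the planted E effect remains.

The `examples/` directory holds one short script per capability
(overlap removal, topographic measures, TANOVA, segmentation, back-fitting,
full pipeline); each prints the numbers it computes and what they mean.

## Command line

```bash
erptopo simulate --out data/ --seed 1 --subjects 12
erptopo combine --stim data/epochs --resp data/epochs --rts data/rts.tsv \
        --level group --out combined/
erptopo segment --epochs combined/ --qmin 1 --qmax 15 --out seg/
erptopo backfit --epochs subj_combined/ --templates seg/templates.tsv \
        --from-ms 300 --out fit/
erptopo run --config cfg.yaml --out run/     # whole pipeline, cached stages
```

All formats are plain text: epochs as TSV matrices with JSON sidecars,
montages as `label x y z` lines, RT tables and results as TSV.

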