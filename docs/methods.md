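# Methods

This note documents the models, conventions and numerical choices behind
`erptopo`, and what the simulator-based validation does and does not show.

## Topographic primitives

A scalp map is the vector of potentials across the montage at one instant.
All measures re-reference to the average across electrodes first, because
only the average-referenced field carries reference-free information.

- **GFP** uses the population normalisation
  `GFP(u) = sqrt((1/N) Σ (u_i − ū)²)` (the spatial standard deviation), the
  standard Lehmann–Skrandies definition, not the sample (1/(N−1)) variant.
- **DISS** is computed on GFP-normalised, average-referenced maps:
  `DISS = sqrt((1/N) Σ (u_i/GFP(u) − v_i/GFP(v))²)`. It is invariant to
  positive rescaling of either input and satisfies `DISS² = 2(1 − r)` with
  the spatial Pearson correlation `r` (tested to 1e-9).
- Flat maps (GFP < 1e-12 μV) raise `ZeroFieldError` rather than returning
  0 or NaN: silent NaN propagation corrupts clustering downstream.

## Epochs, montages, rejection

Epoch files are channels × samples TSV matrices with a JSON sidecar (fs,
alignment, t0, labels); units are fixed to μV and ms; sample k covers the
half-open interval starting at `t0 + k·1000/fs`. Stimulus-aligned epochs
start at 0, response-aligned epochs start at `−(Lr + off)` before
articulation. Montages are `label x y z` text; the adjacency graph is the
spherical Delaunay triangulation (convex hull of the positions projected on
the best-fit sphere), which is parameter-free; a distance-threshold graph is
available as an alternative. Artifact rejection keeps an epoch iff its peak
absolute amplitude is ≤ 100 μV (configurable); the criterion is applied to
the data as stored, i.e. after average re-referencing. Only trials with both
an uncontaminated stimulus- and response-aligned epoch survive pairing.

## Combination by production latency

With stimulus length S, response length Lr and articulation offset `off`
(defaults 500/500/100 ms), the response epoch natively spans
`[rt − Lr − off, rt − off]` in stimulus time. Overlap with `[0, S]` is
removed from the response-aligned side only:
`removed = clamp(S − (rt − Lr − off), 0, Lr)`. The splice is a hard
concatenation — removal, not blending — so any discontinuity stays visible
to downstream analyses by design. RTs are quantized to the nearest sample
(half away from zero); the RT and the offset are quantized independently, so
a combined epoch's length can differ from `round((rt − off)·fs/1000)` by at
most one sample. For `rt − off ≤ S` the combined ERP is the truncated
stimulus epoch (flagged `stim_only`); for `rt > S + Lr + off` the epochs do
not touch and the call fails unless a gap-marked (NaN + mask) output is
explicitly requested. Group-level application averages subject epochs per
condition and combines at the condition mean of the subject mean RTs.

## Pointwise statistics

Waveform comparisons are two-sided paired t-tests per electrode and sample.
Zero-variance points get t = 0, p = 1 with a warning. The extent criterion
retains a timepoint only if its sub-threshold electrodes contain a connected
component of ≥ 5 electrodes in the montage adjacency graph ("adjacent" =
graph-connected, since scalp adjacency is otherwise undefined), and drops
surviving runs shorter than 20 ms; α defaults to 0.01. This is the fixed
heuristic of the analysis tradition, not a cluster-mass permutation
correction, and is deliberately kept so.

TANOVA tests, per timepoint, the DISS between the two condition
grand-average maps against a paired null obtained by swapping each subject's
condition assignment independently. With random sampling
`p = (#{DISS_perm ≥ DISS_obs} + 1)/(n_perm + 1)` (valid permutation p, floor
1/(n_perm+1)); whenever `2^n ≤ n_perm` the full 2^n enumeration (identity
included) is used instead and `p = #{≥}/2^n`. n_perm defaults to 5000.
Significant runs shorter than 20 ms are discarded from the significance
mask; p-values themselves are left untouched. Calibration is verified by
simulation: under the null the p < 0.05 rate stays inside the binomial 99%
interval (the exhaustive test's discreteness makes the true rate
`floor(0.05·2^n)/2^n`, e.g. 0.0498 at n = 10).

## Segmentation

AAHC starts from one cluster per (GFP-normalised) timepoint map and
repeatedly dissolves the cluster contributing least GEV, reassigning each
freed map to the remaining template with the highest **signed** spatial
correlation — the ERP convention (polarity matters); the polarity-invariant
variant used for spontaneous EEG is a flag. Templates are renormalised means
of their members' normalised maps; exact correlation ties go to the lowest
cluster index, making the procedure deterministic given input order. The
concatenated group-averaged combined ERPs of all conditions are clustered
jointly, giving one shared template set.

Model order is chosen from two curves recorded along the hierarchy
(default candidate range q ∈ [1, 15]):

- `CV(q) = σ̂²·((N−1)/(N−1−q))²`, with σ̂² the mean residual of predicting
  each raw map from its (L2-normalised) template; undefined for q ≥ N−1.
- the modified Krzanowski–Lai statistic on the within-cluster dispersion
  W(q) of the normalised maps: `DIFF(q) = (q−1)^{2/N} W(q−1) − q^{2/N} W(q)`,
  `KL(q) = |DIFF(q)|/|DIFF(q+1)|`, reported only where the curve is locally
  concave (`DIFF(q) > 0`, `DIFF(q+1) < DIFF(q)`), else 0.

The selected q is the KL maximum; when that q is not a local minimum of CV
the conflict is logged and KL wins. A flat dispersion curve (no admissible
KL peak) raises an error advising a manual q.

Temporal smoothing dissolves segments shorter than 20 ms (shortest first),
relabeling each timepoint to whichever *adjacent* segment's template
correlates better; it never crosses condition boundaries and terminates
because every dissolution strictly reduces the run count. A block consisting
of a single short segment is an acknowledged fixed point (logged, left
unchanged). With min duration d and sampling rate fs the retained minimum is
`ceil(d·fs/1000)` samples — 11 samples = 21.5 ms at 512 Hz.

GEV is `Σ_t (GFP_t · r_t)² / Σ_t GFP_t²` with `r_t` the correlation between
map t and its assigned template; per-template shares sum to the total.

## Back-fitting and condition comparisons

Each timepoint in an explicit fitting window is labeled with the candidate
template of highest signed correlation (ties to the lowest index); flat
timepoints stay unlabeled and are excluded from duration sums (logged). No
correlation floor is applied by default. Durations are label counts times
the sample period; per-template GEV uses the whole window's summed squared
GFP as denominator so the shares partition the window total.

Wilcoxon signed-rank comparisons drop zero differences, use the exact
distribution for n ≤ 25 (without ties in |d|) and the tie-corrected,
continuity-corrected normal approximation otherwise; the z statistic is
always reported from the normal approximation. Two-sided p values
throughout. The implementation is checked against full 2^n enumeration for
all n ≤ 10.

### The windowing artifact, precisely

If condition B lengthens one microstate by Δ and every later onset *and the
RT* shift by Δ (a pure serial shift), then relative to articulation the
post-shift layout is unchanged — a response-locked window cannot see the
shift at all. The truncation artifact therefore appears in a **fixed
stimulus-locked** window: the following map enters the window Δ later in B
and loses Δ of measured duration, spuriously appearing longer in condition
A. That is the contrast the package demonstrates (fixed 300–500 ms window
vs the combined window from 300 ms to articulation−100). A response-locked
fixed window shows the analogous artifact only when a *late* microstate also
differs between conditions (so the pre-articulation layout changes); that
design is expressible through `condition_effects` with a second entry, but
is not the default because the single-effect design isolates the mechanism.

## The simulator

Each trial is a continuous average-referenced signal
`u(t) = T_{k(t)} · g(t) + noise`: a schedule of unit-GFP template maps
(mutually decorrelated by Gram–Schmidt, pairwise |r| ≤ 0.5 by construction;
in practice ≈ 0) under a per-segment raised-cosine GFP envelope with a
positive floor (floor 1.5 μV, peak +3.0 μV), keeping zero-GFP points out of
the analysed window. Noise is spatially correlated Gaussian
(`cov = exp(−d²/2λ²)`, λ = 0.6 on the unit sphere), temporally white by
default with an AR(1) option, at 1 μV RMS by default. The default schedule
has eight maps of 80/90/100/80/100/150/90/68 ms (sum 758 ms), so the base
RT is 858 ms with the 100 ms articulation offset; subject speed is a
multiplicative factor (sd 0.09) clipped so subject mean RTs stay within
703–1096 ms, with additional trial-level jitter (sd 0.04). The default
condition effect lengthens the fifth map ("E") by 40 ms in condition B,
shifting all later onsets and the RT by 40 ms. Stimulus and response epochs
are cut from the same continuous signal, so combination reproduces it
exactly (a zero-error oracle used throughout the tests).

The simulator emulates piecewise-stable topographies, latency variability
and spatially structured noise; it does **not** emulate volume-conducted
dipolar sources, gradual map transitions, ocular/muscular artifacts or
rhythmic background activity. Passing tests therefore validate the
*analysis logic* (arithmetic, statistics, clustering behaviour, windowing
effects), not performance on any particular real recording.

## Problem sizes used in validation

The test suite and the acceptance script run scaled-down studies chosen as
the smallest sizes at which each property is stable: 16–32 electrodes,
4–18 subjects, 4–10 trials, 512 Hz. Model-order recovery uses a planted
5-map schedule (durations 160/150/160/150/138 ms) at 1 μV RMS noise over 20
seeds; TANOVA calibration uses 10 subjects with exhaustive (1024-swap)
permutations over 200 seeded null studies; the windowing contrast uses the
default 8-map design with 18 subjects. The smoothing contract is scanned
over 100 simulated group-averaged studies.

## Known limitations

- AAHC cost grows with the square of the number of timepoint maps; group-
  averaged desk-scale inputs (≤ a few thousand maps) are the intended scale.
- The extent filter reports maximal significant clusters but no corrected
  cluster-level p value (by design, matching the fixed-criterion tradition).
- Exact Wilcoxon p values require tie-free |differences|; ties fall back to
  the corrected normal approximation even for small n.
- Single-trial back-fitting works but the shipped comparisons operate on
  subject-level averages, the standard design.
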