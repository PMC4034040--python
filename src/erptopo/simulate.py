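"""Synthetic overt-production ERP study generator.

Generates multichannel single-trial ERPs with planted microstate structure:
each trial is a continuous average-referenced signal that passes through a
schedule of quasi-stable scalp topographies (one unit-GFP template per
segment) under a smooth positive GFP envelope, plus spatially correlated
Gaussian noise.  The stimulus-aligned and response-aligned epochs are cut
from the SAME continuous trial, so combining them reproduces the continuous
signal exactly — the ground truth for every downstream stage.

Production latency is tied to the schedule: articulation onset falls a fixed
offset after the last planned segment ends, so RT = sum of (jittered)
segment durations + offset.  A condition effect lengthens a chosen segment
and thereby shifts every later segment onset and the RT by the same amount —
the serial-shift structure whose analysis consequences the rest of the
package studies.

What this emulates: average-referenced 64–128 channel ERPs at ~512 Hz,
piecewise-stable topographies with component-like GFP morphology, per-subject
speed differences (subject mean RTs spread around 858 ms and clipped to
703–1096 ms) and trial-to-trial latency jitter.  What it does not: volume
conduction from realistic sources, ocular/muscular artifacts, gradual map
transitions, or temporally structured background rhythms (an AR(1) noise
option approximates the latter crudely).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .epochs import ErpEpoch, Montage, build_adjacency
from .topography import GFP_EPS

__all__ = [
    "SimulationDesign",
    "TrialSim",
    "StudyData",
    "make_montage",
    "make_templates",
    "simulate_trial",
    "simulate_study",
    "subject_averages",
    "truth_label_track",
]

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _round_smp(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions of the synthetic overt-naming experiment.

    The default schedule has eight templates whose durations sum to 758 ms,
    so the base production latency is 858 ms (articulation 100 ms after the
    last planned segment), matching a typical naming study; subject mean RTs
    are clipped to the 703–1096 ms range.  The default condition effect
    lengthens template 4 ("map E", the fifth map) by 40 ms in condition B.
    """

    n_electrodes: int = 64
    fs: float = 512.0
    durations_ms: tuple[float, ...] = (80.0, 90.0, 100.0, 80.0, 100.0, 150.0, 90.0, 68.0)
    stim_len_ms: float = 500.0
    resp_len_ms: float = 500.0
    resp_offset_ms: float = 100.0
    gfp_floor_uv: float = 1.5
    gfp_peak_uv: float = 3.0
    noise_rms_uv: float = 1.0
    spatial_corr_length: float = 0.6
    ar_coeff: float = 0.0
    n_subjects: int = 18
    n_trials: int = 12
    subject_scale_sd: float = 0.09
    trial_scale_sd: float = 0.04
    rt_clip_ms: tuple[float, float] = (703.0, 1096.0)
    conditions: tuple[str, ...] = ("A", "B")
    condition_effects: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {"B": {4: 40.0}}
    )

    def __post_init__(self):
        if self.n_electrodes < 8:
            raise ValueError("need at least 8 electrodes")
        if not all(d > 0 for d in self.durations_ms):
            raise ValueError("segment durations must be positive")
        if self.n_templates >= self.n_electrodes:
            raise ValueError("need fewer templates than electrodes")
        for cond, eff in self.condition_effects.items():
            if cond not in self.conditions:
                raise ValueError(f"effect on unknown condition {cond!r}")
            for k in eff:
                if not 0 <= k < self.n_templates:
                    raise ValueError(f"effect on unknown template {k}")

    @property
    def n_templates(self) -> int:
        return len(self.durations_ms)

    def condition_durations(self, condition: str) -> np.ndarray:
        d = np.array(self.durations_ms, dtype=float)
        for k, delta in self.condition_effects.get(condition, {}).items():
            d[k] += delta
        return d


def make_montage(n: int, seed: int = 0) -> Montage:
    """Quasi-uniform electrode layout on the upper hemisphere.

    A golden-angle (Fibonacci) spiral over z in (0.05, 0.95] with a small
    seeded jitter, re-projected to the unit sphere; adjacency is the
    spherical Delaunay graph.  Deterministic for a given (n, seed).
    """
    if n < 8:
        raise ValueError("need at least 8 electrodes")
    rng = np.random.default_rng(seed)
    i = np.arange(n)
    z = 0.95 - 0.90 * i / max(n - 1, 1)
    phi = i * GOLDEN_ANGLE
    r = np.sqrt(1.0 - z**2)
    pos = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    pos = pos + rng.normal(0, 0.01, pos.shape)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"E{k + 1:03d}" for k in range(n))
    return Montage(labels, pos, build_adjacency(pos))


def make_templates(
    q: int, montage: Montage, rng: np.random.Generator | int | None = None,
    max_corr: float = 0.5, max_retries: int = 50,
) -> np.ndarray:
    """Generate q average-referenced, unit-GFP, mutually decorrelated maps.

    Each map is a sum of three random spatial Gaussian blobs on the scalp
    (spatially smooth, dipole-like fields); successive maps are
    Gram–Schmidt-orthogonalized against the earlier ones, which guarantees
    pairwise |spatial correlation| ≤ ``max_corr`` by construction.  A nearly
    dependent draw is re-drawn up to ``max_retries`` times.
    """
    if q >= montage.n_electrodes:
        raise ValueError("need q < number of electrodes")
    rng = np.random.default_rng(rng)
    pos = montage.positions / np.linalg.norm(montage.positions, axis=1, keepdims=True)
    out = np.zeros((q, montage.n_electrodes))
    k = 0
    tries = 0
    while k < q:
        centers = rng.normal(size=(3, 3))
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        amps = rng.normal(size=3)
        d2 = ((pos[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        v = (amps * np.exp(-d2 / (2 * 0.8**2))).sum(axis=1)
        v = v - v.mean()
        for j in range(k):  # Gram–Schmidt against accepted maps
            v = v - (v @ out[j]) / (out[j] @ out[j]) * out[j]
        v = v - v.mean()
        g = np.sqrt(np.mean(v * v))
        if g < 1e-6:
            tries += 1
            if tries > max_retries:
                raise RuntimeError("could not draw decorrelated templates")
            continue
        out[k] = v / g  # unit GFP
        k += 1
        tries = 0
    return out


def _spatial_chol(montage: Montage, corr_length: float) -> np.ndarray:
    d2 = ((montage.positions[:, None] - montage.positions[None, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2 * corr_length**2)) + 1e-6 * np.eye(montage.n_electrodes)
    return np.linalg.cholesky(cov)


@dataclass
class TrialSim:
    """One simulated trial: the continuous signal and the two epoch cuts."""

    continuous: np.ndarray        # (n_channels, n_samples)
    t0_smp: int                   # sample index of continuous[:, 0] (<= 0)
    stim: ErpEpoch
    resp: ErpEpoch
    rt_ms: float                  # un-quantized latency (schedule end + offset)
    labels: np.ndarray            # ground-truth template per continuous sample (-1 pre-stimulus)


def simulate_trial(
    design: SimulationDesign,
    templates: np.ndarray,
    condition: str = "A",
    subject_scale: float = 1.0,
    rng: np.random.Generator | int | None = None,
    chol: np.ndarray | None = None,
    montage: Montage | None = None,
    subject_id: str | None = None,
    trial: int | None = None,
) -> TrialSim:
    """Simulate one trial and cut its stimulus-/response-aligned epochs.

    The schedule durations are scaled by ``subject_scale`` and a trial-level
    jitter, then the condition's Δduration effects are added; articulation
    follows the last segment by ``resp_offset_ms``, so the RT inherits every
    duration change.  Both epochs are cut from the same continuous signal.
    """
    rng = np.random.default_rng(rng)
    if chol is None:
        if montage is None:
            raise ValueError("pass either chol or montage for the noise model")
        chol = _spatial_chol(montage, design.spatial_corr_length)
    fs = design.fs
    trial_scale = max(float(rng.normal(1.0, design.trial_scale_sd)), 0.5)
    dur = design.condition_durations(condition) * subject_scale * trial_scale
    rt_ms = float(dur.sum() + design.resp_offset_ms)
    S_smp = _round_smp(design.stim_len_ms * fs / 1000.0)
    Lr_smp = _round_smp(design.resp_len_ms * fs / 1000.0)
    off_smp = _round_smp(design.resp_offset_ms * fs / 1000.0)
    rt_smp = _round_smp(rt_ms * fs / 1000.0)
    end_smp = rt_smp - off_smp  # end of the planned schedule, in samples
    if end_smp <= 0:
        raise ValueError("schedule shorter than the articulation offset")
    n_pre = max(0, Lr_smp + off_smp - rt_smp)
    n_main = max(S_smp, end_smp)
    n_total = n_pre + n_main

    bounds = np.concatenate([[0], np.cumsum(dur)])
    bounds_smp = np.minimum(
        np.array([_round_smp(b * fs / 1000.0) for b in bounds]), end_smp
    )
    bounds_smp[-1] = end_smp
    labels = np.full(n_total, -1)
    env = np.zeros(n_total)
    for k in range(design.n_templates):
        a, b = n_pre + bounds_smp[k], n_pre + bounds_smp[k + 1]
        if b <= a:
            continue
        labels[a:b] = k
        frac = (np.arange(b - a) + 0.5) / (b - a)
        env[a:b] = design.gfp_floor_uv + design.gfp_peak_uv * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * frac)
        )
    # fast trials: the stimulus epoch outlasts the schedule; the last map persists
    tail = n_pre + end_smp
    if tail < n_total:
        labels[tail:] = design.n_templates - 1
        env[tail:] = design.gfp_floor_uv

    signal = np.zeros((templates.shape[1], n_total))
    planned = labels >= 0
    signal[:, planned] = templates[labels[planned]].T * env[planned]
    noise = chol @ rng.standard_normal((templates.shape[1], n_total))
    if design.ar_coeff:
        rho = design.ar_coeff
        for t in range(1, n_total):
            noise[:, t] = rho * noise[:, t - 1] + np.sqrt(1 - rho**2) * noise[:, t]
    data = signal + design.noise_rms_uv * noise
    data = data - data.mean(axis=0, keepdims=True)  # average reference

    stim = ErpEpoch(
        data=data[:, n_pre:n_pre + S_smp], fs=fs, alignment="stimulus", t0_ms=0.0,
        subject_id=subject_id, condition=condition, trial=trial,
    )
    r0 = n_pre + rt_smp - Lr_smp - off_smp
    resp = ErpEpoch(
        data=data[:, r0:r0 + Lr_smp], fs=fs, alignment="response",
        t0_ms=-(Lr_smp + off_smp) * 1000.0 / fs,
        subject_id=subject_id, condition=condition, trial=trial,
    )
    return TrialSim(
        continuous=data, t0_smp=-n_pre, stim=stim, resp=resp,
        rt_ms=rt_ms, labels=labels,
    )


@dataclass
class StudyData:
    """A full simulated study: epochs, RT table and the ground truth."""

    design: SimulationDesign
    montage: Montage
    templates: np.ndarray
    stim_epochs: list[ErpEpoch]
    resp_epochs: list[ErpEpoch]
    rt_table: pd.DataFrame
    subject_scales: dict[str, float]
    truth_durations: pd.DataFrame  # subject_id, condition, template, duration_ms
    trials: list[TrialSim] | None = None


def simulate_study(design: SimulationDesign, seed: int = 0,
                   keep_trials: bool = False) -> StudyData:
    """Simulate the whole study deterministically from one seed."""
    rng = np.random.default_rng(seed)
    montage = make_montage(design.n_electrodes, seed=int(rng.integers(2**31)))
    templates = make_templates(design.n_templates, montage, rng)
    chol = _spatial_chol(montage, design.spatial_corr_length)
    base_sum = float(np.sum(design.durations_ms))
    max_eff = max(
        (sum(e.values()) for e in design.condition_effects.values()), default=0.0
    )
    s_lo = (design.rt_clip_ms[0] - design.resp_offset_ms) / base_sum
    s_hi = (design.rt_clip_ms[1] - design.resp_offset_ms - max_eff) / base_sum
    scales = np.clip(
        rng.normal(1.0, design.subject_scale_sd, design.n_subjects), s_lo, s_hi
    )
    stim_epochs, resp_epochs, rt_rows, truth_rows = [], [], [], []
    trials = [] if keep_trials else None
    subject_scales = {}
    for si in range(design.n_subjects):
        sid = f"S{si + 1:02d}"
        subject_scales[sid] = float(scales[si])
        for cond in design.conditions:
            dur = design.condition_durations(cond) * scales[si]
            for k, d in enumerate(dur):
                truth_rows.append(
                    {"subject_id": sid, "condition": cond, "template": k,
                     "duration_ms": float(d)}
                )
            for tr in range(design.n_trials):
                sim = simulate_trial(
                    design, templates, condition=cond,
                    subject_scale=scales[si], rng=rng, chol=chol,
                    subject_id=sid, trial=tr,
                )
                stim_epochs.append(sim.stim)
                resp_epochs.append(sim.resp)
                rt_rows.append(
                    {"subject_id": sid, "condition": cond, "trial": tr,
                     "rt_ms": sim.rt_ms, "valid": True}
                )
                if keep_trials:
                    trials.append(sim)
    return StudyData(
        design=design,
        montage=montage,
        templates=templates,
        stim_epochs=stim_epochs,
        resp_epochs=resp_epochs,
        rt_table=pd.DataFrame(rt_rows),
        subject_scales=subject_scales,
        truth_durations=pd.DataFrame(truth_rows),
        trials=trials,
    )


def subject_averages(study: StudyData) -> tuple[dict, dict]:
    """Per-(subject, condition) averaged stimulus/response epochs."""
    from .epochs import average_epochs

    stim_by: dict[tuple[str, str], list] = {}
    resp_by: dict[tuple[str, str], list] = {}
    for ep in study.stim_epochs:
        stim_by.setdefault((ep.subject_id, ep.condition), []).append(ep)
    for ep in study.resp_epochs:
        resp_by.setdefault((ep.subject_id, ep.condition), []).append(ep)
    return (
        {k: average_epochs(v) for k, v in stim_by.items()},
        {k: average_epochs(v) for k, v in resp_by.items()},
    )


def truth_label_track(
    study: StudyData, subject_id: str, condition: str
) -> np.ndarray:
    """Expected template per sample of the subject-condition combined window
    (stimulus onset to articulation − offset), from the planted schedule."""
    design = study.design
    dur = design.condition_durations(condition) * study.subject_scales[subject_id]
    fs = design.fs
    end_smp = _round_smp(float(dur.sum()) * fs / 1000.0)
    bounds_smp = np.minimum(
        [_round_smp(b * fs / 1000.0) for b in np.concatenate([[0], np.cumsum(dur)])],
        end_smp,
    )
    labels = np.zeros(end_smp, dtype=int)
    for k in range(design.n_templates):
        labels[bounds_smp[k]:bounds_smp[k + 1]] = k
    return labels
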