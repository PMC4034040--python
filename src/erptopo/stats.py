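"""Waveform and topographic statistics across conditions.

Two complementary tests of a paired two-condition ERP design:

* electrode-/timepoint-wise paired t-tests with a spatio-temporal extent
  criterion (a difference counts only if it covers a connected set of at
  least ``min_electrodes`` adjacent electrodes and lasts at least
  ``min_duration_ms``) — a fixed heuristic guarding against isolated
  false positives;
* TANOVA — a non-parametric randomization test on the global map
  dissimilarity (DISS) between the two condition grand-average topographies
  at each timepoint, permuting the within-subject condition assignment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .epochs import Montage
from .topography import GFP_EPS

__all__ = [
    "StatMatrix",
    "ExtentCriterion",
    "SignificantCluster",
    "TanovaResult",
    "pointwise_paired_ttest",
    "extent_filter",
    "significant_runs",
    "tanova",
]


@dataclass
class StatMatrix:
    """Electrode × timepoint t and p matrices from a paired comparison."""

    t: np.ndarray
    p: np.ndarray
    n_subjects: int
    fs: float
    t0_ms: float = 0.0

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.t.shape[1]) * 1000.0 / self.fs


@dataclass(frozen=True)
class ExtentCriterion:
    """Spatio-temporal extent criterion for retaining waveform differences."""

    min_electrodes: int = 5
    min_duration_ms: float = 20.0
    alpha: float = 0.01

    def __post_init__(self):
        if not (self.min_electrodes > 0 and self.min_duration_ms > 0
                and 0 < self.alpha < 1):
            raise ValueError("criterion fields must be strictly positive (alpha in (0,1))")


def _stack(epochs_or_arrays) -> np.ndarray:
    arrs = [getattr(e, "data", e) for e in epochs_or_arrays]
    out = np.stack([np.asarray(a, dtype=float) for a in arrs])
    if out.ndim != 3:
        raise ValueError("expected a stack of channels × samples matrices")
    return out


def pointwise_paired_ttest(cond_a, cond_b, fs: float = 1000.0,
                           t0_ms: float = 0.0) -> StatMatrix:
    """Two-sided paired t-test per electrode and sample across subjects.

    ``cond_a``/``cond_b`` are same-ordered per-subject epochs (or plain
    channels × samples arrays).  Zero-variance points (identical differences
    across subjects) are reported as t=0, p=1 with a warning.
    """
    A = _stack(cond_a)
    B = _stack(cond_b)
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    if A.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_rel(A, B, axis=0)
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance electrode/timepoints; p set to 1"
        )
        t = np.where(bad, 0.0, t)
        p = np.where(bad, 1.0, p)
    return StatMatrix(t=t, p=p, n_subjects=A.shape[0], fs=fs, t0_ms=t0_ms)


@dataclass
class SignificantCluster:
    """A retained spatio-temporal difference: a time run and the electrodes
    (union of qualifying connected components over the run)."""

    start_sample: int
    end_sample: int  # exclusive
    electrodes: tuple[int, ...]
    start_ms: float = 0.0
    end_ms: float = 0.0

    @property
    def duration_samples(self) -> int:
        return self.end_sample - self.start_sample


def _components(sig_idx: np.ndarray, nbrs: list[list[int]]) -> list[list[int]]:
    sig = set(int(i) for i in sig_idx)
    seen: set[int] = set()
    comps = []
    for start in sorted(sig):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            u = queue.pop()
            for v in nbrs[u]:
                if v in sig and v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return comps


def extent_filter(stat: StatMatrix, montage: Montage,
                  crit: ExtentCriterion = ExtentCriterion()) -> list[SignificantCluster]:
    """Apply the adjacency/duration extent criterion to a t-test matrix.

    A timepoint survives if its sub-threshold electrodes (p < alpha) contain
    a connected component of at least ``min_electrodes`` electrodes in the
    montage adjacency graph; runs of surviving timepoints shorter than
    ``min_duration_ms`` are dropped.  Returns the maximal surviving clusters.
    """
    if stat.p.shape[0] != montage.n_electrodes:
        raise ValueError("stat matrix and montage electrode counts differ")
    nbrs = montage.neighbor_lists()
    n_times = stat.p.shape[1]
    survives = np.zeros(n_times, dtype=bool)
    comps_at: list[list[list[int]]] = []
    for ti in range(n_times):
        sig_idx = np.flatnonzero(stat.p[:, ti] < crit.alpha)
        comps = [c for c in _components(sig_idx, nbrs) if len(c) >= crit.min_electrodes]
        comps_at.append(comps)
        survives[ti] = bool(comps)
    dt = 1000.0 / stat.fs
    clusters: list[SignificantCluster] = []
    for start, end in _runs_of(survives):
        if (end - start) * dt < crit.min_duration_ms:
            continue
        elec = sorted({e for ti in range(start, end) for c in comps_at[ti] for e in c})
        clusters.append(
            SignificantCluster(
                start_sample=start,
                end_sample=end,
                electrodes=tuple(elec),
                start_ms=stat.t0_ms + start * dt,
                end_ms=stat.t0_ms + end * dt,
            )
        )
    return clusters


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean vector."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


# ---------------------------------------------------------------------------
# TANOVA


@dataclass
class TanovaResult:
    """Per-timepoint DISS randomization test results."""

    observed_diss: np.ndarray
    p: np.ndarray                       # NaN where the statistic is undefined
    significant: np.ndarray             # p < alpha after the duration run filter
    n_perm: int                         # permutations used (2**n for exhaustive)
    exhaustive: bool
    alpha: float
    undefined: np.ndarray = field(default=None)  # zero-GFP grand-average timepoints

    @property
    def min_p(self) -> float:
        return float(np.nanmin(self.p))


def _norm_rows(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average-reference rows and return (unit-GFP rows, gfp per row)."""
    M = M - M.mean(axis=-1, keepdims=True)
    g = np.sqrt(np.mean(M * M, axis=-1))
    return M, g


def tanova(
    cond_a,
    cond_b,
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 0.05,
    min_duration_ms: float = 20.0,
    fs: float = 1000.0,
    exhaustive: bool | None = None,
) -> TanovaResult:
    """Topographic randomization test (TANOVA) between two paired conditions.

    ``cond_a``/``cond_b`` are same-ordered per-subject epochs or
    (n_subjects, n_channels, n_times) arrays.  At each timepoint the observed
    statistic is the DISS between the two condition grand-average maps; the
    null is built by independently swapping each subject's condition
    assignment, re-averaging and recomputing DISS.  With random permutations
    ``p = (#{DISS_perm >= DISS_obs} + 1) / (n_perm + 1)``; with exhaustive
    enumeration of all 2**n assignments (chosen automatically whenever
    ``2**n <= n_perm``) the identity is included and ``p = #{>=} / 2**n``.

    Significant runs shorter than ``min_duration_ms`` are discarded from the
    ``significant`` mask (the p values themselves are untouched).  Timepoints
    where a grand average is flat (zero GFP) get ``p = NaN`` and are flagged.
    """
    A = _stack(cond_a)
    B = _stack(cond_b)
    if A.shape != B.shape:
        raise ValueError(f"condition shapes differ: {A.shape} vs {B.shape}")
    n_subj, n_ch, n_times = A.shape
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if exhaustive is None:
        exhaustive = 2**n_subj <= n_perm
    rng = np.random.default_rng(rng)

    if exhaustive:
        S = np.array(list(itertools.product((0.0, 1.0), repeat=n_subj)))
        n_used = S.shape[0]
    else:
        S = (rng.random((n_perm, n_subj)) < 0.5).astype(float)
        n_used = n_perm

    mean_a = A.mean(axis=0)  # (n_ch, n_times)
    mean_b = B.mean(axis=0)
    D = B - A  # swapping subject i moves d_i/n from B's mean into A's

    obs = np.full(n_times, np.nan)
    p = np.full(n_times, np.nan)
    undefined = np.zeros(n_times, dtype=bool)
    for ti in range(n_times):
        ma, ga = _norm_rows(mean_a[None, :, ti])
        mb, gb = _norm_rows(mean_b[None, :, ti])
        if ga[0] < GFP_EPS or gb[0] < GFP_EPS:
            undefined[ti] = True
            continue
        # permuted grand averages via the swap increment
        M = S @ D[:, :, ti] / n_subj                  # (P, n_ch)
        PA, g_pa = _norm_rows(mean_a[None, :, ti] + M)
        PB, g_pb = _norm_rows(mean_b[None, :, ti] - M)
        g_pa = np.maximum(g_pa, GFP_EPS)[:, None]
        g_pb = np.maximum(g_pb, GFP_EPS)[:, None]
        diss = np.sqrt(np.mean((PA / g_pa - PB / g_pb) ** 2, axis=1))
        d_obs = float(np.sqrt(np.mean((ma[0] / ga[0] - mb[0] / gb[0]) ** 2)))
        obs[ti] = d_obs
        count = int(np.sum(diss >= d_obs - 1e-12))
        p[ti] = count / n_used if exhaustive else (count + 1) / (n_used + 1)
    if undefined.any():
        warnings.warn(
            f"TANOVA undefined (flat grand average) at {int(undefined.sum())} timepoints"
        )
    sig = (p < alpha) & ~np.isnan(p)
    if min_duration_ms > 0:
        dt = 1000.0 / fs
        keep = np.zeros_like(sig)
        for start, end in _runs_of(sig):
            if (end - start) * dt >= min_duration_ms:
                keep[start:end] = True
        sig = keep
    return TanovaResult(
        observed_diss=obs,
        p=p,
        significant=sig,
        n_perm=n_used,
        exhaustive=exhaustive,
        alpha=alpha,
        undefined=undefined,
    )
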