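"""Spatio-temporal segmentation of group-averaged ERPs into microstates.

The segmentation compresses a sequence of scalp topographies into a small set
of template maps (microstates) and a label per timepoint, under the model
that the ERP passes through periods of quasi-stable field configuration.

Pipeline:

1. :func:`aahc` — atomize-and-agglomerate hierarchical clustering.  Every
   timepoint map starts as its own cluster; at each step the cluster
   contributing least global explained variance (GEV) is dissolved and its
   members reassigned to the remaining cluster whose template correlates
   best.  The full hierarchy over a candidate range of cluster counts q is
   recorded.
2. Model-order selection — the predictive-residual cross-validation
   criterion CV(q) and the modified Krzanowski–Lai elbow statistic KL(q) on
   the within-cluster dispersion curve W(q); :func:`select_q` combines them.
3. :func:`smooth_labels` — temporal smoothing that dissolves topographic
   segments shorter than a minimum duration (default 20 ms), relabeling
   their timepoints to the best-correlating adjacent segment.
4. :func:`gev` — global explained variance accounting.

Clustering is polarity-SENSITIVE by default (signed spatial correlation),
the ERP convention; the polarity-invariant variant used for spontaneous EEG
is available via ``polarity_sensitive=False``.  Maps enter the clustering
GFP-normalized, so only the field configuration (not its strength) drives
the templates; strength re-enters through the GFP weighting of GEV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .epochs import ErpEpoch
from .topography import GFP_EPS, ZeroFieldError

__all__ = [
    "Clustering",
    "SegmentationHierarchy",
    "SegmentationResult",
    "aahc",
    "cross_validation",
    "krzanowski_lai",
    "select_q",
    "smooth_labels",
    "gev",
    "segment",
]

logger = logging.getLogger(__name__)


def _prepare_maps(maps) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-reference rows; return (raw, unit-L2 rows, gfp)."""
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    if X.ndim != 2:
        raise ValueError("maps must be a (n_times, n_electrodes) matrix")
    X = X - X.mean(axis=1, keepdims=True)
    g = np.sqrt(np.mean(X * X, axis=1))
    if np.any(g < GFP_EPS):
        bad = np.flatnonzero(g < GFP_EPS)
        raise ZeroFieldError(
            f"flat (zero-GFP) maps at timepoints {bad[:5].tolist()}…; "
            "segmentation input must have nonzero GFP everywhere"
        )
    N = X.shape[1]
    Y = X / (g[:, None] * np.sqrt(N))  # unit L2 rows: y·y == 1
    return X, Y, g


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-300 else v


@dataclass
class Clustering:
    """One level of the AAHC hierarchy (labels use 0..q-1)."""

    q: int
    labels: np.ndarray
    templates: np.ndarray  # (q, n_electrodes), unit GFP, average-referenced
    W: float               # within-cluster dispersion of the normalized maps
    cv: float              # cross-validation criterion (NaN if q >= N-1)
    gev_total: float


@dataclass
class SegmentationHierarchy:
    """AAHC clusterings for every candidate q, plus the criterion curves."""

    levels: dict[int, Clustering]

    @property
    def qs(self) -> np.ndarray:
        return np.array(sorted(self.levels))

    def curve(self, name: str) -> np.ndarray:
        return np.array([getattr(self.levels[q], name) for q in self.qs])


def aahc(
    maps,
    q_min: int = 1,
    q_max: int = 15,
    polarity_sensitive: bool = True,
) -> SegmentationHierarchy:
    """Atomize-and-agglomerate hierarchical clustering of topographic maps.

    ``maps`` is (n_times, n_electrodes).  Returns the hierarchy with labels,
    unit-GFP templates, W(q), CV(q) and total GEV recorded at every
    q in [q_min, min(q_max, n_times)].

    At each step the cluster with the smallest GEV contribution
    ``sum((gfp_t * corr(u_t, T_k))**2)`` is dissolved; each freed map joins
    the remaining cluster whose template correlates best (signed correlation
    by default; ties break to the lowest cluster index), and the templates of
    receiving clusters are recomputed as the renormalized mean of their
    members' normalized maps.
    """
    X, Y, g = _prepare_maps(maps)
    T, N = Y.shape
    if q_min < 1:
        raise ValueError("q_min must be >= 1")
    if T < q_min:
        raise ValueError(f"only {T} maps but q_min={q_min}")
    q_max = min(q_max, T)
    if q_max < q_min:
        raise ValueError("empty candidate range after clipping q_max")

    g2_total = float(np.sum(g * g))
    labels = np.arange(T)
    tmpl = Y.copy()  # row c is the (unit-L2) template of cluster id c
    active: list[int] = list(range(T))
    levels: dict[int, Clustering] = {}

    def _corr_with_own() -> np.ndarray:
        c = np.einsum("tn,tn->t", Y, tmpl[labels])
        return c if polarity_sensitive else np.abs(c)

    def _snapshot(n: int) -> None:
        act = np.array(active)
        remap = {cid: i for i, cid in enumerate(act)}
        lab = np.array([remap[c] for c in labels])
        corr = _corr_with_own()
        Wq = float(np.sum(2.0 * N * (1.0 - corr)))
        gev_q = float(np.sum((g * corr) ** 2) / g2_total)
        cv_q = cross_validation(lab, tmpl[act] * np.sqrt(N), X, N)
        levels[n] = Clustering(
            q=n,
            labels=lab,
            templates=tmpl[act].copy() * np.sqrt(N),  # unit GFP
            W=Wq,
            cv=cv_q,
            gev_total=gev_q,
        )

    while True:
        n = len(active)
        if q_min <= n <= q_max:
            _snapshot(n)
        if n == q_min:
            break
        corr = _corr_with_own()
        contrib = np.bincount(labels, weights=(g * corr) ** 2, minlength=T)
        act = np.array(active)
        k = int(act[np.argmin(contrib[act])])
        members = np.flatnonzero(labels == k)
        active.remove(k)
        act = np.array(active)
        C = Y[members] @ tmpl[act].T
        if not polarity_sensitive:
            C = np.abs(C)
        new = act[np.argmax(C, axis=1)]
        labels[members] = new
        for c in np.unique(new):
            mem = np.flatnonzero(labels == c)
            if polarity_sensitive:
                t = Y[mem].sum(axis=0)
            else:
                s = np.sign(Y[mem] @ tmpl[c])
                s[s == 0] = 1.0
                t = (s[:, None] * Y[mem]).sum(axis=0)
            norm = np.linalg.norm(t)
            # opposite-polarity members can cancel; fall back to the first member
            tmpl[c] = t / norm if norm > 1e-12 else Y[mem[0]]
    return SegmentationHierarchy(levels)


def cross_validation(labels, templates, maps, n_electrodes: int) -> float:
    """Predictive-residual cross-validation criterion CV(q).

    ``CV(q) = sigma2 * ((N-1)/(N-1-q))**2`` with
    ``sigma2 = sum_t [u_t·u_t - (t_hat_{L(t)}·u_t)**2] / (T * (N-1))``,
    where ``u_t`` are the raw average-referenced maps and ``t_hat`` the
    L2-normalized templates.  Undefined (NaN) for ``q >= N - 1``.
    """
    labels = np.asarray(labels)
    X = np.atleast_2d(np.asarray(maps, dtype=float))
    X = X - X.mean(axis=1, keepdims=True)
    Tq = np.atleast_2d(np.asarray(templates, dtype=float))
    q = Tq.shape[0]
    N = n_electrodes
    if q >= N - 1:
        return float("nan")
    That = Tq / np.linalg.norm(Tq, axis=1, keepdims=True)
    proj = np.einsum("tn,tn->t", X, That[labels])
    resid = max(np.sum(X * X) - np.sum(proj**2), 0.0)  # round-off guard
    sigma2 = resid / (X.shape[0] * (N - 1))
    return float(sigma2 * ((N - 1) / (N - 1 - q)) ** 2)


def krzanowski_lai(qs, W, n_electrodes: int) -> np.ndarray:
    """Modified Krzanowski–Lai elbow statistic on the dispersion curve W(q).

    ``DIFF(q) = (q-1)**(2/N) * W(q-1) - q**(2/N) * W(q)`` and
    ``KL(q) = |DIFF(q)| / |DIFF(q+1)|``, reported only where the curve is
    locally concave (``DIFF(q) > 0`` and ``DIFF(q+1) < DIFF(q)``), else 0.
    Boundary q without both neighbours are NaN.
    """
    qs = np.asarray(qs)
    W = np.asarray(W, dtype=float)
    if np.any(np.diff(qs) != 1):
        raise ValueError("qs must be consecutive integers")
    N = n_electrodes
    diff = np.full(len(qs), np.nan)
    for i, q in enumerate(qs):
        if i == 0 or q < 2:
            continue
        diff[i] = (q - 1) ** (2.0 / N) * W[i - 1] - q ** (2.0 / N) * W[i]
    kl = np.full(len(qs), np.nan)
    for i in range(len(qs)):
        if i + 1 >= len(qs) or np.isnan(diff[i]) or np.isnan(diff[i + 1]):
            continue
        if diff[i] > 0 and diff[i + 1] < diff[i]:
            with np.errstate(divide="ignore"):
                kl[i] = np.abs(diff[i]) / np.abs(diff[i + 1]) if diff[i + 1] != 0 else np.inf
        else:
            kl[i] = 0.0
    return kl


def select_q(qs, cv_curve, kl_curve) -> int:
    """Pick the cluster count from the CV and KL curves.

    Preferred answer: the q at the KL maximum among the local minima of the
    CV curve.  If the global KL maximum is not a CV local minimum the two
    criteria disagree; KL wins and the conflict is logged.
    """
    qs = np.asarray(qs)
    cv = np.asarray(cv_curve, dtype=float)
    kl = np.asarray(kl_curve, dtype=float)
    finite_kl = np.where(np.isnan(kl), -np.inf, kl)
    if not np.any(finite_kl > 0):
        raise ValueError(
            "no admissible KL peak (flat dispersion curve); choose q manually"
        )
    kl_best = int(np.argmax(finite_kl))
    # interior local minima of CV (NaNs never qualify)
    minima = []
    for i in range(1, len(qs) - 1):
        trio = cv[i - 1:i + 2]
        if np.any(np.isnan(trio)):
            continue
        if cv[i] <= cv[i - 1] and cv[i] <= cv[i + 1]:
            minima.append(i)
    if minima:
        in_minima = [i for i in minima if finite_kl[i] == finite_kl[kl_best]]
        if not in_minima and kl_best not in minima:
            logger.info(
                "CV local minima at q=%s disagree with KL peak at q=%d; KL wins",
                qs[np.array(minima)].tolist(), qs[kl_best],
            )
    return int(qs[kl_best])


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, label) runs, end exclusive."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, int(labels[start])))
            start = i
    return out


def smooth_labels(
    labels,
    maps,
    templates,
    min_duration_ms: float = 20.0,
    fs: float = 512.0,
    boundaries: Sequence[int] = (0,),
) -> np.ndarray:
    """Dissolve topographic segments shorter than ``min_duration_ms``.

    Iteratively takes the shortest sub-threshold segment and relabels each of
    its timepoints to whichever adjacent segment's template correlates better
    with that timepoint's map (signed correlation; ties go to the lower
    template index, and to the left neighbour on exact ties of labels).
    Smoothing never crosses the condition ``boundaries`` (start indices of
    the concatenated blocks).  Stops when every segment satisfies the
    criterion or when nothing can change (a single segment left in a block
    shorter than the criterion), which is logged.
    """
    labels = np.asarray(labels).copy()
    X, Y, _ = _prepare_maps(maps)
    Tq = np.atleast_2d(np.asarray(templates, dtype=float))
    That = Tq - Tq.mean(axis=1, keepdims=True)
    That = That / np.linalg.norm(That, axis=1, keepdims=True)
    dt = 1000.0 / fs
    min_samples = int(np.ceil(min_duration_ms / dt - 1e-9))
    blocks = list(boundaries) + [len(labels)]
    for b0, b1 in zip(blocks[:-1], blocks[1:]):
        while True:
            runs = _runs(labels[b0:b1])
            short = [r for r in runs if (r[1] - r[0]) < min_samples]
            if not short:
                break
            if len(runs) == 1:
                logger.info(
                    "block [%d,%d) is a single %d-sample segment below the "
                    "%d-sample criterion; left unchanged", b0, b1,
                    runs[0][1] - runs[0][0], min_samples,
                )
                break
            start, end, _ = min(short, key=lambda r: (r[1] - r[0], r[0]))
            idx = runs.index((start, end, _))
            cand = []
            if idx > 0:
                cand.append(runs[idx - 1][2])
            if idx + 1 < len(runs):
                cand.append(runs[idx + 1][2])
            cand_t = That[cand]  # (1 or 2, N)
            seg = Y[b0 + start:b0 + end]
            corr = seg @ cand_t.T
            # ties: argmax takes the first candidate (the left neighbour)
            pick = np.argmax(corr, axis=1)
            labels[b0 + start:b0 + end] = np.array(cand)[pick]
    return labels


def gev(maps, templates, labels) -> tuple[float, np.ndarray]:
    """Global explained variance of a labeled map sequence.

    ``GEV = sum_t (gfp_t * corr(u_t, T_{L(t)}))**2 / sum_t gfp_t**2``;
    returns the total and the per-template split (which sums to the total).
    Timepoints labeled ``-1`` (unlabeled) contribute to the denominator only.
    """
    labels = np.asarray(labels)
    X, Y, g = _prepare_maps(maps)
    Tq = np.atleast_2d(np.asarray(templates, dtype=float))
    That = Tq - Tq.mean(axis=1, keepdims=True)
    That = That / np.linalg.norm(That, axis=1, keepdims=True)
    denom = float(np.sum(g * g))
    if denom <= 0:
        raise ZeroFieldError("all-zero GFP stream")
    per = np.zeros(Tq.shape[0])
    valid = labels >= 0
    if valid.any():
        corr = np.einsum("tn,tn->t", Y[valid], That[labels[valid]])
        num = (g[valid] * corr) ** 2
        per = np.bincount(labels[valid], weights=num, minlength=Tq.shape[0]) / denom
    return float(per.sum()), per


@dataclass
class SegmentationResult:
    """Templates, labels and model-selection curves of one segmentation."""

    templates: np.ndarray            # (q, n_electrodes), unit GFP
    labels: np.ndarray               # concatenated, template index per timepoint
    conditions: tuple[str, ...]
    boundaries: tuple[int, ...]      # start index of each condition block
    fs: float
    qs: np.ndarray
    W: np.ndarray
    cv: np.ndarray
    kl: np.ndarray
    q_selected: int
    gev_total: float
    gev_per_template: np.ndarray
    hierarchy: SegmentationHierarchy

    def labels_for(self, condition: str) -> np.ndarray:
        i = self.conditions.index(condition)
        blocks = list(self.boundaries) + [len(self.labels)]
        return self.labels[blocks[i]:blocks[i + 1]]

    def segment_durations_ms(self) -> list[tuple[str, int, float]]:
        """(condition, template, duration_ms) for every labeled segment."""
        out = []
        blocks = list(self.boundaries) + [len(self.labels)]
        for cond, b0, b1 in zip(self.conditions, blocks[:-1], blocks[1:]):
            for s, e, lab in _runs(self.labels[b0:b1]):
                out.append((cond, lab, (e - s) * 1000.0 / self.fs))
        return out


def segment(
    condition_epochs: Mapping[str, ErpEpoch] | Mapping[str, np.ndarray],
    q_min: int = 1,
    q_max: int = 15,
    q: int | None = None,
    min_duration_ms: float = 20.0,
    polarity_sensitive: bool = True,
    fs: float | None = None,
) -> SegmentationResult:
    """Segment the concatenated group-averaged ERPs of all conditions.

    ``condition_epochs`` maps condition name to its group-averaged (usually
    combined) :class:`~erptopo.epochs.ErpEpoch` or a channels × samples
    array.  All conditions are clustered jointly so a single template set
    describes the whole design; labels never smooth across condition
    boundaries.  ``q`` forces the cluster count, otherwise CV/KL selection
    over ``[q_min, q_max]`` is used.
    """
    names = tuple(condition_epochs)
    blocks = []
    boundaries = []
    pos = 0
    for name in names:
        ep = condition_epochs[name]
        data = ep.data if isinstance(ep, ErpEpoch) else np.asarray(ep, dtype=float)
        if isinstance(ep, ErpEpoch):
            if fs is None:
                fs = ep.fs
            elif ep.fs != fs:
                raise ValueError("conditions have different sampling rates")
        boundaries.append(pos)
        blocks.append(data.T)  # (samples, channels)
        pos += data.shape[1]
    if fs is None:
        raise ValueError("fs must be given when passing plain arrays")
    maps = np.vstack(blocks)
    hierarchy = aahc(maps, q_min=q_min, q_max=q_max,
                     polarity_sensitive=polarity_sensitive)
    qs = hierarchy.qs
    W = hierarchy.curve("W")
    cv = hierarchy.curve("cv")
    kl = krzanowski_lai(qs, W, maps.shape[1])
    if q is None:
        q_sel = select_q(qs, cv, kl)
    else:
        if q not in hierarchy.levels:
            raise ValueError(f"q={q} not in the recorded range {qs.tolist()}")
        q_sel = int(q)
    level = hierarchy.levels[q_sel]
    labels = smooth_labels(
        level.labels, maps, level.templates,
        min_duration_ms=min_duration_ms, fs=fs, boundaries=boundaries,
    )
    total, per = gev(maps, level.templates, labels)
    return SegmentationResult(
        templates=level.templates,
        labels=labels,
        conditions=names,
        boundaries=tuple(boundaries),
        fs=fs,
        qs=qs,
        W=W,
        cv=cv,
        kl=kl,
        q_selected=q_sel,
        gev_total=total,
        gev_per_template=per,
        hierarchy=hierarchy,
    )
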