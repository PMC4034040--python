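"""Back-fitting of group-level template maps to individual ERPs.

Each timepoint of an individual (usually combined) ERP is labeled with the
candidate template it correlates with best spatially (signed correlation,
ties to the lowest template index).  Per subject, condition and template this
yields the map's presence in milliseconds (duration) and its share of the
global explained variance (GEV) — the quantities compared across conditions
with Wilcoxon signed-rank tests.

The fitting window is an explicit parameter.  A fixed window (stimulus- or
response-locked) truncates maps that shift between conditions and can turn a
shifted-but-equal-duration map into a spurious duration difference; fitting
over the full combined window (stimulus onset to a fixed offset before
articulation) removes that artifact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .combine import CombinedErp
from .epochs import ErpEpoch
from .topography import GFP_EPS

__all__ = [
    "fit_templates",
    "map_metrics",
    "backfit_study",
    "wilcoxon_signed_rank",
    "compare_conditions",
]


def _window_slice(epoch: ErpEpoch, window_ms: tuple[float, float]) -> slice:
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError("window end must exceed its start")
    dt = epoch.dt_ms
    first = int(np.ceil((lo - epoch.t0_ms) / dt - 1e-9))
    last = int(np.floor((hi - epoch.t0_ms) / dt + 1e-9))  # exclusive
    first = max(first, 0)
    last = min(last, epoch.n_samples)
    if last <= first:
        raise ValueError(
            f"window {window_ms} ms does not intersect the epoch "
            f"[{epoch.t0_ms}, {epoch.t0_ms + epoch.duration_ms}) ms"
        )
    return slice(first, last)


def fit_templates(
    erp: ErpEpoch | CombinedErp,
    templates: np.ndarray,
    window_ms: tuple[float, float] | None = None,
    candidates: list[int] | None = None,
) -> tuple[np.ndarray, slice]:
    """Label each timepoint with its best spatially correlating template.

    ``templates`` is (q, n_electrodes); ``candidates`` restricts the fit to a
    subset of template indices (e.g. only the late maps); labels are always
    expressed in the full template numbering.  Flat (zero-GFP) timepoints get
    label ``-1`` and are excluded from metrics.  Returns the label track and
    the sample slice of the fitted window.
    """
    epoch = erp.epoch if isinstance(erp, CombinedErp) else erp
    sl = _window_slice(epoch, window_ms) if window_ms is not None else slice(0, epoch.n_samples)
    X = epoch.data.T[sl]  # (t, n)
    X = X - X.mean(axis=1, keepdims=True)
    g = np.sqrt(np.mean(X * X, axis=1))
    Tq = np.atleast_2d(np.asarray(templates, dtype=float))
    idx = np.arange(Tq.shape[0]) if candidates is None else np.asarray(candidates, int)
    That = Tq[idx] - Tq[idx].mean(axis=1, keepdims=True)
    That = That / np.linalg.norm(That, axis=1, keepdims=True)
    labels = np.full(X.shape[0], -1)
    ok = g >= GFP_EPS
    if ok.any():
        Y = X[ok] / np.linalg.norm(X[ok], axis=1, keepdims=True)
        corr = Y @ That.T
        labels[ok] = idx[np.argmax(corr, axis=1)]  # first max → lowest index on ties
    return labels, sl


def map_metrics(
    labels: np.ndarray,
    erp: ErpEpoch | CombinedErp,
    templates: np.ndarray,
    window_slice: slice,
) -> pd.DataFrame:
    """Per-template presence (ms) and GEV share inside the fitted window.

    Duration is ``count(label) * 1000 / fs``; the GEV denominator is the
    summed squared GFP of the whole window, so the per-template GEV fractions
    sum to the window's total GEV.  Unlabeled (flat) timepoints count in the
    denominator but belong to no template.
    """
    epoch = erp.epoch if isinstance(erp, CombinedErp) else erp
    X = epoch.data.T[window_slice]
    X = X - X.mean(axis=1, keepdims=True)
    g = np.sqrt(np.mean(X * X, axis=1))
    Tq = np.atleast_2d(np.asarray(templates, dtype=float))
    That = Tq - Tq.mean(axis=1, keepdims=True)
    That = That / np.linalg.norm(That, axis=1, keepdims=True)
    denom = float(np.sum(g * g))
    labels = np.asarray(labels)
    n_unlabeled = int(np.sum(labels < 0))
    if n_unlabeled:
        warnings.warn(f"{n_unlabeled} flat timepoints excluded from durations")
    rows = []
    for k in range(Tq.shape[0]):
        pts = labels == k
        dur = float(pts.sum()) * 1000.0 / epoch.fs
        if pts.any() and denom > 0:
            Xn = X[pts] / np.maximum(
                np.linalg.norm(X[pts], axis=1, keepdims=True), 1e-300
            )
            corr = Xn @ That[k]
            gev_k = float(np.sum((g[pts] * corr) ** 2) / denom)
        else:
            gev_k = 0.0
        rows.append({"template": k, "duration_ms": dur, "gev": gev_k})
    return pd.DataFrame(rows)


def backfit_study(
    erps_by: dict,
    templates: np.ndarray,
    window_ms,
    candidates: list[int] | None = None,
) -> pd.DataFrame:
    """Back-fit templates to every subject-condition ERP.

    ``erps_by`` maps ``(subject_id, condition)`` to an :class:`ErpEpoch` or
    :class:`CombinedErp`.  ``window_ms`` is either one (lo, hi) pair for all,
    or a callable ``(key, erp) -> (lo, hi)`` for RT-dependent windows (e.g.
    300 ms to articulation−100).  Returns a tidy table with columns
    subject_id, condition, template, duration_ms, gev.
    """
    rows = []
    for key in sorted(erps_by, key=lambda k: tuple(map(str, k))):
        erp = erps_by[key]
        win = window_ms(key, erp) if callable(window_ms) else window_ms
        labels, sl = fit_templates(erp, templates, win, candidates)
        m = map_metrics(labels, erp, templates, sl)
        m.insert(0, "subject_id", key[0])
        m.insert(1, "condition", key[1])
        rows.append(m)
    return pd.concat(rows, ignore_index=True)


def wilcoxon_signed_rank(x, y=None) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped.  The p-value uses the exact signed-rank
    distribution for n ≤ 25 without ties in |d| (scipy), otherwise the normal
    approximation with tie and continuity corrections.  The z statistic is
    always reported from the (tie-corrected, continuity-corrected) normal
    approximation, signed so that ranks favouring ``x > y`` give positive z.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1")
        return {"n": 0, "w": 0.0, "z": 0.0, "p": 1.0}
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
    if var <= 0:
        warnings.warn("degenerate rank variance; p = 1")
        return {"n": n, "w": w_pos, "z": 0.0, "p": 1.0}
    dev = w_pos - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    has_ties = np.any(ties > 1)
    if n <= 25 and not has_ties:
        p = float(sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {"n": n, "w": w_pos, "z": float(z), "p": min(p, 1.0)}


def compare_conditions(
    metrics: pd.DataFrame,
    measure: str = "duration_ms",
    cond_a: str | None = None,
    cond_b: str | None = None,
    templates: list[int] | None = None,
) -> pd.DataFrame:
    """Per-template paired Wilcoxon comparison of two conditions.

    ``metrics`` is the tidy table from :func:`backfit_study`.  Pairs subjects
    across the two conditions (defaults: the two conditions present) and
    tests ``measure`` per template (``templates`` restricts which).
    Requires n ≥ 5 subjects.
    """
    conds = sorted(metrics["condition"].unique())
    if cond_a is None or cond_b is None:
        if len(conds) != 2:
            raise ValueError(f"specify cond_a/cond_b among {conds}")
        cond_a, cond_b = conds
    wide = metrics.pivot_table(
        index=["subject_id", "template"], columns="condition", values=measure
    )
    rows = []
    which = sorted(metrics["template"].unique()) if templates is None else templates
    for k in which:
        sub = wide.xs(k, level="template").dropna(subset=[cond_a, cond_b])
        if len(sub) < 5:
            raise ValueError(f"template {k}: need >= 5 paired subjects, got {len(sub)}")
        res = wilcoxon_signed_rank(sub[cond_a].to_numpy(), sub[cond_b].to_numpy())
        rows.append({
            "template": k,
            "measure": measure,
            "n": res["n"],
            f"mean_{cond_a}": sub[cond_a].mean(),
            f"mean_{cond_b}": sub[cond_b].mean(),
            "z": res["z"],
            "p": res["p"],
        })
    return pd.DataFrame(rows)
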