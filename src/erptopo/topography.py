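"""Reference-free topographic primitives.

A scalp topography (one potential value per electrode at one instant) only
carries reference-independent information once it is re-referenced to the
average of all electrodes.  Every measure in this module therefore applies the
average reference internally before computing anything.

The measures are the classical ones of topographic ERP analysis:

* ``gfp`` — Global Field Power, the spatial standard deviation of the field;
  a reference-free measure of momentary response strength.
* ``spatial_correlation`` — Pearson correlation between two fields across
  electrodes; polarity-sensitive.
* ``dissimilarity`` — the global map dissimilarity (DISS), a strength-
  independent distance between two fields ranging from 0 (identical
  configuration) to 2 (polarity-inverted configuration).

DISS and the spatial correlation are linked by ``DISS**2 == 2 * (1 - r)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ZeroFieldError",
    "average_reference",
    "gfp",
    "spatial_correlation",
    "dissimilarity",
]

#: GFP below this (in μV) is treated as a flat, information-free field.
GFP_EPS = 1e-12


class ZeroFieldError(ValueError):
    """Raised when a topographic measure is undefined on a flat (zero-GFP) map."""


def _as_map(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"a topographic map must be 1-D, got shape {v.shape}")
    if v.size < 2:
        raise ValueError("a topographic map needs at least 2 electrodes")
    if not np.all(np.isfinite(v)):
        raise ValueError("topographic map contains non-finite values")
    return v


def average_reference(values) -> np.ndarray:
    """Re-reference a map to the mean across electrodes.

    Returns ``values - mean(values)``; the result has zero mean, which makes
    all downstream topographic measures reference-free.  Idempotent.
    """
    v = _as_map(values)
    return v - v.mean()


def gfp(values) -> float:
    """Global Field Power: spatial standard deviation of the field (μV).

    Uses the population (1/N) normalisation:
    ``sqrt(mean((u - mean(u))**2))``.  Always non-negative; scales linearly
    with the field (``gfp(c*u) == |c| * gfp(u)``).
    """
    v = average_reference(values)
    return float(np.sqrt(np.mean(v * v)))


def _normalized(values) -> np.ndarray:
    """Average-referenced map scaled to unit GFP; raises on flat maps."""
    v = average_reference(values)
    g = np.sqrt(np.mean(v * v))
    if g < GFP_EPS:
        raise ZeroFieldError("measure undefined on a flat (zero-GFP) map")
    return v / g


def spatial_correlation(u, v) -> float:
    """Signed Pearson correlation between two maps across electrodes.

    Polarity-sensitive: ``spatial_correlation(u, -u) == -1``.  Both maps are
    average-referenced first; a flat map raises :class:`ZeroFieldError`.
    """
    un = _normalized(u)
    vn = _normalized(v)
    if un.size != vn.size:
        raise ValueError("maps must share a montage (equal electrode counts)")
    return float(np.clip(np.mean(un * vn), -1.0, 1.0))


def dissimilarity(u, v) -> float:
    """Global map dissimilarity (DISS) between two fields, in [0, 2].

    ``sqrt(mean((u/gfp(u) - v/gfp(v))**2))`` on average-referenced maps.
    Invariant to positive rescaling of either input; 0 for identical
    configurations, 2 for a polarity inversion.
    """
    un = _normalized(u)
    vn = _normalized(v)
    if un.size != vn.size:
        raise ValueError("maps must share a montage (equal electrode counts)")
    d = un - vn
    return float(np.sqrt(np.mean(d * d)))
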