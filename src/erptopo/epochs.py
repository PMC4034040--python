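"""Data model and I/O for ERP epochs, electrode montages and reaction-time tables.

File formats are deliberately plain text:

* epochs — a delimited matrix (one channel per row, one sample per column)
  with a JSON metadata sidecar at ``<path>.json`` carrying sampling rate,
  alignment, time of the first sample, and labels;
* montages — ``label x y z`` per line (.sfp/.xyz style);
* reaction times — a delimited table ``subject_id, condition, trial, rt_ms``.

Units are fixed: potentials in μV, time in ms.  Sample ``k`` of an epoch
covers the half-open interval starting at ``t0_ms + k * 1000 / fs``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "ErpEpoch",
    "Montage",
    "read_epoch",
    "write_epoch",
    "read_montage",
    "write_montage",
    "build_adjacency",
    "read_rt_table",
    "write_rt_table",
    "reject_epochs",
    "pair_filter",
    "average_epochs",
    "EpochFormatError",
]

ALIGNMENTS = ("stimulus", "response", "combined")


class EpochFormatError(ValueError):
    """Malformed epoch/montage file or metadata inconsistent with the data."""


@dataclass
class ErpEpoch:
    """A channels × samples ERP matrix with its timing metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in μV.
    fs : float
        Sampling rate in Hz.
    alignment : {"stimulus", "response", "combined"}
        Time lock of the epoch.  Stimulus- and combined-aligned epochs start
        at the stimulus (``t0_ms == 0``); response-aligned epochs start
        before articulation onset (``t0_ms < 0``).
    t0_ms : float
        Time of the first sample relative to the lock event, in ms.
    """

    data: np.ndarray
    fs: float
    alignment: str
    t0_ms: float = 0.0
    subject_id: str | None = None
    condition: str | None = None
    trial: int | None = None
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2 or self.data.shape[1] < 1 or self.data.shape[0] < 2:
            raise EpochFormatError(
                f"epoch data must be (n_channels>=2, n_samples>=1), got {self.data.shape}"
            )
        if not self.fs > 0:
            raise EpochFormatError(f"sampling rate must be positive, got {self.fs}")
        if self.alignment not in ALIGNMENTS:
            raise EpochFormatError(
                f"alignment must be one of {ALIGNMENTS}, got {self.alignment!r}"
            )
        if self.alignment == "stimulus" and abs(self.t0_ms) > 1e-9:
            raise EpochFormatError("stimulus-aligned epochs must have t0_ms == 0")
        if self.alignment == "response" and not self.t0_ms < 0:
            raise EpochFormatError("response-aligned epochs must have t0_ms < 0")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise EpochFormatError("label count does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        """Start time of each sample relative to the lock event."""
        return self.t0_ms + np.arange(self.n_samples) * self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def key(self) -> tuple:
        """Trial identity used for pairing stimulus- and response-aligned epochs."""
        return (self.subject_id, self.condition, self.trial)

    def copy_with(self, **kw) -> "ErpEpoch":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Montage


@dataclass
class Montage:
    """Electrode labels, 3-D positions and a symmetric neighbour graph."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3)
    adjacency: frozenset = field(default=None)  # frozenset of (i, j) index pairs, i < j

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.positions):
            raise EpochFormatError("label/position count mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise EpochFormatError(f"duplicate electrode labels: {dupes}")
        if self.adjacency is None:
            self.adjacency = build_adjacency(self.positions)
        edges = set()
        for i, j in self.adjacency:
            if i == j:
                raise EpochFormatError("adjacency contains a self-edge")
            edges.add((min(i, j), max(i, j)))
        self.adjacency = frozenset(edges)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_electrodes)]
        for i, j in self.adjacency:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return [sorted(n) for n in nbrs]

    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbor_lists()])


def _fit_sphere(pos: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; falls back to centroid/RMS radius."""
    A = np.c_[2 * pos, np.ones(len(pos))]
    b = (pos**2).sum(axis=1)
    try:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        center = sol[:3]
        r2 = sol[3] + center @ center
        radius = np.sqrt(max(r2, 1e-12))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
        center = pos.mean(axis=0)
        radius = np.sqrt(((pos - center) ** 2).sum(axis=1).mean())
    return center, radius


def build_adjacency(
    positions,
    method: str = "delaunay",
    distance_threshold: float | None = None,
) -> frozenset:
    """Neighbour graph over electrode positions.

    ``method="delaunay"`` (default) projects the electrodes onto their
    best-fit sphere and takes the edges of the convex hull of the projected
    points — the spherical Delaunay triangulation, parameter-free and
    standard for scalp arrays.  ``method="distance"`` connects electrodes
    closer than ``distance_threshold`` (same units as the positions).
    """
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 electrodes")
    if method == "distance":
        if distance_threshold is None:
            raise ValueError("distance method requires distance_threshold")
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        ii, jj = np.where((d <= distance_threshold) & (d > 0))
        return frozenset((min(i, j), max(i, j)) for i, j in zip(ii, jj))
    if method != "delaunay":
        raise ValueError(f"unknown adjacency method {method!r}")
    if n <= 4:
        return frozenset((i, j) for i in range(n) for j in range(i + 1, n))
    center, _ = _fit_sphere(pos)
    v = pos - center
    norms = np.linalg.norm(v, axis=1)
    norms[norms < 1e-12] = 1.0
    proj = v / norms[:, None]
    try:
        hull = ConvexHull(proj)
    except QhullError:
        warnings.warn("degenerate electrode geometry; using complete graph")
        return frozenset((i, j) for i in range(n) for j in range(i + 1, n))
    edges = set()
    for simplex in hull.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(i, j), max(i, j)))
    return frozenset(edges)


def read_montage(path, adjacency_method: str = "delaunay",
                 distance_threshold: float | None = None) -> Montage:
    """Read a ``label x y z`` montage file (.sfp/.xyz style)."""
    labels: list[str] = []
    positions: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise EpochFormatError(
                f"{path}:{lineno}: expected 'label x y z', got {line!r}"
            )
        labels.append(parts[0])
        try:
            positions.append([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise EpochFormatError(f"{path}:{lineno}: bad coordinate") from exc
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise EpochFormatError(f"{path}: duplicate electrode labels: {dupes}")
    pos = np.asarray(positions)
    adjacency = build_adjacency(pos, method=adjacency_method,
                                distance_threshold=distance_threshold)
    return Montage(tuple(labels), pos, adjacency)


def write_montage(montage: Montage, path) -> None:
    lines = [
        f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
        for lab, (x, y, z) in zip(montage.labels, montage.positions)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Epoch I/O


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".json")


def write_epoch(epoch: ErpEpoch, path) -> None:
    """Write the data matrix as TSV (one channel per row) plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, epoch.data, delimiter="\t", fmt="%.17g")
    meta = {
        "fs": epoch.fs,
        "alignment": epoch.alignment,
        "t0_ms": epoch.t0_ms,
        "n_channels": epoch.n_channels,
        "n_samples": epoch.n_samples,
        "subject_id": epoch.subject_id,
        "condition": epoch.condition,
        "trial": epoch.trial,
        "labels": list(epoch.labels) if epoch.labels is not None else None,
        "units": "uV",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_epoch(path, montage: Montage | None = None) -> ErpEpoch:
    """Read an epoch written by :func:`write_epoch`; validates the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise EpochFormatError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t", ndmin=2))
    if data.shape != (meta["n_channels"], meta["n_samples"]):
        raise EpochFormatError(
            f"{path}: data shape {data.shape} does not match sidecar "
            f"({meta['n_channels']}, {meta['n_samples']})"
        )
    if montage is not None and data.shape[0] != montage.n_electrodes:
        raise EpochFormatError(
            f"{path}: {data.shape[0]} channels but montage has "
            f"{montage.n_electrodes} electrodes"
        )
    return ErpEpoch(
        data=data,
        fs=meta["fs"],
        alignment=meta["alignment"],
        t0_ms=meta["t0_ms"],
        subject_id=meta.get("subject_id"),
        condition=meta.get("condition"),
        trial=meta.get("trial"),
        labels=tuple(meta["labels"]) if meta.get("labels") else None,
    )


# ---------------------------------------------------------------------------
# Reaction-time tables

RT_COLUMNS = ["subject_id", "condition", "trial", "rt_ms"]


def read_rt_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RT_COLUMNS if c not in df.columns]
    if missing:
        raise EpochFormatError(f"{path}: RT table missing columns {missing}")
    if "valid" not in df.columns:
        df["valid"] = True
    bad = df[(df["valid"]) & ~(df["rt_ms"] > 0)]
    if len(bad):
        raise EpochFormatError(f"{path}: non-positive rt_ms on valid trials")
    df["subject_id"] = df["subject_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    return df


def write_rt_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Rejection and pairing


def reject_epochs(
    epochs: Sequence[ErpEpoch], threshold_uv: float = 100.0
) -> tuple[list[ErpEpoch], pd.DataFrame]:
    """Amplitude criterion: keep an epoch iff max |value| ≤ threshold (μV).

    Returns the retained epochs and a per-epoch report with the peak absolute
    amplitude and the rejection flag.
    """
    if not threshold_uv > 0:
        raise ValueError("threshold_uv must be positive")
    kept: list[ErpEpoch] = []
    rows = []
    for ep in epochs:
        peak = float(np.abs(ep.data).max())
        rejected = peak > threshold_uv
        if not rejected:
            kept.append(ep)
        rows.append(
            {
                "subject_id": ep.subject_id,
                "condition": ep.condition,
                "trial": ep.trial,
                "alignment": ep.alignment,
                "peak_abs_uv": peak,
                "rejected": rejected,
            }
        )
    return kept, pd.DataFrame(rows)


def pair_filter(
    stim_epochs: Sequence[ErpEpoch], resp_epochs: Sequence[ErpEpoch]
) -> tuple[list[ErpEpoch], list[ErpEpoch]]:
    """Keep only trials with both an uncontaminated stimulus- and
    response-aligned epoch (intersection by trial identity)."""
    stim_by = {ep.key(): ep for ep in stim_epochs}
    resp_by = {ep.key(): ep for ep in resp_epochs}
    common = sorted(set(stim_by) & set(resp_by), key=lambda k: tuple(map(str, k)))
    if not common:
        warnings.warn("pair_filter: no trial retained in both alignments")
    return [stim_by[k] for k in common], [resp_by[k] for k in common]


def average_epochs(epochs: Sequence[ErpEpoch]) -> ErpEpoch:
    """Average epochs of identical geometry/alignment (trial → subject → grand)."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("cannot average an empty epoch list")
    first = epochs[0]
    for ep in epochs[1:]:
        if (ep.data.shape != first.data.shape or ep.fs != first.fs
                or ep.alignment != first.alignment
                or abs(ep.t0_ms - first.t0_ms) > 1e-9):
            raise ValueError("epochs differ in geometry, rate or alignment")
    mean = np.mean([ep.data for ep in epochs], axis=0)

    def _common(attr):
        vals = {getattr(ep, attr) for ep in epochs}
        return vals.pop() if len(vals) == 1 else None

    return ErpEpoch(
        data=mean,
        fs=first.fs,
        alignment=first.alignment,
        t0_ms=first.t0_ms,
        subject_id=_common("subject_id"),
        condition=_common("condition"),
        trial=None,
        labels=first.labels,
    )
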