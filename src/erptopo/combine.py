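"""Combine stimulus-aligned and response-aligned ERPs by production latency.

Fixed stimulus-locked epochs miss late (pre-articulatory) activity on slow
trials, and fixed response-locked epochs mix different encoding stages across
trials with different reaction times.  The combination covers the exact
interval from picture onset to a fixed offset before articulation: the
stimulus-aligned epoch provides the early part, the response-aligned epoch
the late part, and any signal of the response-aligned epoch that overlaps the
stimulus-aligned window is removed from the response-aligned side.

Worked example (stimulus epoch 500 ms, response epoch 500 ms ending 100 ms
before articulation): for a production latency of 850 ms the response epoch
natively covers −600..−100 ms, i.e. 250..750 ms in stimulus time; its first
250 ms overlap the stimulus epoch and are removed, so the retained response
window is −350..−100 ms and the combined ERP covers 0..750 ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .epochs import ErpEpoch, average_epochs

__all__ = [
    "CombineSpec",
    "CombinedErp",
    "CombineError",
    "combined_window",
    "combine_epochs",
    "combine_group",
]


class CombineError(ValueError):
    """Invalid combination request (e.g. RT inside the articulation offset)."""


def _round_smp(x: float) -> int:
    """Nearest-sample quantization, half away from zero (not banker's)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class CombineSpec:
    """Geometry of the combination.

    stim_len_ms : length of the stimulus-aligned epoch (S).
    resp_len_ms : length of the response-aligned epoch (Lr).
    resp_offset_ms : gap before articulation excluded from the response
        epoch (off); the response epoch natively spans [-(Lr+off), -off]
        relative to articulation onset.
    """

    stim_len_ms: float = 500.0
    resp_len_ms: float = 500.0
    resp_offset_ms: float = 100.0

    def __post_init__(self):
        if not (self.stim_len_ms > 0 and self.resp_len_ms > 0):
            raise CombineError("epoch lengths must be positive")
        if self.resp_offset_ms < 0:
            raise CombineError("resp_offset_ms must be >= 0")


class CombinedWindow(NamedTuple):
    resp_keep_start_ms: float  # response-locked frame, negative before articulation
    resp_keep_end_ms: float
    removed_ms: float


def combined_window(rt_ms: float, spec: CombineSpec = CombineSpec()) -> CombinedWindow:
    """Overlap-removal arithmetic for one production latency.

    The response epoch natively spans ``[-(Lr+off), -off]`` relative to
    articulation; in stimulus time that is ``[rt-Lr-off, rt-off]``.  The
    portion overlapping the stimulus epoch ``[0, S]`` is removed:
    ``removed = clamp(S - (rt - Lr - off), 0, Lr)``.  Returns the retained
    response-locked window and the removed duration, all in ms.

    For the no-overlap boundary (``rt >= S + Lr + off``) nothing is removed;
    for ``rt - off <= S`` the whole response epoch is removed and the
    combined ERP is stimulus data only.
    """
    S, Lr, off = spec.stim_len_ms, spec.resp_len_ms, spec.resp_offset_ms
    if not rt_ms > off:
        raise CombineError(
            f"rt_ms={rt_ms} leaves no planning window before the "
            f"{off} ms articulation offset"
        )
    removed = float(np.clip(S - (rt_ms - Lr - off), 0.0, Lr))
    keep_start = -(Lr + off) + removed
    keep_end = -off
    return CombinedWindow(keep_start, keep_end, removed)


@dataclass
class CombinedErp:
    """A combined stimulus→pre-articulation ERP and its provenance."""

    epoch: ErpEpoch                  # alignment="combined", t0_ms=0
    rt_ms: float                     # latency used (quantized to the sample grid)
    splice_ms: float                 # stimulus-time point where response data begins
    removed_ms: float                # overlap removed from the response epoch
    stim_only: bool = False          # rt - off <= S: response epoch contributed nothing
    gap_mask: np.ndarray | None = None  # True where no source covered the sample


def combine_epochs(
    stim: ErpEpoch,
    resp: ErpEpoch,
    rt_ms: float,
    spec: CombineSpec | None = None,
    allow_gap: bool = False,
) -> CombinedErp:
    """Concatenate a stimulus- and a response-aligned epoch for one latency.

    Samples ``[0, splice)`` are copied from the stimulus epoch and
    ``[splice, rt-off)`` from the retained part of the response epoch — a
    hard concatenation with no crossfade (overlap is removed, never blended).
    The RT is quantized to the nearest sample of the shared sampling grid.

    For ``rt > S + Lr + off`` the two epochs do not touch; this raises
    :class:`CombineError` unless ``allow_gap=True``, in which case the gap is
    NaN-filled and flagged in ``gap_mask``.
    """
    if stim.alignment != "stimulus":
        raise CombineError("stim epoch must be stimulus-aligned")
    if resp.alignment != "response":
        raise CombineError("resp epoch must be response-aligned")
    if stim.fs != resp.fs:
        raise CombineError(f"sampling rate mismatch: {stim.fs} vs {resp.fs}")
    if stim.n_channels != resp.n_channels:
        raise CombineError("channel count mismatch between the two epochs")
    fs = stim.fs
    n_stim_native = stim.n_samples
    n_resp = resp.n_samples
    # the response epoch spans [t0, t0 + Lr) relative to articulation
    off_smp = _round_smp(-(resp.t0_ms + resp.duration_ms) * fs / 1000.0)
    if off_smp < 0:
        raise CombineError("response epoch extends past the articulation offset")
    if spec is not None:
        # cross-check declared geometry against the actual epochs (1-sample slack)
        for name, want, have in [
            ("stim_len_ms", spec.stim_len_ms, stim.duration_ms),
            ("resp_len_ms", spec.resp_len_ms, resp.duration_ms),
            ("resp_offset_ms", spec.resp_offset_ms, off_smp * 1000.0 / fs),
        ]:
            if abs(want - have) > 1000.0 / fs + 1e-9:
                raise CombineError(
                    f"spec.{name}={want} ms inconsistent with epoch ({have:.3f} ms)"
                )
    rt_smp = _round_smp(rt_ms * fs / 1000.0)
    n_total = rt_smp - off_smp
    if n_total <= 0:
        raise CombineError(
            f"rt_ms={rt_ms} leaves no planning window before the offset"
        )
    n_from_stim = min(n_stim_native, n_total)
    data = np.empty((stim.n_channels, n_total))
    data[:, :n_from_stim] = stim.data[:, :n_from_stim]
    gap_mask = None
    resp_start_global = rt_smp - off_smp - n_resp  # stimulus-time sample of resp[0]
    removed_smp = int(np.clip(n_from_stim - resp_start_global, 0, n_resp))
    if n_total > n_from_stim:
        gap = resp_start_global - n_from_stim
        if gap > 0:
            if not allow_gap:
                raise CombineError(
                    f"rt_ms={rt_ms} exceeds the epochs' joint coverage by "
                    f"{gap * 1000.0 / fs:.1f} ms; pass allow_gap=True to "
                    "produce a gap-marked output"
                )
            gap_mask = np.zeros(n_total, dtype=bool)
            gap_mask[n_from_stim:n_from_stim + gap] = True
            data[:, n_from_stim:n_from_stim + gap] = np.nan
            data[:, n_from_stim + gap:] = resp.data[:, : n_total - n_from_stim - gap]
        else:
            data[:, n_from_stim:] = resp.data[:, removed_smp:removed_smp + (n_total - n_from_stim)]
    combined = ErpEpoch(
        data=data,
        fs=fs,
        alignment="combined",
        t0_ms=0.0,
        subject_id=stim.subject_id,
        condition=stim.condition,
        trial=stim.trial,
        labels=stim.labels,
    )
    return CombinedErp(
        epoch=combined,
        rt_ms=rt_smp * 1000.0 / fs,
        splice_ms=n_from_stim * 1000.0 / fs,
        removed_ms=removed_smp * 1000.0 / fs,
        stim_only=(n_total <= n_stim_native),
        gap_mask=gap_mask,
    )


def _mean_rts(rt_table: pd.DataFrame) -> pd.Series:
    valid = rt_table[rt_table["valid"]] if "valid" in rt_table.columns else rt_table
    return valid.groupby(["subject_id", "condition"])["rt_ms"].mean()


def combine_group(
    stim_by: Mapping[tuple[str, str], ErpEpoch],
    resp_by: Mapping[tuple[str, str], ErpEpoch],
    rt_table: pd.DataFrame,
    spec: CombineSpec | None = None,
    level: str = "subject",
) -> dict:
    """Apply the combination at the subject or the group level.

    ``stim_by``/``resp_by`` map ``(subject_id, condition)`` to the
    subject-averaged stimulus-/response-aligned epochs.  ``level="subject"``
    combines each subject-condition average at that subject-condition's mean
    RT; ``level="group"`` grand-averages the epochs per condition and
    combines at the condition's mean RT (mean of subject means).  Returns a
    dict keyed by ``(subject_id, condition)`` or by condition.
    """
    if level not in ("subject", "group"):
        raise ValueError("level must be 'subject' or 'group'")
    keys = sorted(stim_by, key=lambda k: tuple(map(str, k)))
    if sorted(resp_by, key=lambda k: tuple(map(str, k))) != keys:
        raise CombineError("stim and resp subject-condition keys differ")
    mean_rt = _mean_rts(rt_table)
    missing = [k for k in keys if k not in mean_rt.index]
    if missing:
        raise CombineError(f"missing mean RT for subject-conditions: {missing}")
    if level == "subject":
        return {
            k: combine_epochs(stim_by[k], resp_by[k], float(mean_rt.loc[k]), spec)
            for k in keys
        }
    out = {}
    for cond in sorted({c for _, c in keys}):
        cond_keys = [k for k in keys if k[1] == cond]
        g_stim = average_epochs([stim_by[k] for k in cond_keys])
        g_resp = average_epochs([resp_by[k] for k in cond_keys])
        g_rt = float(np.mean([mean_rt.loc[k] for k in cond_keys]))
        out[cond] = combine_epochs(
            g_stim.copy_with(condition=cond),
            g_resp.copy_with(condition=cond),
            g_rt,
            spec,
        )
    return out
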