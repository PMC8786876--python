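"""Cleaning chain for block-design Hb recordings.

Order of operations, enforced by the session driver:

1. zero-phase band-pass filtering (0.01–0.7 Hz) removes slow concentration
   drift and cardiac pulsation;
2. motion-artifact screening rejects any (channel, block) whose concentration
   jumps by more than 0.1 mmol×mm over 0.2 s (two samples at 10.4 Hz);
3. channels with useful data in fewer than half of a condition's blocks are
   discarded outright for that subject;
4. surviving (channel, block) pairs are epoched around block onset;
5. a per-epoch linear baseline, fitted on the 5 s before onset together with
   late post-block samples (after a 15 s settling delay), is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import SessionRecording

__all__ = [
    "Reason",
    "ValidityMask",
    "EpochSet",
    "bandpass",
    "detect_motion_artifacts",
    "discard_channels",
    "extract_epochs",
    "baseline_correct",
    "preprocess_session",
]


class Reason(str, Enum):
    OK = "ok"
    MOTION_ARTIFACT = "motion_artifact"
    CHANNEL_DISCARDED = "channel_discarded"


@dataclass
class ValidityMask:
    """Per-(channel, block) validity with rejection reasons."""

    channel_ids: list[int]
    block_conditions: list[str]
    valid: np.ndarray    # (n_channels, n_blocks) bool
    reasons: np.ndarray  # (n_channels, n_blocks) of Reason values (str)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (len(self.channel_ids), len(self.block_conditions)):
            raise ValueError("mask shape mismatch")

    @classmethod
    def all_valid(cls, channel_ids, block_conditions) -> "ValidityMask":
        shape = (len(channel_ids), len(block_conditions))
        return cls(
            list(channel_ids),
            list(block_conditions),
            np.ones(shape, dtype=bool),
            np.full(shape, Reason.OK.value, dtype=object),
        )

    def is_channel_discarded(self, channel_id: int) -> bool:
        i = self.channel_ids.index(channel_id)
        return bool((self.reasons[i] == Reason.CHANNEL_DISCARDED.value).all())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.channel_ids):
            for b, cond in enumerate(self.block_conditions):
                rows.append(
                    dict(channel_id=cid, block_index=b, condition=cond,
                         valid=bool(self.valid[i, b]),
                         reason=str(self.reasons[i, b]))
                )
        return pd.DataFrame(rows)


@dataclass
class EpochSet:
    """Block-locked epochs on a common relative time axis (onset = 0 s)."""

    times: np.ndarray          # (n_times,) seconds relative to block onset
    meta: pd.DataFrame         # channel_id, block_index, condition,
                               # block_duration_s, next_gap_s per epoch row
    oxy: np.ndarray            # (n_epochs, n_times)
    deoxy: np.ndarray
    sampling_rate_hz: float
    analysis_window_s: tuple[float, float] = (0.0, 15.0)
    baseline_coeffs: dict[str, np.ndarray] = field(default_factory=dict)
    baselined: bool = False

    def __post_init__(self) -> None:
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError("oxy/deoxy epoch arrays must share a shape")
        if self.oxy.shape != (len(self.meta), len(self.times)):
            raise ValueError("epoch array shape mismatch")

    def chromophore(self, name: str) -> np.ndarray:
        if name not in ("oxy", "deoxy"):
            raise ValueError(f"unknown chromophore {name!r}")
        return self.oxy if name == "oxy" else self.deoxy

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (epoch, chromophore, sample)."""
        frames = []
        for chrom in ("oxy", "deoxy"):
            data = self.chromophore(chrom)
            for e in range(len(self.meta)):
                m = self.meta.iloc[e]
                frames.append(pd.DataFrame(dict(
                    channel_id=m.channel_id, chromophore=chrom,
                    condition=m.condition, block_index=m.block_index,
                    time_s=self.times, value=data[e],
                )))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    recording: SessionRecording,
    low_hz: float = 0.01,
    high_hz: float = 0.7,
    order: int = 3,
) -> SessionRecording:
    """Zero-phase Butterworth band-pass applied independently per channel and
    chromophore (forward-backward, so no group delay); DC is rejected."""
    fs = recording.sampling_rate_hz
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(
            f"cutoffs must satisfy 0 < low < high < Nyquist, got "
            f"({low_hz}, {high_hz}) at fs={fs}"
        )
    if not (np.all(np.isfinite(recording.oxy))
            and np.all(np.isfinite(recording.deoxy))):
        raise ValueError("recording contains non-finite samples")
    sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    return replace(
        recording,
        oxy=sps.sosfiltfilt(sos, recording.oxy, axis=1),
        deoxy=sps.sosfiltfilt(sos, recording.deoxy, axis=1),
    )


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------

def detect_motion_artifacts(
    recording: SessionRecording,
    threshold_mmolmm: float = 0.1,
    window_s: float = 0.2,
    chromophores: tuple[str, ...] = ("oxy", "deoxy"),
) -> ValidityMask:
    """Flag (channel, block) pairs containing motion artifacts.

    A pair is invalid iff, for any sample ``t`` inside the block, the
    concentration change ``|x[t+k] - x[t]|`` exceeds the threshold, where
    ``k = floor(window_s * fs)`` whole sampling intervals (two samples at
    10.4 Hz).  Exceedance on either chromophore rejects the pair.
    """
    fs = recording.sampling_rate_hz
    k = int(np.floor(window_s * fs))
    if k < 1:
        raise ValueError("window shorter than one sampling interval")
    blocks = recording.blocks
    mask = ValidityMask.all_valid(
        recording.channel_ids, list(blocks["condition"])
    )
    n = recording.n_samples
    for b, row in blocks.iterrows():
        i0 = int(np.floor(row.onset_s * fs))
        i1 = int(np.ceil((row.onset_s + row.duration_s) * fs)) + 1
        if i1 > n:
            raise ValueError(f"block {b} extends past the recording end")
        for chrom in chromophores:
            data = recording.oxy if chrom == "oxy" else recording.deoxy
            seg = data[:, i0:i1]
            jump = np.abs(seg[:, k:] - seg[:, :-k])
            bad = (jump > threshold_mmolmm).any(axis=1)
            newly = bad & mask.valid[:, b]
            mask.valid[newly, b] = False
            mask.reasons[newly, b] = Reason.MOTION_ARTIFACT.value
    return mask


def discard_channels(mask: ValidityMask) -> ValidityMask:
    """Discard a channel entirely if, for any condition, it provides valid
    data in fewer than half of that condition's blocks (7/14 retained, 6/14
    discarded).  Idempotent."""
    conds = np.asarray(mask.block_conditions)
    valid = mask.valid.copy()
    reasons = mask.reasons.copy()
    for i in range(len(mask.channel_ids)):
        for cond in np.unique(conds):
            sel = conds == cond
            if valid[i, sel].sum() < sel.sum() / 2.0:
                valid[i, :] = False
                reasons[i, :] = Reason.CHANNEL_DISCARDED.value
                break
    return ValidityMask(list(mask.channel_ids), list(mask.block_conditions),
                        valid, reasons)


# ---------------------------------------------------------------------------
# epoching and baselining
# ---------------------------------------------------------------------------

def extract_epochs(
    recording: SessionRecording,
    mask: ValidityMask | None = None,
    pre_s: float = 5.0,
    post_s: float = 20.0,
    pad: bool = False,
) -> EpochSet:
    """Cut one epoch per valid (channel, block), time-locked to block onset.

    The epoch spans ``[-pre_s, dur_max + post_s]`` on a common time axis
    (``dur_max`` = longest block), so every epoch covers the 0–15 s analysis
    window, the pre-onset baseline, and the late post-block baseline support.
    Epochs of invalid (channel, block) pairs are omitted.  If an epoch
    extends past the recording, either raise or NaN-pad (``pad=True``).
    """
    fs = recording.sampling_rate_hz
    blocks = recording.blocks
    if mask is None:
        mask = ValidityMask.all_valid(
            recording.channel_ids, list(blocks["condition"])
        )
    dur_max = float(blocks["duration_s"].max())
    i_pre = int(round(pre_s * fs))
    length = i_pre + int(round((dur_max + post_s) * fs)) + 1
    times = (np.arange(length) - i_pre) / fs

    onsets = blocks["onset_s"].to_numpy()
    next_onsets = np.append(onsets[1:], np.inf)
    n = recording.n_samples
    starts = np.round(onsets * fs).astype(int) - i_pre
    for b, start in enumerate(starts):
        if start < 0 and not pad:
            raise ValueError(
                f"pre-window of block {b} precedes recording start "
                "(use pad=True to NaN-pad)"
            )
        if start + length > n and not pad:
            raise ValueError(
                f"epoch of block {b} extends past recording end "
                "(use pad=True to NaN-pad)"
            )
    # gather all (block, sample) indices at once; out-of-range samples (only
    # possible with pad=True) become NaN
    idx = starts[:, None] + np.arange(length)[None, :]       # (B, L)
    oob = (idx < 0) | (idx >= n)
    idx_c = np.clip(idx, 0, n - 1)
    oxy_all = recording.oxy[:, idx_c]                        # (C, B, L)
    deoxy_all = recording.deoxy[:, idx_c]
    if oob.any():
        oxy_all = np.where(oob[None, :, :], np.nan, oxy_all)
        deoxy_all = np.where(oob[None, :, :], np.nan, deoxy_all)
    # epoch order: block-major, then channel (matches the validity mask)
    keep = mask.valid.T                                      # (B, C)
    oxy_arr = oxy_all.transpose(1, 0, 2)[keep]               # (n_epochs, L)
    deoxy_arr = deoxy_all.transpose(1, 0, 2)[keep]
    ids = np.asarray(recording.channel_ids)
    b_idx, c_idx = np.nonzero(keep)
    gaps = next_onsets - (onsets + blocks["duration_s"].to_numpy())
    meta = pd.DataFrame(dict(
        channel_id=ids[c_idx].astype(int),
        block_index=b_idx,
        condition=blocks["condition"].to_numpy()[b_idx],
        block_duration_s=blocks["duration_s"].to_numpy()[b_idx],
        next_gap_s=gaps[b_idx],
    ))
    return EpochSet(
        times=times,
        meta=meta,
        oxy=oxy_arr,
        deoxy=deoxy_arr,
        sampling_rate_hz=fs,
    )


def _baseline_support(
    times: np.ndarray,
    block_duration_s: float,
    next_gap_s: float,
    settle_s: float,
    post_mode: str,
) -> np.ndarray:
    """Boolean support for the baseline fit.

    ``offset`` (default): pre-onset [-5, 0] plus post-block samples *starting*
    15 s after block end (letting the response settle) and ending at the next
    block onset.  ``duration``: pre-onset plus the 15 s immediately following
    block end, capped at the next onset.
    """
    end = block_duration_s
    dt = times[1] - times[0]
    # strictly pre-onset; one-sample guard below the next onset so onset
    # rounding can never leak a stimulated sample into the fit
    pre = (times >= times[0]) & (times < 0)
    if post_mode == "offset":
        lo, hi = end + settle_s, end + next_gap_s - dt
    elif post_mode == "duration":
        lo, hi = end, end + min(settle_s, next_gap_s - dt)
    else:
        raise ValueError(f"unknown post_mode {post_mode!r}")
    post = (times >= lo) & (times < hi)
    return pre | post


def baseline_correct(
    epochs: EpochSet,
    settle_s: float = 15.0,
    post_mode: str = "offset",
) -> EpochSet:
    """Fit and subtract a per-epoch linear baseline.

    For each epoch a least-squares line is estimated on the pre-onset 5 s and
    the late post-block support (see :func:`_baseline_support`) and subtracted
    from the entire epoch; the (slope, intercept) pair is stored.  The
    settling interval (block end → block end + 15 s) never enters the fit in
    the default ``offset`` mode.
    """
    t = epochs.times
    n_e = len(epochs.meta)
    coeffs = {c: np.zeros((n_e, 2)) for c in ("oxy", "deoxy")}
    out = {c: epochs.chromophore(c).copy() for c in ("oxy", "deoxy")}
    # per-epoch boolean support on the shared time axis (bounds vary with the
    # block's own duration and the gap to the next block); vectorized
    # equivalent of _baseline_support
    if n_e:
        dur = epochs.meta["block_duration_s"].to_numpy(float)
        gap = epochs.meta["next_gap_s"].to_numpy(float)
        dt = t[1] - t[0]
        if post_mode == "offset":
            lo, hi = dur + settle_s, dur + gap - dt
        elif post_mode == "duration":
            lo, hi = dur, dur + np.minimum(settle_s, gap - dt)
        else:
            raise ValueError(f"unknown post_mode {post_mode!r}")
        pre = (t >= t[0]) & (t < 0)
        support = pre[None, :] | (
            (t[None, :] >= lo[:, None]) & (t[None, :] < hi[:, None])
        )
    else:
        support = np.empty((0, len(t)), dtype=bool)
    for chrom in ("oxy", "deoxy"):
        y = out[chrom]
        w = (support & np.isfinite(y)).astype(float)
        n = w.sum(axis=1)
        if (n < 4).any():
            bad = int(np.argmax(n < 4))
            raise ValueError(
                f"baseline support of epoch {bad} has fewer than 4 samples"
            )
        yz = np.nan_to_num(y, nan=0.0)
        st = w @ t
        stt = w @ (t * t)
        sy = (w * yz).sum(axis=1)
        sty = (w * yz) @ t
        denom = n * stt - st**2
        slope = (n * sty - st * sy) / denom
        intercept = (sy - slope * st) / n
        out[chrom] = y - (slope[:, None] * t[None, :] + intercept[:, None])
        coeffs[chrom] = np.column_stack([slope, intercept])
    return EpochSet(
        times=t, meta=epochs.meta.copy(),
        oxy=out["oxy"], deoxy=out["deoxy"],
        sampling_rate_hz=epochs.sampling_rate_hz,
        analysis_window_s=epochs.analysis_window_s,
        baseline_coeffs=coeffs, baselined=True,
    )


# ---------------------------------------------------------------------------
# session driver
# ---------------------------------------------------------------------------

def preprocess_session(
    recording: SessionRecording,
    low_hz: float = 0.01,
    high_hz: float = 0.7,
    artifact_threshold_mmolmm: float = 0.1,
    artifact_window_s: float = 0.2,
    artifact_on: str = "filtered",
    pre_s: float = 5.0,
    post_s: float = 20.0,
    settle_s: float = 15.0,
    baseline_post_mode: str = "offset",
) -> tuple[EpochSet, ValidityMask]:
    """Run the full cleaning chain in its contractual order:
    filter → artifact detection → channel exclusion → epoching → baselining.
    """
    filtered = bandpass(recording, low_hz, high_hz)
    target = filtered if artifact_on == "filtered" else recording
    mask = detect_motion_artifacts(
        target, artifact_threshold_mmolmm, artifact_window_s
    )
    mask = discard_channels(mask)
    epochs = extract_epochs(filtered, mask, pre_s=pre_s, post_s=post_s)
    return baseline_correct(epochs, settle_s=settle_s,
                            post_mode=baseline_post_mode), mask
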