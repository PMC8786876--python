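"""Synthetic newborn fNIRS cohorts with known ground truth.

Simulates per-subject oxy/deoxyhemoglobin concentration time series (mmol×mm)
for the 24-channel bilateral fronto-temporal probe used in neonatal speech
studies: a double-gamma hemodynamic response convolved with the block design,
plus low-frequency drift, a cardiac oscillation (newborn heart rate ~150 bpm,
aliased at the 10.4 Hz sampling rate), white noise, and transient motion
spikes.  Every injected effect and artifact is recorded in a ground-truth
sidecar so downstream preprocessing and statistics can be validated against
what was actually put in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .stimulus import Condition, ExperimentSchedule

__all__ = [
    "CONDITIONS",
    "Channel",
    "ProbeLayout",
    "HRFParams",
    "EffectMap",
    "NoiseParams",
    "MotionSpike",
    "GroundTruth",
    "SessionRecording",
    "default_probe",
    "hrf_kernel",
    "simulate_session",
    "simulate_cohort",
]

#: Fixed condition order used for effect-map and response arrays.
CONDITIONS: tuple[Condition, ...] = (
    Condition.COMMUNICATIVE,
    Condition.SINGLE_SPEAKER,
    Condition.ECHOING,
)


# ---------------------------------------------------------------------------
# probe geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    id: int            # 1..24
    hemisphere: str    # "L" or "R"
    position: tuple[float, float]  # cm, schematic head-surface coordinates
    source: str        # optode labels, e.g. "L-S2"
    detector: str


@dataclass
class ProbeLayout:
    """24 measurement channels, 12 per hemisphere, 3 cm source-detector
    separation, with channel adjacency defined by shared optodes."""

    channels: list[Channel]
    adjacency: dict[int, frozenset[int]]
    source_detector_separation_cm: float = 3.0

    @property
    def channel_ids(self) -> list[int]:
        return [c.id for c in self.channels]

    def neighbors(self, channel_id: int) -> frozenset[int]:
        return self.adjacency[channel_id]

    def adjacency_matrix(self) -> np.ndarray:
        ids = self.channel_ids
        pos = {cid: i for i, cid in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)), dtype=bool)
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                m[pos[a], pos[b]] = True
        return m


# Per-hemisphere optode grid (grid unit = 3 cm): 4 LED sources on the edge
# midpoints of a 3x3 grid, 5 detectors on its corners and center.  The 12
# channels per hemisphere are the unit-distance source-detector pairs.
_SOURCES = {"S1": (1.0, 0.0), "S2": (0.0, 1.0), "S3": (2.0, 1.0), "S4": (1.0, 2.0)}
_DETECTORS = {
    "D1": (0.0, 0.0), "D2": (2.0, 0.0), "D3": (1.0, 1.0),
    "D4": (0.0, 2.0), "D5": (2.0, 2.0),
}
# Channel numbering within a hemisphere (1..12), chosen so that the
# fronto-temporal channel groups reported for this montage form
# adjacency-connected sets.
_CHANNEL_PAIRS: dict[int, tuple[str, str]] = {
    1: ("S1", "D3"), 2: ("S2", "D1"), 3: ("S1", "D2"), 4: ("S2", "D3"),
    5: ("S1", "D1"), 6: ("S2", "D4"), 7: ("S3", "D2"), 8: ("S3", "D3"),
    9: ("S4", "D3"), 10: ("S3", "D5"), 11: ("S4", "D4"), 12: ("S4", "D5"),
}


def default_probe(separation_cm: float = 3.0) -> ProbeLayout:
    """The fixed 24-channel layout: 4 sources + 5 detectors per hemisphere at
    mirrored locations, channels at unit optode distance, adjacency = shared
    optode (symmetric, irreflexive)."""
    channels: list[Channel] = []
    for hemi, offset in (("L", -1.0), ("R", 1.0)):
        for local_id, (s, d) in _CHANNEL_PAIRS.items():
            sx, sy = _SOURCES[s]
            dx, dy = _DETECTORS[d]
            # mirror across the midline; positions in cm
            mx = offset * (((sx + dx) / 2.0) + 1.0) * separation_cm
            my = ((sy + dy) / 2.0) * separation_cm
            cid = local_id if hemi == "L" else local_id + 12
            channels.append(
                Channel(
                    id=cid,
                    hemisphere=hemi,
                    position=(mx, my),
                    source=f"{hemi}-{s}",
                    detector=f"{hemi}-{d}",
                )
            )
    adjacency: dict[int, set[int]] = {c.id: set() for c in channels}
    for a in channels:
        for b in channels:
            if a.id != b.id and (a.source == b.source or a.detector == b.detector):
                adjacency[a.id].add(b.id)
    return ProbeLayout(
        channels=channels,
        adjacency={k: frozenset(v) for k, v in adjacency.items()},
        source_detector_separation_cm=separation_cm,
    )


# ---------------------------------------------------------------------------
# hemodynamic model
# ---------------------------------------------------------------------------

@dataclass
class HRFParams:
    """Canonical double-gamma hemodynamic response.

    Defaults use a 5 s peak delay, shorter than the adult 6 s, as a
    configurable infant-appropriate stand-in (the true neonatal latency is
    not pinned down here).
    """

    peak_delay_s: float = 5.0
    undershoot_delay_s: float = 12.0
    dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 30.0

    def __post_init__(self) -> None:
        if min(self.peak_delay_s, self.undershoot_delay_s,
               self.dispersion_s, self.duration_s) <= 0:
            raise ValueError("HRF delays/dispersion must be positive")
        if not 0 <= self.undershoot_ratio < 1:
            raise ValueError("undershoot_ratio must be in [0, 1)")


def hrf_kernel(params: HRFParams, sampling_rate_hz: float) -> np.ndarray:
    """Double-gamma kernel sampled at ``sampling_rate_hz``, normalized to unit
    sum so that convolving a sustained boxcar yields a plateau equal to the
    boxcar amplitude."""
    t = np.arange(0.0, params.duration_s, 1.0 / sampling_rate_hz)
    d = params.dispersion_s
    peak = gamma_dist.pdf(t, params.peak_delay_s / d, scale=d)
    under = gamma_dist.pdf(t, params.undershoot_delay_s / d, scale=d)
    h = peak - params.undershoot_ratio * under
    return h / h.sum()


# ---------------------------------------------------------------------------
# effects and noise
# ---------------------------------------------------------------------------

@dataclass
class EffectMap:
    """Ground-truth oxyHb response amplitudes (mmol×mm) per (channel,
    condition); the deoxy response is ``deoxy_ratio`` times the oxy response.
    """

    amplitudes: np.ndarray  # (n_channels, n_conditions) in CONDITIONS order
    channel_ids: list[int]
    deoxy_ratio: float = -1.0 / 3.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("effect amplitudes must be finite")
        if self.amplitudes.shape != (len(self.channel_ids), len(CONDITIONS)):
            raise ValueError("amplitude array shape mismatch")

    def amplitude(self, channel_id: int, condition: Condition) -> float:
        return float(
            self.amplitudes[self.channel_ids.index(channel_id),
                            CONDITIONS.index(condition)]
        )

    @classmethod
    def null(cls, probe: ProbeLayout) -> "EffectMap":
        ids = probe.channel_ids
        return cls(np.zeros((len(ids), len(CONDITIONS))), ids)

    @classmethod
    def uniform(cls, probe: ProbeLayout, amplitude: float) -> "EffectMap":
        ids = probe.channel_ids
        return cls(np.full((len(ids), len(CONDITIONS)), amplitude), ids)

    @classmethod
    def study_default(
        cls,
        probe: ProbeLayout,
        base: float = 0.06,
        communicative_surplus: float = 0.05,
        surplus_channels: Sequence[int] = (1, 2, 4, 6),
    ) -> "EffectMap":
        """All channels respond to all conditions at ``base``; the
        Communicative condition additionally gains ``communicative_surplus``
        on the left fronto-temporal channels (default {1, 2, 4, 6})."""
        ids = probe.channel_ids
        amp = np.full((len(ids), len(CONDITIONS)), base)
        ci = CONDITIONS.index(Condition.COMMUNICATIVE)
        for ch in surplus_channels:
            amp[ids.index(ch), ci] += communicative_surplus
        return cls(amp, ids)


@dataclass
class NoiseParams:
    """Physiological and instrumental noise (amplitudes in mmol×mm).

    The cardiac frequency defaults to 2.5 Hz (newborn heart rate ~150 bpm);
    it sits above the 0.7 Hz analysis band so band-pass filtering removes it,
    and above the 5.2 Hz Nyquist aliasing is allowed, as in real acquisition.
    ``deoxy_noise_scale`` scales all noise amplitudes for the deoxy channel,
    which is less noisy than oxy in real recordings.
    """

    drift_sd: float = 0.10
    drift_cutoff_hz: float = 0.01
    cardiac_freq_hz: float = 2.5
    cardiac_amp: float = 0.02
    white_sd: float = 0.02
    motion_spike_rate_per_min: float = 0.1
    motion_spike_amp_range: tuple[float, float] = (0.2, 1.0)
    motion_spike_decay_s: float = 0.5
    deoxy_noise_scale: float = 0.5

    def __post_init__(self) -> None:
        if min(self.drift_sd, self.cardiac_amp, self.white_sd,
               self.motion_spike_rate_per_min, self.deoxy_noise_scale) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.motion_spike_amp_range[0] > self.motion_spike_amp_range[1]:
            raise ValueError("inverted spike amplitude range")

    @classmethod
    def silent(cls) -> "NoiseParams":
        return cls(drift_sd=0.0, cardiac_amp=0.0, white_sd=0.0,
                   motion_spike_rate_per_min=0.0)


@dataclass(frozen=True)
class MotionSpike:
    channel_id: int
    time_s: float
    amplitude: float


@dataclass
class GroundTruth:
    effects: EffectMap
    motion_spikes: list[MotionSpike] = field(default_factory=list)


@dataclass
class SessionRecording:
    """One subject's multichannel Hb recording plus its event log."""

    subject_id: str
    sampling_rate_hz: float
    channel_ids: list[int]
    oxy: np.ndarray    # (n_channels, n_samples), mmol×mm
    deoxy: np.ndarray  # same shape
    events: pd.DataFrame  # utterance-level log from the schedule
    blocks: pd.DataFrame  # per-block onset_s, duration_s, condition
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.oxy.shape != self.deoxy.shape:
            raise ValueError("oxy and deoxy must share a shape")

    @property
    def n_samples(self) -> int:
        return self.oxy.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------

def _drift(rng: np.random.Generator, n_ch: int, n: int, fs: float,
           sd: float, cutoff_hz: float) -> np.ndarray:
    """Integrated Gaussian walks low-passed below ``cutoff_hz``, each
    rescaled to standard deviation ``sd`` over the session."""
    if sd == 0:
        return np.zeros((n_ch, n))
    walk = np.cumsum(rng.standard_normal((n_ch, n)), axis=1)
    # zero-phase 2nd-order Butterworth low-pass applied spectrally
    nfft = spfft.next_fast_len(n)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    gain = 1.0 / (1.0 + (freqs / cutoff_hz) ** 4)
    slow = spfft.irfft(
        spfft.rfft(walk, n=nfft, axis=1) * gain, n=nfft, axis=1
    )[:, :n]
    s = slow.std(axis=1, keepdims=True)
    return np.where(s > 0, slow * (sd / np.where(s > 0, s, 1.0)), 0.0)


def simulate_session(
    schedule: ExperimentSchedule,
    probe: ProbeLayout | None = None,
    hrf: HRFParams | None = None,
    effects: EffectMap | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    sampling_rate_hz: float = 10.4,
    tail_s: float = 25.0,
    subject_id: str = "sim",
) -> SessionRecording:
    """Render one subject's session.

    oxy = Σ_blocks amplitude(channel, condition) × (boxcar ⊛ double-gamma HRF)
          + drift + cardiac sinusoid + white noise + motion spikes;
    deoxy = deoxy_ratio × response + independently drawn noise of scaled
    variance (motion spikes hit both chromophores).  All injected spikes are
    recorded in the ground-truth sidecar.  Deterministic given ``seed``.
    """
    probe = probe or default_probe()
    hrf = hrf or HRFParams()
    effects = effects if effects is not None else EffectMap.null(probe)
    noise = noise or NoiseParams()
    if schedule.onsets_s is None:
        raise ValueError("schedule timeline not computed")
    fs = float(sampling_rate_hz)
    total_s = schedule.total_duration_s() + tail_s
    n = int(round(total_s * fs))
    if n <= 0:
        raise ValueError("empty time axis")
    rng = np.random.default_rng(seed)
    ids = probe.channel_ids
    n_ch = len(ids)
    t = np.arange(n) / fs

    # condition regressors: boxcar over each block, convolved with the HRF
    kernel = hrf_kernel(hrf, fs)
    regressors = np.zeros((len(CONDITIONS), n))
    for block, onset in zip(schedule.blocks, schedule.onsets_s):
        ci = CONDITIONS.index(block.condition)
        i0 = int(round(onset * fs))
        i1 = int(round((onset + block.duration_s()) * fs))
        regressors[ci, i0:i1] += 1.0
    for ci in range(len(CONDITIONS)):
        regressors[ci] = np.convolve(regressors[ci], kernel)[:n]

    amp = np.zeros((n_ch, len(CONDITIONS)))
    for i, cid in enumerate(ids):
        for j, cond in enumerate(CONDITIONS):
            amp[i, j] = effects.amplitude(cid, cond)
    response = amp @ regressors  # (n_ch, n)

    def _noise_stack(scale: float) -> np.ndarray:
        out = _drift(rng, n_ch, n, fs, noise.drift_sd * scale,
                     noise.drift_cutoff_hz)
        phases = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        out += noise.cardiac_amp * scale * np.sin(
            2 * np.pi * noise.cardiac_freq_hz * t[None, :] + phases
        )
        if noise.white_sd > 0:
            out += rng.normal(0, noise.white_sd * scale, size=(n_ch, n))
        return out

    oxy = response + _noise_stack(1.0)
    deoxy = effects.deoxy_ratio * response + _noise_stack(noise.deoxy_noise_scale)

    # transient motion spikes: exponential-decay excursions hitting both
    # chromophores; positions/amplitudes recorded as ground truth
    spikes: list[MotionSpike] = []
    if noise.motion_spike_rate_per_min > 0:
        lam = noise.motion_spike_rate_per_min * total_s / 60.0
        a0, a1 = noise.motion_spike_amp_range
        for i, cid in enumerate(ids):
            for _ in range(rng.poisson(lam)):
                ts = float(rng.uniform(0, total_s - 2.0))
                a = float(rng.uniform(a0, a1)) * float(rng.choice([-1.0, 1.0]))
                i0 = int(round(ts * fs))
                length = min(int(round(4 * noise.motion_spike_decay_s * fs)),
                             n - i0)
                shape = a * np.exp(
                    -np.arange(length) / (noise.motion_spike_decay_s * fs)
                )
                oxy[i, i0 : i0 + length] += shape
                deoxy[i, i0 : i0 + length] += shape
                spikes.append(MotionSpike(cid, ts, a))

    return SessionRecording(
        subject_id=subject_id,
        sampling_rate_hz=fs,
        channel_ids=list(ids),
        oxy=oxy,
        deoxy=deoxy,
        events=schedule.event_log(),
        blocks=schedule.block_table(),
        ground_truth=GroundTruth(effects=effects, motion_spikes=spikes),
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_subjects: int = 21,
    schedule_factory: Callable[[int], ExperimentSchedule] | None = None,
    probe: ProbeLayout | None = None,
    hrf: HRFParams | None = None,
    effects: EffectMap | None = None,
    noise: NoiseParams | None = None,
    subject_amplitude_sd: float = 0.02,
    seed: int = 0,
    sampling_rate_hz: float = 10.4,
) -> list[SessionRecording]:
    """Simulate ``n_subjects`` sessions with between-subject variability.

    Each subject's effect amplitudes are the ground-truth means plus iid
    Gaussian deviations of sd ``subject_amplitude_sd`` (per channel ×
    condition), and each subject receives an independently seeded schedule
    randomization, as real cohorts receive distinct stimulus lists.
    Reproducible from the master ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if subject_amplitude_sd < 0:
        raise ValueError("negative between-subject variability")
    probe = probe or default_probe()
    effects = effects if effects is not None else EffectMap.study_default(probe)

    if schedule_factory is None:
        from .stimulus import (DesignParams, build_schedule, compute_timeline,
                               generate_token_inventory)

        def schedule_factory(s: int) -> ExperimentSchedule:
            inv = generate_token_inventory(seed=s)
            sched = build_schedule(inv, DesignParams(), seed=s)
            return compute_timeline(sched, DesignParams(), seed=s)

    rng = np.random.default_rng(seed)
    recs: list[SessionRecording] = []
    for k in range(n_subjects):
        sched_seed, sess_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
        dev = rng.normal(0, subject_amplitude_sd, size=effects.amplitudes.shape)
        subj_effects = EffectMap(
            effects.amplitudes + dev, list(effects.channel_ids),
            deoxy_ratio=effects.deoxy_ratio,
        )
        sched = schedule_factory(sched_seed)
        recs.append(
            simulate_session(
                sched, probe, hrf, subj_effects, noise,
                seed=sess_seed, sampling_rate_hz=sampling_rate_hz,
                subject_id=f"sub-{k + 1:02d}",
            )
        )
    return recs
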