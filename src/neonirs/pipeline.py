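"""End-to-end driver, file I/O, configuration, and report generation.

``run_pipeline`` executes simulate → preprocess → analyze → report from a
single :class:`PipelineConfig`; everything downstream of the master seed is
deterministic, so two runs from the same config produce byte-identical report
JSON.  Recordings travel as wide CSV (one ``ch<k>_<oxy|deoxy>`` column per
measurement) or SNIRF (HDF5, standard ``/nirs/data1`` layout with processed
HbO/HbR measurement lists).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import preprocess as pp
from .simulate import (CONDITIONS, EffectMap, GroundTruth, HRFParams,
                       NoiseParams, ProbeLayout, SessionRecording,
                       default_probe, simulate_cohort)
from .stimulus import DesignParams

logger = logging.getLogger("neonirs")

__all__ = [
    "EffectConfig",
    "PreprocessConfig",
    "StatsConfig",
    "CohortConfig",
    "PipelineConfig",
    "ReportSummary",
    "run_pipeline",
    "read_recording",
    "write_recording",
    "load_config",
    "save_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class EffectConfig:
    base_amplitude: float = 0.06           # mmol×mm, all channels/conditions
    communicative_surplus: float = 0.05    # extra Communicative response
    surplus_channels: tuple[int, ...] = (1, 2, 4, 6)  # left fronto-temporal
    deoxy_ratio: float = -1.0 / 3.0

    def build(self, probe: ProbeLayout) -> EffectMap:
        m = EffectMap.study_default(
            probe, self.base_amplitude, self.communicative_surplus,
            self.surplus_channels,
        )
        m.deoxy_ratio = self.deoxy_ratio
        return m


@dataclass
class PreprocessConfig:
    low_hz: float = 0.01
    high_hz: float = 0.7
    artifact_threshold_mmolmm: float = 0.1
    artifact_window_s: float = 0.2
    artifact_on: str = "filtered"
    pre_s: float = 5.0
    post_s: float = 20.0
    settle_s: float = 15.0
    baseline_post_mode: str = "offset"


@dataclass
class StatsConfig:
    n_perm: int = 5000
    cluster_alpha: float = 0.05
    threshold: float | None = None   # None = parametric 95th percentile
    window_s: tuple[float, float] = (0.0, 15.0)


@dataclass
class CohortConfig:
    n_subjects: int = 21
    subject_amplitude_sd: float = 0.02
    sampling_rate_hz: float = 10.4


@dataclass
class PipelineConfig:
    design: DesignParams = field(default_factory=DesignParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    effects: EffectConfig = field(default_factory=EffectConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    master_seed: int = 0
    output_dir: str | None = None


_TUPLE_FIELDS = {"between_pair_gap_range_ms", "inter_block_silence_range_s",
                 "motion_spike_amp_range", "surplus_channels", "window_s"}


def _from_dict(cls, d: dict):
    """Rebuild a (possibly nested) config dataclass from a plain dict,
    restoring tuple-typed fields that YAML round-trips as lists."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, dict) and f.default_factory is not dataclasses.MISSING:
            proto = f.default_factory()
            if dataclasses.is_dataclass(proto):
                v = _from_dict(type(proto), v)
        if f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config),
                                         sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    return _from_dict(PipelineConfig, d)


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def write_recording(rec: SessionRecording, path: str | Path,
                    format: str = "csv") -> None:
    """Write a recording as wide CSV (+ ``_blocks.tsv``/``_events.tsv``
    sidecars) or SNIRF (HDF5 with block stimulus groups)."""
    path = Path(path)
    if format == "csv":
        cols = {"time": rec.times}
        for i, cid in enumerate(rec.channel_ids):
            cols[f"ch{cid}_oxy"] = rec.oxy[i]
        for i, cid in enumerate(rec.channel_ids):
            cols[f"ch{cid}_deoxy"] = rec.deoxy[i]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
        rec.blocks.to_csv(path.with_name(path.stem + "_blocks.tsv"),
                          sep="\t", index=False)
        if len(rec.events):
            rec.events.to_csv(path.with_name(path.stem + "_events.tsv"),
                              sep="\t", index=False)
    elif format == "snirf":
        _write_snirf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path: str | Path, format: str = "csv") -> SessionRecording:
    path = Path(path)
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise ValueError(f"cannot parse recording CSV {path}: {exc}") from exc
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing required 'time' column")
        oxy_cols = [c for c in df.columns if c.endswith("_oxy")]
        deoxy_cols = [c for c in df.columns if c.endswith("_deoxy")]
        if not oxy_cols or len(oxy_cols) != len(deoxy_cols):
            raise ValueError(
                f"{path}: expected matching ch<k>_oxy / ch<k>_deoxy columns"
            )
        if df.isna().any().any():
            raise ValueError(f"{path}: truncated or non-numeric rows detected")
        ids = [int(c[2:].split("_")[0]) for c in oxy_cols]
        t = df["time"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
        blocks_path = path.with_name(path.stem + "_blocks.tsv")
        events_path = path.with_name(path.stem + "_events.tsv")
        blocks = (pd.read_csv(blocks_path, sep="\t") if blocks_path.exists()
                  else pd.DataFrame(columns=["block_index", "onset_s",
                                             "duration_s", "condition"]))
        events = (pd.read_csv(events_path, sep="\t") if events_path.exists()
                  else pd.DataFrame())
        return SessionRecording(
            subject_id=path.stem,
            sampling_rate_hz=fs,
            channel_ids=ids,
            oxy=df[oxy_cols].to_numpy().T,
            deoxy=df[deoxy_cols].to_numpy().T,
            events=events,
            blocks=blocks,
        )
    if format == "snirf":
        return _read_snirf(path)
    raise ValueError(f"unknown format {format!r}")


def _write_snirf(rec: SessionRecording, path: Path) -> None:
    n_ch = len(rec.channel_ids)
    data = np.vstack([rec.oxy, rec.deoxy]).T  # (n_t, 2*n_ch)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=rec.times)
        probe = default_probe()
        by_id = {c.id: c for c in probe.channels}
        srcs = sorted({by_id[c].source for c in rec.channel_ids})
        dets = sorted({by_id[c].detector for c in rec.channel_ids})
        for m, (cid, label) in enumerate(
            [(c, "HbO") for c in rec.channel_ids]
            + [(c, "HbR") for c in rec.channel_ids],
            start=1,
        ):
            ch = by_id[cid]
            ml = d1.create_group(f"measurementList{m}")
            ml.create_dataset("sourceIndex", data=srcs.index(ch.source) + 1)
            ml.create_dataset("detectorIndex", data=dets.index(ch.detector) + 1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=label)
            ml.create_dataset("dataTypeIndex", data=1)
        pg = nirs.create_group("probe")
        pg.create_dataset("sourceLabels", data=np.array(srcs, dtype="S"))
        pg.create_dataset("detectorLabels", data=np.array(dets, dtype="S"))
        spos = {c.source: c for c in probe.channels}
        dpos = {c.detector: c for c in probe.channels}
        pg.create_dataset("sourcePos2D", data=np.zeros((len(srcs), 2)))
        pg.create_dataset("detectorPos2D", data=np.zeros((len(dets), 2)))
        pg.create_dataset("wavelengths", data=np.array([760.0, 850.0]))
        for si, (_, grp) in enumerate(rec.blocks.groupby("condition"), start=1):
            st = nirs.create_group(f"stim{si}")
            st.create_dataset("name", data=str(grp["condition"].iloc[0]))
            st.create_dataset(
                "data",
                data=np.column_stack([
                    grp["onset_s"].to_numpy(),
                    grp["duration_s"].to_numpy(),
                    np.ones(len(grp)),
                ]),
            )


def _read_snirf(path: Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        try:
            d1 = f["nirs"]["data1"]
            data = d1["dataTimeSeries"][()]
            t = d1["time"][()]
        except KeyError as exc:
            raise ValueError(f"{path}: missing SNIRF field {exc}") from exc
        labels = []
        m = 1
        while f"measurementList{m}" in d1:
            ml = d1[f"measurementList{m}"]
            lab = ml["dataTypeLabel"][()]
            labels.append(lab.decode() if isinstance(lab, bytes) else str(lab))
            m += 1
        if len(labels) != data.shape[1]:
            raise ValueError(
                f"{path}: measurementList count {len(labels)} does not match "
                f"dataTimeSeries width {data.shape[1]}"
            )
        n_ch = labels.count("HbO")
        blocks_rows = []
        si = 1
        while f"stim{si}" in f["nirs"]:
            st = f["nirs"][f"stim{si}"]
            name = st["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            for onset, dur, _ in st["data"][()]:
                blocks_rows.append(dict(onset_s=onset, duration_s=dur,
                                        condition=name))
            si += 1
    blocks = pd.DataFrame(blocks_rows).sort_values("onset_s", ignore_index=True) \
        if blocks_rows else pd.DataFrame(columns=["onset_s", "duration_s",
                                                  "condition"])
    blocks.insert(0, "block_index", range(len(blocks)))
    fs = 1.0 / float(np.median(np.diff(t)))
    return SessionRecording(
        subject_id=path.stem,
        sampling_rate_hz=fs,
        channel_ids=list(range(1, n_ch + 1)),
        oxy=data[:, :n_ch].T,
        deoxy=data[:, n_ch:].T,
        events=pd.DataFrame(),
        blocks=blocks,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ReportSummary:
    """Grand-average time courses (mean ± SEM across subjects) and cluster
    tables for every contrast."""

    grand_averages: pd.DataFrame  # channel, condition, chromophore, time_s,
                                  # mean, sem
    clusters: pd.DataFrame        # contrast, chromophore, channels, mass, p
    counts: dict[str, Any]
    config: PipelineConfig

    def to_json(self) -> str:
        obj = {
            "counts": self.counts,
            "clusters": self.clusters.to_dict(orient="records"),
            "config": dataclasses.asdict(self.config),
            "grand_average_checksum": float(
                np.round(np.nansum(self.grand_averages["mean"].to_numpy()), 12)
            ),
            "n_grand_average_rows": int(len(self.grand_averages)),
        }
        return json.dumps(obj, sort_keys=True, indent=1, default=float)


def _grand_averages(
    epoch_sets: list[pp.EpochSet], channel_ids: list[int]
) -> pd.DataFrame:
    """Mean ± SEM across subjects of per-subject mean epoch time courses."""
    n_t = min(len(es.times) for es in epoch_sets)
    times = epoch_sets[0].times[:n_t]
    rows = []
    for chrom in ("oxy", "deoxy"):
        for cond in (c.value for c in CONDITIONS):
            for cid in channel_ids:
                per_subj = []
                for es in epoch_sets:
                    sel = ((es.meta["channel_id"] == cid)
                           & (es.meta["condition"] == cond)).to_numpy()
                    if sel.any():
                        per_subj.append(
                            es.chromophore(chrom)[sel, :n_t].mean(axis=0)
                        )
                if not per_subj:
                    continue
                stack = np.vstack(per_subj)
                mean = stack.mean(axis=0)
                sem = (stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
                       if len(stack) > 1 else np.zeros(n_t))
                rows.append(pd.DataFrame(dict(
                    channel_id=cid, condition=cond, chromophore=chrom,
                    time_s=times, mean=mean, sem=sem,
                )))
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> ReportSummary:
    """simulate → preprocess → analyze → report, reproducible from the
    config's master seed."""
    probe = default_probe()
    effects = config.effects.build(probe)
    logger.info("simulating cohort: n=%d, seed=%d",
                config.cohort.n_subjects, config.master_seed)
    recs = simulate_cohort(
        n_subjects=config.cohort.n_subjects,
        probe=probe,
        hrf=config.hrf,
        effects=effects,
        noise=config.noise,
        subject_amplitude_sd=config.cohort.subject_amplitude_sd,
        seed=config.master_seed,
        sampling_rate_hz=config.cohort.sampling_rate_hz,
    )

    pc = config.preprocessing
    epoch_sets, masks = [], []
    for rec in recs:
        epochs, mask = pp.preprocess_session(
            rec,
            low_hz=pc.low_hz, high_hz=pc.high_hz,
            artifact_threshold_mmolmm=pc.artifact_threshold_mmolmm,
            artifact_window_s=pc.artifact_window_s,
            artifact_on=pc.artifact_on,
            pre_s=pc.pre_s, post_s=pc.post_s, settle_s=pc.settle_s,
            baseline_post_mode=pc.baseline_post_mode,
        )
        n_rej = int((~mask.valid).sum())
        n_disc = sum(mask.is_channel_discarded(c) for c in mask.channel_ids)
        logger.info("%s: %d (channel,block) pairs rejected, %d channels "
                    "discarded", rec.subject_id, n_rej, n_disc)
        epoch_sets.append(epochs)
        masks.append(mask)

    sc = config.stats
    rng = np.random.default_rng(config.master_seed + 1)
    seeds = iter(int(s) for s in rng.integers(0, 2**31 - 1, size=16))
    cluster_frames = []
    resp = {}
    for chrom in ("oxy", "deoxy"):
        resp[chrom] = cl.condition_means(
            epoch_sets, chromophore=chrom, window_s=sc.window_s,
            channel_ids=probe.channel_ids,
            subjects=[r.subject_id for r in recs],
        )
        anova = cl.permutation_test(
            resp[chrom], probe, threshold=sc.threshold, n_perm=sc.n_perm,
            seed=next(seeds), cluster_alpha=sc.cluster_alpha,
        )
        frames = [cl.clusters_to_frame(anova)]
        names = [c.value for c in CONDITIONS]
        for a, b in [(names[0], names[1]), (names[0], names[2]),
                     (names[1], names[2])]:
            frames.append(cl.clusters_to_frame(cl.pairwise_followup(
                resp[chrom], a, b, probe, threshold=sc.threshold,
                n_perm=sc.n_perm, seed=next(seeds),
                cluster_alpha=sc.cluster_alpha,
            )))
        base = cl.vs_baseline_test(
            resp[chrom], probe, threshold=sc.threshold, n_perm=sc.n_perm,
            seed=next(seeds), cluster_alpha=sc.cluster_alpha,
        )
        for res in base.values():
            frames.append(cl.clusters_to_frame(res))
        nonempty = [f for f in frames if len(f)]
        tab = (pd.concat(nonempty, ignore_index=True) if nonempty
               else frames[0])
        tab.insert(1, "chromophore", chrom)
        cluster_frames.append(tab)
    clusters = pd.concat(cluster_frames, ignore_index=True)

    ga = _grand_averages(epoch_sets, probe.channel_ids)
    counts = {
        "n_subjects": len(recs),
        "n_channels": len(probe.channel_ids),
        "rejected_pairs": int(sum((~m.valid).sum() for m in masks)),
        "discarded_channels": int(sum(
            sum(m.is_channel_discarded(c) for c in m.channel_ids)
            for m in masks
        )),
        "n_perm": sc.n_perm,
        "master_seed": config.master_seed,
    }
    report = ReportSummary(grand_averages=ga, clusters=clusters,
                           counts=counts, config=config)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
        ga.to_csv(out / "grand_averages.tsv", sep="\t", index=False)
        logger.info("report written to %s", out)
    return report
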