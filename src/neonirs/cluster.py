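"""Spatial cluster-based permutation inference over channel responses.

The unit of analysis is the per-subject mean Hb change in the 0–15 s window
after block onset, per channel and condition.  A channelwise statistic
(repeated-measures F across the three conditions, paired t for follow-up
contrasts, or one-sample t against baseline) is thresholded at its parametric
95th percentile; suprathreshold channels are grouped into clusters connected
under the probe's adjacency, and each cluster's mass (summed statistic) is
referred to a max-cluster-mass null distribution built by permuting condition
labels *within subjects* — whole condition vectors are exchanged per subject,
so within-subject correlation (and hence the autocorrelation of the
hemodynamic response that the window means inherit) is preserved under the
null.  p-values use the add-one estimator (1 + #{null >= observed}) /
(1 + n_perm), so the smallest attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .preprocess import EpochSet
from .simulate import CONDITIONS, ProbeLayout

__all__ = [
    "SubjectConditionResponse",
    "ClusterResult",
    "condition_means",
    "channel_F",
    "channel_paired_t",
    "rm_anova_F_map",
    "form_clusters",
    "permutation_test",
    "pairwise_followup",
    "vs_baseline_test",
]

_COND_NAMES = tuple(c.value for c in CONDITIONS)


@dataclass
class SubjectConditionResponse:
    """Window-mean responses: (subject, channel, condition) → mmol×mm.

    Missing cells (channel discarded for a subject, or no valid blocks in a
    condition) are NaN and tracked via ``n_blocks_used``.
    """

    values: np.ndarray        # (n_subjects, n_channels, n_conditions)
    subjects: list[str]
    channel_ids: list[int]
    conditions: list[str]
    n_blocks_used: np.ndarray  # same shape, int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.subjects), len(self.channel_ids),
                    len(self.conditions))
        if self.values.shape != expected:
            raise ValueError("response array shape mismatch")

    @property
    def complete(self) -> np.ndarray:
        """(n_subjects, n_channels) bool: subject has all conditions there."""
        return np.isfinite(self.values).all(axis=2)

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)


@dataclass
class ClusterResult:
    """An adjacency-connected set of suprathreshold channels."""

    channels: frozenset[int]
    statistic: float          # cluster mass (sum of channel statistics)
    p_value: float | None = None
    contrast: str = ""


# ---------------------------------------------------------------------------
# window means
# ---------------------------------------------------------------------------

def condition_means(
    epoch_sets: Sequence[EpochSet],
    chromophore: str = "oxy",
    window_s: tuple[float, float] = (0.0, 15.0),
    channel_ids: Sequence[int] | None = None,
    subjects: Sequence[str] | None = None,
    conditions: Sequence[str] = _COND_NAMES,
) -> SubjectConditionResponse:
    """Average each subject's valid epochs over the analysis window.

    Per (subject, channel, condition): the mean over ``window_s`` of every
    valid epoch of that condition, then the mean across those blocks.  Cells
    with zero valid blocks are NaN (missing) with ``n_blocks_used == 0``.
    """
    lo, hi = window_s
    if not hi > lo:
        raise ValueError(f"empty analysis window {window_s}")
    if channel_ids is None:
        ids: list[int] = sorted(
            set().union(*[set(es.meta["channel_id"]) for es in epoch_sets])
        )
    else:
        ids = list(channel_ids)
    subjects = list(subjects) if subjects is not None else [
        f"sub-{i + 1:02d}" for i in range(len(epoch_sets))
    ]
    conditions = list(conditions)
    shape = (len(epoch_sets), len(ids), len(conditions))
    values = np.full(shape, np.nan)
    n_used = np.zeros(shape, dtype=int)
    for s, es in enumerate(epoch_sets):
        data = es.chromophore(chromophore)
        sel_t = (es.times >= lo) & (es.times <= hi)
        if not sel_t.any():
            raise ValueError("analysis window outside epoch time axis")
        epoch_means = np.nanmean(data[:, sel_t], axis=1)
        meta = es.meta
        for ci, cid in enumerate(ids):
            for ki, cond in enumerate(conditions):
                rows = (meta["channel_id"] == cid) & (meta["condition"] == cond)
                m = epoch_means[rows.to_numpy()]
                if m.size:
                    values[s, ci, ki] = m.mean()
                    n_used[s, ci, ki] = m.size
    return SubjectConditionResponse(values, subjects, ids, conditions, n_used)


# ---------------------------------------------------------------------------
# channel statistics
# ---------------------------------------------------------------------------

def _rm_anova_F(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F, vectorized.

    ``v``: (..., n_subjects, n_channels, k) values with missing entries
    zeroed; ``w``: (n_subjects, n_channels) inclusion weights (a subject
    counts on a channel only with a complete condition k-tuple).  Channels
    with fewer than 2 complete subjects yield NaN.
    """
    k = v.shape[-1]
    n = w.sum(axis=0)                                    # (n_channels,)
    with np.errstate(invalid="ignore", divide="ignore"):
        wv = v * w[..., :, :, None]
        mean_cond = wv.sum(axis=-3) / n[..., :, None]    # (..., C, k)
        mean_subj = v.mean(axis=-1)                      # (..., S, C)
        grand = mean_cond.mean(axis=-1)                  # (..., C)
        ss_cond = n * ((mean_cond - grand[..., None]) ** 2).sum(axis=-1)
        dev_subj = (mean_subj - grand[..., None, :]) * w
        ss_subj = k * (dev_subj**2).sum(axis=-2)
        dev_tot = (v - grand[..., None, :, None]) * w[..., :, :, None]
        ss_tot = (dev_tot**2).sum(axis=(-3, -1))
        ss_err = ss_tot - ss_cond - ss_subj
        ss_err = np.maximum(ss_err, 0.0)
        df1 = k - 1
        df2 = df1 * (n - 1)
        f = (ss_cond / df1) / (ss_err / df2)
        f = np.where(ss_err == 0, np.where(ss_cond == 0, 0.0, np.inf), f)
    return np.where(n >= 2, f, np.nan)


def rm_anova_F_map(resp: SubjectConditionResponse) -> np.ndarray:
    """Repeated-measures F per channel, with pairwise subject deletion."""
    w = resp.complete.astype(float)
    v = np.nan_to_num(resp.values, nan=0.0)
    return _rm_anova_F(v, w)


def channel_F(resp: SubjectConditionResponse, channel_id: int) -> float:
    """One-way repeated-measures F (3 condition levels) for one channel;
    NaN if fewer than 2 subjects have complete condition triples there."""
    i = resp.channel_ids.index(channel_id)
    return float(rm_anova_F_map(resp)[i])


def _paired_t(d: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Paired/one-sample t, vectorized; ``d``: (..., S, C) differences with
    missing entries zeroed, ``w``: (S, C) inclusion weights.  Zero-variance
    channels: t = 0 when the mean is also 0, ±inf otherwise (flagged, never a
    crash); fewer than 2 subjects → NaN.
    """
    n = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = (d * w).sum(axis=-2) / n
        dev = (d - mean[..., None, :]) * w
        var = (dev**2).sum(axis=-2) / (n - 1)
        t = mean / np.sqrt(var / n)
        t = np.where(var == 0, np.where(mean == 0, 0.0, np.inf * np.sign(mean)), t)
    return np.where(n >= 2, t, np.nan)


def channel_paired_t(
    resp: SubjectConditionResponse, condition_a: str, condition_b: str
) -> np.ndarray:
    """Paired t (a − b) across subjects, per channel."""
    a = resp.values[:, :, resp.condition_index(condition_a)]
    b = resp.values[:, :, resp.condition_index(condition_b)]
    d = a - b
    w = np.isfinite(d).astype(float)
    return _paired_t(np.nan_to_num(d, nan=0.0), w)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _components(nodes: set[int], adjacency: Mapping[int, Iterable[int]]):
    """Connected components of ``nodes`` under ``adjacency`` (BFS)."""
    remaining = set(nodes)
    while remaining:
        seed_node = remaining.pop()
        comp = {seed_node}
        frontier = [seed_node]
        while frontier:
            nxt = []
            for u in frontier:
                for vtx in adjacency.get(u, ()):  # neighbors outside stay out
                    if vtx in remaining:
                        remaining.remove(vtx)
                        comp.add(vtx)
                        nxt.append(vtx)
            frontier = nxt
        yield comp


def form_clusters(
    stat_map: Mapping[int, float],
    threshold: float | Mapping[int, float],
    adjacency: Mapping[int, Iterable[int]],
    signed: bool = False,
) -> list[ClusterResult]:
    """Partition suprathreshold channels into adjacency-connected clusters.

    ``stat_map`` maps channel id → statistic (NaN = excluded).  With
    ``signed=True`` (t maps) channels exceed when |t| > threshold and
    positive/negative channels cluster separately; masses keep their sign.
    Singleton clusters are allowed.  Thresholds may be per-channel.
    """
    def thr(ch: int) -> float:
        return threshold[ch] if isinstance(threshold, Mapping) else threshold

    clusters: list[ClusterResult] = []
    # NaN marks an excluded channel; ±inf (zero-variance flags) still cluster
    if signed:
        groups = [
            {ch for ch, v in stat_map.items()
             if not np.isnan(v) and v > thr(ch)},
            {ch for ch, v in stat_map.items()
             if not np.isnan(v) and v < -thr(ch)},
        ]
    else:
        groups = [
            {ch for ch, v in stat_map.items()
             if not np.isnan(v) and v > thr(ch)}
        ]
    for grp in groups:
        for comp in _components(grp, adjacency):
            mass = float(sum(stat_map[ch] for ch in comp))
            clusters.append(ClusterResult(frozenset(comp), mass))
    clusters.sort(key=lambda c: -abs(c.statistic))
    return clusters


def _cluster_masses(
    stats_arr: np.ndarray,
    channel_ids: Sequence[int],
    threshold: np.ndarray,
    adjacency: Mapping[int, Iterable[int]],
    signed: bool,
) -> float:
    """Max |cluster mass| for one permuted statistic map (0 if none)."""
    smap = dict(zip(channel_ids, stats_arr))
    thr = dict(zip(channel_ids, threshold))
    cl = form_clusters(smap, thr, adjacency, signed=signed)
    return max((abs(c.statistic) for c in cl), default=0.0)


def _parametric_threshold_F(resp: SubjectConditionResponse,
                            alpha: float = 0.05) -> np.ndarray:
    """Per-channel F critical value at ``alpha`` (df from complete subjects)."""
    k = len(resp.conditions)
    n = resp.complete.sum(axis=0)
    with np.errstate(invalid="ignore"):
        crit = spstats.f.ppf(1 - alpha, k - 1, (k - 1) * np.maximum(n - 1, 1))
    return np.where(n >= 2, crit, np.inf)


def _parametric_threshold_t(n: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Per-channel two-sided |t| critical value at ``alpha``."""
    with np.errstate(invalid="ignore"):
        crit = spstats.t.ppf(1 - alpha / 2, np.maximum(n - 1, 1))
    return np.where(n >= 2, crit, np.inf)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _adjacency_from(probe_or_adj) -> Mapping[int, Iterable[int]]:
    if isinstance(probe_or_adj, ProbeLayout):
        return probe_or_adj.adjacency
    return probe_or_adj


def permutation_test(
    resp: SubjectConditionResponse,
    adjacency,
    threshold: float | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    _chunk: int = 1000,
) -> list[ClusterResult]:
    """ANOVA-based cluster permutation test for a main effect of condition.

    The null distribution is the maximum cluster mass over ``n_perm``
    permutations that shuffle the condition labels independently within each
    subject (whole condition-mean vectors are exchanged, preserving the
    within-subject correlation structure).  The same per-subject relabeling
    applies to every channel, preserving spatial structure too.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    adjacency = _adjacency_from(adjacency)
    k = len(resp.conditions)
    if resp.complete.sum(axis=0).max() < 2 or k < 2:
        raise ValueError("fewer than 2 realizable permutations")
    w = resp.complete.astype(float)
    v = np.nan_to_num(resp.values, nan=0.0)
    thr = (_parametric_threshold_F(resp, cluster_alpha)
           if threshold is None else np.full(len(resp.channel_ids), threshold))

    observed_map = _rm_anova_F(v, w)
    observed = form_clusters(
        dict(zip(resp.channel_ids, observed_map)),
        dict(zip(resp.channel_ids, thr)),
        adjacency,
    )

    rng = np.random.default_rng(seed)
    n_subj = len(resp.subjects)
    null = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(_chunk, n_perm - done)
        # (m, S, k): an independent uniform permutation of labels per subject
        idx = np.argsort(rng.random((m, n_subj, k)), axis=-1)
        vp = np.take_along_axis(
            np.broadcast_to(v, (m, *v.shape)), idx[:, :, None, :], axis=-1
        )
        fmaps = _rm_anova_F(vp, w)  # (m, n_channels)
        for j in range(m):
            null[done + j] = _cluster_masses(
                fmaps[j], resp.channel_ids, thr, adjacency, signed=False
            )
        done += m

    for cl in observed:
        cl.p_value = float(
            (1 + np.sum(null >= abs(cl.statistic))) / (1 + n_perm)
        )
        cl.contrast = "anova"
    return observed


def _sign_flip_test(
    d: np.ndarray,
    resp: SubjectConditionResponse,
    adjacency,
    threshold: float | None,
    n_perm: int,
    seed: int,
    cluster_alpha: float,
    contrast: str,
) -> list[ClusterResult]:
    """Shared machinery for paired and vs-baseline tests: within-subject sign
    flips of the per-subject difference/response ``d`` (n_subjects ×
    n_channels, NaN = missing)."""
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    adjacency = _adjacency_from(adjacency)
    w = np.isfinite(d).astype(float)
    if w.sum(axis=0).max() < 2:
        raise ValueError("fewer than 2 realizable permutations")
    dv = np.nan_to_num(d, nan=0.0)
    thr = (_parametric_threshold_t(w.sum(axis=0), cluster_alpha)
           if threshold is None else np.full(d.shape[1], threshold))

    # _paired_t expects (..., S, C); treat the channel axis as C
    observed_map = _paired_t(dv, w)
    observed = form_clusters(
        dict(zip(resp.channel_ids, observed_map)),
        dict(zip(resp.channel_ids, thr)),
        adjacency, signed=True,
    )

    rng = np.random.default_rng(seed)
    n_subj = d.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null = np.empty(n_perm)
    tmaps = _paired_t(signs[:, :, None] * dv, w)  # (n_perm, n_channels)
    for j in range(n_perm):
        null[j] = _cluster_masses(
            tmaps[j], resp.channel_ids, thr, adjacency, signed=True
        )
    for cl in observed:
        cl.p_value = float((1 + np.sum(null >= abs(cl.statistic))) / (1 + n_perm))
        cl.contrast = contrast
    return observed


def pairwise_followup(
    resp: SubjectConditionResponse,
    condition_a: str,
    condition_b: str,
    adjacency,
    threshold: float | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> list[ClusterResult]:
    """Follow-up pairwise contrast: paired t per channel, clusters signed
    (positive mass = a > b), null via within-subject sign flips (the 2^n
    exchangeable relabelings of a paired design)."""
    a = resp.values[:, :, resp.condition_index(condition_a)]
    b = resp.values[:, :, resp.condition_index(condition_b)]
    return _sign_flip_test(
        a - b, resp, adjacency, threshold, n_perm, seed, cluster_alpha,
        contrast=f"{condition_a}>{condition_b}",
    )


def vs_baseline_test(
    resp: SubjectConditionResponse,
    adjacency,
    threshold: float | None = None,
    n_perm: int = 5000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> dict[str, list[ClusterResult]]:
    """One-sample t of each condition's (baselined) response against zero,
    per condition, with sign-flip nulls."""
    out: dict[str, list[ClusterResult]] = {}
    rng = np.random.default_rng(seed)
    for cond in resp.conditions:
        d = resp.values[:, :, resp.condition_index(cond)]
        out[cond] = _sign_flip_test(
            d, resp, adjacency, threshold, n_perm,
            int(rng.integers(0, 2**31 - 1)), cluster_alpha,
            contrast=f"{cond}>baseline",
        )
    return out


def clusters_to_frame(clusters: Iterable[ClusterResult]) -> pd.DataFrame:
    rows = [
        dict(
            contrast=c.contrast,
            channels=",".join(str(ch) for ch in sorted(c.channels)),
            mass=c.statistic,
            p_value=c.p_value,
        )
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["contrast", "channels", "mass", "p_value"])
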