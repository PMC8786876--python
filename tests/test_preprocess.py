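"""Filtering, artifact rejection, channel exclusion, epoching, baselining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neonirs as nn
from neonirs import preprocess as pp
from conftest import make_flat_recording


def _sine_recording(probe, freq, amp=1.0, fs=10.4):
    rec = make_flat_recording(probe, fs=fs)
    t = rec.times
    sig = amp * np.sin(2 * np.pi * freq * t)
    rec.oxy[:] = sig
    rec.deoxy[:] = sig
    return rec


# ---------------------------------------------------------------------------
# band-pass filtering
# ---------------------------------------------------------------------------

def _amplitude_ratio(rec_in, rec_out, freq):
    spec_in = np.abs(np.fft.rfft(rec_in.oxy[0]))
    spec_out = np.abs(np.fft.rfft(rec_out.oxy[0]))
    k = np.argmin(np.abs(
        np.fft.rfftfreq(rec_in.n_samples, 1 / rec_in.sampling_rate_hz) - freq
    ))
    return spec_out[k] / spec_in[k]


def test_out_of_band_cardiac_attenuated_at_least_20db(probe):
    rec = _sine_recording(probe, 2.5)
    ratio = _amplitude_ratio(rec, pp.bandpass(rec), 2.5)
    assert 20 * np.log10(ratio) <= -20


def test_in_band_sinusoid_preserved_within_5pct(probe):
    rec = _sine_recording(probe, 0.1)
    ratio = _amplitude_ratio(rec, pp.bandpass(rec), 0.1)
    assert ratio == pytest.approx(1.0, abs=0.05)


def test_constant_signal_rejected_as_dc(probe):
    rec = make_flat_recording(probe, value=0.5)
    out = pp.bandpass(rec)
    assert np.abs(out.oxy).max() < 1e-6


def test_bandpass_preserves_length_and_validates(probe, flat_recording):
    out = pp.bandpass(flat_recording)
    assert out.oxy.shape == flat_recording.oxy.shape
    with pytest.raises(ValueError, match="cutoff"):
        pp.bandpass(flat_recording, low_hz=0.7, high_hz=0.01)
    bad = make_flat_recording(probe)
    bad.oxy[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        pp.bandpass(bad)


# ---------------------------------------------------------------------------
# motion-artifact detection
# ---------------------------------------------------------------------------

def test_single_injected_step_flags_exactly_one_pair(probe):
    rec = make_flat_recording(probe)
    fs = rec.sampling_rate_hz
    onset = rec.blocks.loc[3, "onset_s"]
    i = int((onset + 5.0) * fs)
    ch = rec.channel_ids.index(7)
    rec.oxy[ch, i:] += 0.2  # supra-threshold step inside block 3, channel 7
    mask = pp.detect_motion_artifacts(rec)
    assert not mask.valid[ch, 3]
    assert mask.reasons[ch, 3] == pp.Reason.MOTION_ARTIFACT.value
    expected = np.ones_like(mask.valid)
    expected[ch, 3] = False
    np.testing.assert_array_equal(mask.valid, expected)


def test_infinite_threshold_keeps_everything(probe):
    rec = make_flat_recording(probe)
    rec.oxy += np.random.default_rng(0).normal(0, 1.0, rec.oxy.shape)
    mask = pp.detect_motion_artifacts(rec, threshold_mmolmm=np.inf)
    assert mask.valid.all()


def test_artifact_window_is_two_samples_at_10p4hz(probe):
    rec = make_flat_recording(probe, fs=10.4)
    fs = rec.sampling_rate_hz
    assert int(np.floor(0.2 * fs)) == 2
    # a ramp that moves 0.08 per sample: one-sample change is sub-threshold,
    # the two-sample change (0.16) exceeds 0.1
    onset = rec.blocks.loc[0, "onset_s"]
    i = int((onset + 5.0) * fs)
    rec.oxy[0, i] += 0.08
    rec.oxy[0, i + 1 :] += 0.16
    mask = pp.detect_motion_artifacts(rec)
    assert not mask.valid[0, 0]


def test_flags_match_naive_scan_on_simulated_spikes(small_schedule, probe):
    """Vectorized detector equals an independent sample-by-sample scan, and
    attains 100% recall on ground-truth spikes landing inside blocks."""
    noise = nn.NoiseParams(drift_sd=0, white_sd=0, cardiac_amp=0,
                           motion_spike_rate_per_min=4.0,
                           motion_spike_amp_range=(0.3, 1.0))
    rec = nn.simulate_session(small_schedule, probe,
                              effects=nn.EffectMap.null(probe),
                              noise=noise, seed=8)
    mask = pp.detect_motion_artifacts(rec)
    fs = rec.sampling_rate_hz
    k = 2
    for ci in range(len(rec.channel_ids)):
        for b, row in rec.blocks.iterrows():
            i0 = int(np.floor(row.onset_s * fs))
            i1 = int(np.ceil((row.onset_s + row.duration_s) * fs)) + 1
            bad = False
            for chrom in (rec.oxy, rec.deoxy):
                x = chrom[ci, i0:i1]
                for t in range(len(x) - k):
                    if abs(x[t + k] - x[t]) > 0.1:
                        bad = True
            assert mask.valid[ci, b] == (not bad)
    # recall: every spike whose onset falls inside a block is flagged
    for sp in rec.ground_truth.motion_spikes:
        ci = rec.channel_ids.index(sp.channel_id)
        for b, row in rec.blocks.iterrows():
            if row.onset_s <= sp.time_s <= row.onset_s + row.duration_s - 3 / fs:
                assert not mask.valid[ci, b]


def test_block_past_recording_end_raises(probe):
    rec = make_flat_recording(probe)
    rec.blocks.loc[len(rec.blocks)] = [99, rec.times[-1] + 100, 15.0,
                                       "Echoing"]
    with pytest.raises(ValueError, match="past"):
        pp.detect_motion_artifacts(rec)


# ---------------------------------------------------------------------------
# channel exclusion
# ---------------------------------------------------------------------------

def _mask_with_counts(n_valid_per_cond, n_blocks_per_cond=14):
    """Channel 0 valid in n_valid_per_cond[c] blocks of condition c; channel
    1 fully valid."""
    conds = []
    for c in nn.CONDITIONS:
        conds += [c.value] * n_blocks_per_cond
    mask = pp.ValidityMask.all_valid([1, 2], conds)
    for ci, cond in enumerate(nn.CONDITIONS):
        sel = [i for i, x in enumerate(conds) if x == cond.value]
        for i in sel[n_valid_per_cond[ci]:]:
            mask.valid[0, i] = False
            mask.reasons[0, i] = pp.Reason.MOTION_ARTIFACT.value
    return mask


def test_half_blocks_boundary_7_retained_6_discarded():
    kept = pp.discard_channels(_mask_with_counts([7, 7, 7]))
    assert not kept.is_channel_discarded(1)   # 7 of 14 is not < half
    dropped = pp.discard_channels(_mask_with_counts([14, 14, 6]))
    assert dropped.is_channel_discarded(1)    # 6 of 14 Echoing blocks
    assert not dropped.valid[0].any()
    assert dropped.valid[1].all()


@given(st.data())
@settings(deadline=None, max_examples=40, derandomize=True)
def test_discard_matches_brute_force_counting(data):
    n_per = 4
    conds = [c.value for c in nn.CONDITIONS] * n_per
    n_blocks = len(conds)
    valid = data.draw(st.lists(
        st.lists(st.booleans(), min_size=n_blocks, max_size=n_blocks),
        min_size=3, max_size=3,
    ))
    mask = pp.ValidityMask.all_valid([1, 2, 3], conds)
    mask.valid = np.array(valid)
    mask.reasons = np.where(mask.valid, pp.Reason.OK.value,
                            pp.Reason.MOTION_ARTIFACT.value).astype(object)
    out = pp.discard_channels(mask)
    for i in range(3):
        should_drop = any(
            sum(valid[i][b] for b in range(n_blocks)
                if conds[b] == cond.value) < n_per / 2
            for cond in nn.CONDITIONS
        )
        assert out.is_channel_discarded(i + 1) == should_drop
        if should_drop:
            assert not out.valid[i].any()
        else:
            np.testing.assert_array_equal(out.valid[i], mask.valid[i])


def test_discard_is_idempotent():
    m1 = pp.discard_channels(_mask_with_counts([14, 5, 9]))
    m2 = pp.discard_channels(m1)
    np.testing.assert_array_equal(m1.valid, m2.valid)
    assert (m1.reasons == m2.reasons).all()


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def test_epoch_counts_and_time_axis(flat_recording):
    epochs = pp.extract_epochs(flat_recording)
    n_blocks = len(flat_recording.blocks)
    assert len(epochs.meta) == n_blocks * 24
    assert epochs.times[0] == pytest.approx(-5.0)
    assert epochs.times.max() >= 15.0
    onset_idx = np.argmin(np.abs(epochs.times))
    assert epochs.times[onset_idx] == pytest.approx(0.0, abs=1e-9)


def test_rejected_pairs_absent_from_epochs(flat_recording):
    mask = pp.ValidityMask.all_valid(
        flat_recording.channel_ids, list(flat_recording.blocks["condition"])
    )
    mask.valid[3, 1] = False
    mask.valid[10, 4] = False
    epochs = pp.extract_epochs(flat_recording, mask)
    present = set(zip(epochs.meta["channel_id"], epochs.meta["block_index"]))
    all_pairs = {(cid, b) for cid in flat_recording.channel_ids
                 for b in range(len(flat_recording.blocks))}
    dropped = {(flat_recording.channel_ids[3], 1),
               (flat_recording.channel_ids[10], 4)}
    assert all_pairs - present == dropped


def test_epoch_before_recording_start_raises(probe):
    rec = make_flat_recording(probe, start=2.0)  # pre-window needs 5 s
    with pytest.raises(ValueError, match="precedes"):
        pp.extract_epochs(rec)
    padded = pp.extract_epochs(rec, pad=True)
    assert np.isnan(padded.oxy[0, 0])


# ---------------------------------------------------------------------------
# baseline correction
# ---------------------------------------------------------------------------

def test_exact_line_is_fully_removed(flat_recording):
    rec = flat_recording
    tt = rec.times
    rec.oxy[:] = 0.003 * tt - 0.2
    rec.deoxy[:] = -0.001 * tt + 0.05
    out = pp.baseline_correct(pp.extract_epochs(rec))
    np.testing.assert_allclose(out.oxy, 0.0, atol=1e-10)
    np.testing.assert_allclose(out.deoxy, 0.0, atol=1e-10)
    assert out.baselined


def test_line_plus_boxcar_preserves_response(probe):
    rec = make_flat_recording(probe)
    fs = rec.sampling_rate_hz
    tt = rec.times
    rec.oxy[:] = 0.002 * tt + 0.1
    A = 0.08
    for _, row in rec.blocks.iterrows():
        i0 = int(round(row.onset_s * fs))
        i1 = int(round((row.onset_s + row.duration_s) * fs))
        rec.oxy[:, i0:i1] += A
    out = pp.baseline_correct(pp.extract_epochs(rec))
    t = out.times
    in_block = (t >= 1.0) & (t <= 14.0)
    pre = (t >= -5) & (t < 0)
    np.testing.assert_allclose(out.oxy[:, in_block], A, atol=1e-9)
    np.testing.assert_allclose(out.oxy[:, pre], 0.0, atol=1e-9)
    # coefficients recover the injected line
    slopes = out.baseline_coeffs["oxy"][:, 0]
    np.testing.assert_allclose(slopes, 0.002, atol=1e-9)


def test_baseline_support_skips_settling_window(probe, flat_recording):
    """Garbage confined to (block_end, block_end + 15 s) must not affect the
    fitted baseline."""
    rec = flat_recording
    fs = rec.sampling_rate_hz
    clean = pp.baseline_correct(pp.extract_epochs(rec))
    dirty_rec = make_flat_recording(probe)
    for _, row in rec.blocks.iterrows():
        end = row.onset_s + row.duration_s
        i0 = int(round((end + 0.5) * fs))
        i1 = int(round((end + 14.5) * fs))
        dirty_rec.oxy[:, i0:i1] = 50.0
    dirty = pp.baseline_correct(pp.extract_epochs(dirty_rec))
    np.testing.assert_allclose(dirty.baseline_coeffs["oxy"],
                               clean.baseline_coeffs["oxy"], atol=1e-12)


def test_baseline_matches_closed_form_least_squares(probe):
    rec = make_flat_recording(probe)
    rng = np.random.default_rng(0)
    rec.oxy += rng.normal(0, 0.01, rec.oxy.shape)
    epochs = pp.extract_epochs(rec)
    out = pp.baseline_correct(epochs)
    e = 5
    m = epochs.meta.iloc[e]
    support = pp._baseline_support(
        epochs.times, float(m.block_duration_s), float(m.next_gap_s),
        15.0, "offset",
    )
    coef = np.polyfit(epochs.times[support], epochs.oxy[e, support], 1)
    np.testing.assert_allclose(out.baseline_coeffs["oxy"][e], coef,
                               atol=1e-10)


def test_tiny_baseline_support_raises(probe):
    # ~1-sample pre window and ~1-sample post window: support < 4 samples
    rec = make_flat_recording(probe, silence=15.2)
    with pytest.raises(ValueError, match="fewer than 4"):
        pp.baseline_correct(pp.extract_epochs(rec, pre_s=0.1, post_s=15.3))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def test_full_chain_recovers_rectangular_amplitude_within_2pct(
        inventory, probe):
    """Noise-free rectangular responses survive filter + baseline with the
    plateau amplitude within 2% of ground truth."""
    sched = nn.compute_timeline(nn.build_schedule(inventory, seed=0),
                                seed=0, start_s=30.0)
    rec = nn.simulate_session(sched, probe, effects=nn.EffectMap.null(probe),
                              noise=nn.NoiseParams.silent(), seed=0)
    A = 0.08
    fs = rec.sampling_rate_hz
    for _, row in rec.blocks.iterrows():
        i0 = int(round(row.onset_s * fs))
        i1 = int(round((row.onset_s + row.duration_s) * fs))
        rec.oxy[:, i0:i1] += A
    rec.deoxy[:] = -rec.oxy / 3
    epochs, mask = pp.preprocess_session(rec)
    assert mask.valid.all()
    t = epochs.times
    plateau = (t >= 3.0) & (t <= 13.0)
    for cond in (c.value for c in nn.CONDITIONS):
        sel = (epochs.meta["condition"] == cond).to_numpy()
        m = epochs.oxy[sel].mean(axis=0)
        assert m[plateau].mean() == pytest.approx(A, rel=0.02)


def test_pipeline_respects_validity_mask_downstream(small_schedule, probe):
    noise = nn.NoiseParams(drift_sd=0, white_sd=0, cardiac_amp=0,
                           motion_spike_rate_per_min=6.0,
                           motion_spike_amp_range=(0.5, 1.0))
    rec = nn.simulate_session(small_schedule, probe,
                              effects=nn.EffectMap.null(probe),
                              noise=noise, seed=2)
    epochs, mask = pp.preprocess_session(rec, artifact_on="raw")
    invalid = {(mask.channel_ids[i], b)
               for i, b in zip(*np.nonzero(~mask.valid))}
    present = set(zip(epochs.meta["channel_id"], epochs.meta["block_index"]))
    assert invalid.isdisjoint(present)
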