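import numpy as np
import pandas as pd
import pytest

import neonirs as nn


@pytest.fixture(scope="session")
def probe():
    return nn.default_probe()


@pytest.fixture(scope="session")
def inventory():
    return nn.generate_token_inventory(seed=11)


@pytest.fixture(scope="session")
def schedule(inventory):
    """A full 42-block schedule with a computed timeline."""
    sched = nn.build_schedule(inventory, seed=11)
    return nn.compute_timeline(sched, seed=11)


@pytest.fixture(scope="session")
def small_design():
    """A shrunken block design for fast simulation tests: 2 blocks per
    condition, 2 pairs per block, short silences."""
    return nn.DesignParams(
        n_blocks_per_condition=2,
        pairs_per_block=2,
        inter_block_silence_range_s=(6.0, 7.0),
    )


@pytest.fixture(scope="session")
def small_schedule(inventory, small_design):
    sched = nn.build_schedule(inventory, small_design, seed=5)
    return nn.compute_timeline(sched, small_design, seed=5)


def make_flat_recording(probe, n_blocks=6, fs=10.4, block_dur=15.0,
                        silence=21.0, start=30.0, value=0.0):
    """A constant-valued recording with an evenly spaced block table,
    cycling through the three conditions."""
    conds = [c.value for c in nn.CONDITIONS]
    onsets = start + np.arange(n_blocks) * (block_dur + silence)
    blocks = pd.DataFrame(dict(
        block_index=np.arange(n_blocks),
        onset_s=onsets,
        duration_s=block_dur,
        condition=[conds[i % 3] for i in range(n_blocks)],
    ))
    n = int((onsets[-1] + block_dur + silence + 25.0) * fs)
    shape = (len(probe.channel_ids), n)
    return nn.SessionRecording(
        subject_id="flat",
        sampling_rate_hz=fs,
        channel_ids=list(probe.channel_ids),
        oxy=np.full(shape, float(value)),
        deoxy=np.full(shape, float(value)),
        events=pd.DataFrame(),
        blocks=blocks,
    )


@pytest.fixture
def flat_recording(probe):
    return make_flat_recording(probe)
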