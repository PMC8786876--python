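# Methods

## The experimental design being modeled

The pipeline targets a newborn auditory block design with three conditions
built from the same three-syllable ABB pseudowords (`s1 s2 s2`, `s1 ≠ s2`):
*Communicative* (two voices exchange different tokens in question–answer
rhythm), *Echoing* (the second voice repeats the first voice's token) and
*Single Speaker* (one voice per block, same temporal structure).  The
turn-taking percept is carried entirely by timing: 400 ms gaps inside a pair
versus 900–1100 ms between pairs.  A session is 42 blocks (14 per
condition), each of 5 pairs (10 utterances of 0.9 s each), so a block lasts
15 s at jitter midpoints; blocks are separated by 20–22 s silences so the
session totals ~25 min.  Hemodynamic responses are measured at 10.4 Hz over
24 channels (12 per hemisphere) in mmol×mm concentration-change units.

Design choices where the protocol leaves freedom:

- **Syllable inventory.** The full 140-token list is not published; the
  default inventory is the 11 CV syllables attested in published example
  tokens, extended with two more French-legal CV syllables to 13, so that
  13×12 = 156 ≥ 140 ABB tokens exist.  Configurable.
- **Interleaving rule.** "Pseudo-randomly interleaved" is implemented as a
  uniform shuffle of block labels, retried (bounded attempts) until no more
  than two consecutive blocks share a condition — standard block-design
  practice that keeps conditions locally balanced.
- **Voices.** Communicative/Echoing pairs always alternate voices, with the
  pair-opening voice balanced 50/50 per condition; Single Speaker blocks are
  exactly 7 female-only and 7 male-only in randomized order.
- **Echoed tokens.** The Echoing condition of one stimulus list uses a
  seeded random half (70) of the inventory, each token spoken twice;
  `build_schedule_pair` emits two lists with complementary halves so the two
  lists' Echoing conditions jointly cover the inventory.
- **Jitters** are uniform over their stated ranges.

## Synthetic data

`simulate_session` renders, per channel,

```
oxy(t)   = Σ_c a(ch, c) · (boxcar_c ⊛ h)(t) + drift + cardiac + white + spikes
deoxy(t) = r · Σ_c a(ch, c) · (boxcar_c ⊛ h)(t) + independent scaled noise
```

with `h` a double-gamma HRF (peak delay 5 s as an infant-appropriate
default, undershoot delay 12 s, dispersion 1 s, undershoot ratio 1/6),
normalized to unit sum so a sustained boxcar plateaus at the amplitude
`a(ch, c)`; `r = −1/3` mirrors the oxy response into deoxy.  Noise terms:

| parameter | default | meaning |
|---|---|---|
| `drift_sd` | 0.10 mmol×mm | integrated Gaussian walk, spectrally low-passed below `drift_cutoff_hz` = 0.01 Hz, rescaled to this sd |
| `cardiac_freq_hz`, `cardiac_amp` | 2.5 Hz, 0.02 | newborn heart rate (~150 bpm); above the 0.7 Hz analysis band, aliasing past the 5.2 Hz Nyquist is allowed, as in real acquisition |
| `white_sd` | 0.02 | broadband sensor noise |
| `motion_spike_rate_per_min` | 0.1 /channel | Poisson-timed exponential-decay excursions (τ = 0.5 s), amplitude 0.2–1.0 mmol×mm with random sign, hitting both chromophores |
| `deoxy_noise_scale` | 0.5 | deoxy noise amplitudes relative to oxy |

The default ground-truth effect map gives every channel a 0.06 mmol×mm
response to all conditions plus a 0.05 mmol×mm Communicative surplus on the
left fronto-temporal channels {1, 2, 4, 6}; cohorts add per-subject iid
Gaussian deviations (sd 0.02) to each (channel, condition) amplitude, and
each subject receives an independently seeded schedule randomization.  All
spike positions/amplitudes and per-subject amplitudes are stored in a
ground-truth sidecar.

**What the simulator does not emulate.** Probe geometry is a schematic
mirrored grid (only the shared-optode adjacency matters for clustering, not
metric positions).  Noise is stationary and Gaussian apart from spikes; real
data add Mayer waves, serial correlation beyond the drift model, and
heterogeneous per-channel coupling.  In particular, simulated deoxy is an
exact scaled mirror of oxy plus scaled noise, which leaves it relatively
more detectable than real newborn deoxy, where condition effects are
typically absent; the pipeline analyzes deoxy with identical machinery but
no claim of non-significance is built into the defaults.  Passing tests
therefore demonstrate correctness of the machinery and calibration under
the stated noise model, not performance on real recordings.

## Preprocessing

Fixed order, enforced by `preprocess_session`: band-pass → artifact
detection → channel exclusion → epoching → baselining.

- **Filter**: 3rd-order Butterworth 0.01–0.7 Hz, applied forward–backward
  (zero phase) per channel and chromophore.  The band keeps the block
  fundamental (~0.028 Hz) and rejects drift and cardiac components.
- **Artifact rule**: a (channel, block) is rejected when
  `|x[t+k] − x[t]| > 0.1 mmol×mm` anywhere inside the block for either
  chromophore, with `k = floor(0.2 s × fs)` (= 2 samples at 10.4 Hz).
  Detection runs on filtered data by default (`artifact_on="raw"`
  available).
- **Channel exclusion**: a channel goes entirely for a subject when any
  condition retains fewer than half of its blocks — 7 of 14 is kept, 6 of
  14 discarded.  Idempotent.
- **Epochs** span [−5 s, dur_max + 20 s] on a shared axis, onset = 0.
- **Baseline**: per-epoch least-squares line over [−5, 0) s plus the late
  post-block support, subtracted from the whole epoch.  The post-block
  support starts 15 s after block end (settling delay) and runs to one
  sample before the next onset; the "15 s after the end" phrasing could
  also be read as a 15 s-long window starting at block end, so a
  `baseline_post_mode="duration"` switch implements that reading, but the
  offset reading is the default — a 15 s window starting at block end would
  still contain most of the decaying response.  The one-sample guard below
  the next onset exists because block-onset rounding to the sample grid can
  otherwise leak the first stimulated sample into the fit.

On noise-free rectangular responses the full chain recovers the plateau
amplitude within 2%; the literal epoch maximum overshoots by ~4% because a
band-limited filter rings at discontinuities, so amplitude recovery is
asserted on the 3–13 s plateau mean.

## Statistics

The unit of analysis is the per-subject mean response over 0–15 s after
block onset, per channel and condition, averaged over that condition's valid
blocks.  Channel statistics: one-way repeated-measures F over the three
conditions (main effect), paired t (follow-ups), one-sample t versus zero
(baseline contrasts).  Channels missing a complete condition set for a
subject drop that subject pairwise; channels with < 2 complete subjects are
excluded (NaN).  Zero-variance t statistics are flagged as ±inf and still
cluster — they never crash the test.

Clusters are adjacency-connected components of suprathreshold channels
(singletons allowed; t maps cluster positive and negative channels
separately and keep signed masses).  The cluster-forming threshold defaults
to the parametric 95th percentile of the channel statistic (per-channel df);
it is a tuning constant of sensitivity, not of validity, and is
configurable.

The null distribution is the maximum |cluster mass| over permutations that
relabel conditions independently **within each subject** — whole
condition-mean vectors are exchanged, so within-subject correlation (and the
autocorrelation of the hemodynamic response that window means inherit) is
preserved; the same relabeling applies to all channels, preserving spatial
structure.  Pairwise and baseline contrasts use within-subject sign flips
(the 2^n exchangeable relabelings of a paired design).  p-values use the
add-one estimator `(1 + #{null ≥ obs}) / (1 + n_perm)`; default
`n_perm = 5000` resolves p < .001.

## Problem sizes used by the checks

- Permutation-test calibration: 500 null datasets at the
  subject×channel×condition response level (a shared per-subject-channel
  level plus independent condition noise — exchangeable by construction),
  n = 21, `n_perm = 500`.  Running 500 full time-series cohorts through the
  chain would add nothing to the exchangeability argument; the response
  level is where the permutation machinery operates.
- Exhaustive oracles: n = 5 subjects, all 6^5 = 7776 label arrangements
  (ANOVA) and 2^5 sign patterns (paired), agreement within 0.02.
- Effect recovery: 100 fully simulated 21-subject cohorts through the
  complete chain, `n_perm = 500`.
- Reproducibility: 3-subject pipeline runs, `n_perm = 150`, byte-identical
  report JSON.

## Known limitations

- No spline/wavelet motion correction or short-channel regression; rejection
  is the only artifact handling, as in the modeled protocol.
- Spatial-only clustering on window means; no channel×time clustering.
- No optical-density simulation or Beer–Lambert conversion: the pipeline
  lives entirely in concentration space.
- The SNIRF writer emits the standard processed-Hb layout
  (`/nirs/data1` with HbO/HbR measurement lists) sufficient for round-trip
  and third-party reading; acquisition metadata beyond the required tags is
  minimal.
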