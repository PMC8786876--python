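"""Stimulus inventory and block-schedule generation for a three-condition
turn-taking auditory experiment.

The design presents three-syllable ABB pseudowords (e.g. ``mufefe``) in
turn-taking pairs under three conditions:

* **Communicative** — two voices exchange *different* tokens (question–answer
  dynamics: female ABB — male CDD).
* **Echoing** — the second voice repeats the first voice's token verbatim.
* **SingleSpeaker** — the same temporal pair structure, but a single voice
  speaks throughout a block.

Blocks contain 5 pairs (10 utterances), 14 blocks per condition, 42 blocks in
total, separated by jittered 20–22 s silences.  Within-pair gaps are shorter
(400 ms) than between-pair gaps (900–1100 ms) so pairs sound like exchanges.

Tokens are 2×CV-syllable ABB items rendered at a monotonous 200 Hz pitch with
150 ms phonemes, expressible as MBROLA ``.pho`` files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Voice",
    "Syllable",
    "PseudowordToken",
    "TurnPair",
    "Block",
    "ExperimentSchedule",
    "DesignParams",
    "DEFAULT_SYLLABLES",
    "MBROLA_FR_PHONEMES",
    "generate_token_inventory",
    "build_schedule",
    "build_schedule_pair",
    "compute_timeline",
    "write_pho",
]


class Condition(str, Enum):
    COMMUNICATIVE = "Communicative"
    SINGLE_SPEAKER = "SingleSpeaker"
    ECHOING = "Echoing"


class Voice(str, Enum):
    FEMALE = "female"
    MALE = "male"


#: Default CV syllable inventory.  The first eleven are attested in published
#: example tokens ("mu-be-be", "mufefe", ...); "do" and "ti" extend the set to
#: 13 French-legal CV syllables so that 13x12 = 156 >= 140 ABB tokens exist.
DEFAULT_SYLLABLES: tuple[str, ...] = (
    "mu", "be", "ga", "ze", "pi", "pe", "na", "sa", "lu", "bi", "fe",
    "do", "ti",
)

#: French SAMPA phonemes accepted by the MBROLA fr3/fr4 voices (subset
#: sufficient for CV syllables built from the default inventory).
MBROLA_FR_PHONEMES: frozenset[str] = frozenset(
    "m b g z p n s l f d t k R v j w".split()
) | frozenset("a e i o u y E O 2 9 @".split())


@dataclass(frozen=True)
class Syllable:
    """A consonant+vowel syllable, e.g. ``mu``."""

    text: str

    def __post_init__(self) -> None:
        if not self.text or len(self.text) < 2:
            raise ValueError(f"syllable must be CV-shaped, got {self.text!r}")

    @property
    def phonemes(self) -> tuple[str, ...]:
        """Split into (consonant-cluster..., vowel); last char is the vowel."""
        return tuple(self.text[:-1]) + (self.text[-1],)


@dataclass(frozen=True)
class PseudowordToken:
    """A three-syllable ABB item: s1 s2 s2 with s1 != s2."""

    s1: Syllable
    s2: Syllable
    phoneme_duration_ms: float = 150.0
    pitch_hz: float = 200.0

    def __post_init__(self) -> None:
        if self.s1 == self.s2:
            raise ValueError("ABB structure requires s1 != s2")
        if self.phoneme_duration_ms <= 0 or self.pitch_hz <= 0:
            raise ValueError("phoneme duration and pitch must be positive")

    @property
    def text(self) -> str:
        return self.s1.text + self.s2.text + self.s2.text

    @property
    def phonemes(self) -> tuple[str, ...]:
        return self.s1.phonemes + self.s2.phonemes * 2

    @property
    def duration_ms(self) -> float:
        return len(self.phonemes) * self.phoneme_duration_ms


@dataclass
class TurnPair:
    """Two consecutive utterances forming one turn-taking exchange."""

    first_token: PseudowordToken
    second_token: PseudowordToken
    first_voice: Voice
    second_voice: Voice
    within_pair_gap_ms: float = 400.0

    @property
    def duration_ms(self) -> float:
        return (
            self.first_token.duration_ms
            + self.within_pair_gap_ms
            + self.second_token.duration_ms
        )


@dataclass
class Block:
    condition: Condition
    pairs: list[TurnPair]
    #: 4 jittered gaps (ms) separating the 5 pairs; filled by compute_timeline.
    between_pair_gaps_ms: list[float] | None = None

    def duration_s(self) -> float:
        if self.between_pair_gaps_ms is None:
            raise ValueError("timeline not computed: between-pair gaps unset")
        return (
            sum(p.duration_ms for p in self.pairs)
            + sum(self.between_pair_gaps_ms)
        ) / 1000.0

    def utterances(self) -> list[tuple[PseudowordToken, Voice, int]]:
        """(token, voice, pair_index) in presentation order."""
        out = []
        for i, p in enumerate(self.pairs):
            out.append((p.first_token, p.first_voice, i))
            out.append((p.second_token, p.second_voice, i))
        return out


@dataclass
class DesignParams:
    """Timing and structure of the block design (defaults follow the study)."""

    n_blocks_per_condition: int = 14
    pairs_per_block: int = 5
    phoneme_duration_ms: float = 150.0
    pitch_hz: float = 200.0
    within_pair_gap_ms: float = 400.0
    between_pair_gap_range_ms: tuple[float, float] = (900.0, 1100.0)
    inter_block_silence_range_s: tuple[float, float] = (20.0, 22.0)
    #: interleaving rule: at most this many consecutive same-condition blocks
    max_consecutive: int = 2
    max_interleave_attempts: int = 10_000


@dataclass
class ExperimentSchedule:
    blocks: list[Block]
    rng_seed: int
    #: silence (s) following each block; filled by compute_timeline
    inter_block_silences_s: list[float] | None = None
    #: absolute block onsets (s); filled by compute_timeline
    onsets_s: list[float] | None = None

    # -- structural queries -------------------------------------------------

    def blocks_of(self, condition: Condition) -> list[Block]:
        return [b for b in self.blocks if b.condition is condition]

    def block_durations_s(self) -> list[float]:
        return [b.duration_s() for b in self.blocks]

    def total_duration_s(self) -> float:
        if self.onsets_s is None or self.inter_block_silences_s is None:
            raise ValueError("timeline not computed")
        return (
            self.onsets_s[-1]
            + self.blocks[-1].duration_s()
            + self.inter_block_silences_s[-1]
        )

    # -- serialization ------------------------------------------------------

    def event_log(self) -> pd.DataFrame:
        """Flat utterance-level event table.

        Columns: onset_s, duration_s, condition, block_index, pair_index,
        voice, token.
        """
        if self.onsets_s is None:
            raise ValueError("timeline not computed")
        rows = []
        for bi, (block, onset) in enumerate(zip(self.blocks, self.onsets_s)):
            t = onset
            for pi, pair in enumerate(block.pairs):
                for token, voice in (
                    (pair.first_token, pair.first_voice),
                    (pair.second_token, pair.second_voice),
                ):
                    dur = token.duration_ms / 1000.0
                    rows.append(
                        dict(
                            onset_s=round(t, 6),
                            duration_s=round(dur, 6),
                            condition=block.condition.value,
                            block_index=bi,
                            pair_index=pi,
                            voice=voice.value,
                            token=token.text,
                        )
                    )
                    t += dur
                    if token is pair.first_token:
                        t += pair.within_pair_gap_ms / 1000.0
                if pi < len(block.pairs) - 1:
                    t += block.between_pair_gaps_ms[pi] / 1000.0
        return pd.DataFrame(rows)

    def block_table(self) -> pd.DataFrame:
        """Per-block onset/duration/condition table (for epoching)."""
        if self.onsets_s is None:
            raise ValueError("timeline not computed")
        return pd.DataFrame(
            dict(
                block_index=range(len(self.blocks)),
                onset_s=self.onsets_s,
                duration_s=self.block_durations_s(),
                condition=[b.condition.value for b in self.blocks],
            )
        )

    def to_json(self) -> str:
        def _tok(t: PseudowordToken) -> str:
            return t.text

        obj = {
            "rng_seed": self.rng_seed,
            "onsets_s": self.onsets_s,
            "inter_block_silences_s": self.inter_block_silences_s,
            "blocks": [
                {
                    "condition": b.condition.value,
                    "between_pair_gaps_ms": b.between_pair_gaps_ms,
                    "pairs": [
                        {
                            "first_token": _tok(p.first_token),
                            "second_token": _tok(p.second_token),
                            "first_voice": p.first_voice.value,
                            "second_voice": p.second_voice.value,
                            "within_pair_gap_ms": p.within_pair_gap_ms,
                        }
                        for p in b.pairs
                    ],
                }
                for b in self.blocks
            ],
        }
        return json.dumps(obj, sort_keys=True, indent=1)


# ---------------------------------------------------------------------------
# token inventory
# ---------------------------------------------------------------------------

def _as_syllables(inventory: Iterable[Syllable | str]) -> list[Syllable]:
    return [s if isinstance(s, Syllable) else Syllable(s) for s in inventory]


def generate_token_inventory(
    syllable_inventory: Sequence[Syllable | str] = DEFAULT_SYLLABLES,
    n_tokens: int = 140,
    seed: int = 0,
    phoneme_duration_ms: float = 150.0,
    pitch_hz: float = 200.0,
) -> list[PseudowordToken]:
    """Draw ``n_tokens`` distinct ABB pseudowords from a syllable inventory.

    The ABB space over *k* syllables has exactly ``k*(k-1)`` members (ordered
    pairs with s1 != s2); tokens are a seeded uniform sample without
    replacement from that space.
    """
    syls = _as_syllables(syllable_inventory)
    if len(set(s.text for s in syls)) != len(syls):
        raise ValueError("duplicate syllables in inventory")
    if len(syls) < 2:
        raise ValueError("need at least 2 syllables")
    space = [
        (a, b) for a in syls for b in syls if a != b
    ]
    if n_tokens > len(space):
        raise ValueError(
            f"requested {n_tokens} tokens but only {len(space)} ABB tokens "
            f"exist over {len(syls)} syllables"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(space))[:n_tokens]
    return [
        PseudowordToken(
            s1=space[i][0],
            s2=space[i][1],
            phoneme_duration_ms=phoneme_duration_ms,
            pitch_hz=pitch_hz,
        )
        for i in idx
    ]


# ---------------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------------

def _interleave_conditions(
    n_per_condition: int, max_consecutive: int, max_attempts: int,
    rng: np.random.Generator,
) -> list[Condition]:
    """Uniform shuffle of condition labels, retried until no run exceeds
    ``max_consecutive``."""
    labels = list(Condition) * n_per_condition
    for _ in range(max_attempts):
        order = [labels[i] for i in rng.permutation(len(labels))]
        run, ok = 1, True
        for a, b in zip(order, order[1:]):
            run = run + 1 if a is b else 1
            if run > max_consecutive:
                ok = False
                break
        if ok:
            return order
    raise RuntimeError(
        f"could not interleave conditions within {max_attempts} attempts"
    )


def _balanced_first_voices(n_pairs: int, rng: np.random.Generator) -> list[Voice]:
    """50/50-balanced pseudo-random pair-opening voices."""
    half = n_pairs // 2
    voices = [Voice.FEMALE] * half + [Voice.MALE] * (n_pairs - half)
    return [voices[i] for i in rng.permutation(n_pairs)]


def build_schedule(
    inventory: Sequence[PseudowordToken],
    design: DesignParams | None = None,
    seed: int = 0,
    echo_tokens: Sequence[PseudowordToken] | None = None,
) -> ExperimentSchedule:
    """Assemble the pseudo-randomized 42-block schedule.

    Token-usage contract: every inventory token is uttered exactly once in the
    Communicative condition and once in SingleSpeaker; the Echoing condition
    uses a seeded random half of the inventory (or ``echo_tokens``), each
    token uttered twice (spoken then echoed).

    Voice contract: Communicative and Echoing pairs alternate voices within
    the pair, with the pair-opening voice balanced 50/50 per condition;
    SingleSpeaker blocks use one voice each, half of them female-only and
    half male-only.
    """
    design = design or DesignParams()
    nb, npair = design.n_blocks_per_condition, design.pairs_per_block
    tokens_per_cond = nb * npair * 2
    if len(inventory) < tokens_per_cond:
        raise ValueError(
            f"inventory of {len(inventory)} tokens cannot fill "
            f"{tokens_per_cond} unique slots per condition"
        )
    if len(set(t.text for t in inventory)) != len(inventory):
        raise ValueError("inventory contains duplicate tokens")
    inventory = list(inventory)
    rng = np.random.default_rng(seed)

    order = _interleave_conditions(
        nb, design.max_consecutive, design.max_interleave_attempts, rng
    )

    def _chunk(seq: list, size: int) -> list[list]:
        return [seq[i : i + size] for i in range(0, len(seq), size)]

    # Communicative: all tokens once, pairs of two *different* tokens.
    comm_tokens = [inventory[i] for i in rng.permutation(len(inventory))]
    comm_chunks = _chunk(comm_tokens[:tokens_per_cond], npair * 2)
    comm_first = _balanced_first_voices(nb * npair, rng)

    # SingleSpeaker: all tokens once; 7 female-only + 7 male-only blocks.
    ss_tokens = [inventory[i] for i in rng.permutation(len(inventory))]
    ss_chunks = _chunk(ss_tokens[:tokens_per_cond], npair * 2)
    ss_voices = [Voice.FEMALE] * (nb // 2) + [Voice.MALE] * (nb - nb // 2)
    ss_voices = [ss_voices[i] for i in rng.permutation(nb)]

    # Echoing: half the inventory, each token spoken twice (token, token).
    n_echo = tokens_per_cond // 2
    if echo_tokens is None:
        echo_pool = [inventory[i] for i in rng.permutation(len(inventory))][:n_echo]
    else:
        if len(echo_tokens) != n_echo:
            raise ValueError(f"echo_tokens must contain {n_echo} tokens")
        echo_pool = [echo_tokens[i] for i in rng.permutation(n_echo)]
    echo_chunks = _chunk(echo_pool, npair)
    echo_first = _balanced_first_voices(nb * npair, rng)

    def _other(v: Voice) -> Voice:
        return Voice.MALE if v is Voice.FEMALE else Voice.FEMALE

    blocks: list[Block] = []
    ic = is_ = ie = 0  # per-condition block cursors
    for cond in order:
        pairs: list[TurnPair] = []
        if cond is Condition.COMMUNICATIVE:
            chunk = comm_chunks[ic]
            for k in range(npair):
                fv = comm_first[ic * npair + k]
                pairs.append(
                    TurnPair(
                        first_token=chunk[2 * k],
                        second_token=chunk[2 * k + 1],
                        first_voice=fv,
                        second_voice=_other(fv),
                        within_pair_gap_ms=design.within_pair_gap_ms,
                    )
                )
            ic += 1
        elif cond is Condition.SINGLE_SPEAKER:
            chunk = ss_chunks[is_]
            v = ss_voices[is_]
            for k in range(npair):
                pairs.append(
                    TurnPair(
                        first_token=chunk[2 * k],
                        second_token=chunk[2 * k + 1],
                        first_voice=v,
                        second_voice=v,
                        within_pair_gap_ms=design.within_pair_gap_ms,
                    )
                )
            is_ += 1
        else:
            chunk = echo_chunks[ie]
            for k in range(npair):
                fv = echo_first[ie * npair + k]
                pairs.append(
                    TurnPair(
                        first_token=chunk[k],
                        second_token=chunk[k],
                        first_voice=fv,
                        second_voice=_other(fv),
                        within_pair_gap_ms=design.within_pair_gap_ms,
                    )
                )
            ie += 1
        blocks.append(Block(condition=cond, pairs=pairs))
    return ExperimentSchedule(blocks=blocks, rng_seed=seed)


def build_schedule_pair(
    inventory: Sequence[PseudowordToken],
    design: DesignParams | None = None,
    seed: int = 0,
) -> tuple[ExperimentSchedule, ExperimentSchedule]:
    """Two stimulus lists whose Echoing halves are complementary, so the two
    lists' Echoing conditions jointly cover the full token inventory."""
    design = design or DesignParams()
    n_echo = design.n_blocks_per_condition * design.pairs_per_block
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(inventory))
    half_a = [inventory[i] for i in perm[:n_echo]]
    half_b = [inventory[i] for i in perm[n_echo : 2 * n_echo]]
    sub_a, sub_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    return (
        build_schedule(inventory, design, seed=sub_a, echo_tokens=half_a),
        build_schedule(inventory, design, seed=sub_b, echo_tokens=half_b),
    )


def compute_timeline(
    schedule: ExperimentSchedule,
    design: DesignParams | None = None,
    seed: int = 0,
    start_s: float = 10.0,
) -> ExperimentSchedule:
    """Draw jittered gaps/silences and fill absolute block onsets (in place).

    Between-pair gaps are uniform over ``between_pair_gap_range_ms`` and
    inter-block silences uniform over ``inter_block_silence_range_s``.  With
    jitters at midpoints, a default block lasts
    ``10*0.9 + 5*0.4 + 4*1.0 = 15.0 s`` and 42 blocks with 21 s silences give
    a ~25 min session.
    """
    design = design or DesignParams()
    g0, g1 = design.between_pair_gap_range_ms
    s0, s1 = design.inter_block_silence_range_s
    if g0 > g1 or s0 > s1:
        raise ValueError("inverted jitter range")
    if g0 < 0 or s0 < 0 or start_s < 0:
        raise ValueError("negative durations")
    rng = np.random.default_rng(seed)
    onsets, silences = [], []
    t = start_s
    for block in schedule.blocks:
        ngap = len(block.pairs) - 1
        block.between_pair_gaps_ms = [
            float(x) for x in rng.uniform(g0, g1, size=ngap)
        ]
        silence = float(rng.uniform(s0, s1))
        onsets.append(t)
        silences.append(silence)
        dur = block.duration_s()
        if dur <= 0:
            raise ValueError("non-positive block duration")
        t += dur + silence
    schedule.onsets_s = onsets
    schedule.inter_block_silences_s = silences
    return schedule


# ---------------------------------------------------------------------------
# MBROLA .pho output
# ---------------------------------------------------------------------------

def write_pho(
    token: PseudowordToken,
    out: IO[str],
    alphabet: frozenset[str] = MBROLA_FR_PHONEMES,
) -> None:
    """Emit an MBROLA ``.pho`` file for one token.

    One line per phoneme: ``<phoneme> <duration_ms> <pct> <pitch_hz>`` with a
    single mid-phoneme pitch anchor at the token's constant pitch.
    """
    phonemes = token.phonemes
    if not phonemes:
        raise ValueError("token has no phonemes")
    for ph in phonemes:
        if ph not in alphabet:
            raise ValueError(f"phoneme {ph!r} not in the configured alphabet")
    for ph in phonemes:
        out.write(f"{ph} {token.phoneme_duration_ms:g} 50 {token.pitch_hz:g}\n")
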