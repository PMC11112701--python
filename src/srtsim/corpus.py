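"""Synthetic BKB-like sentence corpus and two-talker masker assembly.

The Bamford-Kowal-Bench (BKB) corpus used for child speech testing contains
21 lists of 16 sentences; each sentence carries 3 or 4 scorable keywords and
every list totals exactly 50 keywords.  Because the sentence text is
copyrighted and no audio is processed here, sentences are represented
symbolically: a list id, a position, a keyword count and a nominal duration.

Lists 1-18 serve as target material; lists 19-21 are reserved for the two
masker streams (one stream = list 19 + the first half of list 20, the other =
the second half of list 20 + list 21), mirroring the standard partition used
when the same talker records both target and masker material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

N_LISTS = 21
SENTENCES_PER_LIST = 16
KEYWORDS_PER_LIST = 50
TARGET_LISTS = tuple(range(1, 19))
MASKER_LISTS = (19, 20, 21)

#: The only composition of 16 sentences with keyword counts in {3, 4}
#: summing to 50: fourteen 3-keyword and two 4-keyword sentences.
N_THREE_KEYWORD = 14
N_FOUR_KEYWORD = 2

#: Silent gaps between consecutive masker sentences are edited down to 200 ms.
MAX_GAP_S = 0.2


@dataclass(frozen=True)
class SentenceToken:
    """One symbolic target/masker sentence."""

    list_id: int
    index_in_list: int
    n_keywords: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.n_keywords not in (3, 4):
            raise ValueError(f"n_keywords must be 3 or 4, got {self.n_keywords}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class TalkerProfile:
    """A recorded talker: identity, familiarity role pool, and mean F0."""

    talker_id: str
    role_pool: str  # "mother_of_subject" or "unfamiliar"
    mean_f0_hz: float

    def __post_init__(self) -> None:
        if self.mean_f0_hz <= 0:
            raise ValueError("mean_f0_hz must be positive")


@dataclass(frozen=True)
class MaskerStream:
    """An ordered masker sentence stream with capped inter-sentence gaps."""

    talker_id: str
    tokens: tuple[SentenceToken, ...]
    gaps_s: tuple[float, ...]  # one gap after each token except the last

    @property
    def total_duration_s(self) -> float:
        return float(sum(t.duration_s for t in self.tokens) + sum(self.gaps_s))


Corpus = dict[int, list[SentenceToken]]


def generate_corpus(
    seed: int | np.random.Generator,
    duration_mean_s: float = 1.8,
    duration_sd_s: float = 0.3,
    duration_min_s: float = 1.0,
) -> Corpus:
    """Generate a synthetic 21-list corpus.

    Keyword counts per list follow the unique {3,4} composition of 50 over 16
    sentences (14 threes, 2 fours); the positions of the two 4-keyword
    sentences are randomized per list.  Durations are truncated-normal
    (re-drawn below ``duration_min_s``), a nominal stand-in since no audio is
    involved.
    """
    if duration_mean_s <= 0 or duration_sd_s < 0 or duration_min_s <= 0:
        raise ValueError("duration parameters must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    corpus: Corpus = {}
    for list_id in range(1, N_LISTS + 1):
        counts = np.full(SENTENCES_PER_LIST, 3, dtype=int)
        four_pos = rng.choice(SENTENCES_PER_LIST, size=N_FOUR_KEYWORD, replace=False)
        counts[four_pos] = 4
        sentences = []
        for idx in range(SENTENCES_PER_LIST):
            dur = rng.normal(duration_mean_s, duration_sd_s)
            while dur < duration_min_s:
                dur = rng.normal(duration_mean_s, duration_sd_s)
            sentences.append(
                SentenceToken(
                    list_id=list_id,
                    index_in_list=idx + 1,
                    n_keywords=int(counts[idx]),
                    duration_s=float(dur),
                )
            )
        corpus[list_id] = sentences
    return corpus


def build_masker_streams(
    corpus: Corpus,
    talker: TalkerProfile,
    rng: np.random.Generator | int | None = None,
    gap_mean_s: float = 0.15,
    gap_cap_s: float = MAX_GAP_S,
) -> tuple[MaskerStream, MaskerStream]:
    """Assemble the two equal-length masker streams from lists 19-21.

    Stream A = list 19 + sentences 1-8 of list 20; stream B = sentences 9-16
    of list 20 + list 21 (24 sentences each).  Inter-sentence silent gaps are
    drawn exponentially with mean ``gap_mean_s`` and edited down to
    ``gap_cap_s`` (200 ms), matching the manual pause-reduction step.
    """
    for lid in MASKER_LISTS:
        if lid not in corpus or len(corpus[lid]) != SENTENCES_PER_LIST:
            raise ValueError(f"corpus is missing masker list {lid}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    half = SENTENCES_PER_LIST // 2
    tokens_a = tuple(corpus[19]) + tuple(corpus[20][:half])
    tokens_b = tuple(corpus[20][half:]) + tuple(corpus[21])

    def _gaps(n_tokens: int) -> tuple[float, ...]:
        raw = rng.exponential(gap_mean_s, size=n_tokens - 1)
        return tuple(float(min(g, gap_cap_s)) for g in raw)

    stream_a = MaskerStream(talker.talker_id, tokens_a, _gaps(len(tokens_a)))
    stream_b = MaskerStream(talker.talker_id, tokens_b, _gaps(len(tokens_b)))
    return stream_a, stream_b


def assign_trial_lists(corpus: Corpus, start_list: int, n_trials: int) -> list[SentenceToken]:
    """Draw ``n_trials`` target sentences starting at ``start_list``.

    Sentences are consumed in numerical list order over the target lists
    (1-18), wrapping from 18 back to 1, and never reused within the returned
    sequence.  Exceeding the 288 available target sentences raises.
    """
    if start_list not in TARGET_LISTS:
        raise ValueError(f"start_list must be a target list 1-18, got {start_list}")
    n_available = len(TARGET_LISTS) * SENTENCES_PER_LIST
    if n_trials > n_available:
        raise ValueError(f"requested {n_trials} sentences but only {n_available} exist")
    order = [((start_list - 1 + k) % len(TARGET_LISTS)) + 1 for k in range(len(TARGET_LISTS))]
    out: list[SentenceToken] = []
    for lid in order:
        if lid not in corpus:
            raise ValueError(f"corpus is missing target list {lid}")
        for tok in corpus[lid]:
            out.append(tok)
            if len(out) == n_trials:
                return out
    return out


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    rows = [
        (t.list_id, t.index_in_list, t.n_keywords, t.duration_s)
        for lid in sorted(corpus)
        for t in corpus[lid]
    ]
    return pd.DataFrame(rows, columns=["list_id", "index_in_list", "n_keywords", "duration_s"])


def corpus_from_frame(df: pd.DataFrame) -> Corpus:
    corpus: Corpus = {}
    for row in df.itertuples(index=False):
        tok = SentenceToken(
            int(row.list_id), int(row.index_in_list), int(row.n_keywords), float(row.duration_s)
        )
        corpus.setdefault(tok.list_id, []).append(tok)
    for lid in corpus:
        corpus[lid].sort(key=lambda t: t.index_in_list)
    return corpus
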