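"""Dual-criterion interleaved one-down/one-up adaptive tracking.

The measurement procedure runs two interleaved staircases per condition,
both one-down/one-up on the target SNR (masker fixed at 70 dB SPL), differing
only in the sentence-scoring criterion:

* lax track    -- the sentence counts as correct if >= 1 keyword is correct;
* strict track -- correct requires >= 3 correct keywords.

Each track presents 20 target sentences (40 per condition).  The SNR starts
at +7 dB, moves in 4-dB steps until the track's first reversal, and in 2-dB
steps thereafter.  A reversal is a change in the direction of consecutive
level movements; the reduced step applies from the movement on which the
first reversal is registered.

A one-down/one-up rule converges on the 50% point of the *sentence-level*
psychometric function under its criterion, so the lax track equilibrates
below the word-level SRT and the strict track above it; pooling keyword data
from both tracks brackets the word-level function for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .corpus import SentenceToken
from .listeners import ListenerModel

Direction = Literal["down", "up"]


@dataclass(frozen=True)
class TrackConfig:
    """Parameters of one adaptive track."""

    criterion_min_correct: int  # 1 = lax, 3 = strict
    n_trials: int = 20
    start_snr_db: float = 7.0
    step_initial_db: float = 4.0
    step_after_first_reversal_db: float = 2.0
    masker_level_db_spl: float = 70.0
    snr_min_db: float | None = None  # no floor/ceiling by default
    snr_max_db: float | None = None

    def __post_init__(self) -> None:
        if self.criterion_min_correct < 1:
            raise ValueError("criterion_min_correct must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.step_initial_db <= 0 or self.step_after_first_reversal_db <= 0:
            raise ValueError("step sizes must be positive")


def lax_track(**kwargs) -> TrackConfig:
    return TrackConfig(criterion_min_correct=1, **kwargs)


def strict_track(**kwargs) -> TrackConfig:
    return TrackConfig(criterion_min_correct=3, **kwargs)


def practice_track(criterion_min_correct: int = 1, **kwargs) -> TrackConfig:
    kwargs.setdefault("n_trials", 16)
    kwargs.setdefault("start_snr_db", 10.0)
    return TrackConfig(criterion_min_correct=criterion_min_correct, **kwargs)


@dataclass(frozen=True)
class TrackState:
    """Live state of one staircase; ``current_snr_db`` is the next trial's level."""

    current_snr_db: float
    n_presented: int = 0
    n_reversals: int = 0
    last_direction: Direction | None = None
    done: bool = False


def initial_state(cfg: TrackConfig) -> TrackState:
    return TrackState(current_snr_db=cfg.start_snr_db)


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    condition: str
    track_label: str  # "lax", "strict" or "practice"
    trial_index: int  # 1-based within the track
    snr_db: float
    list_id: int
    index_in_list: int
    n_keywords: int
    keyword_outcomes: tuple[bool, ...]
    sentence_correct: bool

    @property
    def n_correct(self) -> int:
        return int(sum(self.keyword_outcomes))


def score_sentence(keyword_outcomes: Sequence[bool], criterion_min_correct: int) -> bool:
    return int(sum(keyword_outcomes)) >= criterion_min_correct


def update_track(state: TrackState, cfg: TrackConfig, sentence_correct: bool) -> TrackState:
    """Advance the staircase one trial: correct -> down, incorrect -> up.

    The reversal (if any) caused by this movement is registered first, so the
    reduced step already applies to the movement on which the first reversal
    occurs.
    """
    if state.done:
        raise RuntimeError("cannot update a completed track")
    direction: Direction = "down" if sentence_correct else "up"
    n_reversals = state.n_reversals
    if state.last_direction is not None and direction != state.last_direction:
        n_reversals += 1
    step = cfg.step_initial_db if n_reversals == 0 else cfg.step_after_first_reversal_db
    snr = state.current_snr_db + (-step if sentence_correct else step)
    if cfg.snr_min_db is not None:
        snr = max(snr, cfg.snr_min_db)
    if cfg.snr_max_db is not None:
        snr = min(snr, cfg.snr_max_db)
    n_presented = state.n_presented + 1
    return TrackState(
        current_snr_db=snr,
        n_presented=n_presented,
        n_reversals=n_reversals,
        last_direction=direction,
        done=n_presented >= cfg.n_trials,
    )


def run_track(
    listener: ListenerModel,
    condition: str,
    cfg: TrackConfig,
    sentences: Iterable[SentenceToken],
    rng: np.random.Generator,
    track_label: str = "track",
) -> list[TrialRecord]:
    """Run a single staircase to completion, drawing sentences in order."""
    state = initial_state(cfg)
    records: list[TrialRecord] = []
    sent_iter = iter(sentences)
    while not state.done:
        try:
            tok = next(sent_iter)
        except StopIteration:
            raise RuntimeError("ran out of sentences before the track completed") from None
        outcomes = listener.respond_sentence(condition, state.current_snr_db, tok.n_keywords, rng)
        correct = score_sentence(outcomes, cfg.criterion_min_correct)
        records.append(
            TrialRecord(
                subject_id=listener.subject_id,
                condition=condition,
                track_label=track_label,
                trial_index=state.n_presented + 1,
                snr_db=state.current_snr_db,
                list_id=tok.list_id,
                index_in_list=tok.index_in_list,
                n_keywords=tok.n_keywords,
                keyword_outcomes=tuple(bool(o) for o in outcomes),
                sentence_correct=correct,
            )
        )
        state = update_track(state, cfg, correct)
    return records


def run_block(
    listener: ListenerModel,
    condition: str,
    cfg_lax: TrackConfig,
    cfg_strict: TrackConfig,
    sentences: Sequence[SentenceToken],
    rng: np.random.Generator,
    schedule: Literal["random", "alternate"] = "random",
) -> list[TrialRecord]:
    """Run one condition block: two interleaved tracks sharing one sentence queue.

    ``schedule="random"`` picks uniformly among unfinished tracks each trial
    (the default; prevents the listener from exploiting periodicity);
    ``"alternate"`` strictly alternates, falling through to the unfinished
    track once the other completes.
    """
    need = cfg_lax.n_trials + cfg_strict.n_trials
    if len(sentences) < need:
        raise ValueError(f"block needs {need} sentences, got {len(sentences)}")
    states = {"lax": initial_state(cfg_lax), "strict": initial_state(cfg_strict)}
    cfgs = {"lax": cfg_lax, "strict": cfg_strict}
    records: list[TrialRecord] = []
    sent_iter = iter(sentences)
    turn = 0
    while not all(s.done for s in states.values()):
        open_labels = [lbl for lbl, s in states.items() if not s.done]
        if schedule == "random":
            lbl = open_labels[int(rng.integers(len(open_labels)))]
        elif schedule == "alternate":
            lbl = ("lax", "strict")[turn % 2]
            if states[lbl].done:
                lbl = open_labels[0]
        else:
            raise ValueError(f"unknown schedule {schedule!r}")
        turn += 1
        state, cfg = states[lbl], cfgs[lbl]
        tok = next(sent_iter)
        outcomes = listener.respond_sentence(condition, state.current_snr_db, tok.n_keywords, rng)
        correct = score_sentence(outcomes, cfg.criterion_min_correct)
        records.append(
            TrialRecord(
                subject_id=listener.subject_id,
                condition=condition,
                track_label=lbl,
                trial_index=state.n_presented + 1,
                snr_db=state.current_snr_db,
                list_id=tok.list_id,
                index_in_list=tok.index_in_list,
                n_keywords=tok.n_keywords,
                keyword_outcomes=tuple(bool(o) for o in outcomes),
                sentence_correct=correct,
            )
        )
        states[lbl] = update_track(state, cfg, correct)
    return records


# ---------------------------------------------------------------------------
# Sentence-level psychometric function and staircase equilibrium


def p_sentence_correct(
    snr_db: float,
    srt_db: float,
    slope_db: float,
    criterion_min_correct: int,
    keyword_count_probs: dict[int, float] | None = None,
) -> float:
    """Exact P(sentence scored correct | SNR) under a keyword criterion.

    Keywords are independent Bernoulli(p(snr)); a sentence has k keywords with
    probability ``keyword_count_probs[k]`` (default: the corpus composition,
    14/16 three-keyword and 2/16 four-keyword sentences).  The probability of
    >= m correct of k is the binomial upper tail.
    """
    from scipy.stats import binom

    if keyword_count_probs is None:
        keyword_count_probs = {3: 14 / 16, 4: 2 / 16}
    p = float(expit((snr_db - srt_db) / slope_db))
    total = 0.0
    for k, w in keyword_count_probs.items():
        total += w * float(binom.sf(criterion_min_correct - 1, k, p))
    return total


def track_equilibrium_snr(
    srt_db: float,
    slope_db: float,
    criterion_min_correct: int,
    keyword_count_probs: dict[int, float] | None = None,
) -> float:
    """SNR at which the one-down/one-up track equilibrates.

    The rule converges to the 50% point of the sentence-level (criterion)
    psychometric function: the root of P(sentence correct | snr) = 0.5.
    """

    def f(snr: float) -> float:
        return p_sentence_correct(snr, srt_db, slope_db, criterion_min_correct, keyword_count_probs) - 0.5

    lo, hi = srt_db - 40 * slope_db, srt_db + 40 * slope_db
    return float(brentq(f, lo, hi))


def records_to_frame(records: Sequence[TrialRecord]) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        (
            r.subject_id,
            r.condition,
            r.track_label,
            r.trial_index,
            r.snr_db,
            r.list_id,
            r.index_in_list,
            r.n_keywords,
            r.n_correct,
            r.sentence_correct,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "track",
            "trial",
            "snr_db",
            "list_id",
            "index_in_list",
            "n_keywords",
            "n_correct",
            "sentence_correct",
        ],
    )
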