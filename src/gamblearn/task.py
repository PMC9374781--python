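"""Generative simulator of the gambling card game.

The task: on each trial the subject sees one of three card decks and a
computer-drawn number between 1 and 9, and chooses whether to gamble that a
card drawn from the deck will beat the computer's number. A win pays +1, a
loss -1 (monetary framing is presentation only). Declining yields a hidden
50/50 outcome. One deck is uniform over 1..9 ("even"), one has extra mass on
1 ("low", gambles 30 percentage points less likely to succeed) and one has
extra mass on 9 ("high", 30 points more likely). A session is 180 trials in
three 60-trial blocks; within each 15-trial set the computer draws a triple
of consecutive numbers three times each and every other number once, and the
triple shifts up or down between sets to hold the subject's gamble rate near
50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

DECK_LABELS = ("low", "even", "high")

#: trials per session / per block / per adaptive set
N_TRIALS = 180
BLOCK_SIZE = 60
SET_SIZE = 15

#: default deck success-probability offset, in probability units
DEFAULT_OFFSET = 0.30

#: adaptation thresholds on the fraction of gambles taken against the triple
ADAPT_UP = 2.0 / 3.0
ADAPT_DOWN = 1.0 / 3.0

#: sentinel for a missed response in a trial record
MISS = -1


# ---------------------------------------------------------------------------
# Decks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeckSpec:
    """A deck: a probability distribution over card numbers 1..9.

    ``number_weights[k]`` is the probability of drawing number ``k + 1``.
    """

    label: str
    number_weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.number_weights, dtype=float)
        if w.shape != (9,):
            raise ValueError("deck needs exactly 9 number weights")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("deck weights must be a probability vector")
        object.__setattr__(self, "number_weights", w)


def uniform_deck(label: str = "even") -> DeckSpec:
    return DeckSpec(label, np.full(9, 1.0 / 9.0))


def success_probability(deck: DeckSpec,
                        computer_weights: np.ndarray | None = None) -> float:
    """Marginal gamble success probability by exhaustive enumeration.

    Enumerates all 81 (subject number, computer number) pairs; a tie counts
    as a win with probability 1/2 (fair-coin tie rule).
    """
    if computer_weights is None:
        computer_weights = np.full(9, 1.0 / 9.0)
    s = np.arange(1, 10)[:, None]
    n = np.arange(1, 10)[None, :]
    p_win = (s > n) + 0.5 * (s == n)
    return float(deck.number_weights @ p_win @ computer_weights)


def build_decks(offset: float = DEFAULT_OFFSET) -> dict[str, DeckSpec]:
    """Build the low/even/high deck triple for a given success offset.

    The low/high decks are mixtures ``(1 - q) * uniform + q * point-mass``
    on number 1 (low) or 9 (high), with the mixture weight ``q`` solved so
    that the marginal success probability against a uniform computer number
    is ``0.5 -/+ offset``. Success probability is linear in ``q``, so the
    solution is exact.
    """
    if not 0.0 < offset < 0.5:
        raise ValueError("offset must lie in (0, 0.5)")
    even = uniform_deck("even")
    point_high = np.zeros(9)
    point_high[8] = 1.0
    gain = success_probability(DeckSpec("high", point_high)) - 0.5
    q = offset / gain
    if q > 1.0:
        raise ValueError(
            f"offset {offset} infeasible for the uniform+point-mass family "
            f"(maximum attainable offset is {gain:.6f})")
    base = (1.0 - q) / 9.0
    w_high = np.full(9, base)
    w_high[8] += q
    w_low = np.full(9, base)
    w_low[0] += q
    return {
        "low": DeckSpec("low", w_low),
        "even": even,
        "high": DeckSpec("high", w_high),
    }


# ---------------------------------------------------------------------------
# Computer-number schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComputerSchedule:
    """The active triple of consecutive numbers drawn three times per set."""

    low: int = 4  # lowest member; triple is (low, low+1, low+2)

    def __post_init__(self):
        if not 1 <= self.low <= 7:
            raise ValueError("triple must stay within 1..9")

    @property
    def triple(self) -> tuple[int, int, int]:
        return (self.low, self.low + 1, self.low + 2)


def adapt_schedule(schedule: ComputerSchedule, taken: int,
                   opportunities: int) -> ComputerSchedule:
    """Shift the triple after a 15-trial set.

    ``taken`` counts gambles accepted against the triple's numbers during
    the previous set, out of ``opportunities`` such trials. The triple moves
    up one if the subject took two thirds or more of those gambles, down one
    if a third or less, and is clamped to 1..9.
    """
    if opportunities < 0 or taken < 0 or taken > max(opportunities, 0):
        raise ValueError("invalid adaptation counts")
    if opportunities == 0:
        return schedule
    frac = taken / opportunities
    if frac >= ADAPT_UP:
        return ComputerSchedule(min(schedule.low + 1, 7))
    if frac <= ADAPT_DOWN:
        return ComputerSchedule(max(schedule.low - 1, 1))
    return schedule


def draw_computer_numbers(schedule: ComputerSchedule,
                          rng: np.random.Generator) -> np.ndarray:
    """The 15 computer numbers of one set, in randomized order.

    Each triple member appears three times and every other number in 1..9
    once (3*3 + 6 = 15 draws).
    """
    triple = schedule.triple
    numbers = [n for n in triple for _ in range(3)]
    numbers += [n for n in range(1, 10) if n not in triple]
    return rng.permutation(np.asarray(numbers))


# ---------------------------------------------------------------------------
# Trials and sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    session: int
    trial_index: int  # 1-based
    block: int
    deck: str
    computer_number: int
    choice: int  # 1 gamble, 0 decline, MISS
    outcome: int  # +1 win, -1 loss
    outcome_shown: bool

    def __post_init__(self):
        if self.block != math.ceil(self.trial_index / BLOCK_SIZE):
            raise ValueError("block inconsistent with trial index")
        if self.outcome_shown != (self.choice == 1):
            raise ValueError("outcome is shown iff the gamble was taken")
        if self.choice == MISS and self.outcome != -1:
            raise ValueError("a missed response is always a loss")


@dataclass
class SessionLog:
    """One subject's ordered 180-trial session."""

    subject_id: str
    session: int
    trials: list[TrialRecord] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"expected {N_TRIALS} trials")
        for i, t in enumerate(self.trials, start=1):
            if t.trial_index != i:
                raise ValueError("trials out of order")
        counts = pd.Series([t.deck for t in self.trials]).value_counts()
        if any(counts.get(d, 0) != N_TRIALS // 3 for d in DECK_LABELS):
            raise ValueError("each deck must appear 60 times")


class Policy(Protocol):
    """An agent playing the task.

    ``p_gamble`` maps the visible trial state to a gamble probability;
    ``observe`` is called with the outcome of every taken gamble (declined
    outcomes are hidden and never reported).
    """

    def p_gamble(self, deck: str, computer_number: int) -> float: ...

    def observe(self, deck: str, computer_number: int, outcome: int) -> None: ...


class FixedPolicy:
    """State-free policy from a callable ``(deck, N) -> p``; never learns."""

    def __init__(self, fn: Callable[[str, int], float]):
        self._fn = fn

    def p_gamble(self, deck: str, computer_number: int) -> float:
        return self._fn(deck, computer_number)

    def observe(self, deck: str, computer_number: int, outcome: int) -> None:
        pass


def resolve_gamble(deck: DeckSpec, computer_number: int, choice: int,
                   rng: np.random.Generator) -> int:
    """Outcome of one trial: +1 win or -1 loss.

    A taken gamble draws a subject number from the deck and wins iff it
    beats the computer's number, with ties settled by a fair coin. Declining
    wins with probability 1/2 regardless of the number. A miss is a loss.
    """
    if choice == 1:
        s = int(rng.choice(9, p=deck.number_weights)) + 1
        if s > computer_number:
            return 1
        if s < computer_number:
            return -1
        return 1 if rng.random() < 0.5 else -1
    if choice == 0:
        return 1 if rng.random() < 0.5 else -1
    return -1


def _deck_sequence(rng: np.random.Generator, n_each: int = 5,
                   max_run: int = 2) -> list[int]:
    """Shuffle [0,1,2] * n_each so no deck appears more than max_run in a row."""
    seq = np.repeat(np.arange(3), n_each)
    for _ in range(1000):
        rng.shuffle(seq)
        run, ok = 1, True
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return list(seq)
    raise RuntimeError("could not build a valid deck sequence")


def _deal_numbers(numbers: np.ndarray, rng: np.random.Generator
                  ) -> list[list[int]]:
    """Deal the 15 set numbers to the 3 decks in a balanced round-robin.

    Numbers are sorted and dealt in rotation from a random starting deck, so
    each deck faces a near-identical number multiset within the set.
    """
    order = rng.permutation(3)
    hands: list[list[int]] = [[], [], []]
    for i, n in enumerate(np.sort(numbers)):
        hands[order[i % 3]].append(int(n))
    for h in hands:
        rng.shuffle(h)
    return hands


def generate_session(decks: dict[str, DeckSpec], policy: Policy,
                     rng: np.random.Generator, subject_id: str = "sim",
                     session: int = 1) -> SessionLog:
    """Assemble one 180-trial session with the adaptive number schedule.

    Twelve 15-trial sets; within each set every deck is played five times
    (never more than twice in a row) against a balanced share of the set's
    computer numbers, and the schedule adapts between sets based on gambles
    taken against the triple's numbers.
    """
    schedule = ComputerSchedule()
    log = SessionLog(subject_id=subject_id, session=session)
    t = 0
    for _ in range(N_TRIALS // SET_SIZE):
        numbers = draw_computer_numbers(schedule, rng)
        seq = _deck_sequence(rng)
        hands = _deal_numbers(numbers, rng)
        cursors = [0, 0, 0]
        triple = set(schedule.triple)
        taken = opportunities = 0
        for d in seq:
            t += 1
            deck = decks[DECK_LABELS[d]]
            n = hands[d][cursors[d]]
            cursors[d] += 1
            p = float(policy.p_gamble(deck.label, n))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"policy returned probability {p!r}")
            choice = 1 if rng.random() < p else 0
            outcome = resolve_gamble(deck, n, choice, rng)
            if n in triple:
                opportunities += 1
                taken += choice
            if choice == 1:
                policy.observe(deck.label, n, outcome)
            log.trials.append(TrialRecord(
                session=session, trial_index=t,
                block=math.ceil(t / BLOCK_SIZE), deck=deck.label,
                computer_number=n, choice=choice, outcome=outcome,
                outcome_shown=choice == 1))
        schedule = adapt_schedule(schedule, taken, opportunities)
    log.validate()
    return log


# ---------------------------------------------------------------------------
# Trial-log CSV round-trip
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["subject_id", "session", "trial", "block", "deck",
                "computer_number", "choice", "outcome", "shown"]


def logs_to_frame(logs: Sequence[SessionLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        for t in log.trials:
            rows.append((log.subject_id, log.session, t.trial_index, t.block,
                         t.deck, t.computer_number,
                         pd.NA if t.choice == MISS else t.choice,
                         t.outcome, int(t.outcome_shown)))
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_logs(df: pd.DataFrame) -> list[SessionLog]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial log is missing columns: {sorted(missing)}")
    logs = []
    for (sid, ses), grp in df.groupby(["subject_id", "session"], sort=True):
        grp = grp.sort_values("trial")
        log = SessionLog(subject_id=str(sid), session=int(ses))
        for row in grp.itertuples(index=False):
            choice = MISS if pd.isna(row.choice) else int(row.choice)
            log.trials.append(TrialRecord(
                session=int(row.session), trial_index=int(row.trial),
                block=int(row.block), deck=str(row.deck),
                computer_number=int(row.computer_number), choice=choice,
                outcome=int(row.outcome), outcome_shown=bool(row.shown)))
        logs.append(log)
    return logs


def write_logs(logs: Sequence[SessionLog], path) -> None:
    logs_to_frame(logs).to_csv(path, index=False)


def read_logs(path) -> list[SessionLog]:
    return frame_to_logs(pd.read_csv(path))
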