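"""Monetary gambling task (MGT): design generation, a betting agent, and
behavioral performance scoring.

The task is a 240-trial event-related design on a fixed 2.5 s trial grid.
Each trial shows a pie cue (chance of winning 25/50/75%) for 1.5 s, during
which the subject bets 10 or 50 tokens; a feedback stimulus then reports a
win or loss of the bet amount.  Trial types (pie chance x scheduled
outcome) occur with fixed counts and are presented in random order.

Behavioral scores summarise risky versus safe betting in the face of
recent losses: counts of 50-token (risky) and 10-token (safe) bets made
after runs of 1-3 consecutive losses, and after windows of 2-3 trials
whose net token outcome was negative.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidDesignError, InvalidInputError

TRIAL_DURATION_S = 2.5
FEEDBACK_DELAY_S = 1.5
N_TRIALS = 240

#: 50-token bet = risky choice, 10-token bet = safe choice.
BET_RISKY = 50
BET_SAFE = 10
MISSED = "missed"

WIN = "win"
LOSS = "loss"


@dataclass(frozen=True)
class TrialTypeSpec:
    """One trial type: pie chance, scheduled outcome, and its count."""

    pie_chance: float
    scheduled_outcome: str
    n_trials: int

    def __post_init__(self):
        if self.pie_chance not in (0.25, 0.50, 0.75):
            raise InvalidDesignError(
                f"pie_chance must be one of 0.25/0.50/0.75, got {self.pie_chance}"
            )
        if self.scheduled_outcome not in (WIN, LOSS):
            raise InvalidDesignError(
                f"scheduled_outcome must be 'win' or 'loss', got {self.scheduled_outcome!r}"
            )
        if self.n_trials < 0:
            raise InvalidDesignError("n_trials must be non-negative")


#: The six trial types of the standard 240-trial design.
DEFAULT_TRIAL_SPECS = (
    TrialTypeSpec(0.50, WIN, 40),
    TrialTypeSpec(0.50, LOSS, 40),
    TrialTypeSpec(0.75, WIN, 60),
    TrialTypeSpec(0.75, LOSS, 20),
    TrialTypeSpec(0.25, WIN, 20),
    TrialTypeSpec(0.25, LOSS, 60),
)


@dataclass(frozen=True)
class TrialRecord:
    """One completed (or missed) trial.

    ``delta`` is the signed token change: +bet on a win, -bet on a loss,
    0 on a missed trial.  Onsets are in seconds from acquisition start;
    the feedback stimulus follows the cue by 1.5 s.
    """

    index: int  # 1-based
    pie_chance: float
    bet: object  # 10, 50 or "missed"
    outcome: str  # "win", "loss" or "missed"
    delta: int
    cue_onset_s: float
    feedback_onset_s: float


@dataclass(frozen=True)
class AgentPolicy:
    """Logistic betting policy for the simulated agent.

    The probability of a risky (50-token) bet is
    ``sigmoid(logit(p_bet50_base) + risk_shift_after_loss * n_consecutive_losses
    + pie_sensitivity * (pie_chance - 0.5))``.  A positive
    ``risk_shift_after_loss`` makes the agent chase losses.  Each trial is
    independently missed with probability ``miss_rate``.
    """

    p_bet50_base: float = 0.5
    risk_shift_after_loss: float = 0.0
    pie_sensitivity: float = 0.0
    miss_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.p_bet50_base <= 1.0:
            raise InvalidDesignError("p_bet50_base must be in [0, 1]")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise InvalidDesignError("miss_rate must be in [0, 1]")

    def p_bet50(self, pie_chance: float, n_consecutive_losses: int) -> float:
        base = np.clip(self.p_bet50_base, 0.0, 1.0)
        if base == 0.0:
            logit = -np.inf
        elif base == 1.0:
            logit = np.inf
        else:
            logit = np.log(base / (1.0 - base))
        logit = (
            logit
            + self.risk_shift_after_loss * n_consecutive_losses
            + self.pie_sensitivity * (pie_chance - 0.5)
        )
        return float(1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700))))


#: Output column order for behavioral-score tables.
SCORE_COLUMNS = (
    "Net_Outcome",
    "Bet50_Prv1Loss",
    "Bet10_Prv1Loss",
    "Bet50_Prv2Loss",
    "Bet10_Prv2Loss",
    "Bet50_Prv3Loss",
    "Bet10_Prv3Loss",
    "Bet50_Prv2NetLoss",
    "Bet10_Prv2NetLoss",
    "Bet50_Prv3NetLoss",
    "Bet10_Prv3NetLoss",
)


@dataclass(frozen=True)
class BehavioralScores:
    """The eleven task-performance scores."""

    net_outcome: int
    bet50_prv1loss: int
    bet10_prv1loss: int
    bet50_prv2loss: int
    bet10_prv2loss: int
    bet50_prv3loss: int
    bet10_prv3loss: int
    bet50_prv2netloss: int
    bet10_prv2netloss: int
    bet50_prv3netloss: int
    bet10_prv3netloss: int

    def to_dict(self) -> dict:
        vals = dataclasses.astuple(self)
        return dict(zip(SCORE_COLUMNS, vals))


def generate_task_design(
    specs: Sequence[TrialTypeSpec] = DEFAULT_TRIAL_SPECS,
    seed: int | None = None,
    n_trials: int = N_TRIALS,
    tr: float = TRIAL_DURATION_S,
) -> pd.DataFrame:
    """Generate a randomly ordered trial sequence from the type counts.

    Returns a DataFrame with one row per trial: ``index`` (1-based),
    ``pie_chance``, ``scheduled_outcome``, ``cue_onset_s`` and
    ``feedback_onset_s``.  Counts per type are preserved exactly; the
    order is a seeded uniform random permutation on the ``tr``-second
    trial grid.
    """
    total = sum(s.n_trials for s in specs)
    if total != n_trials:
        raise InvalidDesignError(
            f"trial-type counts sum to {total}, expected {n_trials}"
        )
    pie = np.repeat([s.pie_chance for s in specs], [s.n_trials for s in specs])
    out = np.repeat([s.scheduled_outcome for s in specs], [s.n_trials for s in specs])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    idx = np.arange(1, total + 1)
    cue = (idx - 1) * tr
    return pd.DataFrame(
        {
            "index": idx,
            "pie_chance": pie[perm],
            "scheduled_outcome": out[perm],
            "cue_onset_s": cue,
            "feedback_onset_s": cue + FEEDBACK_DELAY_S,
        }
    )


def simulate_agent_bets(
    design: pd.DataFrame,
    policy: AgentPolicy = AgentPolicy(),
    seed: int | None = None,
) -> list[TrialRecord]:
    """Play the design with a logistic betting agent; returns trial records.

    The outcome of a played trial equals the scheduled outcome; missed
    trials have no bet, no outcome and zero token change.  The agent's
    consecutive-loss count resets on a win and on a missed trial.
    """
    rng = np.random.default_rng(seed)
    records: list[TrialRecord] = []
    consecutive_losses = 0
    for row in design.itertuples(index=False):
        if rng.random() < policy.miss_rate:
            records.append(
                TrialRecord(
                    index=int(row.index),
                    pie_chance=float(row.pie_chance),
                    bet=MISSED,
                    outcome=MISSED,
                    delta=0,
                    cue_onset_s=float(row.cue_onset_s),
                    feedback_onset_s=float(row.feedback_onset_s),
                )
            )
            consecutive_losses = 0
            continue
        p50 = policy.p_bet50(float(row.pie_chance), consecutive_losses)
        bet = BET_RISKY if rng.random() < p50 else BET_SAFE
        outcome = row.scheduled_outcome
        delta = bet if outcome == WIN else -bet
        records.append(
            TrialRecord(
                index=int(row.index),
                pie_chance=float(row.pie_chance),
                bet=bet,
                outcome=outcome,
                delta=int(delta),
                cue_onset_s=float(row.cue_onset_s),
                feedback_onset_s=float(row.feedback_onset_s),
            )
        )
        consecutive_losses = consecutive_losses + 1 if outcome == LOSS else 0
    return records


def _validate_records(records: Sequence[TrialRecord]) -> None:
    indices = [r.index for r in records]
    if len(set(indices)) != len(indices):
        raise InvalidInputError("duplicate trial indices")
    if any(b - a <= 0 for a, b in zip(indices, indices[1:])):
        raise InvalidInputError("trial records must be ordered by index")


def compute_behavioral_scores(
    records: Sequence[TrialRecord],
    missed_breaks_run: bool = True,
) -> BehavioralScores:
    """Compute the eleven performance scores from an ordered trial list.

    A risky/safe bet at trial t is counted toward the consecutive-loss
    scores when the K immediately preceding trials were all losses, and
    toward the net-loss scores when the summed token delta over the K
    preceding trials is strictly negative.  Overlapping windows all
    count.  By default a missed trial breaks a consecutive-loss run
    (``missed_breaks_run=False`` instead skips over missed trials when
    counting the run).
    """
    _validate_records(records)
    outcomes = [r.outcome for r in records]
    bets = [r.bet for r in records]
    deltas = np.array([r.delta for r in records])
    n = len(records)

    # run_len[t]: consecutive losses immediately before trial t
    run_len = np.zeros(n, dtype=int)
    for t in range(1, n):
        prev = outcomes[t - 1]
        if prev == LOSS:
            run_len[t] = run_len[t - 1] + 1
        elif prev == MISSED and not missed_breaks_run:
            run_len[t] = run_len[t - 1]
        else:
            run_len[t] = 0

    counts = {}
    for k in (1, 2, 3):
        for bet_amount, tag in ((BET_RISKY, "bet50"), (BET_SAFE, "bet10")):
            counts[f"{tag}_prv{k}loss"] = int(
                sum(
                    1
                    for t in range(k, n)
                    if bets[t] == bet_amount and run_len[t] >= k
                )
            )
    for k in (2, 3):
        window_net = np.array(
            [deltas[t - k:t].sum() if t >= k else 0 for t in range(n)]
        )
        for bet_amount, tag in ((BET_RISKY, "bet50"), (BET_SAFE, "bet10")):
            counts[f"{tag}_prv{k}netloss"] = int(
                sum(
                    1
                    for t in range(k, n)
                    if bets[t] == bet_amount and window_net[t] < 0
                )
            )

    return BehavioralScores(
        net_outcome=int(deltas.sum()),
        bet50_prv1loss=counts["bet50_prv1loss"],
        bet10_prv1loss=counts["bet10_prv1loss"],
        bet50_prv2loss=counts["bet50_prv2loss"],
        bet10_prv2loss=counts["bet10_prv2loss"],
        bet50_prv3loss=counts["bet50_prv3loss"],
        bet10_prv3loss=counts["bet10_prv3loss"],
        bet50_prv2netloss=counts["bet50_prv2netloss"],
        bet10_prv2netloss=counts["bet10_prv2netloss"],
        bet50_prv3netloss=counts["bet50_prv3netloss"],
        bet10_prv3netloss=counts["bet10_prv3netloss"],
    )


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[
        ["index", "pie_chance", "bet", "outcome", "delta", "cue_onset_s", "feedback_onset_s"]
    ]


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in frame.itertuples(index=False):
        bet = row.bet if row.bet == MISSED else int(row.bet)
        records.append(
            TrialRecord(
                index=int(row.index),
                pie_chance=float(row.pie_chance),
                bet=bet,
                outcome=str(row.outcome),
                delta=int(row.delta),
                cue_onset_s=float(row.cue_onset_s),
                feedback_onset_s=float(row.feedback_onset_s),
            )
        )
    return records


def write_trial_log(records: Iterable[TrialRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_trial_log(path) -> list[TrialRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


def write_scores_table(scores_by_subject: dict, path) -> None:
    """Write one row per subject with columns in the standard score order."""
    frame = pd.DataFrame(
        {sid: s.to_dict() for sid, s in scores_by_subject.items()}
    ).T[list(SCORE_COLUMNS)]
    frame.index.name = "subject"
    frame.to_csv(path, sep="\t")
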