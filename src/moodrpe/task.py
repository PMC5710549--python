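"""Domain types and deterministic structure builders for the three decision tasks.

Three task variants are modelled:

* ``lab`` — a laboratory risky decision task: 160 choices between a certain
  amount and a two-outcome monetary gamble, with a happiness probe after
  every 2 to 3 trials (66 probes).  Outcomes of half the chosen gambles are
  not revealed.
* ``smartphone`` — the same task compressed for a phone app: 30 choices,
  12 probes, stakes in points with a starting endowment of 500, risky
  options shown as equal-probability two-outcome spinners, resolved
  immediately.
* ``probabilistic`` — a 164-trial scanner task with fully described ±£1
  lotteries (win probability 0%, 25%, 75% or 100%) paired against a
  strictly dominated alternative, so a reward-maximising agent always picks
  the "observation" lottery and performance carries no learning signal.

Trial-level quantities follow the mood model's conventions: the certain
reward (CR), the expected value (EV) of a chosen gamble, and the reward
prediction error (RPE = outcome − EV).  Terms for unchosen options are zero,
and the RPE is zero whenever the outcome is not revealed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gamble",
    "ObservationLottery",
    "TrialRecord",
    "Session",
    "gamble_ev",
    "trial_rpe",
    "build_schedule",
    "build_probabilistic_session",
    "regressor_series",
    "VARIANTS",
    "SESSION_STRUCTURE",
    "OBSERVATION_P_LEVELS",
]

VARIANTS = ("lab", "smartphone", "probabilistic")

#: (n_trials, n_probes) fixed by each task's design.
SESSION_STRUCTURE = {
    "lab": (160, 66),
    "smartphone": (30, 12),
    "probabilistic": (164, 0),
}

SMARTPHONE_ENDOWMENT = 500.0

#: Win probabilities of the scanner task's observation lotteries.
OBSERVATION_P_LEVELS = (0.0, 0.25, 0.75, 1.0)

CHOICES = ("certain", "gamble", "observation", "other")


class MalformedTrialError(ValueError):
    """A trial's fields violate the task conventions."""


@dataclass(frozen=True)
class Gamble:
    """A two-outcome monetary gamble.

    ``outcome_hi`` is received with probability ``p_hi``, otherwise
    ``outcome_lo``.  Smartphone spinners constrain ``p_hi`` to 0.5.
    """

    outcome_hi: float
    outcome_lo: float
    p_hi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hi <= 1.0:
            raise ValueError(f"p_hi must lie in [0, 1], got {self.p_hi}")
        if self.outcome_hi < self.outcome_lo:
            raise ValueError(
                f"outcome_hi ({self.outcome_hi}) must be >= outcome_lo "
                f"({self.outcome_lo})"
            )


def gamble_ev(g: Gamble) -> float:
    """Expected value of a gamble: the probability-weighted average return."""
    return g.p_hi * g.outcome_hi + (1.0 - g.p_hi) * g.outcome_lo


@dataclass(frozen=True)
class ObservationLottery:
    """A fully described ±£1 lottery from the scanner task.

    ``p_win`` must be one of the four design levels (0, 25, 75, 100%).
    """

    p_win: float
    win_amount: float = 1.0
    lose_amount: float = -1.0

    def __post_init__(self) -> None:
        if self.p_win not in OBSERVATION_P_LEVELS:
            raise ValueError(
                f"p_win must be one of {OBSERVATION_P_LEVELS}, got {self.p_win}"
            )
        if self.win_amount < self.lose_amount:
            raise ValueError("win_amount must be >= lose_amount")

    @property
    def ev(self) -> float:
        return self.p_win * self.win_amount + (1.0 - self.p_win) * self.lose_amount

    def as_gamble(self) -> Gamble:
        return Gamble(self.win_amount, self.lose_amount, self.p_win)


def trial_rpe(outcome: float | None, ev: float, revealed: bool) -> float:
    """Reward prediction error: experienced minus predicted reward.

    Zero when the outcome is not revealed (no surprise can be experienced).
    """
    if not revealed:
        return 0.0
    if outcome is None:
        raise MalformedTrialError("revealed trial has no outcome")
    return outcome - ev


@dataclass
class TrialRecord:
    """One decision trial with the mood model's per-trial quantities.

    ``cr``/``ev``/``rpe`` already encode the chosen-option conventions:
    at most one of ``cr`` and ``ev`` is nonzero, and ``rpe`` is zero when
    the outcome was not revealed.  The offered options are kept so choices
    can be (re)simulated on a session template.
    """

    index: int  # 1-based trial number
    choice: str  # certain | gamble | observation | other
    cr: float = 0.0
    ev: float = 0.0
    outcome: float | None = None
    revealed: bool = True
    rpe: float = 0.0
    offered_certain: float | None = None
    offered_gamble: Gamble | None = None

    def validate(self) -> None:
        if self.choice not in CHOICES:
            raise MalformedTrialError(
                f"trial {self.index}: unknown choice {self.choice!r}"
            )
        if self.cr != 0.0 and self.ev != 0.0:
            raise MalformedTrialError(
                f"trial {self.index}: CR and EV both nonzero "
                "(terms for unchosen options must be zero)"
            )
        if not self.revealed and self.rpe != 0.0:
            raise MalformedTrialError(
                f"trial {self.index}: RPE must be zero when the outcome "
                "is not revealed"
            )
        if self.choice == "certain" and self.ev != 0.0:
            raise MalformedTrialError(
                f"trial {self.index}: EV nonzero on a certain choice"
            )
        if self.choice in ("gamble", "observation") and self.cr != 0.0:
            raise MalformedTrialError(
                f"trial {self.index}: CR nonzero on a gamble choice"
            )


@dataclass
class Session:
    """An ordered trial sequence plus the probe schedule for one task variant.

    ``probe_after`` holds 1-based trial indices: a probe "after trial t"
    reflects all trials j ≤ t.  ``ratings`` (optional) aligns with
    ``probe_after`` and lives on the [0, 1] cursor scale.
    """

    variant: str
    trials: list[TrialRecord]
    probe_after: list[int] = field(default_factory=list)
    endowment: float | None = None
    ratings: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_probes(self) -> int:
        return len(self.probe_after)

    def probe_gaps(self) -> np.ndarray:
        return np.diff(np.concatenate(([0], self.probe_after)))

    def validate(self, strict: bool = True) -> None:
        """Check structural invariants; ``strict`` also enforces the
        variant's printed trial/probe counts."""
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for tr in self.trials:
            tr.validate()
        if self.variant == "smartphone":
            for tr in self.trials:
                if tr.offered_gamble is not None and tr.offered_gamble.p_hi != 0.5:
                    raise MalformedTrialError(
                        f"trial {tr.index}: smartphone spinners require p_hi = 0.5"
                    )
        if self.probe_after:
            gaps = self.probe_gaps()
            bad = np.flatnonzero(~np.isin(gaps, (2, 3)))
            if bad.size:
                raise ValueError(
                    f"probe gap of {int(gaps[bad[0]])} at probe {int(bad[0]) + 1}: "
                    "probes must occur every 2 to 3 trials"
                )
            if self.probe_after[-1] > self.n_trials:
                raise ValueError("probe index beyond the last trial")
        if strict:
            n_trials, n_probes = SESSION_STRUCTURE[self.variant]
            if self.n_trials != n_trials or self.n_probes != n_probes:
                raise ValueError(
                    f"{self.variant} sessions have {n_trials} trials and "
                    f"{n_probes} probes, got {self.n_trials}/{self.n_probes}"
                )
            if self.variant == "smartphone" and self.endowment != SMARTPHONE_ENDOWMENT:
                raise ValueError(
                    f"smartphone sessions start with an endowment of "
                    f"{SMARTPHONE_ENDOWMENT:g} points"
                )
            if n_probes and self.probe_after[-1] != n_trials:
                raise ValueError("probe gaps must tile the whole session")


def build_schedule(n_trials: int, n_probes: int, seed: int) -> np.ndarray:
    """Probe schedule with gaps of 2 or 3 trials between consecutive probes.

    The gap multiset is fully determined by the pair (``n_trials``,
    ``n_probes``): with ``a`` gaps of 2 and ``b`` of 3, ``a + b = n_probes``
    and ``2a + 3b = n_trials``, so ``a = 3·n_probes − n_trials`` and
    ``b = n_trials − 2·n_probes``.  Only the order of the gaps is random
    (seeded).  Returns the 1-based trial indices after which a probe occurs;
    the first probe follows the first gap and the last lands on the final
    trial.
    """
    a = 3 * n_probes - n_trials
    b = n_trials - 2 * n_probes
    if a < 0 or b < 0:
        raise ValueError(
            f"no schedule with gaps in {{2, 3}} exists for "
            f"(n_trials={n_trials}, n_probes={n_probes})"
        )
    gaps = np.array([2] * a + [3] * b, dtype=int)
    rng = np.random.default_rng(seed)
    rng.shuffle(gaps)
    return np.cumsum(gaps)


def build_probabilistic_session(
    seed: int, n_trials: int = 164, error_rate: float = 0.0,
    n_errors: int | None = None,
) -> Session:
    """Simulate one scanner session of the probabilistic reward task.

    Each trial pairs an observation lottery (the four win-probability
    levels appear equally often, in seeded order) against a strictly
    dominated alternative — the same lottery with both outcomes £0.50
    lower — so a reward-maximising agent always takes the observation
    lottery.  Outcomes are always shown; the RPE is outcome − EV of the
    chosen lottery.  ``error_rate`` is the per-trial probability of
    (erroneously) choosing the dominated lottery; ``n_errors`` instead
    forces an exact, seeded selection of error trials.
    """
    n_levels = len(OBSERVATION_P_LEVELS)
    if n_trials % n_levels:
        raise ValueError(
            f"n_trials must be divisible by {n_levels} to balance lottery types"
        )
    rng = np.random.default_rng(seed)
    levels = np.repeat(OBSERVATION_P_LEVELS, n_trials // n_levels)
    rng.shuffle(levels)
    error_trials: set[int] | None = None
    if n_errors is not None:
        error_trials = set(rng.choice(n_trials, size=n_errors, replace=False))
    trials: list[TrialRecord] = []
    for t, p in enumerate(levels, start=1):
        lottery = ObservationLottery(float(p))
        if error_trials is not None:
            err = (t - 1) in error_trials
        else:
            err = rng.random() < error_rate
        if err:
            chosen = Gamble(lottery.win_amount - 0.5, lottery.lose_amount - 0.5, float(p))
        else:
            chosen = lottery.as_gamble()
        outcome = chosen.outcome_hi if rng.random() < chosen.p_hi else chosen.outcome_lo
        ev = gamble_ev(chosen)
        trials.append(
            TrialRecord(
                index=t,
                choice="other" if err else "observation",
                ev=ev,
                outcome=outcome,
                revealed=True,
                rpe=trial_rpe(outcome, ev, True),
                offered_gamble=lottery.as_gamble(),
            )
        )
    return Session(variant="probabilistic", trials=trials)


def regressor_series(session: Session) -> np.ndarray:
    """Per-trial (choice-period EV, outcome-period RPE) regressor pairs.

    These are the parametric-modulator series a neural analysis would use.
    Returns an (n_trials, 2) array; the RPE entry is NaN on error trials
    (where the observation lottery was not chosen).
    """
    out = np.empty((session.n_trials, 2))
    for i, tr in enumerate(session.trials):
        out[i, 0] = tr.ev
        out[i, 1] = tr.rpe if tr.choice == "observation" else np.nan
    return out
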