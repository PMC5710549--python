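"""The momentary-mood equation and its alternative forms.

Momentary happiness at the probe after trial ``t`` is modelled as a
recency-weighted sum of task events::

    happiness(t) = w0 + w_CR  * sum_{j<=t} gamma**(t-j) * CR_j
                      + w_EV  * sum_{j<=t} gamma**(t-j) * EV_j
                      + w_RPE * sum_{j<=t} gamma**(t-j) * RPE_j

``w0`` is a baseline mood parameter (the intercept, interpretable as a
persistent affective state), the other weights convert money into rating
units, and ``gamma`` in [0, 1] is a forgetting factor giving recent trials
exponentially more influence.  CR_j is the certain reward when the safe
option was chosen, EV_j the expected value of a chosen gamble, and RPE_j
the reward prediction error (outcome − EV) of a revealed gamble outcome;
terms for unchosen options, and RPEs of unrevealed outcomes, are zero.

Two alternative forms are defined for model comparison:

* ``no_expectation`` drops the EV term;
* ``split_rpe`` splits the RPE into its components — the obtained reward
  ``R_j`` and the negated expectation ``−EV_j`` — on revealed gamble
  trials, each with its own weight (the EV term itself is kept, so the
  model nests the full form when w_R = w_negEV = w_RPE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .task import Session

__all__ = [
    "MoodParams",
    "ModelSpec",
    "MODEL_SPECS",
    "TERM_ATTR",
    "decayed_sum",
    "decayed_series",
    "term_series",
    "predict_happiness",
]


class ModelConfigurationError(ValueError):
    """A model spec requests a term the parameter vector does not carry."""


@dataclass
class MoodParams:
    """Parameter vector of the mood equation.

    Weights are in rating units per money unit (pounds or points,
    whichever the session uses).  ``w_r``/``w_negev`` are only meaningful
    for the split-RPE model and default to None (absent).
    """

    w0: float
    gamma: float
    w_cr: float = 0.0
    w_ev: float = 0.0
    w_rpe: float = 0.0
    w_r: float | None = None
    w_negev: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


#: mood-equation term -> MoodParams attribute carrying its weight
TERM_ATTR = {"cr": "w_cr", "ev": "w_ev", "rpe": "w_rpe", "r": "w_r", "negev": "w_negev"}


@dataclass(frozen=True)
class ModelSpec:
    """A named selection of mood-equation terms."""

    id: str
    terms: tuple[str, ...]

    @property
    def k_params(self) -> int:
        """Free parameters: w0, gamma, and one weight per term."""
        return 2 + len(self.terms)


MODEL_SPECS: dict[str, ModelSpec] = {
    "full": ModelSpec("full", ("cr", "ev", "rpe")),
    "no_expectation": ModelSpec("no_expectation", ("cr", "rpe")),
    "split_rpe": ModelSpec("split_rpe", ("cr", "ev", "r", "negev")),
}


def decayed_sum(values: np.ndarray, t: int, gamma: float) -> float:
    """Recency-weighted sum Σ_{j=1..t} gamma**(t−j) · value_j (t is 1-based)."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    values = np.asarray(values, dtype=float)
    if not 1 <= t <= values.size:
        raise ValueError(f"t={t} outside the session (1..{values.size})")
    v = values[:t]
    return float(np.dot(gamma ** np.arange(t - 1, -1, -1), v))


def decayed_series(values: np.ndarray, gamma: float) -> np.ndarray:
    """Running recency-weighted sums for every t at once (linear recursion
    s_t = gamma·s_{t−1} + value_t)."""
    return lfilter([1.0], [1.0, -gamma], np.asarray(values, dtype=float))


def term_series(session: Session) -> dict[str, np.ndarray]:
    """Per-trial series of every mood-equation term, with the zeroing
    conventions applied (unchosen options zero; RPE and R zero when the
    outcome was not revealed)."""
    n = session.n_trials
    out = {k: np.zeros(n) for k in TERM_ATTR}
    for i, tr in enumerate(session.trials):
        out["cr"][i] = tr.cr
        out["ev"][i] = tr.ev
        out["rpe"][i] = tr.rpe
        if tr.choice in ("gamble", "observation") and tr.revealed:
            out["r"][i] = tr.outcome if tr.outcome is not None else 0.0
            out["negev"][i] = -tr.ev
    return out


def predict_happiness(
    params: MoodParams,
    session: Session,
    spec: ModelSpec = MODEL_SPECS["full"],
) -> np.ndarray:
    """Predicted happiness at each probe of a session under a model spec.

    A probe after trial t reflects trials j ≤ t only.  Returns one
    prediction per entry of ``session.probe_after``.
    """
    series = term_series(session)
    idx = np.asarray(session.probe_after, dtype=int) - 1
    pred = np.full(idx.shape, params.w0, dtype=float)
    for term in spec.terms:
        w = getattr(params, TERM_ATTR[term])
        if w is None:
            raise ModelConfigurationError(
                f"model {spec.id!r} needs weight {TERM_ATTR[term]!r}, "
                "absent from the parameter vector"
            )
        if w != 0.0:
            pred += w * decayed_series(series[term], params.gamma)[idx]
    return pred
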