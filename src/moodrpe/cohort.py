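"""Synthetic cohorts: choices, outcomes, ratings, symptoms, covariates.

Generates complete synthetic studies with the statistical structure the
group-level analyses assume, so the whole pipeline is testable without
access to participant data:

* risky-decision sessions (laboratory or smartphone stakes) with choices
  from a logistic choice rule, outcome reveal rules, and happiness
  ratings from the mood equation plus Gaussian noise clipped to [0, 1];
* scanner sessions of the probabilistic reward task with per-participant
  observation-choice error counts (including designated "failure"
  participants who miss more than 30 trials);
* depression-severity questionnaire scores per group (HAM-D and PHQ drawn
  jointly for laboratory cohorts, BDI-II for smartphone cohorts) with a
  configurable negative linkage from standardized symptom severity to the
  baseline mood parameter w0 — the structure behind the reported
  w0–severity correlations — while the other weights are drawn
  independently of symptoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import MODEL_SPECS, ModelSpec, MoodParams, predict_happiness
from .task import (
    SESSION_STRUCTURE,
    SMARTPHONE_ENDOWMENT,
    Gamble,
    Session,
    TrialRecord,
    build_probabilistic_session,
    build_schedule,
    gamble_ev,
    trial_rpe,
)

__all__ = [
    "ChoiceParams",
    "CohortConfig",
    "Participant",
    "Cohort",
    "build_session_template",
    "simulate_choices",
    "simulate_ratings",
    "generate_cohort",
]

log = logging.getLogger(__name__)

#: clipping fraction above which simulate_ratings warns.
CLIP_WARN_FRACTION = 0.1


@dataclass
class ChoiceParams:
    """Logistic gamble-vs-certain choice rule.

    P(gamble) = expit(bias + inverse_temperature · (EV_gamble − CR)).
    ``inverse_temperature`` is per money unit; ``np.inf`` gives a
    deterministic EV-maximiser.
    """

    inverse_temperature: float = 2.0
    bias: float = 0.0

    def p_gamble(self, dev: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        dev = np.asarray(dev, dtype=float)
        if np.isinf(self.inverse_temperature):
            out = np.where(dev > 0, 1.0, np.where(dev < 0, 0.0, expit(self.bias)))
            return out
        return expit(self.bias + self.inverse_temperature * dev)


@dataclass
class CohortConfig:
    """All knobs of a synthetic study; every stochastic element is seeded.

    Defaults describe the laboratory risky-decision study: 54 depressed
    and 20 control participants, HAM-D/PHQ distributions with the groups'
    published means and SDs, rating noise sd 0.05, and a baseline-mood
    linkage slope giving a generating w0–severity Spearman near −0.30.
    Money is in pounds; ``money_scale`` rescales stakes to points (and
    weights/temperature correspondingly) for the smartphone variant.
    """

    variant: str = "lab"
    n_mdd: int = 54
    n_control: int = 20
    seed: int = 0
    # laboratory questionnaire distributions (mean, sd) per group
    hamd_mdd: tuple[float, float] = (15.6, 4.1)
    hamd_control: tuple[float, float] = (0.6, 1.0)
    phq_mdd: tuple[float, float] = (15.8, 4.7)
    phq_control: tuple[float, float] = (1.1, 1.7)
    symptom_corr: float = 0.8  # HAM-D/PHQ latent correlation
    hamd_min_mdd: float | None = None  # e.g. 14 for scanned samples
    # smartphone questionnaire (log-normal BDI-II severity continuum)
    bdi_log_mean: float = 2.2
    bdi_log_sd: float = 0.8
    # mood-parameter population
    w0_mean: float = 0.5
    w0_noise_sd: float = 0.10
    linkage_slope: float = -0.040  # on standardized symptom severity
    weight_mean: float = 0.25  # per pound
    weight_sd: float = 0.10
    weight_floor: float = 0.02
    gamma_range: tuple[float, float] = (0.25, 0.55)
    rating_noise_sd: float = 0.05
    # choice model (per pound)
    choice: ChoiceParams = field(default_factory=ChoiceParams)
    # stake scaling: 1 for pounds (lab), 80 for smartphone points
    money_scale: float = 1.0
    # probabilistic (scanner) sessions
    observation_error_rate: float = 0.03
    n_failures: int = 0  # participants missing > 30 observation choices

    @classmethod
    def laboratory(cls, n_mdd: int = 54, n_control: int = 20, seed: int = 0, **kw):
        return cls(variant="lab", n_mdd=n_mdd, n_control=n_control, seed=seed, **kw)

    @classmethod
    def smartphone(cls, n: int = 1833, seed: int = 0, **kw):
        """Smartphone cohort: a BDI-II severity continuum, stakes in points."""
        kw.setdefault("money_scale", 80.0)
        return cls(variant="smartphone", n_mdd=n, n_control=0, seed=seed, **kw)

    @classmethod
    def scanned(cls, n_mdd: int = 35, n_control: int = 20, seed: int = 0, **kw):
        """fMRI sample: probabilistic-task sessions, moderate-depression
        floor HAM-D ≥ 14, and 3 designated observation-choice failures."""
        kw.setdefault("hamd_mdd", (16.6, 2.5))
        kw.setdefault("phq_mdd", (16.9, 3.6))
        kw.setdefault("hamd_min_mdd", 14.0)
        kw.setdefault("n_failures", 3)
        return cls(
            variant="probabilistic", n_mdd=n_mdd, n_control=n_control, seed=seed, **kw
        )

    @property
    def n_total(self) -> int:
        return self.n_mdd + self.n_control

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValueError("cohort must contain at least one participant")
        if self.n_failures > self.n_mdd:
            raise ValueError("more designated failures than depressed participants")
        for name, (mu, sd) in (
            ("hamd_mdd", self.hamd_mdd),
            ("hamd_control", self.hamd_control),
            ("phq_mdd", self.phq_mdd),
            ("phq_control", self.phq_control),
        ):
            if sd < 0:
                raise ValueError(f"{name}: negative sd")
        if not (0 < self.bdi_log_sd):
            raise ValueError("bdi_log_sd must be positive")


@dataclass
class Participant:
    """One synthetic participant with metadata, true parameters, and data."""

    id: str
    group: str  # "MDD" | "control"
    hamd: float | None = None
    phq: float | None = None
    bdi: float | None = None
    anhedonia: float | None = None
    medicated: bool = False
    age: int = 0
    sex: str = "F"
    education_years: float = 16.0
    degree: bool = True
    true_params: MoodParams | None = None
    session: Session | None = None
    ratings: np.ndarray | None = None
    clip_fraction: float = 0.0
    missed_observation_count: int | None = None

    @property
    def symptom(self) -> float:
        """Primary severity score: HAM-D where present, else BDI-II."""
        return self.hamd if self.hamd is not None else self.bdi


@dataclass
class Cohort:
    participants: list[Participant]
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.participants)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            rows.append(
                {
                    "id": p.id,
                    "group": p.group,
                    "hamd": p.hamd,
                    "phq": p.phq,
                    "bdi": p.bdi,
                    "anhedonia": p.anhedonia,
                    "medicated": int(p.medicated),
                    "age": p.age,
                    "sex": p.sex,
                    "education_years": p.education_years,
                    "degree": int(p.degree),
                    "clip_fraction": p.clip_fraction,
                    "missed_observation_count": p.missed_observation_count,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# session templates and choice simulation

def _draw_risky_trial(rng: np.random.Generator, scale: float, variant: str) -> tuple:
    """One offered (certain, gamble) pair.

    Trial types rotate through gain (certain gain vs {0, larger gain}),
    loss (certain loss vs {0, larger loss}) and mixed (certain 0 vs
    {gain, loss}) stakes; smartphone spinners always use p_hi = 0.5.
    """
    kind = rng.integers(3)
    if kind == 0:  # gain
        certain = rng.uniform(0.2, 0.6)
        g = Gamble(rng.uniform(0.5, 1.5) * 1.0, 0.0, 0.5)
    elif kind == 1:  # loss
        certain = -rng.uniform(0.2, 0.6)
        g = Gamble(0.0, -rng.uniform(0.5, 1.5), 0.5)
    else:  # mixed
        certain = 0.0
        g = Gamble(rng.uniform(0.4, 1.2), -rng.uniform(0.4, 1.2), 0.5)
    certain *= scale
    g = Gamble(g.outcome_hi * scale, g.outcome_lo * scale, g.p_hi)
    return certain, g


def build_session_template(variant: str, seed: int, money_scale: float = 1.0) -> Session:
    """A session with offered options and a probe schedule but no choices."""
    if variant == "probabilistic":
        raise ValueError("probabilistic sessions are built directly with outcomes")
    n_trials, n_probes = SESSION_STRUCTURE[variant]
    rng = np.random.default_rng(seed)
    probes = build_schedule(n_trials, n_probes, int(rng.integers(2**31 - 1)))
    trials = []
    for t in range(1, n_trials + 1):
        certain, g = _draw_risky_trial(rng, money_scale, variant)
        trials.append(
            TrialRecord(
                index=t,
                choice="other",
                offered_certain=certain,
                offered_gamble=g,
            )
        )
    endow = SMARTPHONE_ENDOWMENT if variant == "smartphone" else None
    return Session(variant=variant, trials=trials, probe_after=list(probes), endowment=endow)


def simulate_choices(
    template: Session, choice_params: ChoiceParams, seed: int
) -> Session:
    """Fill a risky-session template with choices, outcomes and reveal flags.

    Gamble-vs-certain choices follow the logistic rule; gamble outcomes are
    drawn with their stated probabilities.  In the lab variant a seeded
    half of the chosen gambles (⌊n/2⌋) is marked unrevealed and their RPEs
    set to zero; smartphone gambles resolve immediately.
    """
    rng = np.random.default_rng(seed)
    dev = np.array(
        [gamble_ev(tr.offered_gamble) - tr.offered_certain for tr in template.trials]
    )
    p = choice_params.p_gamble(dev)
    take_gamble = rng.random(len(p)) < p
    trials: list[TrialRecord] = []
    for tr, g_chosen in zip(template.trials, take_gamble):
        g = tr.offered_gamble
        if g_chosen:
            outcome = g.outcome_hi if rng.random() < g.p_hi else g.outcome_lo
            ev = gamble_ev(g)
            trials.append(
                replace(
                    tr,
                    choice="gamble",
                    cr=0.0,
                    ev=ev,
                    outcome=outcome,
                    revealed=True,
                    rpe=trial_rpe(outcome, ev, True),
                )
            )
        else:
            trials.append(
                replace(
                    tr,
                    choice="certain",
                    cr=tr.offered_certain,
                    ev=0.0,
                    outcome=tr.offered_certain,
                    revealed=True,
                    rpe=0.0,
                )
            )
    if template.variant == "lab":
        g_idx = [i for i, tr in enumerate(trials) if tr.choice == "gamble"]
        hidden = rng.choice(len(g_idx), size=len(g_idx) // 2, replace=False)
        for h in hidden:
            i = g_idx[h]
            trials[i] = replace(trials[i], revealed=False, outcome=None, rpe=0.0)
    return Session(
        variant=template.variant,
        trials=trials,
        probe_after=list(template.probe_after),
        endowment=template.endowment,
    )


def simulate_ratings(
    session: Session,
    true_params: MoodParams,
    noise_sd: float,
    seed: int,
    spec: ModelSpec = MODEL_SPECS["full"],
) -> tuple[np.ndarray, float]:
    """Happiness ratings: model predictions + i.i.d. Gaussian noise,
    clipped to [0, 1].  Returns (ratings, clipped fraction); warns when
    the clipped fraction exceeds 10%."""
    pred = predict_happiness(true_params, session, spec)
    rng = np.random.default_rng(seed)
    raw = pred + rng.normal(0.0, noise_sd, size=pred.shape) if noise_sd > 0 else pred
    ratings = np.clip(raw, 0.0, 1.0)
    clip_fraction = float(np.mean(raw != ratings))
    if clip_fraction > CLIP_WARN_FRACTION:
        warnings.warn(
            f"{clip_fraction:.0%} of simulated ratings clipped to [0, 1]; "
            "consider rescaling parameters",
            stacklevel=2,
        )
    return ratings, clip_fraction


# ---------------------------------------------------------------------------
# cohort generation

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_lab_symptoms(cfg: CohortConfig, rng: np.random.Generator):
    """HAM-D and PHQ drawn jointly (positively correlated) per group,
    rounded and clipped to their scale ranges."""
    hamd = np.empty(cfg.n_total)
    phq = np.empty(cfg.n_total)
    for sl, hm, pm in (
        (slice(0, cfg.n_mdd), cfg.hamd_mdd, cfg.phq_mdd),
        (slice(cfg.n_mdd, cfg.n_total), cfg.hamd_control, cfg.phq_control),
    ):
        n = sl.stop - sl.start
        z1 = rng.standard_normal(n)
        z2 = cfg.symptom_corr * z1 + np.sqrt(1 - cfg.symptom_corr**2) * rng.standard_normal(n)
        h = hm[0] + hm[1] * z1
        if sl.start == 0 and cfg.hamd_min_mdd is not None:
            low = h < cfg.hamd_min_mdd
            while low.any():
                h[low] = hm[0] + hm[1] * rng.standard_normal(int(low.sum()))
                low = h < cfg.hamd_min_mdd
        hamd[sl] = np.clip(np.round(h), 0, 52)
        phq[sl] = np.clip(np.round(pm[0] + pm[1] * z2), 0, 27)
    return hamd, phq


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a complete synthetic study from a config.

    Symptom scores are drawn per group (lab/scanned) or as a severity
    continuum (smartphone); each participant's true baseline mood is
    w0 = w0_mean + linkage_slope · standardized(symptom) + ε while the
    event weights and forgetting factor are drawn independently of
    symptoms; sessions, choices and ratings are then simulated.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    scale = config.money_scale

    if config.variant == "smartphone":
        bdi = np.clip(np.round(np.exp(rng.normal(config.bdi_log_mean, config.bdi_log_sd, n))), 0, 63)
        symptom = bdi
        groups = np.where(bdi >= 15, "MDD", "control")
        hamd = phq = None
        anhedonia = np.clip(np.round(0.15 * bdi + rng.normal(0, 0.8, n)), 0, 12)
    else:
        hamd, phq = _draw_lab_symptoms(config, rng)
        symptom = hamd
        groups = np.array(["MDD"] * config.n_mdd + ["control"] * config.n_control)
        bdi = None
        anhedonia = np.clip(
            np.round(np.where(groups == "MDD", 2.2, 0.1) + rng.normal(0, 0.6, n)), 0, 3
        )

    s_sd = symptom.std()
    z = (symptom - symptom.mean()) / s_sd if s_sd > 0 else np.zeros(n)
    w0 = config.w0_mean + config.linkage_slope * z + rng.normal(0, config.w0_noise_sd, n)
    # per-pound weights, rescaled to the session's money unit
    wdist = lambda: np.maximum(
        rng.normal(config.weight_mean, config.weight_sd, n), config.weight_floor
    ) / scale
    w_cr, w_ev, w_rpe = wdist(), wdist(), wdist()
    gammas = rng.uniform(*config.gamma_range, n)

    age = np.clip(np.round(rng.normal(34.2, 10.0, n)), 18, 70).astype(int)
    sex = np.where(rng.random(n) < 0.55, "F", "M")
    edu = np.round(rng.normal(16.3, 2.2, n), 1)
    degree = edu >= 15.0
    med_p = np.where(groups == "MDD", 0.61, 0.0)
    medicated = rng.random(n) < med_p

    choice = config.choice
    if scale != 1.0:
        choice = ChoiceParams(choice.inverse_temperature / scale, choice.bias)

    # designated observation-choice failures (scanner variant)
    failure_ids = set(rng.choice(config.n_mdd, size=config.n_failures, replace=False)) \
        if config.n_failures else set()

    participants: list[Participant] = []
    seeds = rng.integers(0, 2**31 - 1, size=(n, 3))
    for i in range(n):
        true = MoodParams(
            w0=float(w0[i]),
            gamma=float(gammas[i]),
            w_cr=float(w_cr[i]),
            w_ev=float(w_ev[i]),
            w_rpe=float(w_rpe[i]),
        )
        p = Participant(
            id=f"p{i:04d}",
            group=str(groups[i]),
            hamd=None if hamd is None else float(hamd[i]),
            phq=None if phq is None else float(phq[i]),
            bdi=None if bdi is None else float(bdi[i]),
            anhedonia=float(anhedonia[i]),
            medicated=bool(medicated[i]),
            age=int(age[i]),
            sex=str(sex[i]),
            education_years=float(edu[i]),
            degree=bool(degree[i]),
            true_params=true,
        )
        if config.variant == "probabilistic":
            if i in failure_ids:
                n_miss = int(rng.integers(31, 61))
                sess = build_probabilistic_session(int(seeds[i, 0]), n_errors=n_miss)
            else:
                sess = build_probabilistic_session(
                    int(seeds[i, 0]), error_rate=config.observation_error_rate
                )
            p.session = sess
            p.missed_observation_count = sum(
                1 for tr in sess.trials if tr.choice != "observation"
            )
        else:
            template = build_session_template(config.variant, int(seeds[i, 0]), scale)
            sess = simulate_choices(template, choice, int(seeds[i, 1]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratings, clip = simulate_ratings(
                    sess, true, config.rating_noise_sd, int(seeds[i, 2])
                )
            sess.ratings = ratings
            p.session = sess
            p.ratings = ratings
            p.clip_fraction = clip
        participants.append(p)

    log.info(
        "generated cohort: %d participants (%d MDD, %d control), variant=%s",
        n, int((groups == "MDD").sum()), int((groups == "control").sum()), config.variant,
    )
    return Cohort(participants=participants, config=config)
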