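"""Per-participant estimation of mood-model parameters and model comparison.

The mood equation is linear in its weights once the forgetting factor
``gamma`` is fixed, so fitting is a grid search over gamma (step 0.01 on
[0, 1] by default) with the weights solved by ordinary least squares at
each grid point; the global minimum of the squared error over the grid is
returned, ties broken toward smaller gamma.  Model evidence is
approximated by a Gaussian-likelihood BIC summed across participants
(a fixed-effects comparison) — a standard desk-scale surrogate for full
Bayesian model comparison, and labelled as such in output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import MODEL_SPECS, ModelSpec, MoodParams, term_series
from .task import Session

__all__ = [
    "FitResult",
    "ModelComparisonResult",
    "fit_mood_model",
    "information_criterion",
    "compare_models",
    "DEFAULT_GAMMA_GRID",
    "SSE_FLOOR",
    "UnderdeterminedError",
    "MissingFitsError",
]

#: gamma grid: step 0.01 over [0, 1].
DEFAULT_GAMMA_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)

#: floor on the SSE inside the BIC log, guarding exact (noise-free) fits.
SSE_FLOOR = 1e-12


class UnderdeterminedError(ValueError):
    """Fewer probes with ratings than free parameters."""


class MissingFitsError(ValueError):
    """Model comparison requires every participant fitted under every spec."""


@dataclass
class FitResult:
    """Fitted parameters and goodness of fit for one participant × model."""

    params: MoodParams
    r2: float
    sse: float
    n_probes: int
    k_params: int
    ic: float
    spec_id: str
    degenerate: bool = False  # zero rating variance convention applied


def information_criterion(sse: float, n_probes: int, k_params: int) -> float:
    """Gaussian-likelihood BIC: n·ln(max(sse, floor)/n) + k·ln(n).

    Lower is better.  Serves as the model-evidence proxy for the
    fixed-effects model comparison.
    """
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    if sse < 0:
        raise ValueError("sse must be nonnegative")
    n = n_probes
    return n * math.log(max(sse, SSE_FLOOR) / n) + k_params * math.log(n)


def _design_cube(
    series: dict[str, np.ndarray],
    terms: tuple[str, ...],
    probe_idx: np.ndarray,
    grid: np.ndarray,
) -> np.ndarray:
    """Decayed term sums at the probes for every gamma on the grid.

    Returns an array of shape (n_gammas, n_probes, n_terms) built by the
    recursion s_t = gamma·s_{t−1} + x_t vectorised over the grid.
    """
    S = np.stack([series[t] for t in terms])  # (m, T)
    m, T = S.shape
    acc = np.zeros((grid.size, m))
    cube = np.empty((grid.size, m, T))
    g = grid[:, None]
    for t in range(T):
        acc = acc * g + S[:, t]
        cube[:, :, t] = acc
    return cube[:, :, probe_idx].transpose(0, 2, 1)


def fit_mood_model(
    session: Session,
    ratings: np.ndarray,
    spec: ModelSpec = MODEL_SPECS["full"],
    gamma_grid: np.ndarray | None = None,
) -> FitResult:
    """Global least-squares fit of a mood model to one session's ratings.

    ``ratings`` aligns with ``session.probe_after``.  Raises
    :class:`UnderdeterminedError` with fewer probes than parameters.  With
    zero rating variance the fit degenerates to w0 = mean rating, all
    weights zero, and r² defined as 0 (flagged and warned).
    """
    grid = DEFAULT_GAMMA_GRID if gamma_grid is None else np.asarray(gamma_grid, float)
    y = np.asarray(ratings, dtype=float)
    probes = np.asarray(session.probe_after, dtype=int)
    if y.size != probes.size:
        raise ValueError(
            f"{y.size} ratings for {probes.size} probes — they must align"
        )
    n = y.size
    k = spec.k_params
    if n < k:
        raise UnderdeterminedError(
            f"{n} probes cannot identify {k} parameters of model {spec.id!r}"
        )
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        warnings.warn(
            "zero rating variance: returning w0 = mean rating, weights 0, r2 = 0",
            stacklevel=2,
        )
        params = MoodParams(w0=float(y.mean()), gamma=float(grid[0]))
        if "r" in spec.terms:
            params.w_r, params.w_negev = 0.0, 0.0
        return FitResult(
            params=params,
            r2=0.0,
            sse=0.0,
            n_probes=n,
            k_params=k,
            ic=information_criterion(0.0, n, k),
            spec_id=spec.id,
            degenerate=True,
        )

    series = term_series(session)
    cube = _design_cube(series, spec.terms, probes - 1, grid)
    m = len(spec.terms)
    X = np.empty((n, m + 1))
    X[:, 0] = 1.0
    best_sse = np.inf
    best_beta: np.ndarray | None = None
    best_gamma = grid[0]
    for gi in range(grid.size):
        X[:, 1:] = cube[gi]
        # normal equations; lstsq fallback covers rank-deficient designs
        G = X.T @ X
        b = X.T @ y
        try:
            beta = np.linalg.solve(G, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sse = float(resid @ resid)
        if sse < best_sse - 1e-15:  # strict improvement: ties keep smaller gamma
            best_sse, best_beta, best_gamma = sse, beta.copy(), float(grid[gi])

    assert best_beta is not None
    weights = dict(zip(spec.terms, best_beta[1:]))
    params = MoodParams(
        w0=float(best_beta[0]),
        gamma=best_gamma,
        w_cr=float(weights.get("cr", 0.0)),
        w_ev=float(weights.get("ev", 0.0)),
        w_rpe=float(weights.get("rpe", 0.0)),
        w_r=float(weights["r"]) if "r" in weights else None,
        w_negev=float(weights["negev"]) if "negev" in weights else None,
    )
    best_sse = max(best_sse, 0.0)
    return FitResult(
        params=params,
        r2=1.0 - best_sse / tss,
        sse=best_sse,
        n_probes=n,
        k_params=k,
        ic=information_criterion(best_sse, n, k),
        spec_id=spec.id,
    )


@dataclass
class ModelComparisonResult:
    """Fixed-effects (summed-IC) comparison across model specs.

    ``winners`` lists every spec attaining the minimal summed IC; a list
    longer than one is a tie and is reported, never silently broken.
    ``best_counts`` counts participants for whom each spec is the unique
    per-participant minimum; ``tied_participants`` counts those with a tie.
    """

    total_ic: dict[str, float]
    winners: list[str]
    best_counts: dict[str, int]
    tied_participants: int
    n_participants: int

    @property
    def winning_spec(self) -> str | None:
        """The single winner, or None on a tie."""
        return self.winners[0] if len(self.winners) == 1 else None


_IC_TIE_TOL = 1e-9


def compare_models(
    fits: dict[object, dict[str, FitResult]]
) -> ModelComparisonResult:
    """Compare model specs across a cohort by summed information criterion.

    ``fits`` maps participant id -> {spec id -> FitResult}; every
    participant must be fitted under every spec.
    """
    if not fits:
        raise MissingFitsError("no fits supplied")
    spec_ids = sorted({s for per in fits.values() for s in per})
    missing = [
        (pid, sid)
        for pid, per in fits.items()
        for sid in spec_ids
        if sid not in per
    ]
    if missing:
        raise MissingFitsError(f"missing participant × spec fits: {missing}")

    total = {sid: sum(fits[pid][sid].ic for pid in fits) for sid in spec_ids}
    lo = min(total.values())
    winners = [sid for sid in spec_ids if total[sid] <= lo + _IC_TIE_TOL]
    best_counts = {sid: 0 for sid in spec_ids}
    tied = 0
    for pid, per in fits.items():
        plo = min(per[sid].ic for sid in spec_ids)
        best = [sid for sid in spec_ids if per[sid].ic <= plo + _IC_TIE_TOL]
        if len(best) == 1:
            best_counts[best[0]] += 1
        else:
            tied += 1
    return ModelComparisonResult(
        total_ic=total,
        winners=winners,
        best_counts=best_counts,
        tied_participants=tied,
        n_participants=len(fits),
    )
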