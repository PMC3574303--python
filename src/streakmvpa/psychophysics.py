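"""QUEST adaptive staircases and threshold-elevation analysis.

The contrast-detection experiment is simulated end-to-end: a Bayesian QUEST
staircase maintains a posterior over the observer's log10 contrast
threshold, places each trial at the current posterior mean, and updates the
posterior with the Weibull 2AFC likelihood.  Two staircases per condition
are interleaved trial-by-trial, as in the adaptation procedure, and the
threshold estimate is the mean of the per-staircase posterior means.

Threshold elevation is expressed in decibels with the amplitude convention
``20 * log10(threshold ratio)`` (a factor-10 threshold increase is 20 dB); a
``db_factor`` switch provides the 10*log10 power convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .group_inference import RMAnovaResult, rm_anova
from .psychometric import weibull_2afc
from .synthetic_data import UNADAPTED, ObserverParams, simulate_observer_response

logger = logging.getLogger(__name__)

__all__ = [
    "QuestSettings",
    "QuestState",
    "quest_update",
    "quest_next_level",
    "run_condition",
    "ConditionResult",
    "elevation_db",
    "elevation_analysis",
    "ElevationAnalysis",
    "SPEEDS",
    "ORIENTATIONS",
]

SPEEDS = ("fast", "slow")
ORIENTATIONS = ("parallel", "orthogonal")


@dataclass(frozen=True)
class QuestSettings:
    """QUEST constants: Weibull slope/lapse/guess, prior, grid, read-out.

    Defaults are the conventional choices for a 2AFC contrast task:
    beta 3.5, delta 0.01, gamma 0.5, Gaussian prior SD 1 log unit, grid
    from -4 to 0 log10 contrast in 0.005 steps, posterior-mean read-out.
    """

    beta: float = 3.5
    delta: float = 0.01
    gamma: float = 0.5
    prior_sd: float = 1.0
    grid_lo: float = -4.0
    grid_hi: float = 0.0
    grid_step: float = 0.005
    readout: str = "mean"  # or "mode"

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return np.linspace(self.grid_lo, self.grid_hi, n)


@dataclass
class QuestState:
    """Posterior over log10 threshold on a finite uniform grid."""

    grid: np.ndarray
    log_posterior: np.ndarray
    beta: float
    delta: float
    gamma: float
    trial_log: list[tuple[float, bool]] = field(default_factory=list)

    @classmethod
    def from_settings(cls, settings: QuestSettings, t_guess: float) -> "QuestState":
        grid = settings.grid()
        log_prior = -0.5 * ((grid - t_guess) / settings.prior_sd) ** 2
        state = cls(
            grid=grid,
            log_posterior=log_prior,
            beta=settings.beta,
            delta=settings.delta,
            gamma=settings.gamma,
        )
        state._normalize()
        return state

    def _normalize(self) -> None:
        self.log_posterior = self.log_posterior - np.max(self.log_posterior)
        self.log_posterior -= np.log(np.sum(np.exp(self.log_posterior)))

    def posterior(self) -> np.ndarray:
        return np.exp(self.log_posterior)

    def mean(self) -> float:
        return float(self.posterior() @ self.grid)

    def mode(self) -> float:
        return float(self.grid[int(np.argmax(self.log_posterior))])


def quest_update(state: QuestState, level: float, response: bool) -> QuestState:
    """Bayesian update after one trial at ``level`` (log10 contrast).

    The posterior is multiplied pointwise by the likelihood of the response
    under the Weibull psychometric function evaluated at every candidate
    threshold, then renormalized.  Updates commute (pointwise products).
    """
    level = float(np.clip(level, state.grid[0], state.grid[-1]))
    p_correct = weibull_2afc(level, state.grid, beta=state.beta, gamma=state.gamma, delta=state.delta)
    likelihood = p_correct if response else 1.0 - p_correct
    new = QuestState(
        grid=state.grid,
        log_posterior=state.log_posterior + np.log(np.maximum(likelihood, 1e-300)),
        beta=state.beta,
        delta=state.delta,
        gamma=state.gamma,
        trial_log=[*state.trial_log, (level, bool(response))],
    )
    new._normalize()
    return new


def quest_next_level(state: QuestState, readout: str = "mean") -> float:
    """Placement rule: the posterior mean (or mode) of the threshold,
    clipped to the achievable contrast range spanned by the grid."""
    est = state.mean() if readout == "mean" else state.mode()
    lo, hi = float(state.grid[0]), float(state.grid[-1])
    if est < lo or est > hi:
        logger.warning("quest_next_level: estimate %.3f clipped to grid [%.2f, %.2f]", est, lo, hi)
    return float(np.clip(est, lo, hi))


@dataclass
class ConditionResult:
    """Threshold estimate for one adaptation condition."""

    condition: tuple[str, str] | str
    estimate_log10: float
    staircase_estimates: list[float]
    trials: pd.DataFrame  # staircase, trial, level, response


def run_condition(
    observer: ObserverParams,
    condition: tuple[str, str] | str,
    n_trials: int = 40,
    n_staircases: int = 2,
    seed: int | np.random.SeedSequence | None = None,
    settings: QuestSettings = QuestSettings(),
    t_guess: float | None = None,
) -> ConditionResult:
    """Measure one condition's threshold with interleaved QUEST staircases.

    ``n_trials`` is per staircase (>= 10); staircases are interleaved
    trial-by-trial and the final estimate is the mean of the per-staircase
    posterior means.
    """
    if n_trials < 10:
        raise ValueError("need at least 10 trials per staircase")
    rng = np.random.default_rng(seed)
    if t_guess is None:
        t_guess = observer.t0_log10  # prior centered on the unadapted ballpark
    states = [QuestState.from_settings(settings, t_guess) for _ in range(n_staircases)]
    log_rows = []
    for trial in range(n_trials * n_staircases):
        sc = trial % n_staircases
        level = quest_next_level(states[sc], settings.readout)
        response = simulate_observer_response(observer, condition, level, rng)
        states[sc] = quest_update(states[sc], level, response)
        log_rows.append({"staircase": sc, "trial": trial // n_staircases, "level": level, "response": response})
    per_staircase = [
        s.mean() if settings.readout == "mean" else s.mode() for s in states
    ]
    return ConditionResult(
        condition=condition,
        estimate_log10=float(np.mean(per_staircase)),
        staircase_estimates=per_staircase,
        trials=pd.DataFrame(log_rows),
    )


def elevation_db(t_adapt: float, t_unadapted: float, db_factor: float = 20.0) -> float:
    """Threshold elevation in decibels: ``db_factor * (t_adapt - t_unadapted)``
    for log10 thresholds (20x -> amplitude convention, 10x -> power)."""
    return db_factor * (t_adapt - t_unadapted)


@dataclass
class ElevationAnalysis:
    """Per-cell elevations, the speed x orientation ANOVA, and pairwise tests."""

    table: pd.DataFrame  # participant, speed, orientation, elevation_db
    anova: RMAnovaResult
    pairwise: pd.DataFrame  # speed, t, p_uncorrected, p_corrected

    @property
    def cell_means(self) -> pd.DataFrame:
        return self.table.groupby(["speed", "orientation"], observed=True)["elevation_db"].mean().unstack()


def elevation_analysis(
    estimates: pd.DataFrame,
    db_factor: float = 20.0,
    correction_divisor: int = 2,
) -> ElevationAnalysis:
    """Threshold-elevation table plus the 2x2 repeated-measures ANOVA.

    ``estimates`` is long-format with columns participant, speed,
    orientation, threshold_log10; the unadapted baseline is the row with
    speed == "unadapted" (orientation ignored).  Pairwise tests compare
    parallel vs orthogonal elevations within each speed (paired t,
    Bonferroni over the two comparisons by default).
    """
    from scipy import stats

    base = estimates[estimates["speed"] == UNADAPTED].set_index("participant")["threshold_log10"]
    adapted = estimates[estimates["speed"] != UNADAPTED].copy()
    if base.empty:
        raise ValueError("no unadapted baseline rows")
    expected = {(s, o) for s in SPEEDS for o in ORIENTATIONS}
    for pid, grp in adapted.groupby("participant"):
        cells = set(zip(grp["speed"], grp["orientation"]))
        if cells != expected:
            raise ValueError(f"participant {pid}: incomplete 2x2 design {sorted(cells)}")
        if pid not in base.index:
            raise ValueError(f"participant {pid}: missing unadapted baseline")
    adapted["elevation_db"] = [
        elevation_db(t, base[pid], db_factor)
        for pid, t in zip(adapted["participant"], adapted["threshold_log10"])
    ]
    table = adapted[["participant", "speed", "orientation", "elevation_db"]].reset_index(drop=True)

    anova = rm_anova(table, dv="elevation_db", subject="participant", within=["speed", "orientation"])

    wide = table.pivot_table(index="participant", columns=["speed", "orientation"], values="elevation_db")
    rows = []
    for speed in SPEEDS:
        par, orth = wide[(speed, "parallel")], wide[(speed, "orthogonal")]
        if (par - orth).std(ddof=1) == 0:
            logger.warning("elevation pairwise test degenerate for speed=%s", speed)
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(par, orth)
        rows.append(
            {
                "speed": speed,
                "t_parallel_minus_orthogonal": float(t),
                "p_uncorrected": float(p),
                "p_corrected": float(min(p * correction_divisor, 1.0)),
            }
        )
    return ElevationAnalysis(table=table, anova=anova, pairwise=pd.DataFrame(rows))
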