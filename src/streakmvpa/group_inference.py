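"""Group-level inference: simulated chance distribution, t-tests with
Bonferroni-by-ROI correction, repeated-measures ANOVA, percent signal change.

The chance distribution mirrors the study's permutation logic: in each of
50,000 iterations, every participant's per-trial decoding outcome is a fair
coin (10 runs x 2 trials), and the group-mean accuracy is recorded.  Because
the group mean over equal-sized participants is a pooled Binomial(160, 0.5)
count divided by 160, the empirical 2.5th/97.5th percentiles land exactly on
68/160 = 0.425 and 92/160 = 0.575.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import discard_dummies
from .synthetic_data import RunTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ChanceDistribution",
    "RMAnovaResult",
    "simulate_chance_ci",
    "one_sample_t_vs_chance",
    "bonferroni_by_roi",
    "rm_anova",
    "percent_signal_change",
    "paired_t_table",
]


@dataclass
class ChanceDistribution:
    """Simulated null distribution of group-mean decoding accuracy."""

    n_iter: int
    n_participants: int
    n_runs: int
    trials_per_run: int
    p_null: float
    samples: np.ndarray
    ci95: tuple[float, float]

    def contains(self, accuracy: float) -> bool:
        return self.ci95[0] <= accuracy <= self.ci95[1]


def _nearest_rank_percentile(sorted_samples: np.ndarray, q: float) -> float:
    """Nearest-rank empirical percentile: value at rank ceil(q*n) (1-based)."""
    n = len(sorted_samples)
    rank = int(np.ceil(q * n))
    return float(sorted_samples[max(rank, 1) - 1])


def simulate_chance_ci(
    n_iter: int = 50_000,
    n_participants: int = 8,
    n_runs: int = 10,
    trials_per_run: int = 2,
    p_null: float = 0.5,
    seed: int | np.random.SeedSequence | None = None,
) -> ChanceDistribution:
    """Monte-Carlo 95% CI of group-mean accuracy under per-trial chance.

    Per iteration, each participant's number of correct classifications is
    drawn Binomial(n_runs * trials_per_run, p_null); the group mean accuracy
    is stored and the CI is the empirical 2.5th/97.5th percentile pair.
    With the study's parameters this returns (0.425, 0.575).
    """
    if min(n_iter, n_participants, n_runs, trials_per_run) < 1:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    n_trials = n_runs * trials_per_run
    correct = rng.binomial(n_trials, p_null, size=(n_iter, n_participants))
    samples = correct.mean(axis=1) / n_trials
    s = np.sort(samples)
    ci = (_nearest_rank_percentile(s, 0.025), _nearest_rank_percentile(s, 0.975))
    return ChanceDistribution(n_iter, n_participants, n_runs, trials_per_run, p_null, samples, ci)


def one_sample_t_vs_chance(
    accuracies: Sequence[float], chance: float = 0.5
) -> tuple[float, int, float]:
    """Classical one-sample t-test of per-participant accuracies vs chance.

    Returns (t, df, two-tailed p).  Zero-variance input yields a signed
    infinite t (p = 0, or t = 0/p = 1 if the mean equals chance) with a
    warning rather than an exception.
    """
    a = np.asarray(accuracies, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 observations")
    df = len(a) - 1
    if a.std(ddof=1) == 0:
        if a.mean() == chance:
            warnings.warn("degenerate t-test: zero variance at chance; t set to 0")
            return 0.0, df, 1.0
        warnings.warn("degenerate t-test: zero variance off chance; t set to signed infinity")
        return float(np.sign(a.mean() - chance) * np.inf), df, 0.0
    t, p = stats.ttest_1samp(a, chance)
    return float(t), df, float(p)


def bonferroni_by_roi(
    p_values: Mapping[str, float] | Sequence[float], n_rois: int = 5, alpha: float = 0.05
) -> dict | list:
    """Flag significance at ``p < alpha / n_rois`` (strict, as p < 0.01 for 5 ROIs)."""
    thresh = alpha / n_rois
    if isinstance(p_values, Mapping):
        return {k: bool(v < thresh) for k, v in p_values.items()}
    return [bool(v < thresh) for v in p_values]


@dataclass
class RMAnovaResult:
    """F, dfs and p per within-subject effect, plus degenerate-effect flags."""

    factors: tuple[str, ...]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    degenerate: list[str] = field(default_factory=list)

    def f(self, effect: str) -> float:
        return self.effects[effect]["F"]

    def df(self, effect: str) -> tuple[int, int]:
        e = self.effects[effect]
        return int(e["df_num"]), int(e["df_den"])

    def p(self, effect: str) -> float:
        return self.effects[effect]["p"]


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: Sequence[str],
) -> RMAnovaResult:
    """Balanced within-subject repeated-measures ANOVA (1 or 2 factors).

    Classical sums-of-squares decomposition; each effect is tested against
    its own subject-by-effect interaction error term.  No sphericity
    correction is applied.  Effects whose F is undefined (zero effect and
    zero noise) are flagged as degenerate, not raised.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports 1 or 2 within-subject factors")
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("design must be complete and balanced with one value per cell")

    from statsmodels.stats.anova import AnovaRM

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = AnovaRM(data, depvar=dv, subject=subject, within=list(within)).fit().anova_table

    ss = _within_subject_ss(data, dv, subject, within)
    result = RMAnovaResult(factors=tuple(within))
    for effect, row in table.iterrows():
        F = float(row["F Value"])
        entry = {
            "F": F,
            "df_num": float(row["Num DF"]),
            "df_den": float(row["Den DF"]),
            "p": float(row["Pr > F"]),
        }
        eff_ss, err_ss, scale = ss[str(effect)]
        # 0/0: no effect and no subject-by-effect error left to test against
        if not np.isfinite(F) or (eff_ss <= 1e-12 * scale and err_ss <= 1e-12 * scale):
            entry["F"] = float("nan")
            entry["p"] = float("nan")
            result.degenerate.append(str(effect))
            logger.warning("rm_anova: effect %s degenerate (F undefined)", effect)
        result.effects[str(effect)] = entry
    return result


def _within_subject_ss(data, dv, subject, within):
    """Effect and error sums of squares per within-subject effect."""
    wide = data.pivot_table(index=subject, columns=list(within), values=dv)
    y = wide.to_numpy(float)
    shape = [len(wide)] + [len(lv) for lv in wide.columns.levels] if len(within) > 1 else list(y.shape)
    y = y.reshape(shape)
    g = y.mean()
    scale = max(np.sum((y - g) ** 2), 1.0)
    ys = y.mean(axis=tuple(range(1, y.ndim)), keepdims=True)
    out = {}
    for axes, name in _effect_axes(within):
        keep = tuple(a for a in range(1, y.ndim) if a not in axes)
        y_eff = y.mean(axis=(0, *keep), keepdims=True)
        if len(axes) == 1:
            eff_ss = float(np.sum((y.mean(axis=(0, *keep)) - g) ** 2)) * (y.size // y.mean(axis=(0, *keep)).size)
            cell = y.mean(axis=keep, keepdims=True)
            resid = cell - y_eff - ys + g
            err_ss = float(np.sum(resid**2)) * (y.size // cell.size)
        else:  # two-way interaction
            ya = y.mean(axis=(0, 2), keepdims=True)
            yb = y.mean(axis=(0, 1), keepdims=True)
            yab = y.mean(axis=0, keepdims=True)
            eff_ss = float(np.sum((yab - ya - yb + g) ** 2)) * y.shape[0]
            yas = y.mean(axis=2, keepdims=True)
            ybs = y.mean(axis=1, keepdims=True)
            resid = y - yab - yas - ybs + ya + yb + ys - g
            err_ss = float(np.sum(resid**2))
        out[name] = (eff_ss, err_ss, scale)
    return out


def _effect_axes(within):
    effects = [((i + 1,), f) for i, f in enumerate(within)]
    if len(within) == 2:
        effects.append(((1, 2), f"{within[0]}:{within[1]}"))
    return effects


def percent_signal_change(
    run: RunTimeSeries, shift_vols: int = 1
) -> dict[str, float]:
    """Per-condition percent BOLD signal change relative to the run's global mean.

    Computed on un-z-scored data after dummy discard: for each condition,
    the mean over the lag-shifted block window minus the mean over fixation
    volumes (volumes belonging to no shifted block window), as a percentage
    of the run's global mean signal.
    """
    if run.n_dummy:
        run = discard_dummies(run)
    n_vols = run.n_volumes
    in_block = np.zeros(n_vols, dtype=bool)
    windows = {}
    for ev in run.events:
        start, stop = ev.onset_vol + shift_vols, ev.onset_vol + shift_vols + ev.duration_vol
        if start < 0 or stop > n_vols:
            raise ValueError(f"shifted window for {ev.condition} exceeds run")
        windows[ev.condition] = (start, stop)
        in_block[start:stop] = True
    if in_block.all():
        raise ValueError("run contains no fixation volumes")
    global_mean = float(run.data.mean())
    if global_mean == 0:
        raise ValueError("zero global mean signal")
    fix_mean = float(run.data[:, ~in_block].mean())
    psc = {}
    for cond, (start, stop) in windows.items():
        cond_mean = float(run.data[:, start:stop].mean())
        psc[cond] = 100.0 * (cond_mean - fix_mean) / global_mean
    return psc


def paired_t_table(
    psc: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]] = (("fast", "slow"), ("slow", "static")),
    rois: Sequence[str] | None = None,
    correction_divisor: int | None = None,
) -> pd.DataFrame:
    """Paired t-tests between stimulus types per ROI, Bonferroni-corrected.

    ``psc`` is long-format with columns participant, roi, stimulus_type,
    psc.  The Bonferroni divisor defaults to the number of cells in the
    table (contrasts x ROIs).  Degenerate contrasts (zero-variance paired
    differences) are flagged in the ``degenerate`` column.
    """
    if rois is None:
        rois = [r for r in psc["roi"].unique()]
    if correction_divisor is None:
        correction_divisor = len(rois) * len(contrasts)
    wide = psc.pivot_table(index=["participant", "roi"], columns="stimulus_type", values="psc")
    rows = []
    for roi in rois:
        sub = wide.xs(roi, level="roi")
        for a, b in contrasts:
            diffs = (sub[a] - sub[b]).to_numpy(float)
            degenerate = bool(diffs.std(ddof=1) == 0)
            if degenerate:
                logger.warning("paired_t_table: %s>%s in %s has zero-variance differences", a, b, roi)
                t = 0.0 if np.allclose(diffs, 0) else float(np.sign(diffs.mean()) * np.inf)
                p = 1.0 if t == 0.0 else 0.0
            else:
                t, p = stats.ttest_rel(sub[a], sub[b])
            rows.append(
                {
                    "roi": roi,
                    "contrast": f"{a}>{b}",
                    "t": float(t),
                    "p_uncorrected": float(p),
                    "p_corrected": float(min(p * correction_divisor, 1.0)),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
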