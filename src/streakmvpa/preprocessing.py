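"""Run-level preprocessing: dummy discard, per-run z-scoring, block averaging.

The fixed order is discard -> z-score -> shift -> average.  Volume indexing
is 0-based and block windows are half-open ``[onset + shift, onset + shift +
duration)``.  Z-scoring uses the (n-1) denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import Event, RunTimeSeries, parse_condition

logger = logging.getLogger(__name__)

__all__ = ["PatternSet", "discard_dummies", "zscore_per_run", "shift_and_average", "build_pattern_set"]


@dataclass
class PatternSet:
    """Block-averaged voxel patterns with condition labels.

    One row per stimulus block; for the default design that is
    runs x 6 = 60 patterns per participant per ROI.
    """

    patterns: np.ndarray  # block x voxel, z-units
    class_label: np.ndarray  # per block: 45 or 135
    stimulus_type: np.ndarray  # per block: static | slow | fast
    run_index: np.ndarray  # per block: 1..n_runs
    roi_id: str

    @property
    def n_blocks(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def subset(self, mask: np.ndarray) -> "PatternSet":
        return PatternSet(
            patterns=self.patterns[mask],
            class_label=self.class_label[mask],
            stimulus_type=self.stimulus_type[mask],
            run_index=self.run_index[mask],
            roi_id=self.roi_id,
        )

    def of_type(self, stimulus_type: str) -> "PatternSet":
        return self.subset(self.stimulus_type == stimulus_type)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run, type, label, then voxel values."""
        meta = pd.DataFrame(
            {"run": self.run_index, "stimulus_type": self.stimulus_type, "class_label": self.class_label}
        )
        vox = pd.DataFrame(self.patterns, columns=[f"v{i}" for i in range(self.n_voxels)])
        return pd.concat([meta, vox], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, roi_id: str) -> "PatternSet":
        vox_cols = [c for c in frame.columns if c.startswith("v") and c[1:].isdigit()]
        return cls(
            patterns=frame[vox_cols].to_numpy(float),
            class_label=frame["class_label"].to_numpy(int),
            stimulus_type=frame["stimulus_type"].to_numpy(str),
            run_index=frame["run"].to_numpy(int),
            roi_id=roi_id,
        )


def discard_dummies(run: RunTimeSeries, n: int | None = None) -> RunTimeSeries:
    """Drop the first ``n`` volumes (magnetic-saturation dummies).

    Event onsets are re-expressed relative to the new time origin.
    ``n`` defaults to the run's recorded dummy count.
    """
    if n is None:
        n = run.n_dummy
    if n < 0 or n >= run.n_volumes:
        raise ValueError(f"cannot discard {n} of {run.n_volumes} volumes")
    events = tuple(replace(ev, onset_vol=ev.onset_vol - n) for ev in run.events)
    for ev in events:
        if ev.onset_vol < 0:
            raise ValueError(f"event {ev.condition} starts inside the discarded dummies")
    return replace(run, data=run.data[:, n:], events=events, n_dummy=0)


def zscore_per_run(run: RunTimeSeries, ddof: int = 1) -> RunTimeSeries:
    """Z-score each voxel's time course across the run (SD with n-1).

    Zero-variance voxels are flagged, logged, and set to all-zero rather
    than raising.
    """
    if run.n_volumes < 2:
        raise ValueError("need at least 2 volumes to z-score")
    mean = run.data.mean(axis=1, keepdims=True)
    sd = run.data.std(axis=1, ddof=ddof, keepdims=True)
    # variance at float-rounding scale relative to the signal level is
    # indistinguishable from constant and would amplify cancellation noise
    tol = 1e-12 * (np.abs(mean.ravel()) + 1.0)
    flat = (sd.ravel() <= tol) | ~np.isfinite(sd.ravel())
    if flat.any():
        logger.warning(
            "run %s/%s: %d zero-variance voxel(s) set to zero", run.roi_id, run.run_index, int(flat.sum())
        )
        sd[flat] = 1.0
    z = (run.data - mean) / sd
    z[flat] = 0.0
    return replace(run, data=z)


def shift_and_average(run: RunTimeSeries, shift_vols: int = 1) -> PatternSet:
    """Average each block's volumes after a haemodynamic-lag shift.

    For each event, the pattern is the mean over volumes
    ``[onset + shift, onset + shift + duration)``; the row is labelled from
    the event's condition.
    """
    rows, labels, types, runs = [], [], [], []
    for ev in run.events:
        start = ev.onset_vol + shift_vols
        stop = start + ev.duration_vol
        if start < 0 or stop > run.n_volumes:
            raise ValueError(
                f"shifted window [{start}, {stop}) for block {ev.condition!r} "
                f"(run {run.run_index}) exceeds the {run.n_volumes}-volume run"
            )
        stim, ori = parse_condition(ev.condition)
        rows.append(run.data[:, start:stop].mean(axis=1))
        labels.append(ori)
        types.append(stim)
        runs.append(run.run_index)
    return PatternSet(
        patterns=np.asarray(rows),
        class_label=np.asarray(labels, dtype=int),
        stimulus_type=np.asarray(types, dtype=object),
        run_index=np.asarray(runs, dtype=int),
        roi_id=run.roi_id,
    )


def build_pattern_set(runs: Sequence[RunTimeSeries], shift_vols: int = 1) -> PatternSet:
    """Full preprocessing chain over a participant's runs for one ROI:
    discard dummies, z-score per run, shift and block-average, concatenate."""
    parts = [shift_and_average(zscore_per_run(discard_dummies(r)), shift_vols) for r in runs]
    return PatternSet(
        patterns=np.concatenate([p.patterns for p in parts]),
        class_label=np.concatenate([p.class_label for p in parts]),
        stimulus_type=np.concatenate([p.stimulus_type for p in parts]),
        run_index=np.concatenate([p.run_index for p in parts]),
        roi_id=runs[0].roi_id,
    )
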