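"""Synthetic block-design fMRI sessions and simulated 2AFC observers.

The generator emulates a motion-streak study: participants view three
stimulus types (static oriented noise, slow-moving dots, fast-moving dots),
each at two orientations/directions (45 deg / 135 deg), in a randomized
block design.  Voxels in early-visual ROIs carry orientation-tuned
responses; the fast-motion pattern shares a configurable fraction of its
variance with the static-orientation map (the "streak" signal), while the
slow-motion pattern is built from an independent direction map.  A frontal
control ROI carries no label-dependent signal at all.

The psychophysical side provides a 2AFC contrast-detection observer whose
log threshold is multiplicatively elevated by adaptation, to be probed by
the QUEST staircases in :mod:`streakmvpa.psychophysics`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psychometric import weibull_2afc

__all__ = [
    "STIMULUS_TYPES",
    "CLASS_LABELS",
    "CONDITIONS",
    "DEFAULT_ROIS",
    "SessionDesign",
    "EncodingParams",
    "Event",
    "RunTimeSeries",
    "Session",
    "ObserverParams",
    "gamma_hrf",
    "generate_session",
    "write_dataset",
    "simulate_observer_response",
    "condition_label",
    "parse_condition",
]

STIMULUS_TYPES = ("static", "slow", "fast")
CLASS_LABELS = (45, 135)
CONDITIONS = tuple(f"{s}_{o}" for s in STIMULUS_TYPES for o in CLASS_LABELS)
DEFAULT_ROIS = ("V1", "V2", "V3", "hMT", "control")


def condition_label(stimulus_type: str, orientation: int) -> str:
    return f"{stimulus_type}_{orientation}"


def parse_condition(label: str) -> tuple[str, int]:
    """Split ``"fast_135"`` into ``("fast", 135)``."""
    stim, ori = label.rsplit("_", 1)
    if stim not in STIMULUS_TYPES or int(ori) not in CLASS_LABELS:
        raise ValueError(f"unrecognized condition label {label!r}")
    return stim, int(ori)


# ---------------------------------------------------------------------------
# design & parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionDesign:
    """Timing skeleton of one scanning session.

    Defaults follow the study design: TR 3.2 s, 5 dummy volumes, six 22.4 s
    condition blocks (7 volumes) each followed by 16 s fixation (5 volumes),
    77 volumes per run, 10 runs, 8 participants.
    """

    tr_s: float = 3.2
    n_dummy: int = 5
    block_len_vol: int = 7
    fixation_len_vol: int = 5
    n_runs: int = 10
    n_participants: int = 8
    conditions: tuple[str, ...] = CONDITIONS

    @property
    def volumes_per_run(self) -> int:
        return self.n_dummy + len(self.conditions) * (self.block_len_vol + self.fixation_len_vol)

    def validate(self) -> None:
        if self.n_dummy < 0 or self.block_len_vol <= 0 or self.fixation_len_vol < 0:
            raise ValueError("block/fixation/dummy volume counts are inconsistent")
        if self.n_runs < 1 or self.n_participants < 1 or self.tr_s <= 0:
            raise ValueError("invalid session design")
        for c in self.conditions:
            parse_condition(c)


def _as_roi_map(value: float | Mapping[str, float], rois: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(rois) - set(value)
        if missing:
            raise ValueError(f"per-ROI parameter missing entries for {sorted(missing)}")
        return {r: float(value[r]) for r in rois}
    return {r: float(value) for r in rois}


@dataclass
class EncodingParams:
    """Generative model of voxel selectivity and shared representations.

    ``shared_weight_fast`` is the fraction of the fast-motion pattern drawn
    from the static-orientation map — the motion-streak signal.  The default
    per-ROI profile makes orientation decodable in V1/V2 and puts the
    strongest orientation<->fast generalization in V2, with the frontal
    control ROI carrying no stimulus-specific signal (gain 0).  These are
    package defaults chosen to produce that qualitative pattern, not
    empirical estimates.
    """

    rois: tuple[str, ...] = DEFAULT_ROIS
    n_voxels_per_roi: int = 100
    tuning_gain: float = 1.0
    tuning_width_deg: float = 30.0
    direction_gain_ratio: float = 0.05
    shared_weight_fast: float | Mapping[str, float] = field(
        default_factory=lambda: {"V1": 0.05, "V2": 0.75, "V3": 0.2, "hMT": 0.2, "control": 0.0}
    )
    shared_weight_slow: float | Mapping[str, float] = 0.0
    motion_generic_gain: Mapping[str, float] = field(
        default_factory=lambda: {"fast": 0.6, "slow": 0.1}
    )
    noise_sd: float = 3.0
    baseline: float = 100.0
    run_offset_sd: float = 0.5
    dummy_baseline_boost: float = 3.0
    roi_gain: float | Mapping[str, float] = field(
        default_factory=lambda: {"V1": 1.0, "V2": 1.0, "V3": 0.15, "hMT": 0.1, "control": 0.0}
    )

    def validate(self) -> None:
        if self.n_voxels_per_roi < 1:
            raise ValueError("n_voxels_per_roi must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for name in ("shared_weight_fast", "shared_weight_slow"):
            for roi, w in _as_roi_map(getattr(self, name), self.rois).items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(f"{name}[{roi}]={w} outside [0, 1]")
        for speed in ("fast", "slow"):
            if speed not in self.motion_generic_gain:
                raise ValueError("motion_generic_gain needs 'fast' and 'slow' entries")

    def roi_maps(self) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
        return (
            _as_roi_map(self.roi_gain, self.rois),
            _as_roi_map(self.shared_weight_fast, self.rois),
            _as_roi_map(self.shared_weight_slow, self.rois),
        )


@dataclass(frozen=True)
class Event:
    """One stimulus block: condition label plus onset/duration in volumes."""

    condition: str
    onset_vol: int
    duration_vol: int

    @property
    def stimulus_type(self) -> str:
        return parse_condition(self.condition)[0]

    @property
    def class_label(self) -> int:
        return parse_condition(self.condition)[1]


@dataclass
class RunTimeSeries:
    """One run's voxel x volume BOLD-like matrix for a single ROI."""

    data: np.ndarray
    tr_s: float
    n_dummy: int
    events: tuple[Event, ...]
    roi_id: str
    run_index: int = 0

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        last = -1
        for ev in sorted(self.events, key=lambda e: e.onset_vol):
            if ev.onset_vol <= last:
                raise ValueError(f"overlapping events around volume {ev.onset_vol}")
            if ev.onset_vol < 0 or ev.onset_vol + ev.duration_vol > self.n_volumes:
                raise ValueError(f"event {ev.condition} at volume {ev.onset_vol} exceeds run")
            last = ev.onset_vol + ev.duration_vol - 1


@dataclass
class Session:
    """All runs of one synthetic participant, keyed by ROI."""

    participant: str
    design: SessionDesign
    roi_runs: dict[str, list[RunTimeSeries]]

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(self.roi_runs)


# ---------------------------------------------------------------------------
# haemodynamics & generation
# ---------------------------------------------------------------------------


def gamma_hrf(tr_s: float, shape: float = 7.0, scale_s: float = 0.8, duration_s: float = 32.0) -> np.ndarray:
    """Gamma-variate haemodynamic response sampled on the TR grid.

    Peak-normalized; with the defaults the peak sits at (shape-1)*scale =
    4.8 s, so a 1-TR (3.2 s) shift approximately aligns a block window with
    the plateau of the convolved response, and the response has decayed to
    ~0.1% of peak 16 s after stimulus offset — by the end of a fixation
    interval, as for the canonical haemodynamic response.
    """
    t = np.arange(0.0, duration_s + tr_s / 2, tr_s)
    h = stats.gamma.pdf(t, a=shape, scale=scale_s)
    return h / h.max()


def _von_mises_tuning(theta_deg: float, pref_deg: np.ndarray, gain: float, width_deg: float) -> np.ndarray:
    """Orientation tuning on the doubled angle (period 180 deg).

    kappa is set so the small-angle limit matches a Gaussian of SD
    ``width_deg``: exp(kappa*(cos(2*delta)-1)) ~ exp(-delta^2/(2*sd^2)).
    """
    kappa = 1.0 / (4.0 * np.deg2rad(width_deg) ** 2)
    delta = np.deg2rad(theta_deg - pref_deg)
    return gain * np.exp(kappa * (np.cos(2.0 * delta) - 1.0))


def _condition_amplitudes(
    params: EncodingParams, roi: str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-voxel noiseless response amplitude for each of the 6 conditions."""
    roi_gain, w_fast, w_slow = (m[roi] for m in params.roi_maps())
    nv = params.n_voxels_per_roi
    # three mutually independent preference maps: static orientation f,
    # fast-motion direction d, slow-motion direction d'.  Direction maps
    # carry a reduced amplitude (direction_gain_ratio), reflecting the weak
    # voxel-scale direction signal that block-design MVPA typically sees.
    prefs = {key: rng.uniform(0.0, 180.0, size=nv) for key in ("static", "fast", "slow")}
    gains = {
        "static": params.tuning_gain,
        "fast": params.tuning_gain * params.direction_gain_ratio,
        "slow": params.tuning_gain * params.direction_gain_ratio,
    }

    def tuned(key: str, theta: float) -> np.ndarray:
        return _von_mises_tuning(theta, prefs[key], gains[key], params.tuning_width_deg)

    amps: dict[str, np.ndarray] = {}
    for ori in CLASS_LABELS:
        f = tuned("static", ori)
        amps[condition_label("static", ori)] = roi_gain * f
        amps[condition_label("fast", ori)] = roi_gain * (
            w_fast * f + (1.0 - w_fast) * tuned("fast", ori) + params.motion_generic_gain["fast"]
        )
        amps[condition_label("slow", ori)] = roi_gain * (
            w_slow * f + (1.0 - w_slow) * tuned("slow", ori) + params.motion_generic_gain["slow"]
        )
    return amps


def _run_events(design: SessionDesign, order: np.ndarray) -> tuple[Event, ...]:
    period = design.block_len_vol + design.fixation_len_vol
    return tuple(
        Event(design.conditions[c], design.n_dummy + k * period, design.block_len_vol)
        for k, c in enumerate(order)
    )


def generate_session(
    params: EncodingParams,
    design: SessionDesign,
    participant_seed: int | np.random.SeedSequence,
    participant: str = "sub-01",
) -> Session:
    """Generate one participant's synthetic session for every ROI.

    Each condition block is a boxcar convolved with the gamma-variate HRF,
    scaled per voxel by the condition amplitude, with i.i.d. Gaussian noise
    per volume, a run-specific baseline offset, and dummy volumes carrying an
    elevated baseline but no task signal.  Deterministic given the seed.
    """
    params.validate()
    design.validate()
    rng = np.random.default_rng(participant_seed)
    n_vols = design.volumes_per_run
    hrf = gamma_hrf(design.tr_s)

    # condition order per run is shared across ROIs (one scanner session)
    orders = [rng.permutation(len(design.conditions)) for _ in range(design.n_runs)]

    roi_runs: dict[str, list[RunTimeSeries]] = {}
    for roi in params.rois:
        amps = _condition_amplitudes(params, roi, rng)
        runs = []
        for r in range(design.n_runs):
            events = _run_events(design, orders[r])
            regressors = np.zeros((len(events), n_vols))
            for j, ev in enumerate(events):
                boxcar = np.zeros(n_vols)
                boxcar[ev.onset_vol : ev.onset_vol + ev.duration_vol] = 1.0
                regressors[j] = np.convolve(boxcar, hrf)[:n_vols]
            amp_mat = np.stack([amps[ev.condition] for ev in events])  # block x voxel
            signal = amp_mat.T @ regressors  # voxel x volume
            run_offset = rng.normal(0.0, params.run_offset_sd)
            data = params.baseline + run_offset + signal
            data[:, : design.n_dummy] += params.dummy_baseline_boost
            data += rng.normal(0.0, params.noise_sd, size=data.shape)
            ts = RunTimeSeries(
                data=data,
                tr_s=design.tr_s,
                n_dummy=design.n_dummy,
                events=events,
                roi_id=roi,
                run_index=r + 1,
            )
            ts.validate()
            runs.append(ts)
        roi_runs[roi] = runs
    return Session(participant=participant, design=design, roi_runs=roi_runs)


# ---------------------------------------------------------------------------
# on-disk bundle (NIfTI + events)
# ---------------------------------------------------------------------------


def _roi_box_shape(n_voxels: int, nx: int = 6, ny: int = 6) -> tuple[int, int, int]:
    nz = math.ceil(n_voxels / (nx * ny))
    return nx, ny, nz


def roi_layout(rois: Sequence[str], n_voxels: int) -> dict[str, tuple[slice, tuple[int, int, int]]]:
    """Stack one small 3D box per ROI along z; returns z-slab and box shape."""
    layout = {}
    z0 = 0
    for roi in rois:
        shape = _roi_box_shape(n_voxels)
        layout[roi] = (slice(z0, z0 + shape[2]), shape)
        z0 += shape[2]
    return layout


def _mask_volume(layout, roi: str, full_shape: tuple[int, int, int], n_voxels: int) -> np.ndarray:
    zslab, box = layout[roi]
    mask = np.zeros(full_shape, dtype=np.uint8)
    block = np.zeros(box[0] * box[1] * box[2], dtype=np.uint8)
    block[:n_voxels] = 1
    mask[:, :, zslab] = block.reshape(box)
    return mask


def write_dataset(session: Session, directory: str | Path) -> Path:
    """Write a session as 4D NIfTI runs, per-ROI mask NIfTIs, and events TSVs.

    Layout::

        <dir>/masks/<roi>_mask.nii
        <dir>/<participant>/<participant>_run-NN_bold.nii
        <dir>/<participant>/<participant>_run-NN_events.tsv

    Voxels of each ROI occupy a small box in a shared grid; data round-trip
    losslessly (float64) through :func:`streakmvpa.cli_io.read_bold_bundle`.
    """
    import nibabel as nib

    directory = Path(directory)
    design = session.design
    rois = session.rois
    n_vox = {roi: session.roi_runs[roi][0].n_voxels for roi in rois}
    if len(set(n_vox.values())) != 1:
        raise ValueError("write_dataset assumes equal ROI sizes")
    nv = next(iter(n_vox.values()))
    layout = roi_layout(rois, nv)
    nz_total = max(sl.stop for sl, _ in layout.values())
    full_shape = (6, 6, nz_total)
    affine = np.diag([1.5, 1.5, 1.5, 1.0])

    mask_dir = directory / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    masks = {}
    for roi in rois:
        mask = _mask_volume(layout, roi, full_shape, nv)
        masks[roi] = mask
        nib.save(nib.Nifti1Image(mask, affine), mask_dir / f"{roi}_mask.nii")

    sub_dir = directory / session.participant
    sub_dir.mkdir(parents=True, exist_ok=True)
    for r in range(design.n_runs):
        n_vols = session.roi_runs[rois[0]][r].n_volumes
        vol = np.zeros(full_shape + (n_vols,), dtype=np.float64)
        for roi in rois:
            run = session.roi_runs[roi][r]
            idx = np.nonzero(masks[roi])
            vol[idx[0], idx[1], idx[2], :] = run.data
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((1.5, 1.5, 1.5, design.tr_s))
        stem = f"{session.participant}_run-{r + 1:02d}"
        nib.save(img, sub_dir / f"{stem}_bold.nii")

        events = session.roi_runs[rois[0]][r].events
        pd.DataFrame(
            {
                "onset": [ev.onset_vol * design.tr_s for ev in events],
                "duration": [ev.duration_vol * design.tr_s for ev in events],
                "trial_type": [ev.condition for ev in events],
            }
        ).to_csv(sub_dir / f"{stem}_events.tsv", sep="\t", index=False)
    return directory


# ---------------------------------------------------------------------------
# simulated psychophysical observer
# ---------------------------------------------------------------------------

UNADAPTED = "unadapted"


@dataclass
class ObserverParams:
    """A 2AFC contrast-detection observer with adaptation-elevated thresholds.

    ``elevation_factor`` maps (speed, test orientation relative to motion) to
    a multiplicative threshold factor >= 1.  The defaults encode the
    crossover hypothesis: fast adaptation elevates parallel test thresholds
    most, slow adaptation elevates orthogonal thresholds most.
    """

    t0_log10: float = -1.5
    elevation_factor: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("fast", "parallel"): 2.0,
            ("fast", "orthogonal"): 1.2,
            ("slow", "parallel"): 1.1,
            ("slow", "orthogonal"): 1.6,
        }
    )
    psychometric_slope_beta: float = 3.5
    lapse_delta: float = 0.01
    guess_gamma: float = 0.5

    def validate(self) -> None:
        if not 0.0 <= self.lapse_delta <= 0.1:
            raise ValueError("lapse_delta outside [0, 0.1]")
        if self.guess_gamma != 0.5:
            warnings.warn("guess_gamma != 0.5 is unusual for a left/right 2AFC task")
        for cond, f in self.elevation_factor.items():
            if f < 1.0:
                raise ValueError(f"elevation factor {cond} < 1")

    def true_threshold(self, condition: tuple[str, str] | str) -> float:
        """log10 threshold for an adapted condition or the unadapted baseline."""
        if condition == UNADAPTED:
            return self.t0_log10
        return self.t0_log10 + math.log10(self.elevation_factor[tuple(condition)])


def simulate_observer_response(
    observer: ObserverParams,
    condition: tuple[str, str] | str,
    log10_contrast: float,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli 2AFC trial: True if the simulated response is correct."""
    if not np.isfinite(log10_contrast):
        raise ValueError("contrast level must be finite")
    p = weibull_2afc(
        log10_contrast,
        observer.true_threshold(condition),
        beta=observer.psychometric_slope_beta,
        gamma=observer.guess_gamma,
        delta=observer.lapse_delta,
    )
    return bool(rng.random() < p)
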