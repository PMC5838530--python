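"""Synthetic cohorts, tap sequences and 4-D BOLD runs with known truth.

Every downstream stage — the feedback engine, localizer GLM, motion
scrubbing, mixed-model trend and connectivity analyses — is exercised on
data generated here, where the ground truth (active voxels, planted
upregulation amplitude and its growth across visits, AR(1)/drift/white
noise parameters, motion spikes) is recorded alongside each run.

The cohort generator emulates a small Huntington's disease sample:
age/CAG pairs give the CAP burden score, caudate volume (%ICV) is
negatively rank-correlated with CAP through a Gaussian copula over a
latent disease-burden variable, and the seven cognitive/motor measures
depend monotonically on caudate volume.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm as _norm

from .clinical import cap_score
from .hemodynamics import BlockDesign, HrfParams, convolve_design, neurofeedback_design

__all__ = [
    "AcquisitionGrid",
    "SimulationTruth",
    "RunData",
    "CohortSpec",
    "TapSequence",
    "simulate_cohort",
    "simulate_run",
    "simulate_taps",
    "default_roi_voxels",
]

#: mean BOLD level in arbitrary signal units; fixed so that planted
#: amplitudes in percent signal change are directly interpretable.
BASELINE_LEVEL = 100.0

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Voxel grid and sampling interval of a simulated acquisition."""

    shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 1.0

    def __post_init__(self) -> None:
        if any(s < 2 for s in self.shape):
            raise ValueError("grid must have at least 2 voxels per axis")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")


def default_roi_voxels(grid: AcquisitionGrid, half_width: int = 1) -> np.ndarray:
    """Central cube of voxel indices (the planted 'SMA-like' target)."""
    c = [s // 2 for s in grid.shape]
    idx = [
        (i, j, k)
        for i in range(c[0] - half_width, c[0] + half_width + 1)
        for j in range(c[1] - half_width, c[1] + half_width + 1)
        for k in range(c[2] - half_width, c[2] + half_width + 1)
    ]
    return np.asarray(idx, dtype=int)


@dataclass
class SimulationTruth:
    """Ground truth recorded with every simulated run.

    ``base_amplitude`` is the upregulation PSC (%) at visit 1 and
    ``learning_slope`` its increase per visit, emulating training-induced
    learning.  Noise is AR(1) with coefficient ``ar_coefficient`` driven
    by white noise of SD ``noise_sd`` (signal units), plus a linear drift
    of ``drift_slope`` signal units per second.  Motion spikes of
    ``spike_magnitude`` mm are planted on the first translation at
    ``spike_times`` (volume indices).
    """

    roi_voxels: np.ndarray
    base_amplitude: float = 0.5
    learning_slope: float = 0.3
    ar_coefficient: float = 0.3
    noise_sd: float = 1.0
    drift_slope: float = 0.0
    spike_times: tuple[int, ...] = ()
    spike_magnitude: float = 1.2

    def __post_init__(self) -> None:
        self.roi_voxels = np.asarray(self.roi_voxels, dtype=int)
        if self.roi_voxels.ndim != 2 or self.roi_voxels.shape[1] != 3:
            raise ValueError("roi_voxels must be an (n, 3) index array")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("|ar_coefficient| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def amplitude_at_visit(self, visit: int) -> float:
        """Planted upregulation PSC (%) at a 1-based visit index."""
        return max(0.0, self.base_amplitude + self.learning_slope * (visit - 1))

    def roi_mask(self, grid: AcquisitionGrid) -> np.ndarray:
        mask = np.zeros(grid.shape, dtype=bool)
        mask[tuple(self.roi_voxels.T)] = True
        return mask

    def to_json(self, path) -> None:
        obj = asdict(self)
        obj["roi_voxels"] = self.roi_voxels.tolist()
        obj["spike_times"] = list(self.spike_times)
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            obj = json.load(fh)
        obj["roi_voxels"] = np.asarray(obj["roi_voxels"], dtype=int)
        obj["spike_times"] = tuple(obj["spike_times"])
        return cls(**obj)


@dataclass
class RunData:
    """One fMRI run: 4-D data, its block design, and identifiers."""

    data: np.ndarray
    design: BlockDesign
    grid: AcquisitionGrid
    participant: str = "sub-01"
    visit: int = 1
    run: int = 1

    def save(self, nii_path, events_path) -> None:
        affine = np.diag(list(self.grid.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(nii_path))
        self.design.to_tsv(events_path)

    @classmethod
    def load(cls, nii_path, events_path, **ids) -> "RunData":
        img = nib.load(str(nii_path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        tr = tr if tr > 0 else 1.0
        design = BlockDesign.from_tsv(events_path, tr=tr)
        grid = AcquisitionGrid(shape=data.shape[:3], voxel_size=vox, tr=tr)
        return cls(data=data, design=design, grid=grid, **ids)


def _ar1_noise(rng, phi: float, sd: float, n_series: int, n_time: int) -> np.ndarray:
    """Stationary AR(1) noise, one row per series."""
    w = rng.normal(0.0, sd, size=(n_series, n_time))
    if phi == 0 or sd == 0:
        return w
    # x[t] = phi x[t-1] + w[t], started from the stationary distribution
    x_prev = rng.normal(0.0, sd / np.sqrt(1 - phi**2), size=(n_series, 1))
    zi = phi * x_prev
    out, _ = lfilter([1.0], [1.0, -phi], w, axis=1, zi=zi)
    return out


def simulate_run(
    truth: SimulationTruth,
    design: BlockDesign | None = None,
    grid: AcquisitionGrid | None = None,
    seed: int = 0,
    participant: str = "sub-01",
    visit: int = 1,
    run: int = 1,
    active_kind: str = "upregulate",
):
    """Simulate one block-design BOLD run plus its motion table.

    Voxels in ``truth.roi_voxels`` carry
    ``BASELINE_LEVEL * (1 + amp/100 * x(t))`` where ``x`` is the active
    block kind's boxcar convolved with the canonical HRF and scaled to a
    unit plateau, and ``amp`` is the visit-dependent planted amplitude.
    All voxels additionally receive AR(1) + drift + white noise.  The
    motion table carries six realignment parameters with the configured
    spikes planted on the first translation.

    Returns ``(RunData, motion DataFrame)``.
    """
    grid = grid or AcquisitionGrid()
    design = design or neurofeedback_design(tr=grid.tr)
    if truth.roi_voxels.shape[0] == 0:
        raise ValueError("ROI voxel set is empty")
    n_vols = design.n_volumes
    rng = np.random.default_rng(seed)

    n_vox = int(np.prod(grid.shape))
    noise = _ar1_noise(rng, truth.ar_coefficient, truth.noise_sd, n_vox, n_vols)
    t_sec = np.arange(n_vols) * grid.tr
    signal = np.full((n_vox, n_vols), BASELINE_LEVEL, dtype=float)
    signal += truth.drift_slope * t_sec

    amp = truth.amplitude_at_visit(visit)
    if amp > 0:
        x = convolve_design(design, active_kind, scale="plateau")
        flat_roi = np.ravel_multi_index(tuple(truth.roi_voxels.T), grid.shape)
        signal[flat_roi] += BASELINE_LEVEL * (amp / 100.0) * x

    data = (signal + noise).reshape(grid.shape + (n_vols,)).astype(np.float32)

    motion = rng.normal(0.0, 0.01, size=(n_vols, 6))
    motion[:, 3:] *= 0.02  # rotations in radians, much smaller scale
    for t0 in truth.spike_times:
        if not 0 < t0 < n_vols:
            raise ValueError("spike_times must be interior volume indices")
        motion[t0:, 0] += truth.spike_magnitude  # step: one scan-to-scan jump
    motion_df = pd.DataFrame(motion, columns=MOTION_COLUMNS)

    run_data = RunData(
        data=data, design=design, grid=grid, participant=participant, visit=visit, run=run
    )
    return run_data, motion_df


@dataclass(frozen=True)
class TapSequence:
    """A recorded (or simulated) sequence of tap onsets."""

    onsets: tuple
    target_period: float
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.target_period <= 0:
            raise ValueError("target_period must be > 0")
        arr = np.asarray(self.onsets, dtype=float)
        if arr.size >= 2 and np.any(np.diff(arr) <= 0):
            raise ValueError("onsets must be strictly increasing")


def simulate_taps(
    n_taps: int,
    target_period: float = 1.0 / 1.8,
    jitter_sd: float = 0.02,
    seed: int = 0,
    start: float = 0.0,
) -> TapSequence:
    """Paced tapping at the target rate with Gaussian timing jitter.

    Onsets are ``start + k * target_period + N(0, jitter_sd)``; the 1.8 Hz
    default matches left-index-finger paced tapping.
    """
    if n_taps < 2:
        raise ValueError("need at least 2 taps")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    onsets = start + np.arange(n_taps) * target_period
    if jitter_sd > 0:
        onsets = np.sort(onsets + rng.normal(0.0, jitter_sd, n_taps))
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("jitter too large: onsets no longer strictly increasing")
    return TapSequence(
        onsets=tuple(float(x) for x in onsets),
        target_period=target_period,
        jitter_sd=jitter_sd,
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

#: per-measure (baseline value, slope on caudate %ICV, residual SD).
#: Slopes are signed so that larger caudate volume (less atrophy) means
#: better performance: higher counts/length, faster and steadier tapping.
MEASURE_MODELS = {
    "stroop_word_correct": (85.0, 80.0, 6.0),
    "sdmt_correct": (40.0, 60.0, 4.0),
    "circle_annulus_length": (420.0, 400.0, 40.0),
    "emotion_recog_correct": (18.0, 25.0, 2.5),
    "iti": (0.28, -0.25, 0.02),
    "sd_ioi": (0.045, -0.08, 0.006),
    "sd_dmti": (0.055, -0.09, 0.007),
}

COUNT_MEASURES = {"stroop_word_correct", "sdmt_correct", "emotion_recog_correct"}


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a simulated HD cohort.

    ``caudate_cap_rho`` is the target (negative) Spearman correlation
    between caudate %ICV and the CAP score; ``measure_effect`` scales the
    default dependence of every measure on caudate volume (0 severs it).
    """

    n_participants: int = 10
    age_range: tuple[float, float] = (39.0, 68.0)
    cag_range: tuple[int, int] = (39, 46)
    caudate_range: tuple[float, float] = (0.28, 0.55)
    caudate_cap_rho: float = -0.86
    measure_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        if self.cag_range[0] <= 30:
            raise ValueError("cag_range minimum must be > 30 (CAP needs CAG - 30 > 0)")
        if not -1.0 < self.caudate_cap_rho <= 0.0:
            raise ValueError("caudate_cap_rho must be negative (or 0)")
        if self.age_range[0] <= 0 or self.age_range[0] > self.age_range[1]:
            raise ValueError("invalid age_range")
        if self.cag_range[0] > self.cag_range[1]:
            raise ValueError("invalid cag_range")
        if self.caudate_range[0] <= 0 or self.caudate_range[0] >= self.caudate_range[1]:
            raise ValueError("invalid caudate_range")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table with correlated burden, atrophy and measures.

    A latent disease-burden variable and a second latent are drawn from a
    Gaussian copula whose Pearson correlation ``2 sin(pi * rho / 6)`` is
    chosen so the *Spearman* correlation between the monotone images of
    the latents hits ``caudate_cap_rho``.  Sampled (age, CAG) pairs are
    reordered so the CAP score is a monotone image of the burden latent;
    caudate %ICV is a monotone (inverse-normal) image of the second
    latent; the seven measures are linear in caudate volume plus noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    rho_s = spec.caudate_cap_rho
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    z_burden, z_caudate = z[:, 0], z[:, 1]

    ages = np.round(rng.uniform(spec.age_range[0], spec.age_range[1], n)).astype(int)
    ages = np.clip(ages, 1, None)
    cags = rng.integers(spec.cag_range[0], spec.cag_range[1] + 1, n)
    caps = np.array([cap_score(a, c) for a, c in zip(ages, cags)])
    # reorder (age, CAG) pairs so CAP rank follows the burden latent rank
    pair_order = np.argsort(caps)
    burden_rank = np.argsort(np.argsort(z_burden))
    ages = ages[pair_order][burden_rank]
    cags = cags[pair_order][burden_rank]
    caps = caps[pair_order][burden_rank]

    lo, hi = spec.caudate_range
    caudate = lo + (hi - lo) * _norm.cdf(z_caudate)

    sex = rng.choice(["F", "M"], size=n, p=[0.7, 0.3])
    moca = np.clip(np.round(33.0 - 0.07 * caps + rng.normal(0, 1.5, n)), 0, 30)
    tms = np.clip(np.round(-8.0 + 0.18 * caps + rng.normal(0, 3.0, n)), 0, 40)
    dcs = np.clip(np.round(tms / 4.0), 0, 4)
    tfc = np.clip(np.round(13.5 - 0.08 * tms + rng.normal(0, 0.5, n)), 0, 13)

    rows = {
        "participant": [f"sub-{i+1:02d}" for i in range(n)],
        "sex": sex,
        "age": ages,
        "cag": cags,
        "cap": caps,
        "caudate_pct_icv": caudate,
        "moca": moca,
        "tms": tms,
        "dcs": dcs,
        "tfc": tfc,
    }
    mid = (lo + hi) / 2.0
    for name, (base, slope, sd) in MEASURE_MODELS.items():
        vals = base + spec.measure_effect * slope * (caudate - mid) + rng.normal(0, sd, n)
        if name in COUNT_MEASURES:
            vals = np.clip(np.round(vals), 0, None)
        else:
            vals = np.clip(vals, 1e-3, None)
        rows[name] = vals
    return pd.DataFrame(rows)


def cohort_panels(df: pd.DataFrame):
    """MeasurePanel per participant from a cohort table."""
    from .clinical import MeasurePanel

    out = {}
    for r in df.itertuples():
        out[r.participant] = MeasurePanel(
            stroop_word_correct=float(r.stroop_word_correct),
            sdmt_correct=float(r.sdmt_correct),
            circle_annulus_length=float(r.circle_annulus_length),
            emotion_recog_correct=float(r.emotion_recog_correct),
            iti=float(r.iti),
            sd_ioi=float(r.sd_ioi),
            sd_dmti=float(r.sd_dmti),
        )
    return out
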