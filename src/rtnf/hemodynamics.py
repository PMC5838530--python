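"""Canonical hemodynamic response model and block-design utilities.

The BOLD response to a brief burst of neural activity is modelled as the
difference of two gamma densities: a positive peak around 5-6 s after the
event and a smaller, later undershoot.  Everything downstream — GLM
regressors, the simulated BOLD signal, and the weighted baseline used by
the real-time feedback loop — is built from this kernel.

A neurofeedback training run is a fixed block design: 6 baseline blocks
(30 s), 6 response blocks (16 s, letting the response decay before the
next upregulation period) and 5 upregulation blocks (30 s), interleaved
as repeating baseline -> response -> upregulation triplets, 426 s total
at TR = 1 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist

__all__ = [
    "HrfParams",
    "BlockDesign",
    "BaselineWeights",
    "hrf_value",
    "convolve_design",
    "baseline_weights",
    "neurofeedback_design",
    "localizer_design",
    "tapping_design",
]

#: block labels understood by the design builders; a design may use a
#: subset, and convolving a known-but-absent kind yields a zero regressor.
KNOWN_BLOCK_KINDS = (
    "baseline",
    "response",
    "upregulate",
    "rest",
    "clench",
    "tap",
)

#: length (s) of the sampled HRF kernel used for discrete convolution.
HRF_KERNEL_LENGTH = 32.0


@dataclass(frozen=True)
class HrfParams:
    """Parameters of the double-gamma hemodynamic response.

    Defaults follow the standard canonical HRF: a shape-6 peak gamma and a
    shape-16 undershoot gamma (unit rate, so the peak falls near 5 s and
    the undershoot near 15 s), undershoot scaled by 1/6.
    """

    peak_shape: float = 6.0
    peak_rate: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_rate: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("peak_shape", "peak_rate", "undershoot_shape", "undershoot_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")


def hrf_value(t, params: HrfParams | None = None):
    """Evaluate the double-gamma HRF at time(s) ``t`` seconds after an event.

    Returns the difference of the two gamma densities (peak minus
    ``undershoot_ratio`` times undershoot).  Scalar in, scalar out.

    Raises
    ------
    ValueError
        If any ``t`` is negative: the response is causal.
    """
    params = params or HrfParams()
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("HRF is causal: t must be >= 0")
    peak = _gamma_dist.pdf(t_arr, params.peak_shape, scale=1.0 / params.peak_rate)
    under = _gamma_dist.pdf(
        t_arr, params.undershoot_shape, scale=1.0 / params.undershoot_rate
    )
    out = peak - params.undershoot_ratio * under
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _sample_hrf(tr: float, params: HrfParams) -> np.ndarray:
    t = np.arange(0.0, HRF_KERNEL_LENGTH + tr / 2, tr)
    return np.asarray(hrf_value(t, params), dtype=float)


@dataclass
class BlockDesign:
    """An ordered, non-overlapping sequence of labelled blocks.

    Each block is ``(kind, onset_s, duration_s)``.  ``tr`` is the volume
    sampling interval; volume ``i`` is acquired over ``[i*tr, (i+1)*tr)``.
    """

    blocks: list[tuple[str, float, float]]
    tr: float = 1.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if not self.blocks:
            raise ValueError("design must contain at least one block")
        self.blocks = [(str(k), float(o), float(d)) for k, o, d in self.blocks]
        prev_end = -np.inf
        for kind, onset, dur in self.blocks:
            if dur <= 0:
                raise ValueError(f"block duration must be > 0 ({kind} at {onset})")
            if onset < prev_end - 1e-9:
                raise ValueError("blocks must be sorted and non-overlapping")
            prev_end = onset + dur

    @property
    def duration(self) -> float:
        kind, onset, dur = self.blocks[-1]
        return onset + dur

    @property
    def n_volumes(self) -> int:
        n = self.duration / self.tr
        if abs(n - round(n)) > 1e-9:
            raise ValueError("design duration is not a whole number of TRs")
        return int(round(n))

    def kinds(self) -> set[str]:
        return {k for k, _, _ in self.blocks}

    def blocks_of(self, kind: str) -> list[tuple[str, float, float]]:
        return [b for b in self.blocks if b[0] == kind]

    def volume_slice(self, onset: float, duration: float) -> slice:
        start = int(round(onset / self.tr))
        n = int(round(duration / self.tr))
        return slice(start, start + n)

    def boxcar(self, kind: str) -> np.ndarray:
        """Indicator regressor: 1 for volumes inside blocks of ``kind``."""
        if kind not in self.kinds() and kind not in KNOWN_BLOCK_KINDS:
            raise ValueError(f"unknown block kind {kind!r}")
        box = np.zeros(self.n_volumes)
        for k, onset, dur in self.blocks:
            if k == kind:
                box[self.volume_slice(onset, dur)] = 1.0
        return box

    # -- events TSV (BIDS-style: onset, duration, trial_type) -------------
    def to_events(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.blocks, columns=["trial_type", "onset", "duration"]
        )[["onset", "duration", "trial_type"]]

    def to_tsv(self, path) -> None:
        self.to_events().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_events(cls, events: pd.DataFrame, tr: float = 1.0) -> "BlockDesign":
        rows = events.sort_values("onset")
        blocks = [
            (str(r.trial_type), float(r.onset), float(r.duration))
            for r in rows.itertuples()
        ]
        return cls(blocks=blocks, tr=tr)

    @classmethod
    def from_tsv(cls, path, tr: float = 1.0) -> "BlockDesign":
        return cls.from_events(pd.read_csv(path, sep="\t"), tr=tr)


def neurofeedback_design(
    tr: float = 1.0,
    baseline_duration: float = 30.0,
    response_duration: float = 16.0,
    upregulate_duration: float = 30.0,
    n_upregulate: int = 5,
) -> BlockDesign:
    """The neurofeedback training run layout.

    Repeating baseline -> response -> upregulation triplets (the response
    block lets the hemodynamic response return to baseline before the next
    upregulation), closed by a final baseline + response pair, giving 6
    baseline, 6 response and 5 upregulation blocks (426 s at the defaults).
    """
    blocks: list[tuple[str, float, float]] = []
    t = 0.0
    for _ in range(n_upregulate):
        blocks.append(("baseline", t, baseline_duration))
        t += baseline_duration
        blocks.append(("response", t, response_duration))
        t += response_duration
        blocks.append(("upregulate", t, upregulate_duration))
        t += upregulate_duration
    blocks.append(("baseline", t, baseline_duration))
    t += baseline_duration
    blocks.append(("response", t, response_duration))
    return BlockDesign(blocks=blocks, tr=tr)


def validate_neurofeedback(design: BlockDesign) -> None:
    """Check the 6 baseline / 6 response / 5 upregulation structure."""
    counts = {k: len(design.blocks_of(k)) for k in ("baseline", "response", "upregulate")}
    if counts != {"baseline": 6, "response": 6, "upregulate": 5}:
        raise ValueError(f"not a neurofeedback run design: block counts {counts}")


def localizer_design(
    tr: float = 1.0, n_blocks: int = 21, block_duration: float = 20.0
) -> BlockDesign:
    """Fist-clenching functional localizer: alternating rest/clench blocks."""
    blocks = []
    for i in range(n_blocks):
        kind = "rest" if i % 2 == 0 else "clench"
        blocks.append((kind, i * block_duration, block_duration))
    return BlockDesign(blocks=blocks, tr=tr)


def tapping_design(
    tr: float = 1.0, n_blocks: int = 11, block_duration: float = 20.0
) -> BlockDesign:
    """Paced-tapping task: alternating rest/tap blocks."""
    blocks = []
    for i in range(n_blocks):
        kind = "rest" if i % 2 == 0 else "tap"
        blocks.append((kind, i * block_duration, block_duration))
    return BlockDesign(blocks=blocks, tr=tr)


def convolve_design(
    design: BlockDesign,
    kind: str,
    params: HrfParams | None = None,
    scale: str = "none",
) -> np.ndarray:
    """HRF-convolved boxcar regressor for one block kind, one value per TR.

    Discrete convolution at TR resolution, truncated to the run length.
    ``scale="plateau"`` divides by the discrete HRF integral so a long
    block plateaus at 1 — convenient when the regressor multiplies a
    percent-signal-change amplitude in simulation.
    """
    params = params or HrfParams()
    box = design.boxcar(kind)
    kernel = _sample_hrf(design.tr, params)
    reg = np.convolve(box, kernel)[: design.n_volumes] * design.tr
    if scale == "plateau":
        denom = kernel.sum() * design.tr
        if denom == 0:
            raise ValueError("HRF kernel integrates to zero; cannot plateau-scale")
        reg = reg / denom
    elif scale != "none":
        raise ValueError(f"unknown scale mode {scale!r}")
    return reg


@dataclass
class BaselineWeights:
    """Nonnegative per-volume weights over one baseline block, summing to 1."""

    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or self.weights.size == 0:
            raise ValueError("weights must be a nonempty 1-D sequence")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def __len__(self) -> int:
        return self.weights.size


def baseline_weights(
    duration: float,
    tr: float,
    params: HrfParams | None = None,
    mode: str = "hrf",
) -> BaselineWeights:
    """Hemodynamically weighted averaging scheme for a baseline block.

    The ROI signal over the preceding baseline block is averaged with
    weights following the double-gamma response sampled at times since
    block onset (``mode="hrf"``, the default), or the block-convolved
    response (``mode="convolved"``).  Negative undershoot values are
    floored at zero so the baseline stays a convex combination of the
    observed samples; the result is normalized to sum to 1.
    """
    params = params or HrfParams()
    n = duration / tr
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration must be divisible by TR")
    n = int(round(n))
    if n < 1:
        raise ValueError("baseline block must span at least one volume")
    t = np.arange(n) * tr
    if mode == "hrf":
        raw = np.clip(np.asarray(hrf_value(t, params), dtype=float), 0.0, None)
    elif mode == "convolved":
        kernel = _sample_hrf(tr, params)
        conv = np.convolve(np.ones(n), kernel)[:n] * tr
        raw = np.clip(conv, 0.0, None)
    else:
        raise ValueError(f"unknown baseline weighting mode {mode!r}")
    total = raw.sum()
    if total <= 0:
        raise ValueError("all baseline weights vanished before normalization")
    w = raw / total
    w = w / w.sum()  # second pass tightens the sum to 1 within 1e-16
    return BaselineWeights(weights=w)
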