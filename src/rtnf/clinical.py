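"""Clinical disease-burden and performance scoring.

Covers the CAP score (CAG-Age Product, the standard Huntington's disease
burden index), a seven-measure cognitive/motor composite with direction
harmonization and reference-norm standardization, quantitative-motor
tapping variability measures, and (partial) Spearman rank correlation.

The composite combines four cognitive measures (Stroop word reading,
Symbol Digit Modalities Test, indirect circle tracing annulus length —
log transformed — and negative emotion recognition, all counts/lengths
where more is better) with three Q-Motor timing measures (speeded-tapping
inter-tap interval, log SD of inter-onset intervals, log SD of mid-tap
deviation from the paced rhythm, all where less is better).  Timing
measures are negated so that larger always means better, each measure is
z-scored against norms from an independent early-HD reference sample,
and the composite is the mean of the seven z-scores.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASURES",
    "MeasurePanel",
    "ReferenceNorms",
    "ParticipantRecord",
    "cap_score",
    "cap_score_rounded",
    "harmonize",
    "composite",
    "tapping_measures",
    "spearman",
    "partial_spearman",
    "load_reference_cohort",
    "default_reference_norms",
]

#: canonical measure order used for harmonized vectors and norms
MEASURES = (
    "stroop_word_correct",
    "sdmt_correct",
    "log_circle_annulus",
    "emotion_recog_correct",
    "neg_iti",
    "neg_log_sd_ioi",
    "neg_log_sd_dmti",
)


@dataclass(frozen=True)
class MeasurePanel:
    """Raw values of the seven composite measures for one assessment.

    Counts and lengths are stored untransformed; :func:`harmonize`
    applies the log transforms and sign flips.
    """

    stroop_word_correct: float
    sdmt_correct: float
    circle_annulus_length: float
    emotion_recog_correct: float
    iti: float
    sd_ioi: float
    sd_dmti: float

    def __post_init__(self) -> None:
        if self.stroop_word_correct < 0 or self.sdmt_correct < 0:
            raise ValueError("counts must be nonnegative")
        if self.emotion_recog_correct < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class ReferenceNorms:
    """Per-measure mean and SD (harmonized scale) from a reference cohort."""

    means: dict
    sds: dict

    def __post_init__(self) -> None:
        for m in MEASURES:
            if m not in self.means or m not in self.sds:
                raise ValueError(f"norms missing measure {m!r}")
            if self.sds[m] <= 0:
                raise ValueError(f"reference SD for {m!r} must be > 0")


@dataclass(frozen=True)
class ParticipantRecord:
    """One cohort-table row: demographics, genetics and clinical scores."""

    id: str
    sex: str
    age: float
    cag: int
    cap: float
    caudate_pct_icv: float
    moca: float
    tms: float
    dcs: float
    tfc: float


def cap_score(age: float, cag: float) -> float:
    """CAG-Age Product: 100 * age * (CAG - 30) / 627.

    Scaled so the score is about 100 at a gene carrier's expected age of
    onset.  Defined only for expanded repeats (CAG > 30) and positive age;
    the exact value is returned, see :func:`cap_score_rounded` for the
    integer form used in tables.
    """
    if cag <= 30:
        raise ValueError("CAP requires CAG > 30")
    if age <= 0:
        raise ValueError("age must be > 0")
    return 100.0 * age * (cag - 30.0) / 627.0


def cap_score_rounded(age: float, cag: float) -> int:
    """CAP score rounded to the nearest integer (table display form)."""
    return int(round(cap_score(age, cag)))


def harmonize(panel: MeasurePanel) -> np.ndarray:
    """Direction-harmonized 7-vector in :data:`MEASURES` order.

    Circle-tracing annulus length and the two timing SDs are log
    transformed; the three timing measures (ITI and both log SDs) are
    negated so that a larger value always means better performance.
    """
    for name, value in (
        ("circle_annulus_length", panel.circle_annulus_length),
        ("sd_ioi", panel.sd_ioi),
        ("sd_dmti", panel.sd_dmti),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0 before log transform")
    return np.array(
        [
            panel.stroop_word_correct,
            panel.sdmt_correct,
            np.log(panel.circle_annulus_length),
            panel.emotion_recog_correct,
            -panel.iti,
            -np.log(panel.sd_ioi),
            -np.log(panel.sd_dmti),
        ],
        dtype=float,
    )


def composite(panel: MeasurePanel, norms: ReferenceNorms) -> float:
    """Mean of the reference-standardized harmonized measures.

    Each harmonized value is z-scored against the reference norms; the
    composite is the mean of the seven z-scores, so a participant exactly
    at the reference means scores 0 and one reference SD on a single
    measure moves the composite by 1/7.
    """
    h = harmonize(panel)
    z = np.array([(h[i] - norms.means[m]) / norms.sds[m] for i, m in enumerate(MEASURES)])
    return float(z.mean())


class TapMeasures(NamedTuple):
    iti: float
    log_sd_ioi: float
    log_sd_dmti: float
    sd_ioi: float
    sd_dmti: float


def tapping_measures(onsets, target_period: float) -> TapMeasures:
    """Q-Motor timing measures from a tap-onset sequence.

    Returns ``(iti, log_sd_ioi, log_sd_dmti, sd_ioi, sd_dmti)`` where

    * ``iti`` is the mean inter-onset interval (s),
    * ``sd_ioi`` the sample SD of inter-onset intervals,
    * ``sd_dmti`` the sample SD of the deviation of inter-tap midpoints
      from the index-matched midpoints of the target-rhythm grid anchored
      at the first tap (a convention — the midpoint definition is
      isolated here so an alternative can be swapped in).

    Perfectly periodic tapping has zero variance, which would make the
    log transforms undefined; that degenerate case raises.
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 3:
        raise ValueError("need at least 3 taps")
    if target_period <= 0:
        raise ValueError("target_period must be > 0")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    ioi = np.diff(onsets)
    iti = float(ioi.mean())
    sd_ioi = float(ioi.std(ddof=1))
    midpoints = (onsets[:-1] + onsets[1:]) / 2.0
    grid_mid = onsets[0] + (np.arange(midpoints.size) + 0.5) * target_period
    dmti = midpoints - grid_mid
    sd_dmti = float(dmti.std(ddof=1))
    if sd_ioi <= 0 or sd_dmti <= 0:
        raise ValueError("zero timing variance: log SD measures undefined")
    return TapMeasures(
        iti, float(np.log(sd_ioi)), float(np.log(sd_dmti)), sd_ioi, sd_dmti
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def partial_spearman(x, y, control) -> float:
    """Spearman correlation of x and y adjusted for a control variable.

    All three variables are rank transformed (average ranks); the x- and
    y-ranks are residualized on the control ranks by OLS (with
    intercept) and the Pearson correlation of the residuals is returned.
    A constant control carries no information and reduces the result to
    the plain Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    control = np.asarray(control, dtype=float)
    if not (x.shape == y.shape == control.shape) or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    if np.ptp(control) == 0:
        return spearman(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = stats.rankdata(control)
    X = np.column_stack([np.ones_like(rc), rc])
    ex = rx - X @ np.linalg.lstsq(X, rx, rcond=None)[0]
    ey = ry - X @ np.linalg.lstsq(X, ry, rcond=None)[0]
    if np.allclose(ex, 0) or np.allclose(ey, 0):
        raise ValueError("variable is collinear with the control; partial undefined")
    return float(np.corrcoef(ex, ey)[0, 1])


def load_reference_cohort() -> pd.DataFrame:
    """The 10-participant proof-of-concept HD neurofeedback cohort table.

    Columns: participant, sex, age (years), cag (repeats), cap (printed
    rounded CAP score), caudate_pct_icv, moca, tms, dcs, tfc.
    """
    with importlib.resources.files("rtnf.data").joinpath("cohort_table.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    return [
        ParticipantRecord(
            id=str(r.participant),
            sex=str(r.sex),
            age=float(r.age),
            cag=int(r.cag),
            cap=float(r.cap),
            caudate_pct_icv=float(r.caudate_pct_icv),
            moca=float(r.moca),
            tms=float(r.tms),
            dcs=float(r.dcs),
            tfc=float(r.tfc),
        )
        for r in df.itertuples()
    ]


def default_reference_norms() -> ReferenceNorms:
    """Synthetic stand-in for norms from an independent early-HD sample.

    Means/SDs on the harmonized scale, chosen to be plausible for an
    early-HD population; they are a synthetic construction, not the
    original normative values, and can be replaced via a norms JSON.
    """
    means = {
        "stroop_word_correct": 80.0,
        "sdmt_correct": 38.0,
        "log_circle_annulus": float(np.log(400.0)),
        "emotion_recog_correct": 17.0,
        "neg_iti": -0.30,
        "neg_log_sd_ioi": float(-np.log(0.05)),
        "neg_log_sd_dmti": float(-np.log(0.06)),
    }
    sds = {
        "stroop_word_correct": 12.0,
        "sdmt_correct": 8.0,
        "log_circle_annulus": 0.25,
        "emotion_recog_correct": 3.5,
        "neg_iti": 0.05,
        "neg_log_sd_ioi": 0.45,
        "neg_log_sd_dmti": 0.45,
    }
    return ReferenceNorms(means=means, sds=sds)


def norms_from_json(path) -> ReferenceNorms:
    import json

    with open(path) as fh:
        obj = json.load(fh)
    return ReferenceNorms(means=obj["means"], sds=obj["sds"])


def norms_to_json(norms: ReferenceNorms, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump({"means": norms.means, "sds": norms.sds}, fh, indent=2)
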