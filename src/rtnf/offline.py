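"""Offline inference: scrubbing, contrasts, trend models, PPI, regression.

After training, runs are analysed offline: motion spikes (> 1 mm
scan-to-scan displacement) become one-hot nuisance regressors and runs
with > 2 mm displacement are excluded; each run yields an
upregulate-versus-baseline contrast; per-run target-ROI contrasts enter
a linear mixed model (random intercept per participant, fixed visit and
run effects, age and caudate %ICV as confounds) testing for learning
across visits; psychophysiological-interaction (PPI) terms quantify
condition-dependent coupling with a seed region, and their across-visit
trend tests connectivity change; voxelwise regression relates activation
change to the change in the clinical composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
import statsmodels.api as sm

from .hemodynamics import HrfParams, convolve_design
from .localizer import GlmFit, RoiMask, fit_glm

__all__ = [
    "MotionParams",
    "SpikeResult",
    "TrendModelResult",
    "PpiDesign",
    "spike_regressors",
    "run_exceeds_motion",
    "block_contrast",
    "visit_trend",
    "ppi_terms",
    "fit_ppi",
    "connectivity_change",
    "behavior_regression",
    "tapping_contrast_comparison",
]

#: assumed head radius (mm) for converting rotations to displacements
HEAD_RADIUS_MM = 50.0


def _motion_array(motion) -> np.ndarray:
    arr = motion.to_numpy() if isinstance(motion, pd.DataFrame) else np.asarray(motion)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion table must have 6 columns (3 trans mm, 3 rot rad)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    return arr


@dataclass
class SpikeResult:
    """Scan-to-scan displacement trace, flagged volumes, spike regressors."""

    displacement: np.ndarray
    flagged: list[int]
    regressors: np.ndarray  # (n_volumes, n_flagged) one-hot columns


def scan_displacement(motion, head_radius: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Max absolute scan-to-scan parameter change, in mm.

    Rotations (radians) are converted to worst-case surface displacement
    on a ``head_radius`` mm sphere.  The first volume has displacement 0.
    """
    arr = _motion_array(motion)
    delta = np.abs(np.diff(arr, axis=0))
    delta[:, 3:] *= head_radius
    disp = np.concatenate([[0.0], delta.max(axis=1)])
    return disp


def spike_regressors(
    motion, threshold: float = 1.0, head_radius: float = HEAD_RADIUS_MM
) -> SpikeResult:
    """One-hot nuisance columns for volumes moving strictly more than 1 mm."""
    disp = scan_displacement(motion, head_radius)
    flagged = [int(i) for i in np.nonzero(disp > threshold)[0]]
    reg = np.zeros((disp.size, len(flagged)))
    for col, vol in enumerate(flagged):
        reg[vol, col] = 1.0
    return SpikeResult(displacement=disp, flagged=flagged, regressors=reg)


def run_exceeds_motion(
    motion, threshold: float = 2.0, head_radius: float = HEAD_RADIUS_MM
) -> bool:
    """Run-level QC: True when any scan-to-scan displacement exceeds 2 mm."""
    return bool(np.any(scan_displacement(motion, head_radius) > threshold))


# `MotionParams` is simply a 6-column table; accept DataFrame or array.
MotionParams = pd.DataFrame


@dataclass
class BlockContrast:
    """Upregulate-versus-baseline contrast for one run."""

    roi_contrast: float  # ROI-mean contrast, percent signal change
    voxel_contrast: np.ndarray  # PSC contrast per masked voxel
    tmap: np.ndarray  # t per masked voxel
    fit: GlmFit


def block_contrast(
    run,
    mask,
    hrf: HrfParams | None = None,
    nuisance: np.ndarray | None = None,
    active_kind: str = "upregulate",
    rest_kind: str = "baseline",
    other_kinds: tuple[str, ...] = ("response",),
) -> BlockContrast:
    """GLM contrast of the active condition against the implicit baseline.

    The design holds an intercept, a centered linear drift column, the
    HRF-convolved active and other explicit regressors (the rest/baseline
    condition stays implicit), and any nuisance columns (motion, spikes).
    The active beta is converted to percent signal change against the
    voxel's intercept, and the ROI contrast is the mean of the voxelwise
    PSC contrasts over the mask.
    """
    hrf = hrf or HrfParams()
    design = run.design
    kinds = design.kinds()
    if active_kind not in kinds or rest_kind not in kinds:
        raise ValueError(f"design must contain {active_kind!r} and {rest_kind!r} blocks")

    n = design.n_volumes
    cols = [np.ones(n)]
    names = ["intercept"]
    drift = np.arange(n, dtype=float)
    cols.append(drift - drift.mean())
    names.append("drift")
    cols.append(convolve_design(design, active_kind, hrf, scale="plateau"))
    names.append(active_kind)
    for k in other_kinds:
        if k in kinds:
            cols.append(convolve_design(design, k, hrf, scale="plateau"))
            names.append(k)
    X = np.column_stack(cols)
    if nuisance is not None and np.asarray(nuisance).size:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        X = np.column_stack([X, nuis])
        names += [f"nuisance_{i}" for i in range(nuis.shape[1])]

    mask_arr = np.asarray(getattr(mask, "data", mask), dtype=bool)
    Y = np.asarray(run.data)[mask_arr].T  # (time, voxels)
    fit = fit_glm(Y, X)
    c = np.zeros(X.shape[1])
    c[names.index(active_kind)] = 1.0
    beta_active = fit.contrast_estimate(c)
    baseline_level = fit.betas[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        psc = 100.0 * beta_active / baseline_level
    psc = np.where(np.isfinite(psc), psc, 0.0)
    tmap = fit.t_contrast(c)
    return BlockContrast(
        roi_contrast=float(psc.mean()), voxel_contrast=psc, tmap=tmap, fit=fit
    )


@dataclass
class TrendModelResult:
    """Fixed effects and variance components of a longitudinal trend fit.

    ``fixed_effects`` is indexed by term with columns estimate, se, df,
    tvalue, pvalue.  Wald tests use t with residual degrees of freedom
    (observations minus fixed-effect parameters) — the convention is
    recorded in ``dof_method``.
    """

    fixed_effects: pd.DataFrame
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool
    method: str
    dof_method: str = "residual"

    def effect(self, term: str) -> pd.Series:
        return self.fixed_effects.loc[term]


def _trend_design(df: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    names = ["intercept", "visit", "run"] + list(covariates)
    cols = [np.ones(len(df)), df["visit"].to_numpy(float), df["run"].to_numpy(float)]
    for c in covariates:
        cols.append(df[c].to_numpy(float))
    X = np.column_stack(cols)
    # drop covariate columns that are constant (no information, singular fit)
    keep = [0, 1, 2] + [
        3 + i for i, c in enumerate(covariates) if np.ptp(X[:, 3 + i]) > 0
    ]
    return X[:, keep], [names[i] for i in keep]


def visit_trend(
    estimates: pd.DataFrame,
    response: str = "roi_contrast",
    covariates: tuple[str, ...] = ("age", "caudate_pct_icv"),
    random_intercept: bool = True,
) -> TrendModelResult:
    """Linear mixed model of per-run estimates across visits.

    Fixed effects: visit, run, and the covariates; random intercept per
    subject; REML estimation; Wald t-test on each fixed effect.  With
    ``random_intercept=False`` the same fixed-effects model is fit by
    ordinary least squares (the constrained zero-variance case).
    """
    df = estimates.copy()
    required = {"subject", "visit", "run", response}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"estimates table missing columns {sorted(missing)}")
    covariates = tuple(c for c in covariates if c in df.columns)
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if df["visit"].nunique() < 2:
        raise ValueError("need at least 2 visits")

    y = df[response].to_numpy(float)
    X, names = _trend_design(df, covariates)
    n, p = X.shape
    dof = n - p
    groups = df["subject"].to_numpy()
    n_groups = df["subject"].nunique()

    if np.ptp(y) == 0:
        # degenerate: identical responses; every slope is exactly 0
        fe = pd.DataFrame(
            {
                "estimate": [y[0]] + [0.0] * (p - 1),
                "se": [0.0] * p,
                "df": [dof] * p,
                "tvalue": [np.inf] + [0.0] * (p - 1),
                "pvalue": [0.0] + [1.0] * (p - 1),
            },
            index=names,
        )
        return TrendModelResult(
            fixed_effects=fe,
            random_intercept_var=0.0,
            residual_var=0.0,
            n_obs=n,
            n_groups=n_groups,
            converged=True,
            singular=True,
            method="degenerate",
        )

    singular = False
    if random_intercept:
        model = sm.MixedLM(y, X, groups=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True)
                converged = bool(res.converged)
            except Exception:
                res = model.fit(reml=True, method="powell")
                converged = bool(res.converged)
        params = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        # cov_re is already on the response scale in statsmodels
        re_var = float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0
        resid_var = float(res.scale)
        singular = re_var < 1e-10
        method = "mixed-reml"
    else:
        ols = sm.OLS(y, X).fit()
        params = np.asarray(ols.params)
        se = np.asarray(ols.bse)
        re_var = 0.0
        resid_var = float(ols.mse_resid)
        converged = True
        method = "ols"

    tvals = params / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    fe = pd.DataFrame(
        {"estimate": params, "se": se, "df": dof, "tvalue": tvals, "pvalue": pvals},
        index=names,
    )
    return TrendModelResult(
        fixed_effects=fe,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_obs=n,
        n_groups=n_groups,
        converged=converged,
        singular=singular,
        method=method,
    )


@dataclass
class PpiDesign:
    """Regressors of a psychophysiological-interaction model.

    The interaction is the elementwise product of the mean-centered seed
    series and the centered, HRF-convolved condition regressor — no
    deconvolution is applied.
    """

    seed: np.ndarray  # mean-centered seed series
    condition: np.ndarray  # centered HRF-convolved condition regressor
    interaction: np.ndarray
    nuisance: np.ndarray | None = None


def ppi_terms(
    seed_series,
    condition_boxcar,
    hrf: HrfParams | None = None,
    tr: float = 1.0,
    nuisance=None,
) -> PpiDesign:
    """Construct PPI regressors from a seed series and condition boxcar."""
    hrf = hrf or HrfParams()
    seed = np.asarray(seed_series, dtype=float)
    box = np.asarray(condition_boxcar, dtype=float)
    if seed.shape != box.shape or seed.ndim != 1:
        raise ValueError("seed series and condition boxcar lengths differ")
    from .hemodynamics import _sample_hrf

    kernel = _sample_hrf(tr, hrf)
    cond = np.convolve(box, kernel)[: box.size] * tr
    cond = cond - cond.mean()
    seed_c = seed - seed.mean()
    interaction = seed_c * cond
    nuis = None
    if nuisance is not None and np.asarray(nuisance).size:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
    return PpiDesign(seed=seed_c, condition=cond, interaction=interaction, nuisance=nuis)


@dataclass
class PpiFit:
    beta: float
    se: float
    tvalue: float
    dof: int


def fit_ppi(target_series, design: PpiDesign) -> PpiFit:
    """OLS fit of a target series on seed + condition + interaction.

    Returns the interaction (PPI) coefficient: the condition-dependent
    change in seed-target coupling.
    """
    y = np.asarray(target_series, dtype=float)
    cols = [np.ones_like(y), design.seed, design.condition, design.interaction]
    if design.nuisance is not None:
        cols += [design.nuisance[:, i] for i in range(design.nuisance.shape[1])]
    X = np.column_stack(cols)
    if y.shape[0] != X.shape[0]:
        raise ValueError("target series length differs from the PPI design")
    fit = fit_glm(y, X)
    c = np.zeros(X.shape[1])
    c[3] = 1.0
    beta = float(fit.contrast_estimate(c)[0])
    t = float(fit.t_contrast(c)[0])
    se = beta / t if t != 0 else np.inf
    return PpiFit(beta=beta, se=abs(se), tvalue=t, dof=fit.dof)


def connectivity_change(
    ppi_betas: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "caudate_pct_icv"),
    random_intercept: bool = True,
) -> TrendModelResult:
    """Across-visit trend of first-level PPI coefficients (second level)."""
    return visit_trend(
        ppi_betas, response="beta", covariates=covariates, random_intercept=random_intercept
    )


@dataclass
class ClusterTable:
    """Voxelwise regression output: t-map and 26-connected clusters."""

    tmap: np.ndarray
    threshold_t: float
    clusters: pd.DataFrame  # size, peak_i/j/k, peak_t (descending size)
    dof: int
    permutation_p: float | None = None


def _label_clusters(above: np.ndarray, tmap: np.ndarray) -> pd.DataFrame:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(above, structure=structure)
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        size = int(sel.sum())
        masked = np.where(sel, tmap, -np.inf)
        peak = np.unravel_index(int(np.argmax(masked)), tmap.shape)
        rows.append(
            {
                "size": size,
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "peak_t": float(tmap[peak]),
            }
        )
    df = pd.DataFrame(rows, columns=["size", "peak_i", "peak_j", "peak_k", "peak_t"])
    return df.sort_values("size", ascending=False).reset_index(drop=True)


def behavior_regression(
    change_maps: np.ndarray,
    composite_change,
    covariates,
    p_threshold: float = 0.001,
    mask=None,
    n_permutations: int = 0,
    seed: int = 0,
) -> ClusterTable:
    """Voxelwise regression of activation change on composite-score change.

    ``change_maps`` is (n_subjects, nx, ny, nz); the model at each voxel
    is OLS of the change value on the composite change plus covariates
    (age and caudate %ICV by convention).  Voxels whose one-sided p for a
    positive composite effect falls below ``p_threshold`` are grouped
    into 26-connected clusters.  No family-wise error calibration is
    applied; optionally a max-cluster-size permutation null (permuting
    the composite change) yields a cluster-level p for the largest
    cluster.
    """
    maps = np.asarray(change_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("change_maps must be (n_subjects, nx, ny, nz)")
    n_subj = maps.shape[0]
    comp = np.asarray(composite_change, dtype=float)
    if covariates is None:
        cov = np.empty((n_subj, 0))
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(float)
    else:
        cov = np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if comp.shape[0] != n_subj or cov.shape[0] != n_subj:
        raise ValueError("subject dimensions differ")
    X = np.column_stack([np.ones(n_subj), comp, cov])
    p = X.shape[1]
    dof = n_subj - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom (too few subjects)")

    spatial_shape = maps.shape[1:]
    Y = maps.reshape(n_subj, -1)
    fit = fit_glm(Y, X, spatial_shape=spatial_shape)
    c = np.zeros(p)
    c[1] = 1.0
    tmap = fit.t_contrast(c)
    t_crit = float(stats.t.isf(p_threshold, dof))
    above = tmap > t_crit
    if mask is not None:
        mask_arr = np.asarray(getattr(mask, "data", mask), dtype=bool)
        above &= mask_arr
    clusters = _label_clusters(above, tmap)

    perm_p = None
    if n_permutations > 0 and len(clusters):
        rng = np.random.default_rng(seed)
        observed = int(clusters["size"].iloc[0])
        null_max = np.zeros(n_permutations)
        for b in range(n_permutations):
            Xp = X.copy()
            Xp[:, 1] = rng.permutation(comp)
            fit_p = fit_glm(Y, Xp, spatial_shape=spatial_shape)
            t_p = fit_p.t_contrast(c)
            above_p = t_p > t_crit
            if mask is not None:
                above_p &= mask_arr
            lab, nl = ndimage.label(above_p, structure=np.ones((3, 3, 3), bool))
            null_max[b] = max(
                (np.sum(lab == i) for i in range(1, nl + 1)), default=0
            )
        perm_p = float((1 + np.sum(null_max >= observed)) / (1 + n_permutations))

    return ClusterTable(
        tmap=tmap, threshold_t=t_crit, clusters=clusters, dof=dof, permutation_p=perm_p
    )


@dataclass
class TappingComparison:
    """Per-condition tapping contrasts and the paired upregulation effect."""

    condition_means: pd.DataFrame  # condition, mean, se, n
    difference_estimate: float  # with minus without upregulation
    difference_se: float
    tvalue: float
    dof: int
    pvalue: float


TAPPING_CONDITIONS = ("pre", "post_without", "post_with")


def tapping_contrast_comparison(
    contrasts: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "caudate_pct_icv"),
) -> TappingComparison:
    """Compare tapping-task activation with versus without upregulation.

    ``contrasts`` holds one row per subject and condition (columns:
    subject, condition in {pre, post_without, post_with}, contrast, plus
    covariates).  Per-subject differences (with minus without) are
    regressed on an intercept and the covariates; the intercept's t-test
    is the covariate-adjusted paired comparison.
    """
    df = contrasts.copy()
    for cond in TAPPING_CONDITIONS:
        if cond not in set(df["condition"]):
            raise ValueError(f"missing condition {cond!r}")
    wide = df.pivot_table(index="subject", columns="condition", values="contrast")
    if wide[list(TAPPING_CONDITIONS)].isna().any().any():
        raise ValueError("subjects are not matched across the three conditions")

    summary = (
        df.groupby("condition")["contrast"]
        .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n="count")
        .reindex(list(TAPPING_CONDITIONS))
        .reset_index()
    )

    diff = (wide["post_with"] - wide["post_without"]).sort_index()
    subj_cov = (
        df.drop_duplicates("subject").set_index("subject").loc[diff.index, list(covariates)]
        if covariates
        else None
    )
    n = diff.size
    cols = [np.ones(n)]
    if subj_cov is not None:
        for c in covariates:
            v = subj_cov[c].to_numpy(float)
            if np.ptp(v) > 0:
                cols.append(v - v.mean())  # centered so the intercept is the adjusted mean
    X = np.column_stack(cols)
    dof = n - X.shape[1]
    if dof <= 0:
        raise ValueError("too few subjects for the covariate-adjusted comparison")
    y = diff.to_numpy(float)
    if np.ptp(y) == 0:
        est = float(y[0])
        return TappingComparison(
            condition_means=summary,
            difference_estimate=est,
            difference_se=0.0,
            tvalue=np.inf if est != 0 else 0.0,
            dof=dof,
            pvalue=0.0 if est != 0 else 1.0,
        )
    ols = sm.OLS(y, X).fit()
    est = float(ols.params[0])
    se = float(ols.bse[0])
    t = est / se
    pval = 2.0 * stats.t.sf(abs(t), dof)
    return TappingComparison(
        condition_means=summary,
        difference_estimate=est,
        difference_se=se,
        tvalue=float(t),
        dof=dof,
        pvalue=float(pval),
    )
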