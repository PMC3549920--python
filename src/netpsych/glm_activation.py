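"""Voxelwise General Linear Model, activation contrast t-maps, and ROI-level
correlation / psycho-physiological interaction (PPI) analysis.

The GLM regresses each voxel's BOLD series on HRF-convolved condition
indicator trains plus discrete-cosine drift regressors, optional motion
regressors, and an intercept.  Eight named contrasts over the three task
conditions (FrenchNative, Foreign, Silence) produce per-voxel t-maps; the
global activation summary is the mean absolute t over the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import CONDITIONS, BoldRun, Paradigm

__all__ = [
    "HRF_PARAMS",
    "CONTRAST_NAMES",
    "DesignMatrix",
    "GlmFit",
    "ActivationMap",
    "RoiSet",
    "canonical_hrf",
    "hrf_convolved_regressor",
    "build_design_matrix",
    "fit_glm",
    "contrast_tmap",
    "contrast_vector",
    "normalize_map",
    "mean_abs_t",
    "extract_roi_timeseries",
    "roi_correlation",
    "ppi_contrast",
    "read_rois",
]

# Canonical double-gamma HRF: response gamma (shape 6, rate 1), undershoot
# gamma (shape 16, rate 1) scaled by 1/6, then normalized to unit peak.
HRF_PARAMS = {"a1": 6.0, "b1": 1.0, "a2": 16.0, "b2": 1.0, "ratio": 1.0 / 6.0}
_HRF_FINE_DT = 0.1  # s, fine grid for convolution
_HRF_LENGTH_S = 32.0

#: The eight activation contrasts; 6-8 test a single condition's amplitude
#: against baseline (the intercept absorbs the baseline, so the contrast
#: vector is the bare condition indicator).
CONTRAST_NAMES = {
    1: "FrenchNative-Silence",
    2: "FrenchNative-Foreign",
    3: "Silence-FrenchNative",
    4: "Foreign-FrenchNative",
    5: "Foreign-Silence",
    6: "FrenchNative",
    7: "Foreign",
    8: "Silence",
}


def canonical_hrf(t):
    """Canonical double-gamma hemodynamic response, unit peak.

    Zero at t=0, peaks near 5 s, undershoots around 15 s.
    """
    t = np.asarray(t, dtype=float)
    p = HRF_PARAMS
    h = stats.gamma.pdf(t, p["a1"], scale=1.0 / p["b1"]) - p["ratio"] * stats.gamma.pdf(
        t, p["a2"], scale=1.0 / p["b2"]
    )
    grid = np.arange(0.0, _HRF_LENGTH_S, _HRF_FINE_DT)
    peak = np.max(
        stats.gamma.pdf(grid, p["a1"], scale=1.0 / p["b1"])
        - p["ratio"] * stats.gamma.pdf(grid, p["a2"], scale=1.0 / p["b2"])
    )
    return h / peak


def hrf_convolved_regressor(
    paradigm: Paradigm, condition: str, tr: float, n_volumes: int
) -> np.ndarray:
    """Condition boxcar convolved with the canonical HRF, sampled at the TR.

    Built on a 0.1 s grid, then sampled at volume acquisition times k*TR.
    """
    fine_t = np.arange(0.0, tr * n_volumes + _HRF_LENGTH_S, _HRF_FINE_DT)
    boxcar = np.zeros_like(fine_t)
    for onset, duration, cond in paradigm.events:
        if cond == condition:
            boxcar[(fine_t >= onset) & (fine_t < onset + duration)] = 1.0
    kernel = canonical_hrf(np.arange(0.0, _HRF_LENGTH_S, _HRF_FINE_DT))
    conv = np.convolve(boxcar, kernel)[: len(fine_t)] * _HRF_FINE_DT
    sample_idx = np.round(np.arange(n_volumes) * tr / _HRF_FINE_DT).astype(int)
    return conv[sample_idx]


def dct_drift_basis(n_volumes: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Unit-norm DCT-II columns spanning frequencies strictly below cutoff_hz.

    The k-th basis function has frequency k / (2 * T * TR); the number of
    retained columns is floor(2 * T * TR * cutoff_hz).
    """
    n_basis = int(np.floor(2.0 * n_volumes * tr * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (t + 0.5) * k / n_volumes)
        for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    values: np.ndarray  # T x R
    names: list[str]
    condition_cols: dict[str, int]
    drift_cols: list[int]
    motion_cols: list[int]
    intercept_col: int

    @property
    def n_regressors(self) -> int:
        return self.values.shape[1]


def build_design_matrix(
    paradigm: Paradigm,
    motion: np.ndarray | None = None,
    drift_cutoff: float = 1.0 / 128.0,
) -> DesignMatrix:
    """Assemble [conditions | drift | motion | intercept].

    Raises if the result is column-rank deficient, naming a collinear column.
    """
    if drift_cutoff <= 0:
        raise ValueError("drift_cutoff must be positive")
    t, tr = paradigm.n_volumes, paradigm.tr
    cols, names = [], []
    condition_cols = {}
    for c in CONDITIONS:
        condition_cols[c] = len(cols)
        cols.append(hrf_convolved_regressor(paradigm, c, tr, t))
        names.append(c)
    drift = dct_drift_basis(t, tr, drift_cutoff)
    drift_cols = list(range(len(cols), len(cols) + drift.shape[1]))
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift{k + 1}")
    motion_cols: list[int] = []
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (t, 6):
            raise ValueError("motion must be T x 6")
        motion_cols = list(range(len(cols), len(cols) + 6))
        for k in range(6):
            cols.append(motion[:, k])
            names.append(f"motion{k + 1}")
    intercept_col = len(cols)
    cols.append(np.ones(t))
    names.append("intercept")

    x = np.column_stack(cols)
    if x.shape[1] >= t:
        raise ValueError("more regressors than time points")
    # all-zero condition columns (a condition absent from the paradigm) are
    # permitted; the rank requirement applies to the nonzero columns
    nonzero = [j for j in range(x.shape[1]) if np.any(x[:, j])]
    xnz = x[:, nonzero]
    rank = np.linalg.matrix_rank(xnz)
    if rank < xnz.shape[1]:
        # identify an offending column for the error message
        names_nz = [names[j] for j in nonzero]
        keep: list[int] = []
        culprit = names_nz[-1]
        for j in range(xnz.shape[1]):
            if np.linalg.matrix_rank(xnz[:, keep + [j]]) == len(keep):
                culprit = names_nz[j]
                break
            keep.append(j)
        raise ValueError(f"design matrix is rank deficient (column {culprit!r})")
    return DesignMatrix(
        values=x,
        names=names,
        condition_cols=condition_cols,
        drift_cols=drift_cols,
        motion_cols=motion_cols,
        intercept_col=intercept_col,
    )


@dataclass
class GlmFit:
    beta: np.ndarray  # V x R
    residual_variance: np.ndarray  # V
    dof: int
    xtx_inv: np.ndarray  # R x R, (X'X)^-1 cached for contrast t-maps


def fit_glm(bold: BoldRun, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares per masked voxel."""
    x = design.values
    if x.shape[0] != bold.n_volumes:
        raise ValueError("design length does not match run length")
    y = bold.masked_series().T  # T x V
    bad = ~np.isfinite(y).all(axis=0)
    if bad.any():
        raise ValueError(f"non-finite series at masked voxel index {int(np.where(bad)[0][0])}")
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ y)  # R x V
    resid = y - x @ beta
    dof = x.shape[0] - np.linalg.matrix_rank(x)
    rss = np.einsum("tv,tv->v", resid, resid)
    return GlmFit(
        beta=beta.T,
        residual_variance=np.maximum(rss, 0.0) / dof,
        dof=dof,
        xtx_inv=xtx_inv,
    )


@dataclass
class ActivationMap:
    contrast: str
    tvalues: np.ndarray  # per masked voxel
    normalized: bool = False


def contrast_vector(design: DesignMatrix, contrast_id: int) -> np.ndarray:
    """Contrast vector over regressors for one of the eight named contrasts."""
    name = CONTRAST_NAMES[contrast_id]
    c = np.zeros(design.n_regressors)
    if "-" in name:
        a, b = name.split("-")
        c[design.condition_cols[a]] = 1.0
        c[design.condition_cols[b]] = -1.0
    else:
        c[design.condition_cols[name]] = 1.0
    return c


def contrast_tmap(fit: GlmFit, design: DesignMatrix, contrast: np.ndarray,
                  name: str = "") -> ActivationMap:
    """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c) per voxel.

    Voxels with zero residual variance get t = signed infinity when the
    numerator is nonzero (a sentinel excluded from downstream ranking) and
    t = 0 when both are zero.
    """
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (design.n_regressors,):
        raise ValueError("contrast length must equal the number of regressors")
    if not contrast.any():
        raise ValueError("contrast must not be all zeros")
    num = fit.beta @ contrast
    quad = float(contrast @ fit.xtx_inv @ contrast)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(fit.residual_variance * quad)
    zero_var = fit.residual_variance == 0.0
    t[zero_var & (num == 0.0)] = 0.0
    t[zero_var & (num > 0.0)] = np.inf
    t[zero_var & (num < 0.0)] = -np.inf
    return ActivationMap(contrast=name, tvalues=t)


def all_contrast_tmaps(fit: GlmFit, design: DesignMatrix) -> dict[int, ActivationMap]:
    return {
        cid: contrast_tmap(fit, design, contrast_vector(design, cid),
                           name=CONTRAST_NAMES[cid])
        for cid in CONTRAST_NAMES
    }


def normalize_map(amap):
    """Divide by the maximum absolute value over voxels (all-zero maps pass
    through unchanged).  Works for ActivationMap or bare feature arrays."""
    if isinstance(amap, ActivationMap):
        return replace(amap, tvalues=normalize_map(amap.tvalues), normalized=True)
    values = np.asarray(amap, dtype=float)
    finite = values[np.isfinite(values)]
    peak = np.max(np.abs(finite)) if finite.size else 0.0
    if peak == 0.0:
        return values.copy()
    return values / peak


def mean_abs_t(amap: ActivationMap) -> float:
    """Global activation feature: mean |t| over masked voxels (finite only)."""
    t = amap.tvalues
    finite = t[np.isfinite(t)]
    if finite.size == 0:
        raise ValueError("no finite t-values")
    return float(np.mean(np.abs(finite)))


@dataclass(frozen=True)
class RoiSet:
    labels: tuple[str, ...]
    centers_mm: np.ndarray  # n x 3
    radii_mm: np.ndarray  # n

    def __post_init__(self) -> None:
        if np.any(self.radii_mm <= 0):
            raise ValueError("ROI radii must be positive")


def read_rois(path: str | Path) -> RoiSet:
    df = pd.read_csv(path, sep="\t")
    return RoiSet(
        labels=tuple(df["label"].astype(str)),
        centers_mm=df[["x", "y", "z"]].to_numpy(float),
        radii_mm=df["radius_mm"].to_numpy(float),
    )


def _residualize_drift(series: np.ndarray, tr: float, drift_cutoff: float) -> np.ndarray:
    """Project out the cosine drift basis plus intercept (axis 0 = time)."""
    t = series.shape[0]
    basis = np.column_stack([np.ones(t), dct_drift_basis(t, tr, drift_cutoff)])
    coef, *_ = np.linalg.lstsq(basis, series, rcond=None)
    return series - basis @ coef


def extract_roi_timeseries(
    bold: BoldRun, rois: RoiSet, drift_cutoff: float = 1.0 / 128.0
) -> np.ndarray:
    """ROI x T spatial-mean series, drift-removed (cosine basis + intercept).

    ROI membership: masked voxels whose mm center lies within (<=) the ROI
    radius of its center.
    """
    coords = bold.voxel_coords_mm()
    series = bold.masked_series()  # V x T
    out = np.empty((len(rois.labels), bold.n_volumes))
    for i, label in enumerate(rois.labels):
        inside = np.linalg.norm(coords - rois.centers_mm[i], axis=1) <= rois.radii_mm[i]
        if not inside.any():
            raise ValueError(f"ROI {label!r} contains no masked voxel")
        out[i] = series[inside].mean(axis=0)
    return _residualize_drift(out.T, bold.tr, drift_cutoff).T


def roi_correlation(roi_ts: np.ndarray) -> np.ndarray:
    """Symmetric Pearson correlation between ROI series, unit diagonal."""
    roi_ts = np.asarray(roi_ts, dtype=float)
    if roi_ts.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = roi_ts.std(axis=1)
    if np.any(sd == 0):
        raise ValueError(f"constant series for ROI index {int(np.argmax(sd == 0))}")
    return np.corrcoef(roi_ts)


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        return 0.0
    return cov / np.sqrt(vx * vy)


def ppi_contrast(
    roi_ts: np.ndarray, design: DesignMatrix, cond_a: str, cond_b: str
) -> np.ndarray:
    """Condition-weighted correlation difference (PPI) per ROI pair.

    Weights are the HRF-convolved condition regressor clipped at zero and
    renormalized to sum 1; the contrast is corr weighted by condition a minus
    corr weighted by condition b.
    """
    weights = {}
    for cond in (cond_a, cond_b):
        if cond not in design.condition_cols:
            raise ValueError(f"condition {cond!r} not in design")
        w = np.clip(design.values[:, design.condition_cols[cond]], 0.0, None)
        if w.sum() == 0:
            raise ValueError(f"all-zero weights for condition {cond!r}")
        weights[cond] = w / w.sum()
    n = roi_ts.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _weighted_corr(roi_ts[i], roi_ts[j], weights[cond_a]) - _weighted_corr(
                roi_ts[i], roi_ts[j], weights[cond_b]
            )
            out[i, j] = out[j, i] = d
    return out
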