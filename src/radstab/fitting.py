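"""Voxelwise ADC / IVIM / DKI parameter estimation with goodness of fit.

Models (b in s/mm^2, diffusivities in mm^2/s, signals normalized to S0):

* mono-exponential ADC from the (0, 800) pair: ADC = ln(S0/S800)/800
* IVIM bi-exponential over the 9 b-values <= 800:
      S(b)/S0 = (1 - f) exp(-b D) + f exp(-b (D + D*))
* diffusion kurtosis over the 6 b-values {0, 200, 400, 800, 1500, 2000}:
      S(b)/S0 = exp(-b MD + b^2 MD^2 MK / 6)

IVIM uses the classical segmented initialization (log-linear D above the
perfusion/diffusion split b, f from the intercept, D* from the low-b residue)
followed, by default, by a bounded full nonlinear least-squares refinement.
DKI is initialized by linear least squares in (b, b^2) and refined the same
way. The refinement is a projected, Levenberg-damped Gauss-Newton iteration
vectorized across all voxels at once, which keeps whole-cohort map fitting
within seconds.

Goodness of fit is the ordinary R^2 = 1 - SS_res/SS_tot; the fit-quality
exclusion rule (R^2 < 0.8) is applied per voxel (map masking) and per subject
(ROI-median, mirroring patient-level exclusion), both configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import BValueScheme, DwiSeries

__all__ = [
    "FitOptions",
    "ParametricMapSet",
    "MAP_NAMES",
    "fit_adc",
    "fit_ivim",
    "fit_dki",
    "goodness_of_fit",
    "fit_map_set",
]

#: Canonical order of the six parametric maps fed to feature extraction.
MAP_NAMES = ("ADC", "D", "Dstar", "f", "MD", "MK")

DKI_B_VALUES = (0.0, 200.0, 400.0, 800.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class FitOptions:
    """Fitting configuration.

    ``ivim_split_b`` separates the perfusion-dominated low-b regime from the
    diffusion-dominated high-b regime (default 200 s/mm^2). Bounds are
    physiological ranges that keep the low-SNR refinement from diverging.
    ``r2_threshold`` is the fit-quality exclusion cutoff; ``voxel_r2_mask``
    drops failing voxels from the fit mask, and the subject-level flag uses
    the ROI median.
    """

    ivim_split_b: float = 200.0
    adc_b_pair: tuple[float, float] = (0.0, 800.0)
    ivim_max_b: float = 800.0
    d_bounds: tuple[float, float] = (1e-5, 4e-3)
    dstar_bounds: tuple[float, float] = (1e-5, 0.5)
    f_bounds: tuple[float, float] = (0.0, 1.0)
    md_bounds: tuple[float, float] = (1e-5, 4e-3)
    mk_bounds: tuple[float, float] = (0.0, 3.0)
    refine_full_nlls: bool = True
    r2_threshold: float = 0.8
    voxel_r2_mask: bool = True
    max_iter: int = 60

    def __post_init__(self):
        if not (0.0 < self.ivim_split_b < self.ivim_max_b):
            raise ValueError("ivim_split_b must lie strictly inside the b range")
        for lo, hi in (self.d_bounds, self.dstar_bounds, self.f_bounds,
                       self.md_bounds, self.mk_bounds):
            if lo >= hi:
                raise ValueError("bounds must be ordered (lo < hi)")


def goodness_of_fit(observed, predicted, axis: int = -1):
    """R^2 = 1 - SS_res / SS_tot with SS_tot about the observed mean.

    Returns NaN where the observed values have zero total variance.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have the same shape")
    if obs.shape[axis] < 3:
        raise ValueError("need at least 3 points for R^2")
    ss_res = np.sum((obs - pred) ** 2, axis=axis)
    ss_tot = np.sum((obs - np.mean(obs, axis=axis, keepdims=True)) ** 2, axis=axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return np.where(ss_tot > 0, r2, np.nan)


def fit_adc(signals, b_pair: tuple[float, float] = (0.0, 800.0)):
    """Closed-form ADC from a (b=0, b=high) signal pair.

    ``signals`` is (..., 2) stacked as (S_b0, S_bhigh). Nonpositive signals
    yield NaN (the voxel is excluded from the fit mask by the caller).
    """
    s = np.asarray(signals, dtype=float)
    b0, b1 = b_pair
    if b1 <= b0:
        raise ValueError("b_pair must be increasing")
    s0, sb = s[..., 0], s[..., 1]
    valid = (s0 > 0) & (sb > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s0 / sb) / (b1 - b0)
    return np.where(valid, adc, np.nan)


def _ivim_model(b, D, Ds, f):
    e1 = np.exp(-b * D[..., None])
    e2 = np.exp(-b * (D + Ds)[..., None])
    return (1.0 - f)[..., None] * e1 + f[..., None] * e2


def _ivim_residual_jac(x, b, y):
    D, Ds, f = x[:, 0], x[:, 1], x[:, 2]
    e1 = np.exp(-b * D[:, None])
    e2 = np.exp(-b * (D + Ds)[:, None])
    pred = (1.0 - f)[:, None] * e1 + f[:, None] * e2
    r = pred - y
    J = np.empty(x.shape[:1] + b.shape + (3,))
    J[..., 0] = -b * ((1.0 - f)[:, None] * e1 + f[:, None] * e2)
    J[..., 1] = -b * f[:, None] * e2
    J[..., 2] = e2 - e1
    return r, J, pred


def _dki_residual_jac(x, b, y):
    MD, MK = x[:, 0], x[:, 1]
    expo = -b * MD[:, None] + (b**2) * (MD**2 * MK)[:, None] / 6.0
    pred = np.exp(expo)
    r = pred - y
    J = np.empty(x.shape[:1] + b.shape + (2,))
    J[..., 0] = pred * (-b + (b**2) * (MD * MK)[:, None] / 3.0)
    J[..., 1] = pred * (b**2) * (MD**2)[:, None] / 6.0
    return r, J, pred


def _projected_gauss_newton(residual_jac, x0, lb, ub, b, y, max_iter=60, tol=1e-14):
    """Bounded nonlinear least squares, vectorized across voxels.

    Gauss-Newton steps with a small Levenberg ridge, projection onto the box
    [lb, ub], and per-voxel step halving when the SSE does not decrease.
    """
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)
    n_vox, n_par = x.shape
    eye = np.eye(n_par)
    ever_improved = np.zeros(n_vox, dtype=bool)
    active = np.arange(n_vox)  # voxels still being iterated
    xa = x[active]
    r, J, _ = residual_jac(xa, b, y)
    sse = np.sum(r**2, axis=1)
    for _ in range(max_iter):
        if active.size == 0:
            break
        g = np.einsum("vbp,vb->vp", J, r)
        H = np.einsum("vbp,vbq->vpq", J, J)
        ridge = 1e-10 * np.trace(H, axis1=1, axis2=2) + 1e-300
        H = H + ridge[:, None, None] * eye
        delta = -np.linalg.solve(H, g[..., None])[..., 0]
        sse_before = sse.copy()
        step = np.ones(active.size)
        improved = np.zeros(active.size, dtype=bool)
        x_try = xa
        for _bt in range(8):
            cand = np.clip(xa + (step[:, None] * delta), lb, ub)
            r_c, J_c, _ = residual_jac(cand, b, y[active])
            sse_c = np.sum(r_c**2, axis=1)
            newly = (sse_c < sse - 1e-18) & ~improved
            if newly.any():
                x_try = np.where(newly[:, None], cand, x_try)
                r = np.where(newly[:, None], r_c, r)
                J = np.where(newly[:, None, None], J_c, J)
                sse = np.where(newly, sse_c, sse)
                improved |= newly
            if improved.all():
                break
            step = np.where(improved, step, step * 0.5)
        x[active] = x_try
        ever_improved[active[improved]] = True
        # retire voxels at a box optimum, taking negligible steps, or making
        # negligible SSE progress (per-parameter scale: 1e-9 of the box width
        # is far below any tolerance asserted on the fitted parameters)
        tol_vec = np.maximum(1e-9 * (ub - lb), tol)
        progress = (sse_before - sse) > 1e-12 * (sse_before + 1e-30)
        keep = improved & progress & np.any(
            np.abs(step[:, None] * delta) > tol_vec, axis=1
        )
        active = active[keep]
        xa, r, J, sse = x_try[keep], r[keep], J[keep], sse[keep]
    return x, ever_improved


def _masked_lowb_slope(lnr, b, valid):
    """Per-voxel weighted linear fit ln r = a - slope*b over valid entries."""
    w = valid.astype(float)
    lnr = np.where(valid, lnr, 0.0)
    n = w.sum(axis=1)
    sx = (w * b).sum(axis=1)
    sy = (w * lnr).sum(axis=1)
    sxx = (w * b * b).sum(axis=1)
    sxy = (w * b * lnr).sum(axis=1)
    denom = n * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (n * sxy - sx * sy) / denom
    ok = (n >= 2) & (denom > 0)
    return -slope, ok  # decay rate = D + D*


def fit_ivim(signals, scheme: BValueScheme, options: FitOptions | None = None):
    """Segmented (optionally NLLS-refined) IVIM fit.

    ``signals`` is (..., nb) over the scheme's b-values (all <= ivim_max_b,
    first b = 0). Returns (D, D*, f, R^2) arrays of the leading shape.
    Non-convergent voxels fall back to the segmented estimate; f is clipped
    to [0, 1].
    """
    options = options or FitOptions()
    b = scheme.b_values
    if b.max() > options.ivim_max_b:
        raise ValueError("scheme contains b-values above the IVIM range")
    sig = np.asarray(signals, dtype=float)
    lead_shape = sig.shape[:-1]
    sig = sig.reshape(-1, sig.shape[-1])
    n_vox = sig.shape[0]

    valid = np.all(sig > 0, axis=1)
    y = np.where(valid[:, None], sig / np.where(sig[:, [0]] > 0, sig[:, [0]], 1.0), np.nan)

    hi = b >= options.ivim_split_b
    if hi.sum() < 2 or (~hi).sum() < 2:
        raise ValueError("need >= 2 b-values on each side of ivim_split_b")

    # --- segmented stage 1: log-linear D and intercept-derived f (high b) ---
    X = np.column_stack([np.ones(hi.sum()), -b[hi]])
    lny = np.log(np.where(valid[:, None], y, 1.0))[:, hi]
    beta, *_ = np.linalg.lstsq(X, lny.T, rcond=None)
    c0, D0 = beta[0], beta[1]
    f0 = 1.0 - np.exp(c0)
    D0 = np.clip(D0, *options.d_bounds)
    f0 = np.clip(f0, *options.f_bounds)

    # --- segmented stage 2: D* from the low-b pseudo-diffusion residue ---
    lo = ~hi & (b > 0)
    resid = y[:, lo] - (1.0 - f0[:, None]) * np.exp(-b[lo] * D0[:, None])
    pos = valid[:, None] & (resid > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnr = np.where(pos, np.log(np.where(pos, resid, 1.0)), 0.0)
    rate, ok = _masked_lowb_slope(lnr, b[lo], pos)
    Ds0 = np.where(ok, rate - D0, 10.0 * D0)
    Ds0 = np.clip(Ds0, *options.dstar_bounds)

    x0 = np.column_stack([D0, Ds0, f0])
    lb = np.array([options.d_bounds[0], options.dstar_bounds[0], options.f_bounds[0]])
    ub = np.array([options.d_bounds[1], options.dstar_bounds[1], options.f_bounds[1]])

    y_fit = np.where(valid[:, None], y, 1.0)
    if options.refine_full_nlls and n_vox:
        # Voxels where no refinement step improves the SSE keep the segmented
        # start point (the fallback is inherent: steps are only accepted when
        # they decrease the SSE).
        x, _ = _projected_gauss_newton(
            _ivim_residual_jac, x0, lb, ub, b, y_fit, max_iter=options.max_iter
        )
    else:
        x = x0
    D, Ds, f = x[:, 0], x[:, 1], x[:, 2]
    pred = _ivim_model(b, D, Ds, f)
    r2 = goodness_of_fit(y_fit, pred)
    out = [np.where(valid, v, np.nan).reshape(lead_shape) for v in (D, Ds, f, r2)]
    return tuple(out)


def fit_dki(signals, scheme: BValueScheme, options: FitOptions | None = None):
    """DKI fit over the 6-b-value subset: returns (MD, MK, R^2).

    Linear least squares on ln(S/S0) = -b c1 + b^2 c2 initializes
    MD = c1, MK = 6 c2 / c1^2; a bounded nonlinear refinement follows.
    Voxels with c1 <= 0 (non-decaying signal) are invalid (NaN).
    """
    options = options or FitOptions()
    b = scheme.b_values
    sig = np.asarray(signals, dtype=float)
    lead_shape = sig.shape[:-1]
    sig = sig.reshape(-1, sig.shape[-1])

    valid = np.all(sig > 0, axis=1)
    y = np.where(valid[:, None], sig / np.where(sig[:, [0]] > 0, sig[:, [0]], 1.0), 1.0)
    lny = np.log(y)
    X = np.column_stack([-b, b**2])
    beta, *_ = np.linalg.lstsq(X, lny.T, rcond=None)
    c1, c2 = beta[0], beta[1]
    valid = valid & (c1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mk0 = 6.0 * c2 / c1**2
    md0 = np.clip(c1, *options.md_bounds)
    mk0 = np.clip(np.where(np.isfinite(mk0), mk0, 0.0), *options.mk_bounds)

    x0 = np.column_stack([md0, mk0])
    lb = np.array([options.md_bounds[0], options.mk_bounds[0]])
    ub = np.array([options.md_bounds[1], options.mk_bounds[1]])
    if options.refine_full_nlls and sig.shape[0]:
        x, _ = _projected_gauss_newton(
            _dki_residual_jac, x0, lb, ub, b, y, max_iter=options.max_iter
        )
    else:
        x = x0
    MD, MK = x[:, 0], x[:, 1]
    pred = np.exp(-b * MD[:, None] + (b**2) * (MD**2 * MK)[:, None] / 6.0)
    r2 = goodness_of_fit(y, pred)
    out = [np.where(valid, v, np.nan).reshape(lead_shape) for v in (MD, MK, r2)]
    return tuple(out)


@dataclass(frozen=True)
class ParametricMapSet:
    """Voxelwise ADC/D/D*/f/MD/MK maps with per-model R^2 and fit mask."""

    adc: np.ndarray
    d: np.ndarray
    d_star: np.ndarray
    f: np.ndarray
    md: np.ndarray
    mk: np.ndarray
    r2_ivim: np.ndarray
    r2_dki: np.ndarray
    fit_mask: np.ndarray
    report: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"ADC": self.adc, "D": self.d, "Dstar": self.d_star,
                "f": self.f, "MD": self.md, "MK": self.mk}


def fit_map_set(series: DwiSeries, options: FitOptions | None = None, mask=None) -> ParametricMapSet:
    """Fit all three models voxelwise over ``mask`` (or the whole grid).

    The fit mask excludes voxels with invalid signals, and (by default)
    voxels whose IVIM or DKI R^2 falls below ``options.r2_threshold``. A
    subject-level exclusion flag is raised in the report when the ROI-median
    R^2 of either model is below the threshold — the synthetic analog of
    excluding a patient for poor model fitting.
    """
    options = options or FitOptions()
    grid = series.volumes.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError("mask shape does not match series grid")
    if not mask.any():
        raise ValueError("mask is empty")

    scheme = series.scheme
    b_all = scheme.b_values
    sig = series.volumes[mask]  # (nv, nb)

    # ADC from the (0, 800) pair
    adc_idx = scheme.indices_of(options.adc_b_pair)
    adc_v = fit_adc(sig[:, adc_idx], options.adc_b_pair)

    # IVIM over b <= 800
    ivim_cols = np.flatnonzero(b_all <= options.ivim_max_b)
    ivim_scheme = BValueScheme(tuple(scheme.entries[i] for i in ivim_cols))
    d_v, ds_v, f_v, r2i_v = fit_ivim(sig[:, ivim_cols], ivim_scheme, options)

    # DKI over the 6-b subset
    dki_scheme = scheme.restrict(DKI_B_VALUES)
    dki_cols = scheme.indices_of(DKI_B_VALUES)
    md_v, mk_v, r2d_v = fit_dki(sig[:, dki_cols], dki_scheme, options)

    def to_map(vals):
        out = np.full(grid, np.nan)
        out[mask] = vals
        return out

    maps = [to_map(v) for v in (adc_v, d_v, ds_v, f_v, md_v, mk_v, r2i_v, r2d_v)]
    adc, d, d_star, f, md, mk, r2_ivim, r2_dki = maps

    voxel_ok = (
        np.isfinite(adc_v) & np.isfinite(d_v) & np.isfinite(md_v)
        & np.isfinite(r2i_v) & np.isfinite(r2d_v)
    )
    if options.voxel_r2_mask:
        voxel_ok &= (r2i_v >= options.r2_threshold) & (r2d_v >= options.r2_threshold)
    fit_mask = np.zeros(grid, dtype=bool)
    fit_mask[mask] = voxel_ok

    med_i = float(np.nanmedian(r2i_v)) if np.isfinite(r2i_v).any() else np.nan
    med_d = float(np.nanmedian(r2d_v)) if np.isfinite(r2d_v).any() else np.nan
    excluded = bool(
        (np.isnan(med_i) or med_i < options.r2_threshold)
        or (np.isnan(med_d) or med_d < options.r2_threshold)
    )
    report = {
        "subject_id": series.subject_id,
        "sequence": series.sequence_label,
        "n_voxels": int(mask.sum()),
        "n_fit": int(fit_mask.sum()),
        "median_r2_ivim": med_i,
        "median_r2_dki": med_d,
        "subject_excluded": excluded,
        "r2_threshold": options.r2_threshold,
    }
    return ParametricMapSet(
        adc=adc, d=d, d_star=d_star, f=f, md=md, mk=mk,
        r2_ivim=r2_ivim, r2_dki=r2_dki, fit_mask=fit_mask, report=report,
    )
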