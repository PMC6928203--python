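"""Per-pixel diffusion-coefficient fitting.

Two fitting pathways are provided, matching the two signal models:

* :func:`fit_adc_loglinear` — mono-exponential ADC: ordinary least
  squares of ln S on b over all b-values (the phantom pathway);
* :func:`fit_ivim_simplified` — the simplified IVIM pure-diffusion fit:
  nonlinear least squares of S = A·exp(−b·D) restricted to b ≥ 200 s/mm²,
  where the pseudo-diffusion compartment (Dp ≫ D) has fully decayed and
  only slow tissue diffusion remains (the in-vivo pathway).

Multi-direction series are first collapsed with
:func:`average_directions` to account for diffusion anisotropy.

All D values are reported in 10⁻³ mm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import DWISeries, ProtocolConfig

__all__ = ["DiffusionMap", "average_directions", "fit_adc_loglinear",
           "fit_ivim_simplified"]

#: Upper bound for fitted D, 10⁻³ mm²/s (well above any liquid at room T).
D_MAX = 50.0
#: Convergence tolerance on the parameter step of the nonlinear fit.
STEP_TOL = 1e-10
#: Iteration cap of the nonlinear fit.
MAX_ITER = 60


@dataclass
class DiffusionMap:
    """Per-pixel fitted diffusion coefficient with a validity mask.

    D in 10⁻³ mm²/s; ``valid`` is False where the fit preconditions were
    violated (non-positive signals, too few usable b-values); ``f`` is
    the perfusion-fraction map of the simplified IVIM fit (None for the
    plain ADC fit).
    """

    D: np.ndarray
    S0_fit: np.ndarray
    valid: np.ndarray
    fit_meta: dict = field(default_factory=dict)
    f: np.ndarray | None = None


def average_directions(series: DWISeries, method: str = "arithmetic") -> DWISeries:
    """Collapse the direction axis by per-pixel signal averaging.

    The arithmetic mean of the per-direction signals at each b is the
    default reading of direction averaging; a geometric-mean option is
    exposed (the geometric mean of exponential decays corresponds to
    averaging the per-direction diffusivities instead of the signals).
    """
    if method not in ("arithmetic", "geometric"):
        raise ValueError("method must be 'arithmetic' or 'geometric'")
    if series.protocol.n_directions == 1 and method == "arithmetic":
        return series
    if method == "arithmetic":
        avg = series.data.mean(axis=1, keepdims=True)
    else:
        avg = np.exp(np.log(np.maximum(series.data, 1e-300)).mean(axis=1, keepdims=True))
    proto = series.protocol
    new_proto = ProtocolConfig(
        b_values=proto.b_values,
        n_directions=1,
        image_shape=proto.image_shape,
        pixel_size=proto.pixel_size,
    )
    return DWISeries(
        data=avg,
        protocol=new_proto,
        ground_truth=series.ground_truth,
        masks=dict(series.masks),
        meta={**series.meta, "direction_average": method},
    )


def _flatten_series(series: DWISeries, b_subset) -> tuple[np.ndarray, np.ndarray]:
    """Return (b_used, signals[n_b_used, n_pixels]) for a 1-direction series."""
    if series.protocol.n_directions != 1:
        raise ValueError(
            "series must be direction-averaged before fitting "
            "(use average_directions)"
        )
    b_all = np.asarray(series.protocol.b_values, dtype=float)
    if b_subset is None:
        sel = np.ones(b_all.size, dtype=bool)
    else:
        sel = np.isin(b_all, np.asarray(b_subset, dtype=float))
        if sel.sum() != len(b_subset):
            raise ValueError(
                f"b_subset {b_subset} not a subset of protocol b-values {b_all}"
            )
    sig = series.data[sel, 0].reshape(sel.sum(), -1)
    return b_all[sel], sig


def _loglinear(b: np.ndarray, sig: np.ndarray, valid: np.ndarray):
    """Closed-form OLS of ln(signal) on b, vectorized over pixels.

    Returns (D in 10⁻³ mm²/s, S0, residual L2 norm), defined where valid.
    """
    logs = np.where(sig > 0, np.log(np.maximum(sig, 1e-300)), 0.0)
    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = (bc[:, None] * logs).sum(axis=0) / denom      # d lnS / db, mm²/s
    intercept = logs.mean(axis=0) - slope * b.mean()
    resid = logs - (intercept[None] + slope[None] * b[:, None])
    rnorm = np.sqrt((resid**2).sum(axis=0))
    d_map = -slope * 1e3                                   # report in 10⁻³ mm²/s
    s0 = np.exp(intercept)
    for arr in (d_map, s0, rnorm):
        arr[~valid] = np.nan
    return d_map, s0, rnorm


def fit_adc_loglinear(
    series: DWISeries, b_subset=None
) -> DiffusionMap:
    """Pixel-wise log-linear ADC fit: OLS of ln S on b; slope = −D.

    Pixels with any non-positive signal among the used b-values are
    excluded (marked invalid) rather than clipped, because clipping
    biases the slope. Requires >= 2 usable b-values.
    """
    b, sig = _flatten_series(series, b_subset)
    if b.size < 2:
        raise ValueError("need at least 2 b-values for a log-linear fit")
    shape = series.protocol.image_shape
    valid = (sig > 0).all(axis=0)
    if not valid.any():
        raise ValueError("no pixel has positive signal at every used b-value")
    d_map, s0, rnorm = _loglinear(b, sig, valid)
    return DiffusionMap(
        D=d_map.reshape(shape),
        S0_fit=s0.reshape(shape),
        valid=valid.reshape(shape),
        fit_meta={
            "model": "adc_loglinear",
            "b_used": b.tolist(),
            "residual_norm": rnorm.reshape(shape),
            "n_invalid": int((~valid).sum()),
        },
    )


def fit_ivim_simplified(
    series: DWISeries, b_threshold: float = 200.0
) -> DiffusionMap:
    """Simplified IVIM pure-diffusion fit over the b >= ``b_threshold`` regime.

    With Dp ≫ D the perfusion compartment contributes nothing beyond
    b ≈ 200 s/mm², so S(b) = A·exp(−b·D) there, with A = S0·(1−f). The
    fit is a per-pixel damped Gauss–Newton least squares (bounded
    iterations, D clamped to [0, 50]·10⁻³ mm²/s, step tolerance 1e−10),
    initialized from the log-linear fit of the same points; pixels that
    fail to converge keep the log-linear estimate and are flagged in
    ``fit_meta['fallback']``. If the series contains b = 0, the
    perfusion fraction is derived from the intercept as
    f = 1 − A/S(0), clamped to [0, 1].
    """
    b_all = np.asarray(series.protocol.b_values, dtype=float)
    b_used = b_all[b_all >= b_threshold]
    if b_used.size < 2:
        raise ValueError(
            f"need >= 2 b-values >= {b_threshold} s/mm², protocol has {b_used.size}"
        )
    b, sig = _flatten_series(series, b_used)
    shape = series.protocol.image_shape
    valid = (sig > 0).all(axis=0)
    if not valid.any():
        raise ValueError("no pixel has positive signal at every used b-value")

    d0, a0, _ = _loglinear(b, sig, valid)
    d = np.clip(np.nan_to_num(d0, nan=1.0), 0.0, D_MAX) * 1e-3   # mm²/s
    a = np.nan_to_num(a0, nan=1.0)
    active = valid.copy()
    lam = 1e-8  # Levenberg damping keeps the 2×2 solve well-posed
    for _ in range(MAX_ITER):
        if not active.any():
            break
        bi = b[:, None]
        model = a[None, active] * np.exp(-bi * d[None, active])
        r = sig[:, active] - model
        # Jacobian columns: dm/da = m/a (= exp term), dm/dD = -b·m
        ja = model / np.maximum(a[None, active], 1e-300)
        jd = -bi * model
        jtj_aa = (ja * ja).sum(axis=0) + lam
        jtj_ad = (ja * jd).sum(axis=0)
        jtj_dd = (jd * jd).sum(axis=0) + lam
        g_a = (ja * r).sum(axis=0)
        g_d = (jd * r).sum(axis=0)
        det = jtj_aa * jtj_dd - jtj_ad**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (jtj_dd * g_a - jtj_ad * g_d) / det
        dd = (jtj_aa * g_d - jtj_ad * g_a) / det
        a_new = np.maximum(a[active] + da, 0.0)
        d_new = np.clip(d[active] + dd, 0.0, D_MAX * 1e-3)
        step = np.maximum(np.abs(a_new - a[active]) / np.maximum(a_new, 1e-12),
                          np.abs(d_new - d[active]))
        a[active], d[active] = a_new, d_new
        still = np.zeros_like(active)
        still[active] = step > STEP_TOL
        active = still
    fallback = active & valid  # not converged within MAX_ITER
    if fallback.any():
        d[fallback] = np.clip(np.nan_to_num(d0[fallback]), 0.0, D_MAX) * 1e-3
        a[fallback] = np.nan_to_num(a0[fallback])

    model = a[None] * np.exp(-b[:, None] * d[None])
    rnorm = np.sqrt(((sig - model) ** 2).sum(axis=0))
    d_out = np.where(valid, d * 1e3, np.nan)
    a_out = np.where(valid, a, np.nan)
    rnorm = np.where(valid, rnorm, np.nan)

    f_map = None
    if b_all[0] == 0.0:
        s_b0 = series.data[0, 0].reshape(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_flat = 1.0 - a_out / s_b0
        f_map = np.clip(np.where(valid & (s_b0 > 0), f_flat, np.nan), 0.0, 1.0)
        f_map = f_map.reshape(shape)

    return DiffusionMap(
        D=d_out.reshape(shape),
        S0_fit=a_out.reshape(shape),
        valid=valid.reshape(shape),
        f=f_map,
        fit_meta={
            "model": "ivim_simplified",
            "b_threshold": float(b_threshold),
            "b_used": b.tolist(),
            "residual_norm": rnorm.reshape(shape),
            "n_invalid": int((~valid).sum()),
            "fallback": fallback.reshape(shape),
            "n_fallback": int(fallback.sum()),
        },
    )
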