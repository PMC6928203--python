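"""Image-level acquisition artifacts: EPI-like warp and echo-train blur.

Echo-planar readouts have a low effective bandwidth along the phase-encode
axis, so off-resonance (B0 inhomogeneity, susceptibility) translates into
pixel displacement along that axis; fast-spin-echo (RARE) readouts are
immune to that displacement but convolve the image along the phase-encode
axis with a point-spread function set by the T2 decay over the echo train.
Both effects are modelled directly in image space — there is no k-space
pulse-sequence simulation here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import DWISeries

__all__ = ["WarpSpec", "BlurSpec", "random_smooth_field", "apply_warp",
           "warp_mask", "apply_etl_blur", "etl_psf"]


@dataclass
class WarpSpec:
    """Displacement of image content along the phase-encode axis.

    ``field`` gives per-pixel displacement in pixels (positive = toward
    larger indices along ``phase_axis``). Build smooth random fields with
    :func:`random_smooth_field`.
    """

    field: np.ndarray
    phase_axis: int = 0

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        if not np.isfinite(self.field).all():
            raise ValueError("displacement field must be finite")
        if self.phase_axis not in (0, 1):
            raise ValueError("phase_axis must be 0 or 1")

    def negated(self) -> "WarpSpec":
        return WarpSpec(field=-self.field, phase_axis=self.phase_axis)


@dataclass(frozen=True)
class BlurSpec:
    """Echo-train blurring parameters of a RARE-like readout.

    T2 and echo_spacing in ms; ``etl`` echoes per excitation; ``ordering``
    is the phase-encode ordering ('centric': k-space centre acquired
    first, the scheme used for diffusion-prepared RARE; 'linear': edge to
    edge).
    """

    T2: float
    echo_spacing: float
    etl: int
    ordering: str = "centric"

    def __post_init__(self) -> None:
        if self.T2 <= 0 or self.echo_spacing <= 0:
            raise ValueError("T2 and echo_spacing must be positive (ms)")
        if self.etl < 1:
            raise ValueError("etl must be >= 1")
        if self.ordering not in ("centric", "linear"):
            raise ValueError("ordering must be 'centric' or 'linear'")


def random_smooth_field(
    shape: tuple[int, int],
    amplitude: float,
    spatial_scale: float = 20.0,
    poly_weight: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Smooth random displacement field, max |value| = ``amplitude`` pixels.

    Sum of a low-order 2D polynomial trend and a band-limited random
    component (white noise smoothed at ``spatial_scale`` pixels), rescaled
    so the maximum absolute displacement equals ``amplitude``. Mimics the
    smooth off-resonance fields that drive EPI distortion.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    y = (yy - h / 2) / (h / 2)
    x = (xx - w / 2) / (w / 2)
    coef = rng.standard_normal(6)
    poly = (coef[0] + coef[1] * x + coef[2] * y + coef[3] * x * y
            + coef[4] * x**2 + coef[5] * y**2)
    poly /= max(np.abs(poly).max(), 1e-12)
    rough = ndimage.gaussian_filter(rng.standard_normal(shape), spatial_scale)
    rough /= max(np.abs(rough).max(), 1e-12)
    fld = poly_weight * poly + (1.0 - poly_weight) * rough
    return amplitude * fld / max(np.abs(fld).max(), 1e-12)


def _warp_image(img: np.ndarray, warp: WarpSpec, order: int) -> np.ndarray:
    if warp.field.shape != img.shape:
        raise ValueError(
            f"field shape {warp.field.shape} != image shape {img.shape}"
        )
    span = img.shape[warp.phase_axis]
    if np.abs(warp.field).max() >= span:
        warnings.warn(
            "displacement exceeds the image extent; content is clipped"
        )
    rr, cc = np.indices(img.shape, dtype=float)
    # pull-back sampling: output(x) = input(x - u(x)) moves content by +u
    if warp.phase_axis == 0:
        rr = rr - warp.field
    else:
        cc = cc - warp.field
    return ndimage.map_coordinates(
        img, [rr, cc], order=order, mode="constant", cval=0.0
    )


def apply_warp(obj: DWISeries | np.ndarray, warp: WarpSpec) -> DWISeries | np.ndarray:
    """Displace a signal image (or every image of a series) along the
    phase-encode axis by the field value, with linear interpolation.

    For binary masks use :func:`warp_mask`, which re-thresholds so the
    result stays binary.
    """
    if isinstance(obj, DWISeries):
        out = np.empty_like(obj.data)
        for ib in range(obj.data.shape[0]):
            for idir in range(obj.data.shape[1]):
                out[ib, idir] = _warp_image(obj.data[ib, idir], warp, order=1)
        return obj.copy_with(np.maximum(out, 0.0), warped=True)
    return _warp_image(np.asarray(obj, dtype=float), warp, order=1)


def warp_mask(mask: np.ndarray, warp: WarpSpec) -> np.ndarray:
    """Warp a binary mask with the same field as the signal images.

    The mask is interpolated linearly as a {0,1} image and re-thresholded
    at 0.5, which keeps it binary and tracks the warped region boundary
    to sub-pixel accuracy.
    """
    m = np.asarray(mask, dtype=bool)
    return _warp_image(m.astype(float), warp, order=1) >= 0.5


def _echo_indices(n_lines: int, blur: BlurSpec) -> np.ndarray:
    """Echo number (0-based) at which each fftshifted k-space line is read.

    Lines are indexed ky = -n//2 .. n//2-1. With fewer echoes than lines
    the acquisition is segmented into ceil(n/etl) interleaved shots, so a
    line of acquisition rank q is read at echo q // n_segments.
    """
    ky = np.arange(n_lines) - n_lines // 2
    if blur.ordering == "centric":
        order = np.lexsort((ky < 0, np.abs(ky)))  # centre out, +ky first
    else:
        order = np.argsort(ky)
    rank = np.empty(n_lines, dtype=int)
    rank[order] = np.arange(n_lines)
    n_segments = int(np.ceil(n_lines / blur.etl))
    return rank // n_segments


def _line_weights(n_lines: int, blur: BlurSpec) -> np.ndarray:
    """T2 attenuation per fftshifted k-space line, symmetrized in ±ky.

    w(line) = exp(−echo·esp/T2). Lines at ±ky are averaged so the
    point-spread function is real and even; the paired lines differ by at
    most one echo in any ordering, so the symmetrization is a negligible
    model simplification that removes a spurious half-pixel phase ramp.
    """
    echo = _echo_indices(n_lines, blur)
    w = np.exp(-echo * blur.echo_spacing / blur.T2)
    ky = np.arange(n_lines) - n_lines // 2
    sym = w.copy()
    for k in range(1, n_lines // 2):
        i, j = n_lines // 2 + k, n_lines // 2 - k
        sym[i] = sym[j] = 0.5 * (w[i] + w[j])
    return sym


def etl_psf(n_lines: int, blur: BlurSpec) -> np.ndarray:
    """Point-spread function of the echo-train weighting, centred at
    n_lines//2. Its sum (DC gain) is the weight of the k-space centre
    line: 1 for centric ordering, < 1 for linear."""
    w = _line_weights(n_lines, blur)
    psf = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(w)))
    return np.real(psf)


def apply_etl_blur(
    obj: DWISeries | np.ndarray, blur: BlurSpec, phase_axis: int = 0
) -> DWISeries | np.ndarray:
    """Filter image(s) along the phase-encode axis with the echo-train PSF.

    Implemented as multiplication of the image's 1D spectrum by the
    k-space line weights w(n) = exp(−n·echo_spacing/T2) under the given
    ordering. Total intensity is conserved up to the PSF's DC gain
    (exactly conserved for centric ordering, attenuated for linear).
    """
    def _blur2d(img: np.ndarray) -> np.ndarray:
        n = img.shape[phase_axis]
        w = np.fft.ifftshift(_line_weights(n, blur))
        spec = np.fft.fft(img, axis=phase_axis)
        shape = [1, 1]
        shape[phase_axis] = n
        return np.real(np.fft.ifft(spec * w.reshape(shape), axis=phase_axis))

    if isinstance(obj, DWISeries):
        out = np.empty_like(obj.data)
        for ib in range(obj.data.shape[0]):
            for idir in range(obj.data.shape[1]):
                out[ib, idir] = _blur2d(obj.data[ib, idir])
        return obj.copy_with(np.maximum(out, 0.0), blurred=True)
    return _blur2d(np.asarray(obj, dtype=float))
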