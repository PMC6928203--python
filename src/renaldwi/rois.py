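"""Layer-wise ROI placement and diffusion statistics for the kidney.

The kidney parenchyma is analysed through small circular ROIs placed on
the three concentric layers: 5 in the cortex (COR), 5 in the outer
medulla (OM) and 3 in the inner medulla (IM). Placement is deterministic
and morphology-driven: COR and OM ROIs sit on the layer's medial band at
evenly spaced angular positions around the kidney centroid; IM ROIs sit
at evenly spaced stations along the inner medulla's principal axis. This
is a simplified, reproducible stand-in for semi-automated morphological
ROI placement; externally supplied ROI masks can be used instead through
:class:`LayerROISet`.

Layer statistics follow the ROI-mean convention: each ROI contributes its
mean D, the layer mean is the mean of its ROI means, and the layer
variability (SD/mean, a coefficient of variation) and variance (SD²) are
computed over the ROI means with the sample (n−1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .diffusion import DiffusionMap

__all__ = ["ROI", "LayerROISet", "LayerStats", "place_layer_rois", "layer_stats",
           "DEFAULT_ROI_COUNTS"]

DEFAULT_ROI_COUNTS = {"COR": 5, "OM": 5, "IM": 3}
LAYERS = ("COR", "OM", "IM")


@dataclass(frozen=True)
class ROI:
    layer: str
    mask: np.ndarray
    center: tuple[int, int]
    radius: int


@dataclass
class LayerROISet:
    """The 13 layer ROIs (5 COR, 5 OM, 3 IM by default), non-overlapping,
    each fully inside its layer mask."""

    rois: list[ROI]

    def by_layer(self, layer: str) -> list[ROI]:
        return [r for r in self.rois if r.layer == layer]

    def validate(self, layer_masks=None, counts=DEFAULT_ROI_COUNTS) -> None:
        for lay, n in counts.items():
            got = len(self.by_layer(lay))
            if got != n:
                raise ValueError(f"expected {n} ROIs in {lay}, got {got}")
        union = None
        for r in self.rois:
            if layer_masks is not None and (r.mask & ~layer_masks[r.layer]).any():
                raise ValueError(f"a {r.layer} ROI leaves its layer mask")
            if union is not None and (r.mask & union).any():
                raise ValueError("ROIs overlap")
            union = r.mask.copy() if union is None else (union | r.mask)


@dataclass
class LayerStats:
    """Per-layer D statistics over ROI means (units 10⁻³ mm²/s)."""

    layer: str
    roi_means: list[float]
    mean: float
    median: float
    min: float
    max: float
    variability: float   # SD/mean over ROI means (coefficient of variation)
    variance: float      # SD² over ROI means
    n_rois_excluded: int = 0


def _disk_offsets(radius: int) -> np.ndarray:
    rr, cc = np.indices((2 * radius + 1, 2 * radius + 1))
    d2 = (rr - radius) ** 2 + (cc - radius) ** 2
    return np.argwhere(d2 <= radius * radius) - radius


def _roi_mask(shape, center, radius) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    pts = _disk_offsets(radius) + np.asarray(center)
    m[pts[:, 0], pts[:, 1]] = True
    return m


def _fit_centers(layer_mask: np.ndarray, radius: int) -> tuple[np.ndarray, int]:
    """Pixels where a radius-r disk fits inside the layer; auto-reduce r."""
    r = radius
    while r >= 1:
        ok = ndimage.binary_erosion(
            layer_mask, structure=_roi_mask((2 * r + 1, 2 * r + 1), (r, r), r),
            border_value=0,
        )
        if ok.any():
            if r < radius:
                warnings.warn(
                    f"ROI radius reduced from {radius} to {r} px to fit the layer"
                )
            return ok, r
        r -= 1
    raise ValueError("layer too thin to place any ROI")


def _angular_centers(
    layer_mask: np.ndarray, n: int, radius: int, centroid, dist
) -> list[tuple[tuple[int, int], int]]:
    """Evenly spaced angular stations on the layer's medial band."""
    ok, r = _fit_centers(layer_mask, radius)
    cy, cx = centroid
    cand = np.argwhere(ok)
    ang = np.arctan2(cand[:, 0] - cy, cand[:, 1] - cx)
    depth = dist[cand[:, 0], cand[:, 1]]
    # angular stations avoid the medial notch (at angle π) by starting at 0
    stations = np.linspace(0, 2 * np.pi, n, endpoint=False) - np.pi / 2
    out = []
    for theta in stations:
        delta = np.angle(np.exp(1j * (ang - theta)))
        # closest-in-angle pixels, deepest in the layer; lexicographic tie-break
        score = np.abs(delta) * 1000.0 - depth
        order = np.lexsort((cand[:, 1], cand[:, 0], score))
        out.append(((int(cand[order[0], 0]), int(cand[order[0], 1])), r))
    return out


def _axis_centers(
    layer_mask: np.ndarray, n: int, radius: int
) -> list[tuple[tuple[int, int], int]]:
    """Evenly spaced stations along the region's principal axis."""
    ok, r = _fit_centers(layer_mask, radius)
    cand = np.argwhere(ok).astype(float)
    mean = cand.mean(axis=0)
    cov = np.cov((cand - mean).T)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    axis = evecs[:, np.argmax(evals)]
    proj = (cand - mean) @ axis
    lo, hi = proj.min(), proj.max()
    stations = lo + (hi - lo) * (np.arange(n) + 0.5) / n
    out = []
    for s in stations:
        score = np.abs(proj - s)
        order = np.lexsort((cand[:, 1], cand[:, 0], score))
        c = cand[order[0]]
        out.append(((int(c[0]), int(c[1])), r))
    return out


def place_layer_rois(
    layer_masks: dict[str, np.ndarray],
    roi_radius: int = 3,
    counts: dict[str, int] | None = None,
) -> LayerROISet:
    """Place the default 5/5/3 circular ROIs on the COR/OM/IM layer masks.

    Deterministic for fixed inputs. The radius is reduced per layer (with
    a warning) if a layer is too thin; overlapping placements raise.
    """
    counts = dict(counts or DEFAULT_ROI_COUNTS)
    for lay in LAYERS:
        if lay not in layer_masks or not np.asarray(layer_masks[lay]).any():
            raise ValueError(f"missing or empty layer mask {lay!r}")
    kidney = layer_masks.get("kidney")
    if kidney is None:
        kidney = layer_masks["COR"] | layer_masks["OM"] | layer_masks["IM"]
    centroid = np.argwhere(kidney).mean(axis=0)
    dist = ndimage.distance_transform_edt(kidney)
    shape = np.asarray(layer_masks["COR"]).shape

    last_err: Exception | None = None
    for radius in range(int(roi_radius), 0, -1):
        rois: list[ROI] = []
        for lay in ("COR", "OM"):
            for center, r in _angular_centers(
                np.asarray(layer_masks[lay], bool), counts[lay], radius,
                centroid, dist,
            ):
                rois.append(ROI(lay, _roi_mask(shape, center, r), center, r))
        for center, r in _axis_centers(
            np.asarray(layer_masks["IM"], bool), counts["IM"], radius
        ):
            rois.append(ROI("IM", _roi_mask(shape, center, r), center, r))
        roi_set = LayerROISet(rois)
        try:
            roi_set.validate(layer_masks, counts)
        except ValueError as err:  # overlap at this radius: shrink and retry
            last_err = err
            continue
        if radius < roi_radius:
            warnings.warn(
                f"ROI radius reduced from {roi_radius} to {radius} px to "
                "avoid overlapping placements"
            )
        return roi_set
    raise ValueError(f"impossible ROI placement: {last_err}")


def layer_stats(
    dmap: DiffusionMap, rois: LayerROISet, min_valid_frac: float = 0.8
) -> dict[str, LayerStats]:
    """Per-layer D statistics from per-ROI means over valid pixels.

    ROIs with no valid pixels are excluded (warned and counted); ROIs
    with < ``min_valid_frac`` valid coverage trigger a warning but are
    kept. SD is the sample standard deviation over ROI means.
    """
    out: dict[str, LayerStats] = {}
    for lay in LAYERS:
        means, excluded = [], 0
        for i, roi in enumerate(rois.by_layer(lay)):
            sel = roi.mask & dmap.valid
            n_sel, n_roi = int(sel.sum()), int(roi.mask.sum())
            if n_sel == 0:
                warnings.warn(f"{lay} ROI {i} has no valid pixels; excluded")
                excluded += 1
                continue
            if n_sel < min_valid_frac * n_roi:
                warnings.warn(
                    f"{lay} ROI {i}: only {n_sel}/{n_roi} pixels valid"
                )
            means.append(float(dmap.D[sel].mean()))
        if not means:
            raise ValueError(f"no usable ROI in layer {lay}")
        arr = np.asarray(means)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out[lay] = LayerStats(
            layer=lay,
            roi_means=means,
            mean=mean,
            median=float(np.median(arr)),
            min=float(arr.min()),
            max=float(arr.max()),
            variability=sd / mean if mean != 0 else np.inf,
            variance=sd * sd,
            n_rois_excluded=excluded,
        )
    return out
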