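"""Digital phantoms with known diffusion ground truth.

Two phantom families are provided:

* a three-tube liquid phantom (oil / water / acetone tubes in an agarose
  cylinder), used to validate the mono-exponential ADC fitting path;
* a layered kidney phantom (cortex / outer medulla / inner medulla as
  nested bands of a bean-shaped parenchyma), used to exercise the IVIM
  fitting, ROI placement and cohort-comparison paths.

Both are rendered through the same forward model :func:`ivim_signal` and
carry their per-pixel ground-truth parameter maps and region masks, so
every downstream stage can be tested against a known answer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .series import DWISeries, IVIMParams, ParameterDomainError, ProtocolConfig

__all__ = [
    "ivim_signal",
    "DigitalPhantomSpec",
    "RegionSpec",
    "generate_phantom",
    "generate_tube_phantom",
    "generate_kidney_phantom",
    "kidney_layer_masks",
    "add_rician_noise",
    "LITERATURE_D",
    "INVIVO_LAYER_D",
]

# Literature self-diffusion coefficients at room temperature, 10⁻³ mm²/s:
# vegetable oil, water and acetone — the three tube fillings.
LITERATURE_D = {"oil": 0.010, "water": 2.13, "acetone": 4.21}

# Healthy rat kidney per-layer slow diffusion coefficients, 10⁻³ mm²/s
# (in-vivo medians; used as ground-truth inputs for the kidney phantom).
INVIVO_LAYER_D = {"COR": 1.61, "OM": 1.78, "IM": 1.88}


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Bi-exponential IVIM signal S(b) = S0·(f·e^(−b·Dp) + (1−f)·e^(−b·D)).

    Parameters
    ----------
    params : IVIMParams
        Compartment parameters; D and Dp in 10⁻³ mm²/s.
    b : float or array-like
        Diffusion weighting(s), s/mm², >= 0.

    Returns
    -------
    Signal intensity with the shape of ``b``.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0) or not np.all(np.isfinite(b_arr)):
        raise ParameterDomainError("b-values must be finite and >= 0")
    # single point of unit conversion: 10⁻³ mm²/s -> mm²/s
    d = params.D * 1e-3
    dp = params.Dp * 1e-3
    s = params.S0 * (
        params.f * np.exp(-b_arr * dp) + (1.0 - params.f) * np.exp(-b_arr * d)
    )
    return s if b_arr.ndim else float(s)


@dataclass(frozen=True)
class RegionSpec:
    """A labelled phantom region: a geometric primitive plus its IVIM params.

    ``geometry`` is either ``("disk", (row, col), radius_px)`` or
    ``("mask", boolean_array)``.
    """

    label: str
    geometry: tuple
    params: IVIMParams

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        kind = self.geometry[0]
        if kind == "disk":
            (cy, cx), r = self.geometry[1], self.geometry[2]
            rr, cc = np.indices(shape)
            return (rr - cy) ** 2 + (cc - cx) ** 2 <= r * r
        if kind == "mask":
            m = np.asarray(self.geometry[1], dtype=bool)
            if m.shape != shape:
                raise ValueError(
                    f"region '{self.label}' mask shape {m.shape} != image {shape}"
                )
            return m
        raise ValueError(f"unknown geometry kind {kind!r}")


@dataclass
class DigitalPhantomSpec:
    """Full description of a synthetic phantom: regions, background, noise."""

    regions: Sequence[RegionSpec] = ()
    background: IVIMParams = field(default_factory=lambda: IVIMParams(S0=0.0, D=0.0))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError(f"region labels must be unique, got {labels}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _paint(
    shape: tuple[int, int],
    regions: Sequence[RegionSpec],
    background: IVIMParams,
    allow_overlap: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Rasterize regions onto parameter maps; return (param maps, masks)."""
    maps = {
        "S0": np.full(shape, background.S0),
        "D": np.full(shape, background.D),
        "Dp": np.full(shape, background.Dp),
        "f": np.full(shape, background.f),
    }
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(shape, dtype=bool)
    for reg in regions:
        m = reg.rasterize(shape)
        if not allow_overlap and (m & claimed).any():
            clash = [lab for lab, prev in masks.items() if (prev & m).any()]
            raise ValueError(
                f"region '{reg.label}' overlaps previously placed region(s) {clash}"
            )
        claimed |= m
        masks[reg.label] = m
        for key, val in (("S0", reg.params.S0), ("D", reg.params.D),
                         ("Dp", reg.params.Dp), ("f", reg.params.f)):
            maps[key][m] = val
    return maps, masks


def generate_phantom(
    spec: DigitalPhantomSpec,
    protocol: ProtocolConfig,
    allow_overlap: bool = False,
) -> DWISeries:
    """Forward-model a noiseless DW series from a phantom description.

    Every pixel decays according to its ground-truth IVIM parameters,
    identically in all diffusion directions (isotropic phantom). Noise is
    *not* added here — see :func:`add_rician_noise` — so the returned
    series matches the forward model exactly.
    """
    shape = protocol.image_shape
    maps, masks = _paint(shape, spec.regions, spec.background, allow_overlap)
    b = np.asarray(protocol.b_values)[:, None, None]
    d = maps["D"] * 1e-3
    dp = maps["Dp"] * 1e-3
    f = maps["f"]
    decay = f * np.exp(-b * dp) + (1.0 - f) * np.exp(-b * d)  # (n_b, H, W)
    signal = maps["S0"] * decay
    data = np.repeat(signal[:, None], protocol.n_directions, axis=1)
    return DWISeries(
        data=data,
        protocol=protocol,
        ground_truth=maps,
        masks=masks,
        meta={"phantom_seed": spec.seed},
    )


def generate_tube_phantom(
    protocol: ProtocolConfig | None = None,
    tube_d: Mapping[str, float] | None = None,
    s0: float = 1000.0,
    background_d: float = 2.0,
    tube_radius_frac: float = 0.13,
) -> DWISeries:
    """Three-tube liquid phantom: oil, water and acetone in agarose.

    Tube D defaults to the literature coefficients (``LITERATURE_D``).
    The agarose background diffuses water-like (configurable) with a
    lower baseline signal. Three tubes sit at 120° spacing inside the
    agarose cylinder; geometry scales with the image.
    """
    protocol = protocol or ProtocolConfig(n_directions=1)
    tube_d = dict(tube_d or LITERATURE_D)
    h, w = protocol.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    big_r = 0.45 * min(h, w)
    tube_r = max(2, int(round(tube_radius_frac * min(h, w))))
    ring_r = 0.52 * big_r
    regions = []
    for k, (label, d) in enumerate(tube_d.items()):
        ang = -np.pi / 2 + 2 * np.pi * k / len(tube_d)
        center = (int(round(cy + ring_r * np.sin(ang))),
                  int(round(cx + ring_r * np.cos(ang))))
        regions.append(
            RegionSpec(label, ("disk", center, tube_r), IVIMParams(S0=s0, D=d))
        )
    # agarose cylinder painted first, tubes on top (overlap is intentional)
    rr, cc = np.indices((h, w))
    agarose = (rr - cy) ** 2 + (cc - cx) ** 2 <= big_r**2
    cylinder = RegionSpec(
        "agarose", ("mask", agarose), IVIMParams(S0=0.6 * s0, D=background_d)
    )
    spec = DigitalPhantomSpec(
        regions=[cylinder, *regions], background=IVIMParams(S0=0.0, D=0.0)
    )
    series = generate_phantom(spec, protocol, allow_overlap=True)
    for label in tube_d:  # agarose mask minus the tubes, for ROI statistics
        series.masks["agarose"] &= ~series.masks[label]
    return series


def _bean_mask(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    semi_axes: tuple[float, float] | None = None,
    notch_frac: float = 0.45,
) -> np.ndarray:
    """Bean-shaped (kidney-like) mask: an ellipse minus a medial notch."""
    h, w = shape
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    ry, rx = semi_axes if semi_axes is not None else (0.40 * h, 0.26 * w)
    rr, cc = np.indices(shape)
    ellipse = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    # medial notch: circle centred on the hilum (left edge of the ellipse)
    nr = notch_frac * rx
    notch = (rr - cy) ** 2 + (cc - (cx - rx)) ** 2 <= nr**2
    return ellipse & ~notch


def kidney_layer_masks(
    shape: tuple[int, int] = (96, 96),
    center: tuple[float, float] | None = None,
    semi_axes: tuple[float, float] | None = None,
    area_fractions: tuple[float, float, float] = (0.40, 0.35, 0.25),
) -> dict[str, np.ndarray]:
    """Nested COR / OM / IM layer masks of a bean-shaped kidney.

    Layers are concentric bands of the parenchyma delimited by quantiles
    of the Euclidean distance to the kidney border, so IM ⊂ (OM ∪ IM) ⊂
    kidney holds by construction and the bands have the requested area
    fractions (cortex outermost).
    """
    if abs(sum(area_fractions) - 1.0) > 1e-9:
        raise ValueError("area_fractions must sum to 1")
    kidney = _bean_mask(shape, center=center, semi_axes=semi_axes)
    dist = ndimage.distance_transform_edt(kidney)
    inner = dist[kidney]
    f_cor, f_om, _ = area_fractions
    t1 = np.quantile(inner, f_cor)          # cortex band: dist <= t1
    t2 = np.quantile(inner, f_cor + f_om)   # medulla bands split at t2
    cor = kidney & (dist <= t1)
    om = kidney & (dist > t1) & (dist <= t2)
    im = kidney & (dist > t2)
    if not (cor.any() and om.any() and im.any()):
        raise ValueError("kidney too small for three layers at this resolution")
    return {"kidney": kidney, "COR": cor, "OM": om, "IM": im}


def _check_nested(masks: Mapping[str, np.ndarray]) -> None:
    cor, om, im = masks["COR"], masks["OM"], masks["IM"]
    if (cor & om).any() or (cor & im).any() or (om & im).any():
        raise ValueError("COR/OM/IM layer masks must be disjoint")
    interior = masks["kidney"] & ~cor
    # OM ∪ IM must fill the interior left by the cortex, and IM must be
    # enclosed by OM (no IM pixel touches the cortex or the outside).
    if not np.array_equal(om | im, interior):
        raise ValueError("layers do not tile the kidney: OM ∪ IM ≠ kidney ∖ COR")
    im_dilated = ndimage.binary_dilation(im)
    if (im_dilated & ~(im | om)).any():
        raise ValueError("layers are not nested: IM touches pixels outside OM")


def generate_kidney_phantom(
    layer_params: Mapping[str, IVIMParams] | None = None,
    protocol: ProtocolConfig | None = None,
    layer_masks: Mapping[str, np.ndarray] | None = None,
    background: IVIMParams | None = None,
    **mask_kwargs,
) -> DWISeries:
    """Layered kidney phantom with per-layer IVIM ground truth.

    ``layer_params`` maps ``COR``/``OM``/``IM`` to :class:`IVIMParams`;
    the default uses the healthy in-vivo per-layer medians
    (``INVIVO_LAYER_D``) with cortex-dominant perfusion. Custom
    ``layer_masks`` (keys ``kidney``, ``COR``, ``OM``, ``IM``) are
    validated for nesting.
    """
    protocol = protocol or ProtocolConfig()
    if layer_params is None:
        # perfusion fraction decreases cortex -> inner medulla; Dp well
        # above D so the b >= 200 s/mm² regime isolates slow diffusion
        layer_params = {
            "COR": IVIMParams(S0=1000.0, D=INVIVO_LAYER_D["COR"], Dp=30.0, f=0.20),
            "OM": IVIMParams(S0=1000.0, D=INVIVO_LAYER_D["OM"], Dp=30.0, f=0.15),
            "IM": IVIMParams(S0=1000.0, D=INVIVO_LAYER_D["IM"], Dp=30.0, f=0.10),
        }
    missing = {"COR", "OM", "IM"} - set(layer_params)
    if missing:
        raise ValueError(f"layer_params missing layers {sorted(missing)}")
    masks = dict(
        layer_masks
        if layer_masks is not None
        else kidney_layer_masks(protocol.image_shape, **mask_kwargs)
    )
    _check_nested(masks)
    regions = [
        RegionSpec(layer, ("mask", masks[layer]), layer_params[layer])
        for layer in ("COR", "OM", "IM")
    ]
    spec = DigitalPhantomSpec(
        regions=regions,
        background=background or IVIMParams(S0=80.0, D=0.3),
    )
    series = generate_phantom(spec, protocol)
    series.masks["kidney"] = masks["kidney"]
    return series


def add_rician_noise(
    series: DWISeries, sigma: float, seed: int | np.random.Generator = 0
) -> DWISeries:
    """Corrupt magnitude signals with Rician noise of scale ``sigma``.

    Each pixel S becomes sqrt((S + g1·σ)² + (g2·σ)²) with independent
    standard-normal g1, g2 — the magnitude of complex Gaussian noise
    around the true signal. Deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return series.copy_with(series.data.copy(), noise_sigma=0.0)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    g1 = rng.standard_normal(series.data.shape)
    g2 = rng.standard_normal(series.data.shape)
    noisy = np.hypot(series.data + sigma * g1, sigma * g2)
    return series.copy_with(noisy, noise_sigma=float(sigma))


def gaussian_noise_option(
    series: DWISeries, sigma: float, seed: int | np.random.Generator = 0
) -> DWISeries:
    """Additive Gaussian alternative to the Rician model, for analytic tests.

    Negative excursions are clipped at zero to preserve the magnitude
    contract of :class:`DWISeries`; choose sigma ≪ signal when the
    Gaussian limit matters.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    noisy = series.data + sigma * rng.standard_normal(series.data.shape)
    n_clip = int((noisy < 0).sum())
    if n_clip:
        warnings.warn(f"Gaussian noise clipped at zero for {n_clip} pixels")
    return series.copy_with(np.maximum(noisy, 0.0), noise_sigma=float(sigma))
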