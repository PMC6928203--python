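"""Core containers for diffusion-weighted image series.

Unit conventions used throughout the package:

* b-values are in s/mm².
* Diffusion coefficients (``D``, ``Dp``) are stored and reported in the
  conventional unit 10⁻³ mm²/s; the single ×10⁻³ conversion to mm²/s
  happens inside the signal model / fitting routines.
* Signal intensities are in arbitrary units, non-negative.
* Images are 2D, indexed (row, col), 0-based, pixel-centre aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["IVIMParams", "ProtocolConfig", "DWISeries", "ParameterDomainError"]


class ParameterDomainError(ValueError):
    """A physical parameter is outside its admissible domain."""


@dataclass(frozen=True)
class IVIMParams:
    """Intravoxel-incoherent-motion parameters of one compartment mixture.

    Attributes
    ----------
    S0 : float
        Signal intensity at b = 0, arbitrary units, >= 0.
    D : float
        Slow (tissue water) diffusion coefficient, 10⁻³ mm²/s, >= 0.
    Dp : float
        Pseudo-diffusion coefficient of the flowing compartment,
        10⁻³ mm²/s; must satisfy Dp >= D (pseudo-diffusion is faster).
    f : float
        Flow (perfusion) fraction, dimensionless, in [0, 1].
    """

    S0: float
    D: float
    Dp: float = 0.0
    f: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.S0, self.D, self.Dp, self.f]).all():
            raise ParameterDomainError("IVIM parameters must be finite")
        if self.S0 < 0:
            raise ParameterDomainError(f"S0 must be >= 0, got {self.S0}")
        if self.D < 0:
            raise ParameterDomainError(f"D must be >= 0, got {self.D}")
        if self.f < 0 or self.f > 1:
            raise ParameterDomainError(f"f must lie in [0, 1], got {self.f}")
        if self.f > 0 and self.Dp < self.D:
            raise ParameterDomainError(
                f"Dp ({self.Dp}) must be >= D ({self.D}): pseudo-diffusion "
                "is faster than tissue diffusion"
            )


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition protocol of a DW series.

    The default mirrors a 5 b-value, 3-direction single-slice protocol
    (b = 0, 200, 300, 500, 700 s/mm²) on a 96×96 grid with 0.47 mm pixels.
    """

    b_values: tuple[float, ...] = (0.0, 200.0, 300.0, 500.0, 700.0)
    n_directions: int = 3
    image_shape: tuple[int, int] = (96, 96)
    pixel_size: tuple[float, float] = (0.47, 0.47)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.size < 1 or b[0] != 0.0:
            raise ValueError("b_values must start at 0")
        if not np.all(np.diff(b) > 0):
            raise ValueError("b_values must be strictly increasing")
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape must be positive")

    @property
    def n_acquisitions(self) -> int:
        """Total number of acquired images (b-values × directions)."""
        return len(self.b_values) * self.n_directions


@dataclass
class DWISeries:
    """A stack of 2D DW images indexed (b_index, direction_index, row, col).

    ``ground_truth`` optionally carries per-pixel IVIM parameter maps
    (keys ``S0``, ``D``, ``Dp``, ``f``; D/Dp in 10⁻³ mm²/s) for synthetic
    data; ``masks`` carries named binary region/layer masks.
    """

    data: np.ndarray
    protocol: ProtocolConfig
    ground_truth: Mapping[str, np.ndarray] | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (
            len(self.protocol.b_values),
            self.protocol.n_directions,
            *self.protocol.image_shape,
        )
        if self.data.shape != expected:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with protocol "
                f"(expected {expected})"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("signals must be finite")
        if (self.data < 0).any():
            raise ValueError("signals must be non-negative")

    @property
    def n_acquisitions(self) -> int:
        return self.protocol.n_acquisitions

    def copy_with(self, data: np.ndarray, **meta) -> "DWISeries":
        """Return a copy with new pixel data and updated metadata."""
        return DWISeries(
            data=data,
            protocol=self.protocol,
            ground_truth=self.ground_truth,
            masks=dict(self.masks),
            meta={**self.meta, **meta},
        )
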