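"""Reading and writing of series, maps, masks and sidecar metadata.

4D DW series are stored as NIfTI-1 with on-disk axis order
(x, y, direction, b) — i.e. ``data[b, dir, row, col]`` maps to
``nifti[x=col, y=row, z=direction, t=b]`` — with the layout and the
b-values recorded in the header description and a JSON sidecar. Binary
masks go to 8-bit PNG (0/255) or NIfTI; diffusion and distortion maps to
NIfTI float32/int8.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .series import DWISeries, ProtocolConfig

__all__ = [
    "write_series", "read_series", "write_map", "read_map",
    "write_mask", "read_mask", "write_distortion_map",
]

_DESCRIP = "axes=(x,y,dir,b)"


def _affine(protocol: ProtocolConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = protocol.pixel_size[1], protocol.pixel_size[0]
    return aff


def write_series(series: DWISeries, path, sidecar: bool = True) -> Path:
    """Write a DW series as 4D NIfTI plus a JSON protocol sidecar."""
    path = Path(path)
    # (b, dir, row, col) -> (col, row, dir, b) = (x, y, z, t)
    vol = np.transpose(series.data, (3, 2, 1, 0)).astype(np.float32)
    img = nib.Nifti1Image(vol, _affine(series.protocol))
    img.header["descrip"] = _DESCRIP.encode()
    nib.save(img, path)
    if sidecar:
        meta = {
            "b_values": list(series.protocol.b_values),
            "n_directions": series.protocol.n_directions,
            "image_shape": list(series.protocol.image_shape),
            "pixel_size": list(series.protocol.pixel_size),
            "axis_order": "(x,y,dir,b)",
            "meta": {k: v for k, v in series.meta.items()
                     if isinstance(v, (str, int, float, bool))},
        }
        sidecar_path = path.with_suffix("").with_suffix(".json") \
            if path.suffix == ".gz" else path.with_suffix(".json")
        sidecar_path.write_text(json.dumps(meta, indent=1))
    return path


def read_series(path, protocol: ProtocolConfig | None = None) -> DWISeries:
    """Read a 4D NIfTI series written by :func:`write_series` (or any
    NIfTI with axes (x, y, dir, b)); the protocol comes from the JSON
    sidecar unless given explicitly."""
    path = Path(path)
    img = nib.load(path)
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 3:
        vol = vol[..., None]
    data = np.transpose(vol, (3, 2, 1, 0))
    if protocol is None:
        sidecar = path.with_suffix("").with_suffix(".json") \
            if path.suffix == ".gz" else path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no protocol sidecar {sidecar}; pass protocol= explicitly"
            )
        meta = json.loads(sidecar.read_text())
        protocol = ProtocolConfig(
            b_values=tuple(meta["b_values"]),
            n_directions=int(meta["n_directions"]),
            image_shape=tuple(meta["image_shape"]),
            pixel_size=tuple(meta["pixel_size"]),
        )
    return DWISeries(data=data, protocol=protocol)


def write_map(arr: np.ndarray, path, pixel_size=(1.0, 1.0),
              unit: str = "1e-3 mm^2/s") -> Path:
    """Write a 2D parameter map as float32 NIfTI with the unit recorded
    in the header description."""
    path = Path(path)
    vol = np.asarray(arr, dtype=np.float32).T[..., None]
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = pixel_size[1], pixel_size[0]
    img = nib.Nifti1Image(vol, aff)
    img.header["descrip"] = f"unit={unit}"[:79].encode()
    nib.save(img, path)
    return path


def read_map(path) -> np.ndarray:
    vol = np.asarray(nib.load(path).dataobj, dtype=float)
    return np.squeeze(vol).T


def write_mask(mask: np.ndarray, path) -> Path:
    """Write a binary mask: PNG (0/255 8-bit) if the suffix is .png,
    NIfTI uint8 otherwise."""
    path = Path(path)
    m = np.asarray(mask, dtype=bool)
    if path.suffix.lower() == ".png":
        iio.imwrite(path, (m * np.uint8(255)))
    else:
        img = nib.Nifti1Image(m.astype(np.uint8).T[..., None], np.eye(4))
        nib.save(img, path)
    return path


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".png", ".tif", ".tiff"):
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        return arr > (arr.max() / 2 if arr.max() > 1 else 0)
    return np.squeeze(np.asarray(nib.load(path).dataobj)).T > 0


def write_distortion_map(dmap: np.ndarray, path) -> Path:
    """Write a signed {−1,0,+1} distortion map: int8 NIfTI, or a rendered
    PNG (blue = false positive, white = agreement, red = false negative)
    if the suffix is .png."""
    path = Path(path)
    m = np.asarray(dmap, dtype=np.int8)
    if path.suffix.lower() == ".png":
        rgb = np.full((*m.shape, 3), 255, dtype=np.uint8)
        rgb[m == 1] = (220, 50, 50)
        rgb[m == -1] = (50, 80, 220)
        iio.imwrite(path, rgb)
    else:
        img = nib.Nifti1Image(m.T[..., None], np.eye(4))
        nib.save(img, path)
    return path
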