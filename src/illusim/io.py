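"""Reading and writing images, masks and model outputs.

Stimuli and brightness maps travel as 16-bit grayscale PNG (affine map
[-0.5, 0.5] -> [0, 65535]) or raw float NPY; region masks as run-length JSON
sidecars; Gabor banks as NPZ archives with JSON metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .encoding import GaborBank, GaborKernel
from .stimuli import LuminanceImage

__all__ = [
    "write_image_png",
    "read_image",
    "write_image_npy",
    "write_masks_json",
    "read_masks_json",
    "save_bank",
    "load_bank",
]

_RANGE = (-0.5, 0.5)


def write_image_png(path, img: LuminanceImage | np.ndarray) -> None:
    """16-bit grayscale PNG; luminance mapped affinely from [-0.5, 0.5]."""
    pixels = img.pixels if isinstance(img, LuminanceImage) else np.asarray(img)
    scaled = np.clip((pixels - _RANGE[0]) / (_RANGE[1] - _RANGE[0]), 0, 1)
    iio.imwrite(Path(path), (scaled * 65535).round().astype(np.uint16))


def write_image_npy(path, img: LuminanceImage | np.ndarray) -> None:
    pixels = img.pixels if isinstance(img, LuminanceImage) else np.asarray(img)
    np.save(Path(path), pixels.astype(float))


def read_image(path) -> LuminanceImage:
    """Load a PNG/TIFF (8/16-bit, mapped affinely into [-0.5, 0.5]) or float NPY.

    RGB inputs are converted with luminance weights (0.299, 0.587, 0.114).
    """
    path = Path(path)
    if path.suffix.lower() == ".npy":
        pixels = np.load(path).astype(float)
        lo, hi = pixels.min(), pixels.max()
        if lo < -0.5 or hi > 0.5:
            rng = hi - lo
            pixels = (pixels - lo) / rng - 0.5 if rng > 0 else np.zeros_like(pixels)
        return LuminanceImage(pixels=pixels)
    raw = iio.imread(path)
    if raw.ndim == 3:
        import warnings

        warnings.warn(f"{path.name}: RGB input converted to luminance")
        raw = raw[..., :3] @ np.array([0.299, 0.587, 0.114])
    raw = raw.astype(float)
    peak = 65535.0 if raw.max() > 255 else 255.0
    return LuminanceImage(pixels=raw / peak - 0.5)


def write_masks_json(path, img: LuminanceImage) -> None:
    """Region masks as row-wise run-length encoding."""
    payload = {}
    for name, mask in img.regions.items():
        runs = []
        for y, row in enumerate(mask):
            xs = np.flatnonzero(np.diff(np.concatenate(([0], row.view(np.uint8), [0]))))
            for start, stop in zip(xs[::2], xs[1::2]):
                runs.append([int(y), int(start), int(stop)])
        payload[name] = {"shape": list(mask.shape), "runs": runs}
    Path(path).write_text(json.dumps(payload))


def read_masks_json(path) -> dict[str, np.ndarray]:
    payload = json.loads(Path(path).read_text())
    masks = {}
    for name, spec in payload.items():
        mask = np.zeros(tuple(spec["shape"]), dtype=bool)
        for y, start, stop in spec["runs"]:
            mask[y, start:stop] = True
        masks[name] = mask
    return masks


def save_bank(path, bank: GaborBank) -> None:
    """NPZ archive of kernel grids plus JSON metadata."""
    arrays = {f"kernel_{i}": k.weights for i, k in enumerate(bank.kernels)}
    meta = {
        "channel": bank.channel,
        "spatial_frequency": bank.spatial_frequency,
        "kernels": [
            {"orientation": k.orientation, "spatial_frequency": k.spatial_frequency, "phase": k.phase}
            for k in bank.kernels
        ],
    }
    np.savez(Path(path), _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_bank(path) -> GaborBank:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        kernels = [
            GaborKernel(
                weights=data[f"kernel_{i}"],
                orientation=km["orientation"],
                spatial_frequency=km["spatial_frequency"],
                phase=km["phase"],
                channel=meta["channel"],
            )
            for i, km in enumerate(meta["kernels"])
        ]
    return GaborBank(kernels=kernels, channel=meta["channel"], spatial_frequency=meta["spatial_frequency"])
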