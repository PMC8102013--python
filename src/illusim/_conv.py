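"""2-D convolution with mirror (symmetric) boundary handling and exact adjoints.

All model stages convolve with odd-sized kernels and keep the output on the
input grid.  The forward map is ``crop . conv . sym_pad``; its exact adjoint is
``fold . corr . zero_pad`` where ``fold`` re-accumulates the mirrored border
contributions.  Using the exact adjoint (rather than plain correlation with
mirror padding) keeps the composite normal-equations operator of the
filling-in stage symmetric positive definite, which conjugate gradients
requires.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["conv_same", "conv_same_adjoint", "sym_pad", "sym_pad_adjoint"]


def _half(kernel: np.ndarray) -> tuple[int, int]:
    kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"kernel must have odd sides, got {kernel.shape}")
    return kh // 2, kw // 2


def sym_pad(img: np.ndarray, pad: tuple[int, int]) -> np.ndarray:
    """Mirror-pad by ``pad`` pixels per side (numpy 'symmetric' convention)."""
    py, px = pad
    return np.pad(img, ((py, py), (px, px)), mode="symmetric")


def sym_pad_adjoint(arr: np.ndarray, pad: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    """Adjoint of :func:`sym_pad`: fold mirrored border rows/columns back in."""
    py, px = pad
    h, w = shape
    iy = np.pad(np.arange(h), py, mode="symmetric")
    ix = np.pad(np.arange(w), px, mode="symmetric")
    out = np.zeros((h, arr.shape[1]), dtype=arr.dtype)
    np.add.at(out, iy, arr)
    out2 = np.zeros((h, w), dtype=arr.dtype)
    np.add.at(out2.T, ix, out.T)
    return out2


def conv_same(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True convolution, same output size, mirror boundary."""
    pad = _half(kernel)
    return fftconvolve(sym_pad(img, pad), kernel, mode="valid")


def conv_same_adjoint(resp: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`conv_same` with respect to the image argument."""
    pad = _half(kernel)
    full = fftconvolve(resp, kernel[::-1, ::-1], mode="full")
    return sym_pad_adjoint(full, pad, resp.shape)
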