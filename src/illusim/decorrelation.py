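"""Stage 2: dynamic filtering (zero-phase whitening) and divisive gain control.

The heart of the model: an image-specific *dynamic filter* is learned from the
patch covariance of the local energy map by zero-phase whitening (ZCA).
Convolving the energy map with this filter equalizes its amplitude spectrum,
so spatially redundant edge patterns are attenuated while non-redundant ones
are enhanced.  The whitened map, passed through a sigmoid, yields a gain
control field G in [-1, 1] that boosts (G > 0) or suppresses (G < 0) the
simple-cell responses of both contrast channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._conv import conv_same
from .encoding import ChannelResponseSet, EnergyMap

__all__ = [
    "DynamicFilter",
    "WhitenedEnergyMap",
    "GainControlMap",
    "GainParams",
    "learn_dynamic_filter",
    "whiten_energy",
    "gain_control_map",
    "apply_gain_control",
    "spectral_flatness",
]


def spectral_flatness(arr: np.ndarray) -> float:
    """Flatness (geometric over arithmetic mean) of the radially averaged
    power spectrum, DC excluded.  1 for a white spectrum, -> 0 for a peaky one."""
    power = np.abs(np.fft.fft2(arr)) ** 2
    h, w = arr.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.sqrt(fy**2 + fx**2)
    n_bins = min(h, w) // 2
    bins = np.clip((r * 2 * n_bins).astype(int), 0, n_bins)
    radial = np.bincount(bins.ravel(), weights=power.ravel()) / np.bincount(bins.ravel())
    radial = radial[1:n_bins]  # drop DC and the corner bin
    radial = np.maximum(radial, 1e-300)
    return float(np.exp(np.mean(np.log(radial))) / np.mean(radial))


@dataclass
class GainParams:
    """Fixed gain-control parameters, shared across all displays.

    a: sigmoid slope. b_cap/b_mult: the sigmoid inflection is
    b = min(b_mult * mean(whitened energy over its support), b_cap).
    omega_frac: energy threshold as a fraction of max energy.
    tau: response bound of the divisive interaction.
    smooth_sd: Gaussian low-pass (pixels) applied after gain control.
    """

    a: float = 5.0
    b_cap: float = 0.3
    b_mult: float = 3.0
    omega_frac: float = 0.1
    tau: float = 0.5
    smooth_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b_cap", "b_mult", "omega_frac", "tau", "smooth_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"GainParams.{name} must be positive")

    def b_for(self, whitened: "WhitenedEnergyMap") -> float:
        """Sigmoid inflection for this map: b = min(b_mult * mean, b_cap), with the
        mean taken over the support of the whitened map on the same max-normalized
        scale the sigmoid sees."""
        support = whitened.values[whitened.values != 0]
        peak = float(np.abs(support).max()) if support.size else 0.0
        m = float(support.mean()) / peak if peak > 0 else 0.0
        return min(self.b_mult * m, self.b_cap)


@dataclass
class DynamicFilter:
    kernel: np.ndarray
    patch_size: int
    eigen_floor: float
    seed: int

    def __post_init__(self) -> None:
        rot = self.kernel[::-1, ::-1]
        scale = max(np.abs(self.kernel).max(), 1e-30)
        if np.abs(self.kernel - rot).max() > 1e-6 * scale:
            raise ValueError("dynamic filter kernel is not centro-symmetric (zero-phase violated)")


@dataclass
class WhitenedEnergyMap:
    values: np.ndarray
    threshold_used: float


@dataclass
class GainControlMap:
    values: np.ndarray
    slope: float
    inflection: float


def _sample_patches(E: np.ndarray, patch_size: int, n_patches: int, rng: np.random.Generator) -> np.ndarray:
    h, w = E.shape
    ys = rng.integers(0, h - patch_size + 1, n_patches)
    xs = rng.integers(0, w - patch_size + 1, n_patches)
    out = np.empty((n_patches, patch_size * patch_size))
    for i, (y, x) in enumerate(zip(ys, xs)):
        out[i] = E[y : y + patch_size, x : x + patch_size].ravel()
    return out


def learn_dynamic_filter(
    E: EnergyMap,
    patch_size: int = 31,
    n_patches: int = 5000,
    eigen_floor: float = 5e-2,
    seed: int = 0,
) -> DynamicFilter:
    """Learn the zero-phase whitening kernel from the energy map's patch covariance.

    Patches are sampled uniformly at random; the symmetric whitening matrix
    W = U (L + eps)^(-1/2) U' of their covariance is formed, and its center row
    — reshaped to the patch — is the spatial kernel.  The kernel is averaged
    with its own 180-degree rotation, which enforces the zero-phase
    (centro-symmetric) property exactly without altering its even part.
    """
    values = np.asarray(E.values if isinstance(E, EnergyMap) else E, dtype=float)
    if patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd, got {patch_size}")
    if values.shape[0] < patch_size or values.shape[1] < patch_size:
        raise ValueError("energy map smaller than the sampling patch")
    rng = np.random.default_rng(seed)
    X = _sample_patches(values, patch_size, n_patches, rng)
    X = X - X.mean(axis=0, keepdims=True)
    C = (X.T @ X) / max(n_patches - 1, 1)
    lam, U = np.linalg.eigh(C)
    lam_max = float(lam.max())
    if lam_max <= 0:
        warnings.warn("energy map has no spatial structure; dynamic filter is a delta kernel")
        kernel = np.zeros((patch_size, patch_size))
        kernel[patch_size // 2, patch_size // 2] = 1.0
        return DynamicFilter(kernel=kernel, patch_size=patch_size, eigen_floor=eigen_floor, seed=seed)
    eps = eigen_floor * lam_max
    inv_sqrt = 1.0 / np.sqrt(np.maximum(lam, 0.0) + eps)
    W = (U * inv_sqrt) @ U.T
    center = patch_size * patch_size // 2
    kernel = W[center].reshape(patch_size, patch_size)
    kernel = 0.5 * (kernel + kernel[::-1, ::-1])
    return DynamicFilter(kernel=kernel, patch_size=patch_size, eigen_floor=eigen_floor, seed=seed)


def whiten_energy(E: EnergyMap, F: DynamicFilter, omega_frac: float = 0.1) -> WhitenedEnergyMap:
    """Convolve the mean-removed energy map with the dynamic filter and
    zero every pixel whose *raw* energy falls below omega = omega_frac * max(E)."""
    values = np.asarray(E.values if isinstance(E, EnergyMap) else E, dtype=float)
    omega = omega_frac * float(values.max())
    whitened = conv_same(values - values.mean(), F.kernel)
    whitened = np.where(values >= omega, whitened, 0.0)
    return WhitenedEnergyMap(values=whitened, threshold_used=omega)


def gain_control_map(whitened: WhitenedEnergyMap, a: float = 5.0, b: float = 0.3) -> GainControlMap:
    """Sigmoid-normalize the whitened energy into a gain field G in [-1, 1].

    G = 2 S(Et/max|Et|) - 1 on the support of the whitened map and exactly 0
    off it, with the logistic soft threshold S(x) = 1 / (1 + exp(-a (x - b))):
    normalized whitened energy above the inflection b is enhanced (G > 0),
    energy below it — the redundant part of the edge map — is suppressed
    (G < 0).  As a grows the soft threshold approaches a hard one at b.
    """
    values = whitened.values
    support = values != 0
    G = np.zeros_like(values)
    peak = float(np.abs(values).max())
    if peak > 0:
        x = values[support] / peak
        G[support] = 2.0 / (1.0 + np.exp(-a * (x - b))) - 1.0
    return GainControlMap(values=G, slope=a, inflection=b)


#: relative floor for the divisive denominator (fraction of tau)
DENOM_FLOOR = 0.05


def apply_gain_control(
    responses: ChannelResponseSet,
    G: GainControlMap,
    tau: float = 0.5,
    smooth_sd: float = 1.0,
) -> ChannelResponseSet:
    """Divisively modulate channel responses by the gain field.

    R* = R (tau + tau G) / (tau + |R| G), with the denominator clamped below
    at DENOM_FLOOR * tau (the raw expression is singular when |R| G -> -tau).
    Fixed points: R* = R wherever G = 0 or |R| = tau.  Each modulated response
    is then low-pass filtered with a Gaussian of ``smooth_sd`` pixels.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    g = G.values
    out = {}
    for orientation, R in responses.responses.items():
        denom = np.maximum(tau + np.abs(R) * g, DENOM_FLOOR * tau)
        mod = R * (tau + tau * g) / denom
        if smooth_sd > 0:
            mod = ndimage.gaussian_filter(mod, smooth_sd, mode="mirror")
        out[orientation] = mod
    return ChannelResponseSet(responses=out, channel=responses.channel)
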