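"""Stage 1: Gabor encoding of the two contrast channels and the local energy map.

Two banks of oriented Gabor filters model V1 simple cells:

* the **contrast-only** channel (0.25 cycles/pixel) has balanced ON/OFF
  sub-regions (zero DC), so it is blind to homogeneous luminance;
* the **contrast-luminance** channel (0.125 cycles/pixel) is unbalanced to a
  small positive DC, so it carries a weak luminance signal in addition to
  contrast.

Odd-symmetric (sine-phase) kernels define the encoding responses used by the
later stages; even-symmetric quadrature partners are only used to compute the
phase-invariant local energy map (model complex cells), pooled across
orientations.

Each kernel is scaled so that a full-range (+/-0.5) luminance grating at the
kernel's own frequency and orientation elicits a peak response of 0.5.  This
ties the response scale to the gain-control bound tau = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._conv import conv_same

__all__ = [
    "GaborKernel",
    "GaborBank",
    "ChannelResponseSet",
    "EnergyMap",
    "build_bank",
    "filter_image",
    "local_energy",
    "CONTRAST_ONLY",
    "CONTRAST_LUMINANCE",
]

CONTRAST_ONLY = "contrast_only"
CONTRAST_LUMINANCE = "contrast_luminance"

#: channel -> spatial frequency in cycles/pixel
CHANNEL_FREQUENCIES = {CONTRAST_ONLY: 0.25, CONTRAST_LUMINANCE: 0.125}

#: fraction of sum(|weights|) used as the positive DC of contrast-luminance
#: kernels; sized so the uniform-field response stays well below the step
#: response while still covering the lowest spatial frequencies during
#: reconstruction
DC_FRACTION = 0.125


@dataclass
class GaborKernel:
    weights: np.ndarray
    orientation: float  # radians in [0, pi)
    spatial_frequency: float  # cycles/pixel
    phase: str  # "odd" | "even"
    channel: str

    @property
    def dc(self) -> float:
        return float(self.weights.sum())


@dataclass
class GaborBank:
    kernels: list[GaborKernel]
    channel: str
    spatial_frequency: float

    @property
    def orientations(self) -> np.ndarray:
        return np.array(sorted({k.orientation for k in self.kernels}))

    def odd_kernels(self) -> list[GaborKernel]:
        return [k for k in self.kernels if k.phase == "odd"]

    def quadrature_pairs(self) -> list[tuple[GaborKernel, GaborKernel]]:
        """(odd, even) kernel pairs, one per orientation."""
        odd = {k.orientation: k for k in self.kernels if k.phase == "odd"}
        even = {k.orientation: k for k in self.kernels if k.phase == "even"}
        if set(odd) != set(even):
            raise ValueError("bank is missing a quadrature partner for some orientation")
        return [(odd[o], even[o]) for o in sorted(odd)]


@dataclass
class ChannelResponseSet:
    """One response grid per odd (encoding) kernel, keyed by orientation."""

    responses: dict[float, np.ndarray]
    channel: str

    def as_list(self) -> list[np.ndarray]:
        return [self.responses[o] for o in sorted(self.responses)]


@dataclass
class EnergyMap:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _raw_gabor(size: int, sigma: float, frequency: float, theta: float, phase: str) -> np.ndarray:
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    envelope = np.exp(-(x**2 + y**2) / (2.0 * sigma**2))
    carrier = np.sin(2 * np.pi * frequency * xr) if phase == "odd" else np.cos(2 * np.pi * frequency * xr)
    return envelope * carrier


def _response_ceiling(weights: np.ndarray) -> float:
    """Largest |response| any luminance image in [-0.5, 0.5] can evoke.

    Attained by the sign-matched binary stimulus 0.5*sign(w); for an odd
    (zero-DC) Gabor that stimulus is exactly the matched full-range square
    grating.  Normalizing by this makes the gain-control parameter tau = 0.5
    a true response ceiling.
    """
    return 0.5 * float(np.abs(weights).sum())


def build_bank(
    channel: str,
    n_orientations: int = 8,
    envelope_sd: float | None = None,
    kernel_size: int | None = None,
) -> GaborBank:
    """Construct the Gabor bank for one channel.

    Defaults: envelope sigma = a quarter of the carrier wavelength (1 px for
    contrast-only, 2 px for contrast-luminance) and kernel side = smallest odd
    integer >= 6*sigma + 1 — compact, broadly tuned kernels.
    """
    if channel not in CHANNEL_FREQUENCIES:
        raise ValueError(f"unknown channel {channel!r}")
    if n_orientations < 2:
        raise ValueError("n_orientations must be >= 2")
    frequency = CHANNEL_FREQUENCIES[channel]
    wavelength = 1.0 / frequency
    if envelope_sd is None:
        envelope_sd = 0.25 * wavelength
    if kernel_size is None:
        kernel_size = int(np.ceil(6 * envelope_sd + 1))
        if kernel_size % 2 == 0:
            kernel_size += 1
    if kernel_size % 2 == 0:
        raise ValueError(f"kernel_size must be odd, got {kernel_size}")

    kernels: list[GaborKernel] = []
    thetas = np.arange(n_orientations) * np.pi / n_orientations
    for theta in thetas:
        pair = {}
        for phase in ("odd", "even"):
            w = _raw_gabor(kernel_size, envelope_sd, frequency, theta, phase)
            if channel == CONTRAST_ONLY:
                w = w - w.mean()  # balanced ON/OFF: exact zero DC
            pair[phase] = w
        # one scale per quadrature pair, set by the odd kernel's response
        # ceiling, so that |R| <= tau = 0.5 for every in-range image
        scale = _response_ceiling(pair["odd"])
        for phase in ("odd", "even"):
            w = 0.5 * pair[phase] / scale
            if channel == CONTRAST_LUMINANCE:
                # unbalance ON/OFF so the kernel sum is small and positive
                target_dc = DC_FRACTION * np.abs(w).sum()
                w = w + (target_dc - w.sum()) / w.size
            kernels.append(
                GaborKernel(
                    weights=w,
                    orientation=float(theta),
                    spatial_frequency=frequency,
                    phase=phase,
                    channel=channel,
                )
            )
    return GaborBank(kernels=kernels, channel=channel, spatial_frequency=frequency)


def _pixels(img) -> np.ndarray:
    return np.asarray(getattr(img, "pixels", img), dtype=float)


def filter_image(img, bank: GaborBank) -> ChannelResponseSet:
    """Convolve the image with every odd (encoding) kernel of the bank."""
    pixels = _pixels(img)
    ksize = bank.kernels[0].weights.shape[0]
    if pixels.shape[0] < ksize or pixels.shape[1] < ksize:
        raise ValueError(f"image {pixels.shape} smaller than kernel ({ksize}x{ksize})")
    responses = {k.orientation: conv_same(pixels, k.weights) for k in bank.odd_kernels()}
    return ChannelResponseSet(responses=responses, channel=bank.channel)


def local_energy(img, bank: GaborBank) -> EnergyMap:
    """Orientation-pooled complex-cell energy of the contrast-only channel.

    For each orientation, the energy is sqrt(odd^2 + even^2) of the quadrature
    pair (phase invariant); the map averages these across orientations.
    """
    pixels = _pixels(img)
    pairs = bank.quadrature_pairs()
    acc = np.zeros_like(pixels)
    for odd, even in pairs:
        r_odd = conv_same(pixels, odd.weights)
        r_even = conv_same(pixels, even.weights)
        acc += np.sqrt(r_odd**2 + r_even**2)
    return EnergyMap(values=acc / len(pairs))
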