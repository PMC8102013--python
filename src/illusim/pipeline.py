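"""End-to-end model run: encoding -> dynamic decorrelation -> filling-in.

`run_model` executes the whole three-stage pipeline on a luminance image with
one fixed parameter set and returns every intermediate map, so the analysis
layer (and the CLI) can read off brightness effects, gain maps and
diagnostics from a single object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decorrelation, encoding, filling_in
from .decorrelation import DynamicFilter, GainControlMap, GainParams, WhitenedEnergyMap
from .encoding import CONTRAST_LUMINANCE, CONTRAST_ONLY, ChannelResponseSet, EnergyMap, GaborBank
from .filling_in import BrightnessMap, SolverConfig
from .stimuli import LuminanceImage

__all__ = ["ModelConfig", "ModelResult", "build_banks", "run_model"]


@dataclass
class ModelConfig:
    """All tunable parameters of the three stages, with the fixed defaults
    used for every display."""

    n_orientations: int = 8
    #: Gabor envelope sigma as a fraction of the carrier wavelength, per channel
    envelope_frac_co: float = 0.25
    envelope_frac_cl: float = 0.25
    gain: GainParams = field(default_factory=GainParams)
    solver: SolverConfig = field(default_factory=SolverConfig)
    patch_size: int = 31
    n_patches: int = 5000
    eigen_floor: float = 5e-2
    seed: int = 0


@dataclass
class ModelResult:
    image: LuminanceImage
    energy: EnergyMap
    dynamic_filter: DynamicFilter
    whitened: WhitenedEnergyMap
    gain_map: GainControlMap
    responses: dict[str, ChannelResponseSet]  # raw encoding responses per channel
    modulated: dict[str, ChannelResponseSet]  # after gain control + smoothing
    brightness: BrightnessMap


_BANK_CACHE: dict[tuple, tuple[GaborBank, GaborBank]] = {}


def build_banks(
    n_orientations: int = 8, envelope_frac_co: float = 0.25, envelope_frac_cl: float = 0.25
) -> tuple[GaborBank, GaborBank]:
    """(contrast-only, contrast-luminance) banks; cached, they are input-independent."""
    key = (n_orientations, envelope_frac_co, envelope_frac_cl)
    if key not in _BANK_CACHE:
        f_co = encoding.CHANNEL_FREQUENCIES[CONTRAST_ONLY]
        f_cl = encoding.CHANNEL_FREQUENCIES[CONTRAST_LUMINANCE]
        _BANK_CACHE[key] = (
            encoding.build_bank(CONTRAST_ONLY, n_orientations, envelope_sd=envelope_frac_co / f_co),
            encoding.build_bank(CONTRAST_LUMINANCE, n_orientations, envelope_sd=envelope_frac_cl / f_cl),
        )
    return _BANK_CACHE[key]


def run_model(img: LuminanceImage, cfg: ModelConfig | None = None, *, gain_enabled: bool = True) -> ModelResult:
    """Run all three stages on ``img``.

    ``gain_enabled=False`` skips dynamic filtering and gain control (G = 0),
    leaving pure encode/decode — the control condition in which no illusions
    should arise beyond reconstruction error.
    """
    cfg = cfg or ModelConfig()
    bank_co, bank_cl = build_banks(cfg.n_orientations, cfg.envelope_frac_co, cfg.envelope_frac_cl)

    resp_co = encoding.filter_image(img, bank_co)
    resp_cl = encoding.filter_image(img, bank_cl)
    energy = encoding.local_energy(img, bank_co)

    # FFT roundoff leaves ~1e-16 residue on truly homogeneous inputs
    if gain_enabled and float(energy.values.max()) > 1e-9:
        dyn = decorrelation.learn_dynamic_filter(
            energy,
            patch_size=cfg.patch_size,
            n_patches=cfg.n_patches,
            eigen_floor=cfg.eigen_floor,
            seed=cfg.seed,
        )
        whitened = decorrelation.whiten_energy(energy, dyn, omega_frac=cfg.gain.omega_frac)
        b = cfg.gain.b_for(whitened)
        gain_map = decorrelation.gain_control_map(whitened, a=cfg.gain.a, b=b)
    else:
        dyn = DynamicFilter(
            kernel=_delta(cfg.patch_size), patch_size=cfg.patch_size,
            eigen_floor=cfg.eigen_floor, seed=cfg.seed,
        )
        whitened = WhitenedEnergyMap(values=np.zeros_like(energy.values), threshold_used=0.0)
        gain_map = GainControlMap(values=np.zeros_like(energy.values), slope=cfg.gain.a, inflection=0.0)

    mod_co = decorrelation.apply_gain_control(resp_co, gain_map, tau=cfg.gain.tau, smooth_sd=cfg.gain.smooth_sd)
    mod_cl = decorrelation.apply_gain_control(resp_cl, gain_map, tau=cfg.gain.tau, smooth_sd=cfg.gain.smooth_sd)

    brightness = filling_in.reconstruct([mod_co, mod_cl], [bank_co, bank_cl], cfg.solver)

    return ModelResult(
        image=img,
        energy=energy,
        dynamic_filter=dyn,
        whitened=whitened,
        gain_map=gain_map,
        responses={CONTRAST_ONLY: resp_co, CONTRAST_LUMINANCE: resp_cl},
        modulated={CONTRAST_ONLY: mod_co, CONTRAST_LUMINANCE: mod_cl},
        brightness=brightness,
    )


def _delta(size: int) -> np.ndarray:
    k = np.zeros((size, size))
    k[size // 2, size // 2] = 1.0
    return k
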