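"""Effect measurement, the illusion sign battery, parameter sweeps and metrics.

Brightness effects are read from the model output the way profile plots are
read: as mean estimated brightness over the (eroded) interiors of the target
regions, or — for Mach/Chevreul-type edge phenomena — as the signed extremum
of (brightness - input) in a narrow band adjacent to the edge or knee point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pipeline as _pipeline
from .filling_in import BrightnessMap
from .stimuli import LuminanceImage, StimulusSpec, add_noise, generate

__all__ = [
    "EffectMeasurement",
    "SweepResult",
    "TARGET_PAIRS",
    "effect_size",
    "illusion_battery",
    "sweep",
    "modulation_depth",
    "snr_psnr",
    "sbc_size_sweep",
]

#: family -> (region_A, region_B, perceived sign of brightness_A - brightness_B)
TARGET_PAIRS = {
    "sbc": ("patch_dark_bg", "patch_bright_bg", +1),
    "white": ("bar_on_black", "bar_on_white", +1),
    "benary": ("triangle_in_cross", "triangle_on_bg", +1),
    "reverse_contrast": ("patch_on_dark", "patch_on_bright", -1),
    "dungeon": ("target_white_context", "target_black_context", +1),
    "checkerboard": ("target_white_flanks", "target_black_flanks", +1),
    "shevell_rings": ("ring_white_neighbors", "ring_black_neighbors", +1),
    "coce": ("left_region", "right_region", +1),
    "cowskin": ("blob_bright_edge", "blob_dark_edge", +1),
    "hermann": ("intersection", "segment", -1),
}


@dataclass
class EffectMeasurement:
    family: str
    params: dict
    region_a: str
    region_b: str
    brightness_a: float
    brightness_b: float

    @property
    def effect(self) -> float:
        return self.brightness_a - self.brightness_b

    @property
    def abs_effect(self) -> float:
        return abs(self.effect)


@dataclass
class SweepResult:
    family: str
    parameter: str
    values: list
    measurements: list[EffectMeasurement]
    fit: dict | None = None

    def abs_effects(self) -> np.ndarray:
        return np.array([m.abs_effect for m in self.measurements])

    def effects(self) -> np.ndarray:
        return np.array([m.effect for m in self.measurements])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.values,
                "effect": self.effects(),
                "abs_effect": self.abs_effects(),
            }
        )


def effect_size(
    brightness: BrightnessMap | np.ndarray,
    img: LuminanceImage,
    region_a: str,
    region_b: str,
) -> EffectMeasurement:
    """Mean brightness difference between two named target regions."""
    z = brightness.values if isinstance(brightness, BrightnessMap) else np.asarray(brightness)
    for name in (region_a, region_b):
        if name not in img.regions:
            raise KeyError(f"region {name!r} not present in image (has {sorted(img.regions)})")
        if not img.regions[name].any():
            raise ValueError(f"region {name!r} is empty")
    return EffectMeasurement(
        family=img.meta.get("family", "?"),
        params={k: v for k, v in img.meta.items() if k != "family"},
        region_a=region_a,
        region_b=region_b,
        brightness_a=float(z[img.regions[region_a]].mean()),
        brightness_b=float(z[img.regions[region_b]].mean()),
    )


def _run_effect(family: str, cfg, seed: int = 0, **params) -> EffectMeasurement:
    img = generate(StimulusSpec(family, params=params, seed=seed))
    res = _pipeline.run_model(img, cfg)
    a, b, _ = TARGET_PAIRS[family]
    return effect_size(res.brightness, img, a, b)


def band_extremum(brightness, img: LuminanceImage, band: str, mode: str) -> float:
    """Signed extremum of (brightness - input) within a probe band."""
    z = brightness.values if isinstance(brightness, BrightnessMap) else np.asarray(brightness)
    dz = z - img.pixels
    vals = dz[img.regions[band]]
    if vals.size == 0:
        raise ValueError(f"band {band!r} is empty")
    return float(vals.max() if mode == "max" else vals.min())


def mach_band_strengths(cfg=None, ramp_width: int = 32, seed: int = 0, **params) -> tuple[float, float]:
    """(bright overshoot, dark undershoot) adjacent to the ramp knee points."""
    img = generate(StimulusSpec("mach", params={"ramp_width": ramp_width, **params}, seed=seed))
    res = _pipeline.run_model(img, cfg)
    return (
        band_extremum(res.brightness, img, "bright_band", "max"),
        band_extremum(res.brightness, img, "dark_band", "min"),
    )


def modulation_depth(
    brightness, img: LuminanceImage, testfield_region: str = "test_field"
) -> tuple[float, float]:
    """Peak-to-trough amplitude of the induced modulation across the test
    field, plus its phase alignment with the (top) inducer grating.

    The row-averaged brightness profile is projected onto the inducer
    frequency (single Fourier component), so broadband reconstruction ripple
    does not count as modulation.  The second value is the cosine of the
    phase difference to the inducer: -1 means perfect antiphase.
    """
    z = brightness.values if isinstance(brightness, BrightnessMap) else np.asarray(brightness)
    mask = img.regions[testfield_region]
    rows = np.where(mask.any(axis=1))[0]
    if rows.size == 0 or not mask[rows[0]].all():
        raise ValueError("test-field mask must span the full image width")
    profile = z[rows].mean(axis=0)
    w = profile.size
    freq = float(img.meta.get("inducer_frequency", 4.0))
    x = np.arange(w)
    carrier = np.exp(-2j * np.pi * freq * x / w)
    coeff = 2.0 * np.dot(profile - profile.mean(), carrier) / w
    depth = float(2.0 * np.abs(coeff))  # peak to trough of that component
    if depth == 0.0:
        return 0.0, 0.0
    # inducer is sin(2*pi*f*x/w): its complex coefficient points along -i
    phase_align = float(np.cos(np.angle(coeff) - np.angle(-1j)))
    return depth, phase_align


def snr_psnr(reference: np.ndarray, test: np.ndarray) -> tuple[float, float]:
    """Standard dB signal-to-noise and peak signal-to-noise ratios.

    SNR uses the reference variance over the mean squared error; PSNR uses the
    reference dynamic range.  Identical inputs return +inf for both.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch {reference.shape} vs {test.shape}")
    var = float(reference.var())
    if var == 0:
        raise ValueError("reference has zero variance")
    mse = float(((reference - test) ** 2).mean())
    if mse == 0:
        return float("inf"), float("inf")
    peak = float(reference.max() - reference.min())
    return 10 * np.log10(var / mse), 10 * np.log10(peak**2 / mse)


# ---------------------------------------------------------------------------
# the sign battery


def illusion_battery(cfg=None, seed: int = 0, noise_sd: float = 0.0) -> pd.DataFrame:
    """Run the full model on every display with one fixed parameter set and
    check each predicted brightness direction against the perceived one.

    Columns: check, effect, expected_sign, passed.  ``noise_sd`` adds seeded
    white noise to every display before the model runs (robustness variant).
    """
    cfg = cfg or _pipeline.ModelConfig()
    rows: list[tuple[str, float, int, bool]] = []

    def model(family, **params):
        img = generate(StimulusSpec(family, params=params, seed=seed))
        if noise_sd > 0:
            img = add_noise(img, noise_sd, seed=seed + 1)
        return img, _pipeline.run_model(img, cfg)

    def pair_check(name, family, **params):
        a, b, sgn = TARGET_PAIRS[family]
        img, res = model(family, **params)
        m = effect_size(res.brightness, img, a, b)
        rows.append((name, m.effect, sgn, bool(m.effect * sgn > 0)))
        return m.effect

    pair_check("sbc", "sbc")
    pair_check("white", "white")
    pair_check("benary", "benary")
    pair_check("reverse_contrast", "reverse_contrast")

    todor = {}
    for ctx in "ABC":
        img, res = model("todorovic", context=ctx)
        m = effect_size(res.brightness, img, "disk_white_squares", "disk_black_squares")
        todor[ctx] = m.effect
    rows.append(("todorovic_B", todor["B"], +1, todor["B"] > 0))
    rows.append(("todorovic_C", todor["C"], -1, todor["C"] < 0))
    # context A: the effect collapses relative to the occluded/window contexts
    weak = abs(todor["A"]) < max(abs(todor["B"]), abs(todor["C"]))
    rows.append(("todorovic_A_weak", todor["A"], 0, bool(weak)))

    pair_check("dungeon", "dungeon")
    pair_check("checkerboard", "checkerboard")
    pair_check("shevell_rings", "shevell_rings")
    pair_check("coce", "coce")
    pair_check("cowskin", "cowskin")

    e_reg = pair_check("hermann", "hermann")
    # the corrugated grid removes the darkening: only the reduction is checked
    img, res = model("hermann", corrugated=True)
    m = effect_size(res.brightness, img, "intersection", "segment")
    rows.append(
        ("corrugation_weakens_hermann", m.effect - e_reg, +1, bool(m.effect > e_reg))
    )

    # Chevreul: within-step gradient, brighter toward the darker neighbor
    img, res = model("chevreul")
    g = float(
        res.brightness.values[img.regions["step_left_band"]].mean()
        - res.brightness.values[img.regions["step_right_band"]].mean()
    )
    rows.append(("chevreul_gradient", g, +1, g > 0))

    img, res = model("chevreul", pyramid=True)
    dz = res.brightness.values - img.pixels
    g = float(dz[img.regions["frame_diagonal"]].mean() - dz[img.regions["frame_edge"]].mean())
    rows.append(("chevreul_pyramid_diagonals", g, +1, g > 0))

    # Mach bands present at a ramp, absent at a step
    img, res = model("mach", ramp_width=32, low=-0.5, high=0.5)
    bright = band_extremum(res.brightness, img, "bright_band", "max")
    dark = band_extremum(res.brightness, img, "dark_band", "min")
    rows.append(("mach_bright_band", bright, +1, bright > 0))
    rows.append(("mach_dark_band", dark, -1, dark < 0))

    img, res = model("mach", ramp_width=0, low=-0.5, high=0.5)
    sb = band_extremum(res.brightness, img, "bright_band", "max")
    sd = band_extremum(res.brightness, img, "dark_band", "min")
    step_amp = max(abs(sb), abs(sd))
    ramp_amp = max(abs(bright), abs(dark))
    rows.append(("mach_absent_at_step", step_amp - ramp_amp, -1, step_amp < ramp_amp))

    # grating induction: antiphase modulation, reduced for antiphase inducers
    img, res = model("grating_induction", phase_difference=0.0)
    d0, c0 = modulation_depth(res.brightness, img)
    img, res = model("grating_induction", phase_difference=float(np.pi))
    dpi, _ = modulation_depth(res.brightness, img)
    rows.append(("gi_antiphase_modulation", c0, -1, c0 < 0))
    rows.append(("gi_reduced_at_antiphase", dpi - d0, -1, dpi < d0))

    return pd.DataFrame(rows, columns=["check", "effect", "expected_sign", "passed"])


# ---------------------------------------------------------------------------
# sweeps


def _log_linear_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS fit of y = a + b ln(x) with R^2 and RMSE."""
    if len(x) < 3:
        raise ValueError("log-linear fit needs at least 3 points")
    lx = np.log(np.asarray(x, dtype=float))
    b, a = np.polyfit(lx, y, 1)
    pred = a + b * lx
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "model": "y = a + b*log(x)",
        "intercept": float(a),
        "slope": float(b),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "rmse": float(np.sqrt(ss_res / len(x))),
    }


def sweep(
    family: str,
    parameter: str,
    values,
    cfg=None,
    fit_spec: str | None = None,
    seed: int = 0,
    base_params: dict | None = None,
) -> SweepResult:
    """Measure the target-pair effect while sweeping one stimulus parameter."""
    values = list(values)
    if len(values) < 2:
        raise ValueError("a sweep needs at least 2 values")
    if fit_spec is not None and len(values) < 3:
        raise ValueError("a fit needs at least 3 swept values")
    cfg = cfg or _pipeline.ModelConfig()
    base = dict(base_params or {})
    measurements = [
        _run_effect(family, cfg, seed=seed, **{**base, parameter: v}) for v in values
    ]
    result = SweepResult(family=family, parameter=parameter, values=values, measurements=measurements)
    if fit_spec == "log-linear":
        result.fit = _log_linear_fit(np.array(values, dtype=float), result.abs_effects())
    elif fit_spec is not None:
        raise ValueError(f"unknown fit_spec {fit_spec!r}")
    return result


#: patch sizes (pixels) for the brightness-vs-size sweep on the SBC display
SBC_SWEEP_SIZES = (8, 12, 16, 24, 32, 44, 56, 64)


def sbc_size_sweep(cfg=None, sizes=SBC_SWEEP_SIZES, seed: int = 0) -> SweepResult:
    """Mean absolute brightness difference between the SBC patches as a
    function of patch size, with the log-linear fit."""
    return sweep("sbc", "patch_size", sizes, cfg=cfg, fit_spec="log-linear", seed=seed)
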