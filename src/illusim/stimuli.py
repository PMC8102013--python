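"""Programmatic generation of brightness-illusion displays.

Every display used in the simulations is generated here on a common canvas
(default 256 x 256) with luminance values in [-0.5, 0.5] and a three-level
palette (black -0.5, gray 0, white +0.5) unless a family needs intermediate
levels.  Each display carries named boolean region masks for its target
areas; masks are eroded interiors so that downstream effect measurements
avoid edge ringing.

Conventions: row-major arrays, origin top-left, 0-based indices; rectangles
are half-open pixel ranges; disks/ellipses are rasterized by pixel-center
inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BLACK",
    "GRAY",
    "WHITE",
    "FAMILIES",
    "LuminanceImage",
    "StimulusSpec",
    "StimulusParameterError",
    "generate",
    "add_noise",
    "normalize",
]

BLACK, GRAY, WHITE = -0.5, 0.0, 0.5

#: default erosion (pixels) applied to target masks
MASK_EROSION = 3


class StimulusParameterError(ValueError):
    """A stimulus parameter is invalid or its geometry does not fit the canvas."""


@dataclass
class LuminanceImage:
    """A 2-D luminance field in [-0.5, 0.5] with optional named region masks."""

    pixels: np.ndarray
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        for name, mask in self.regions.items():
            if mask.shape != self.pixels.shape:
                raise ValueError(f"region {name!r} shape {mask.shape} != image {self.pixels.shape}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "LuminanceImage":
        return LuminanceImage(
            pixels=self.pixels.copy(),
            regions={k: v.copy() for k, v in self.regions.items()},
            meta=dict(self.meta),
        )


@dataclass
class StimulusSpec:
    """Family name, canvas size and family-specific parameters."""

    family: str
    size: tuple[int, int] = (256, 256)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise StimulusParameterError(f"unknown stimulus family {self.family!r}")
        h, w = self.size
        if h <= 0 or w <= 0:
            raise StimulusParameterError(f"size must be positive, got {self.size}")


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Affinely map [min, max] to [-0.5, 0.5]; constant images map to 0.

    Idempotent on images that already span the full range.
    """
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = pixels.min(), pixels.max()
    if hi - lo < 1e-15:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo) - 0.5


def add_noise(img: LuminanceImage, noise_sd: float, seed: int) -> LuminanceImage:
    """Add pixelwise i.i.d. zero-mean Gaussian noise, clipped to [-0.5, 0.5]."""
    if noise_sd < 0:
        raise StimulusParameterError(f"noise_sd must be >= 0, got {noise_sd}")
    out = img.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out.pixels = np.clip(out.pixels + rng.normal(0.0, noise_sd, out.pixels.shape), -0.5, 0.5)
    return out


# ---------------------------------------------------------------------------
# rasterization helpers

def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise StimulusParameterError(msg)


def _rect(shape, y0, y1, x0, x1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[max(y0, 0) : max(y1, 0), max(x0, 0) : max(x1, 0)] = True
    return m


def _disk(shape, cy, cx, r) -> np.ndarray:
    y, x = np.ogrid[: shape[0], : shape[1]]
    return (y - cy) ** 2 + (x - cx) ** 2 <= r**2


def _erode_keep(mask: np.ndarray, width: int = MASK_EROSION) -> np.ndarray:
    """Erode by ``width`` pixels, backing off just enough to keep the mask nonempty."""
    for w in range(width, 0, -1):
        er = ndimage.binary_erosion(mask, iterations=w)
        if er.any():
            return er
    return mask.copy()


def _finalize(pixels, regions, family, params, erosion=MASK_EROSION) -> LuminanceImage:
    assert np.all(pixels >= -0.5 - 1e-12) and np.all(pixels <= 0.5 + 1e-12)
    eroded = {k: _erode_keep(v, erosion) for k, v in regions.items()}
    return LuminanceImage(pixels=pixels, regions=eroded, meta={"family": family, **params})


def _levels(params) -> tuple[float, float, float]:
    lo = params.get("black", BLACK)
    mid = params.get("gray", GRAY)
    hi = params.get("white", WHITE)
    for name, v in (("black", lo), ("gray", mid), ("white", hi)):
        _check(-0.5 <= v <= 0.5, f"luminance level {name}={v} outside [-0.5, 0.5]")
    return lo, mid, hi


# ---------------------------------------------------------------------------
# display families

def _sbc(size, p):
    h, w = size
    patch = int(p.get("patch_size", 32))
    lo, mid, hi = _levels(p)
    _check(0 < patch <= min(h, w // 2), f"patch_size={patch} does not fit half canvas")
    px = np.full(size, lo)
    px[:, w // 2 :] = hi
    s = patch // 2
    left = _rect(size, h // 2 - s, h // 2 - s + patch, w // 4 - s, w // 4 - s + patch)
    right = _rect(size, h // 2 - s, h // 2 - s + patch, 3 * w // 4 - s, 3 * w // 4 - s + patch)
    px[left] = mid
    px[right] = mid
    return px, {"patch_dark_bg": left, "patch_bright_bg": right}


def _white(size, p):
    h, w = size
    n_cycles = int(p.get("stripe_cycles", 8))
    bar_h = int(p.get("bar_height", 64))
    lo, mid, hi = _levels(p)
    _check(n_cycles >= 1, "stripe_cycles must be >= 1")
    sw = w // (2 * n_cycles)
    _check(sw >= 2, f"stripe_cycles={n_cycles} gives stripe width < 2 px")
    _check(0 < bar_h <= h, f"bar_height={bar_h} does not fit canvas")
    x = np.arange(w)
    stripe_idx = np.minimum(x // sw, 2 * n_cycles - 1)
    row = np.where(stripe_idx % 2 == 0, lo, hi)
    px = np.tile(row, (h, 1))
    # one bar on a black stripe (~1/3 width), one on a white stripe (~2/3 width)
    i_black = int(round((w / 3) / sw))
    i_black -= i_black % 2  # even index = black stripe
    i_white = int(round((2 * w / 3) / sw)) | 1  # odd index = white stripe
    _check(i_white < 2 * n_cycles, "canvas too narrow for both bars")
    y0 = h // 2 - bar_h // 2
    bars = {}
    for name, i in (("bar_on_black", i_black), ("bar_on_white", i_white)):
        m = _rect(size, y0, y0 + bar_h, i * sw, (i + 1) * sw)
        px[m] = mid
        bars[name] = m
    return px, bars


def _benary(size, p):
    h, w = size
    arm = int(p.get("arm_width", 56))
    leg = int(p.get("triangle_leg", 40))
    lo, mid, hi = _levels(p)
    _check(0 < arm < min(h, w) // 2, f"arm_width={arm} does not fit")
    _check(0 < leg <= min(h, w) // 4, f"triangle_leg={leg} does not fit")
    px = np.full(size, hi)
    cy, cx = h // 2, w // 2
    a = arm // 2
    cross = _rect(size, cy - a, cy + a, 0, w) | _rect(size, 0, h, cx - a, cx + a)
    px[cross] = lo
    y, x = np.mgrid[:h, :w]
    # triangle embedded in the cross corner: legs along the upper-left inner
    # corner of the cross, hypotenuse facing the white quadrant
    x0, y0 = cx - a, cy - a  # inner corner
    tri_in = (x < x0) & (y < y0) & ((x0 - x) + (y0 - y) <= leg)
    # triangle on the background: base resting on the outer edge of the right
    # arm (one black-gray edge), apex pointing up into the white field
    xb = cx + (cx - a) // 2 + a // 2  # mid of right arm stretch
    tri_out = (y < cy - a) & ((cy - a - y) <= (leg // 2 - np.abs(x - xb)))
    _check(not (tri_in & cross).any() and not (tri_out & cross).any(), "triangles overlap the cross")
    px[tri_in] = mid
    px[tri_out] = mid
    return px, {"triangle_in_cross": tri_in, "triangle_on_bg": tri_out}


def _reverse_contrast(size, p):
    h, w = size
    n_flanks = int(p.get("n_flanks", 3))
    misalign = int(p.get("misalign", 0))
    bw = int(p.get("bar_width", 8))
    bh = int(p.get("bar_height", 96))
    gap = int(p.get("gap", 8))
    lo, mid, hi = _levels(p)
    _check(n_flanks >= 0, "n_flanks must be >= 0")
    _check(bw > 0 and bh > 0 and gap >= 0, "bar dimensions must be positive")
    extent = (n_flanks + 0.5) * (bw + gap)
    _check(extent <= w // 4, f"n_flanks={n_flanks} with bar_width/gap does not fit half canvas")
    _check(bh + 2 * abs(misalign) <= h, f"bar_height={bh} plus misalign does not fit")
    px = np.full(size, lo)
    px[:, w // 2 :] = hi
    regions = {}
    for name, cx0, bg_flank in (("patch_on_dark", w // 4, hi), ("patch_on_bright", 3 * w // 4, lo)):
        y0 = h // 2 - bh // 2
        target = _rect(size, y0, y0 + bh, cx0 - bw // 2, cx0 - bw // 2 + bw)
        px[target] = mid
        regions[name] = target
        for j in range(1, n_flanks + 1):
            dy = misalign if j % 2 == 1 else -misalign
            for sgn in (-1, 1):
                fx = cx0 + sgn * j * (bw + gap) - bw // 2
                fm = _rect(size, y0 + dy, y0 + dy + bh, fx, fx + bw)
                px[fm] = bg_flank
    return px, regions


def _todorovic(size, p):
    h, w = size
    context = p.get("context", "B")
    r = int(p.get("disk_radius", 40))
    s = int(p.get("square_size", 48))
    gap = int(p.get("cross_gap", 24))
    lo, mid, hi = _levels(p)
    _check(context in ("A", "B", "C"), f"context must be A, B or C, got {context!r}")
    half = w // 4  # half-width of each panel
    _check(gap // 2 + s <= min(half, h // 2) - 2, f"square_size={s}/cross_gap={gap} does not fit panel")
    _check(0 < r <= min(half, h // 2) - 2, f"disk_radius={r} does not fit panel")
    px = np.empty(size)
    regions = {}
    for name, cx, bg, occ in (("disk_white_squares", w // 4, lo, hi), ("disk_black_squares", 3 * w // 4, hi, lo)):
        panel = _rect(size, 0, h, cx - half, cx + half)
        px[panel] = bg
        cy = h // 2
        off = gap // 2 + s // 2
        squares = np.zeros(size, dtype=bool)
        for dy in (-off, off):
            for dx in (-off, off):
                squares |= _rect(size, cy + dy - s // 2, cy + dy - s // 2 + s, cx + dx - s // 2, cx + dx - s // 2 + s)
        disk = _disk(size, cy, cx, r)
        ext = off + s // 2
        big_square = _rect(size, cy - ext, cy + ext, cx - ext, cx + ext)
        cross = (_rect(size, cy - gap // 2, cy + gap // 2, cx - ext, cx + ext)
                 | _rect(size, cy - ext, cy + ext, cx - gap // 2, cx + gap // 2))
        if context == "A":  # disk in the foreground, fully visible
            px[squares] = occ
            px[disk] = mid
            visible = disk
        elif context == "B":  # squares occlude the disk corners
            px[disk] = mid
            px[squares] = occ
            visible = disk & ~squares
        else:  # C: disk on a single occluder square, seen through a window cross
            px[big_square] = occ
            px[disk] = mid
            px[cross & big_square] = bg
            visible = disk & ~cross
        regions[name] = visible
    return px, regions


def _dungeon(size, p):
    """Gray squares in alternate holes of a connected grid of bars (the
    "dungeon grill"); the remaining holes show the background.  The gray
    squares assimilate toward the bar (context) luminance."""
    h, w = size
    cell = int(p.get("cell_size", 14))
    bar = int(p.get("bar_width", 10))
    lo, mid, hi = _levels(p)
    pitch = cell + bar
    _check(cell > 0 and bar > 0, "cell_size/bar_width must be positive")
    n = (w // 2) // pitch
    _check(n >= 5, f"cell_size+bar_width={pitch} leaves fewer than 5 grid columns per panel")
    px = np.empty(size)
    regions = {}
    for name, cx, bg, ctx in (("target_white_context", w // 4, lo, hi), ("target_black_context", 3 * w // 4, hi, lo)):
        panel = _rect(size, 0, h, cx - w // 4, cx + w // 4)
        px[panel] = ctx  # the bar lattice
        ny = h // pitch
        oy = (h - ny * pitch + bar) // 2
        ox = cx - w // 4 + (w // 2 - n * pitch + bar) // 2
        targets = np.zeros(size, dtype=bool)
        for i in range(ny):
            for j in range(n):
                hole = _rect(size, oy + i * pitch, oy + i * pitch + cell, ox + j * pitch, ox + j * pitch + cell)
                if (i + j) % 2 == 0:
                    px[hole] = mid  # gray square framed by bars on all sides
                    if 0 < i < ny - 1 and 0 < j < n - 1:
                        targets |= hole
                else:
                    px[hole] = bg
        # bars outside the lattice footprint revert to background
        lattice = _rect(size, oy - bar, oy + ny * pitch, ox - bar, ox + n * pitch)
        px[panel & ~lattice] = bg
        regions[name] = targets
    return px, regions


def _checkerboard(size, p):
    h, w = size
    c = int(p.get("check_size", 16))
    lo, mid, hi = _levels(p)
    _check(c > 0 and 6 * c <= w and 2 * c <= h, f"check_size={c} does not fit")
    yi, xi = np.mgrid[:h, :w]
    px = np.where((yi // c + xi // c) % 2 == 0, lo, hi)
    row = (h // c) // 2
    # one target replaces a black check (white lateral flanks), one a white check
    col_b = (w // c) // 3
    if (row + col_b) % 2 != 0:
        col_b += 1
    col_w = 2 * (w // c) // 3
    if (row + col_w) % 2 != 1:
        col_w += 1
    _check(col_w < w // c, "canvas too narrow for both targets")
    t_white = _rect(size, row * c, (row + 1) * c, col_b * c, (col_b + 1) * c)
    t_black = _rect(size, row * c, (row + 1) * c, col_w * c, (col_w + 1) * c)
    px = px.astype(float)
    px[t_white] = mid
    px[t_black] = mid
    return px, {"target_white_flanks": t_white, "target_black_flanks": t_black}


def _shevell_rings(size, p):
    h, w = size
    rw = int(p.get("ring_width", 10))
    n_rings = int(p.get("n_rings", 6))
    target_idx = int(p.get("target_ring", 2))
    lo, mid, hi = _levels(p)
    _check(rw > 0, "ring_width must be positive")
    _check(0 < target_idx < n_rings - 1, "target_ring must be an interior ring")
    _check(n_rings * rw <= min(h // 2, w // 4) - 2, f"n_rings={n_rings} rings of width {rw} do not fit panel")
    px = np.full(size, mid)
    regions = {}
    y, x = np.mgrid[:h, :w]
    for name, cx, first in (("ring_white_neighbors", w // 4, lo), ("ring_black_neighbors", 3 * w // 4, hi)):
        d = np.sqrt((y - h // 2) ** 2 + (x - cx) ** 2)
        second = hi if first == lo else lo
        for k in range(n_rings):
            ring = (d >= k * rw) & (d < (k + 1) * rw)
            if k == target_idx:
                px[ring] = mid
                regions[name] = ring
            else:
                px[ring] = first if k % 2 == 0 else second
    return px, regions


def _coce(size, p):
    h, w = size
    amp = float(p.get("cusp_amplitude", 0.25))
    sc = float(p.get("cusp_width", 12.0))
    base = float(p.get("base_level", 0.0))
    _check(amp > 0 and sc > 0, "cusp_amplitude and cusp_width must be positive")
    _check(-0.5 <= base - amp and base + amp <= 0.5, "cusp exceeds luminance range")
    x = np.arange(w, dtype=float)
    edge = w / 2 - 0.5
    # exponential cusp, truncated and rescaled so it reaches the base level
    # exactly at 4 space constants (the plateaus are then strictly uniform)
    cut = 4.0 * sc
    tail = np.exp(-4.0)

    def cusp(d):
        g = (np.exp(-d / sc) - tail) / (1.0 - tail)
        return np.where(d < cut, g, 0.0)

    profile = np.where(
        x < w / 2,
        base + amp * cusp(edge - x),
        base - amp * cusp(x - edge),
    )
    px = np.tile(profile, (h, 1))
    margin = int(min(4 * sc, w / 4)) + 1
    left = _rect(size, h // 4, 3 * h // 4, w // 8, w // 2 - margin)
    right = _rect(size, h // 4, 3 * h // 4, w // 2 + margin, 7 * w // 8)
    _check(left.any() and right.any(), "cusp_width too large: no plateau region left")
    return px, {"left_region": left, "right_region": right}


def _cowskin(size, p, seed):
    h, w = size
    n_blobs = int(p.get("n_blobs", 8))
    lw = int(p.get("line_width", 3))
    lo, mid, hi = _levels(p)
    _check(n_blobs >= 2 and n_blobs % 2 == 0, "n_blobs must be an even number >= 2")
    _check(lw > 0, "line_width must be positive")
    rng = np.random.default_rng(seed)
    px = np.full(size, mid)
    y, x = np.mgrid[:h, :w]
    occupied = np.zeros(size, dtype=bool)
    bright = np.zeros(size, dtype=bool)
    dark = np.zeros(size, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_blobs and attempts < 500:
        attempts += 1
        ay, ax = rng.uniform(14, 26, 2)
        cy = rng.uniform(ay + lw + 4, h - ay - lw - 4)
        cx = rng.uniform(ax + lw + 4, w - ax - lw - 4)
        d = np.sqrt(((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2)
        inside = d < 1.0
        footprint = d < 1.0 + (2 * lw + 6) / min(ay, ax)
        if (footprint & occupied).any():
            continue
        inner = inside & ~ndimage.binary_erosion(inside, iterations=lw)
        outer = ndimage.binary_dilation(inside, iterations=lw) & ~inside
        if placed % 2 == 0:  # white line inside the contour, black outside
            px[inner] = hi
            px[outer] = lo
            bright |= ndimage.binary_erosion(inside, iterations=lw)
        else:
            px[inner] = lo
            px[outer] = hi
            dark |= ndimage.binary_erosion(inside, iterations=lw)
        occupied |= footprint
        placed += 1
    _check(placed == n_blobs, f"could only place {placed}/{n_blobs} non-overlapping blobs")
    return px, {"blob_bright_edge": bright, "blob_dark_edge": dark}


def _hermann(size, p, seed):
    h, w = size
    block = int(p.get("block_width", 26))
    line = int(p.get("line_width", 4))
    corrugated = bool(p.get("corrugated", False))
    corr_amp = float(p.get("corrugation_amplitude", 3.0))
    corr_period = float(p.get("corrugation_period", 64.0))
    lo, mid, hi = _levels(p)
    _check(block > 0 and line > 0, "block_width and line_width must be positive")
    pitch = block + line
    _check(2 * pitch <= min(h, w), f"block+line={pitch} leaves fewer than 2 grid periods")
    xi = np.arange(w)
    yi = np.arange(h)
    n_h = h // pitch
    n_v = w // pitch
    oy = (h - n_h * pitch + block) // 2 + block // 2  # first horizontal line center offset
    ox = (w - n_v * pitch + block) // 2 + block // 2
    hcenters = [oy + k * pitch + line / 2 for k in range(n_h)]
    vcenters = [ox + k * pitch + line / 2 for k in range(n_v)]
    H = np.zeros(size, dtype=bool)
    V = np.zeros(size, dtype=bool)
    rng = np.random.default_rng(seed)
    hphase = rng.uniform(0, 2 * np.pi, n_h) if corrugated else np.zeros(n_h)
    vphase = rng.uniform(0, 2 * np.pi, n_v) if corrugated else np.zeros(n_v)
    for k, yc in enumerate(hcenters):
        off = corr_amp * np.sin(2 * np.pi * xi / corr_period + hphase[k]) if corrugated else 0.0
        yy = yc + off
        H |= np.abs(yi[:, None] - yy[None, :] if corrugated else yi[:, None] - yc) < line / 2
    for k, xc in enumerate(vcenters):
        off = corr_amp * np.sin(2 * np.pi * yi / corr_period + vphase[k]) if corrugated else 0.0
        xx = xc + off
        V |= np.abs(xi[None, :] - xx[:, None] if corrugated else xi[None, :] - xc) < line / 2
    px = np.full(size, lo)
    px[H | V] = hi
    inter = np.zeros(size, dtype=bool)
    seg = np.zeros(size, dtype=bool)
    win = int(np.ceil(line / 2 + (corr_amp if corrugated else 0))) + 1
    for yc in hcenters[1:-1] if n_h > 2 else hcenters:
        for k, xc in enumerate(vcenters):
            if 0 < k < n_v - 1 or n_v <= 2:
                box = _rect(size, int(yc) - win, int(yc) + win, int(xc) - win, int(xc) + win)
                inter |= box & H & V
            if k < n_v - 1:
                xm = (vcenters[k] + vcenters[k + 1]) / 2
                box = _rect(size, int(yc) - win, int(yc) + win, int(xm) - line // 2, int(xm) + (line + 1) // 2)
                seg |= box & H & ~V
    _check(inter.any() and seg.any(), "grid geometry produced empty intersection/segment masks")
    return px, {"intersection": inter, "segment": seg}


def _chevreul(size, p):
    h, w = size
    n_steps = int(p.get("n_steps", 5))
    pyramid = bool(p.get("pyramid", False))
    lo = float(p.get("low", BLACK))
    hi = float(p.get("high", WHITE))
    _check(n_steps >= 3, "n_steps must be >= 3")
    _check(-0.5 <= lo < hi <= 0.5, "low/high levels invalid")
    levels = np.linspace(lo, hi, n_steps)
    if pyramid:
        y, x = np.mgrid[:h, :w]
        d = np.maximum(np.abs(y - (h - 1) / 2), np.abs(x - (w - 1) / 2))
        band = max(h, w) / 2 / n_steps
        idx = np.clip((d // band).astype(int), 0, n_steps - 1)
        px = levels[::-1][idx]  # brightest at the center
        # corners (diagonal) vs mid-edge probes on one interior frame
        k = n_steps // 2
        ring = (idx == k)
        diag = ring & (np.abs(np.abs(y - h / 2) - np.abs(x - w / 2)) < band / 2)
        edge = ring & (np.abs(y - h / 2) < band / 2)
        _check(diag.any() and edge.any(), "pyramid frame probes are empty")
        return px, {"frame_diagonal": diag, "frame_edge": edge}
    sw = w // n_steps
    _check(sw >= 12, f"n_steps={n_steps} gives steps narrower than 12 px")
    xi = np.arange(w)
    idx = np.minimum(xi // sw, n_steps - 1)
    px = np.tile(levels[idx], (h, 1))
    i = n_steps // 2  # interior step
    x0, x1 = i * sw, (i + 1) * sw
    band = 5
    left = _rect(size, h // 4, 3 * h // 4, x0 + MASK_EROSION, x0 + MASK_EROSION + band)
    right = _rect(size, h // 4, 3 * h // 4, x1 - MASK_EROSION - band, x1 - MASK_EROSION)
    return px, {"step_left_band": left, "step_right_band": right}


def _mach(size, p):
    h, w = size
    rw = int(p.get("ramp_width", 32))
    lo = float(p.get("low", -0.25))
    hi = float(p.get("high", 0.25))
    band = int(p.get("probe_band", 5))
    _check(rw >= 0, "ramp_width must be >= 0")
    _check(-0.5 <= lo < hi <= 0.5, "low/high levels invalid")
    _check(rw + 4 * band + 8 <= w, f"ramp_width={rw} leaves no plateau")
    x0 = (w - rw) // 2
    x1 = x0 + rw
    x = np.arange(w, dtype=float)
    if rw == 0:
        profile = np.where(x < x0, lo, hi)
    else:
        profile = np.clip(lo + (hi - lo) * (x - x0) / rw, lo, hi)
    px = np.tile(profile, (h, 1))
    dark = _rect(size, h // 4, 3 * h // 4, x0 - band, x0)
    bright = _rect(size, h // 4, 3 * h // 4, x1 + 1, x1 + 1 + band)
    # plateau probes just beyond the knee bands
    pd1 = x0 - band - 2
    pb0 = x1 + band + 3
    plat_d = _rect(size, h // 4, 3 * h // 4, max(2, pd1 - band), pd1)
    plat_b = _rect(size, h // 4, 3 * h // 4, pb0, min(w - 2, pb0 + band))
    return px, {"dark_band": dark, "bright_band": bright, "dark_plateau": plat_d, "bright_plateau": plat_b}


def _grating_induction(size, p):
    h, w = size
    freq = float(p.get("inducer_frequency", 4.0))  # cycles per image width
    tfh = int(p.get("testfield_height", 32))
    phase_diff = float(p.get("phase_difference", 0.0))
    amp = float(p.get("inducer_amplitude", 0.4))
    _check(freq > 0, "inducer_frequency must be positive")
    _check(0 < tfh <= h - 16, f"testfield_height={tfh} does not fit")
    _check(0 < amp <= 0.5, "inducer_amplitude must be in (0, 0.5]")
    x = np.arange(w, dtype=float)
    top = amp * np.sin(2 * np.pi * freq * x / w)
    bottom = amp * np.sin(2 * np.pi * freq * x / w + phase_diff)
    px = np.empty(size)
    y0 = h // 2 - tfh // 2
    y1 = y0 + tfh
    px[:y0] = top[None, :]
    px[y1:] = bottom[None, :]
    px[y0:y1] = 0.0
    # inset vertically only: the modulation readout needs the full width
    test = _rect(size, y0 + MASK_EROSION, y1 - MASK_EROSION, 0, w)
    _check(test.any(), "testfield_height too small for the probe band")
    return px, {"test_field": test}


def _step(size, p):
    h, w = size
    lo = float(p.get("low", -0.25))
    hi = float(p.get("high", 0.25))
    _check(-0.5 <= lo < hi <= 0.5, "low/high levels invalid")
    px = np.full(size, lo)
    px[:, w // 2 :] = hi
    left = _rect(size, h // 4, 3 * h // 4, w // 8, 3 * w // 8)
    right = _rect(size, h // 4, 3 * h // 4, 5 * w // 8, 7 * w // 8)
    return px, {"left_region": left, "right_region": right}


def _uniform(size, p):
    level = float(p.get("level", 0.0))
    _check(-0.5 <= level <= 0.5, f"level={level} outside [-0.5, 0.5]")
    return np.full(size, level), {}


_BUILDERS = {
    "sbc": _sbc,
    "white": _white,
    "benary": _benary,
    "reverse_contrast": _reverse_contrast,
    "todorovic": _todorovic,
    "dungeon": _dungeon,
    "checkerboard": _checkerboard,
    "shevell_rings": _shevell_rings,
    "coce": _coce,
    "cowskin": _cowskin,
    "hermann": _hermann,
    "chevreul": _chevreul,
    "mach": _mach,
    "grating_induction": _grating_induction,
    "step": _step,
    "uniform": _uniform,
}

FAMILIES = tuple(_BUILDERS)

#: families whose geometry involves randomness (seeded through StimulusSpec.seed)
STOCHASTIC_FAMILIES = ("cowskin",)


def generate(spec: StimulusSpec) -> LuminanceImage:
    """Generate the display for ``spec`` with its target-region masks."""
    builder = _BUILDERS[spec.family]
    if spec.family in ("cowskin", "hermann"):
        pixels, regions = builder(spec.size, spec.params, spec.seed)
    else:
        pixels, regions = builder(spec.size, spec.params)
    # narrow profile-probe bands (Mach/Chevreul) and thin grid lines are not
    # equal-luminance targets; erosion would slide them off the measured pixels
    erosion = {"hermann": 1, "mach": 0, "chevreul": 0, "grating_induction": 0}.get(spec.family, MASK_EROSION)
    img = _finalize(pixels, regions, spec.family, spec.params, erosion=erosion)
    if spec.family == "grating_induction":
        img.meta.setdefault("inducer_frequency", spec.params.get("inducer_frequency", 4.0))
        img.meta.setdefault("inducer_amplitude", spec.params.get("inducer_amplitude", 0.4))
        img.meta.setdefault("phase_difference", spec.params.get("phase_difference", 0.0))
    return img
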