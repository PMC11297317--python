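"""Renderers for the 7 localization patterns.

Each category maps to a distinct, deterministic-under-seed stain geometry on
a shared "tissue" layout of cells (nucleus + cell body on a jittered grid):

* Nuclear              - solid stain over the nucleus disks (high coverage)
* Cytoplasm            - diffuse smooth stain across the cell body
* Plasma membrane      - thin ring at the cell boundary
* Mitochondria         - many small granules in the cytoplasm
* Vesicles             - few larger round puncta
* Golgi apparatus      - one compact juxtanuclear blob per cell
* Endoplasmic reticulum- thin reticular strands through the cytoplasm

Brown (DAB-like) stain is composited over a blue (hematoxylin-like) nuclear
counterstain on a light background.  The hues are fixed constants; classes
are separated by coverage, granularity and edge density so that even simple
intensity-profile statistics can tell them apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from locdiff.categories import CATEGORIES

# fixed colors (RGB in [0,1])
_BACKGROUND = np.array([0.93, 0.91, 0.94])
_HEMATOXYLIN = np.array([0.38, 0.40, 0.68])
_DAB = np.array([0.45, 0.27, 0.12])

_INTENSITY_ALPHA = {"strong": 0.95, "moderate": 0.62, "weak": 0.28}


@dataclass
class PatternSpec:
    """One image's staining recipe: what pattern, how strongly, how widely."""

    labels: tuple[str, ...]
    stain_intensity: str = "strong"
    stained_quantity: float = 100.0
    render_params: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.labels) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown localization labels: {sorted(unknown)}")
        if self.stain_intensity not in _INTENSITY_ALPHA:
            raise ValueError(f"stain_intensity must be one of {sorted(_INTENSITY_ALPHA)}")
        if not 0.0 <= self.stained_quantity <= 100.0:
            raise ValueError("stained_quantity must be in [0, 100]")


@dataclass
class _Cell:
    cx: float
    cy: float
    nucleus_r: float
    cell_r: float


def _make_layout(size: int, rng: np.random.Generator) -> list[_Cell]:
    """Jittered grid of cells filling the frame."""
    pitch = max(18, size // 5)
    cells = []
    for gy in range(pitch // 2, size, pitch):
        for gx in range(pitch // 2, size, pitch):
            cx = gx + rng.uniform(-0.18, 0.18) * pitch
            cy = gy + rng.uniform(-0.18, 0.18) * pitch
            cell_r = pitch * rng.uniform(0.42, 0.50)
            nucleus_r = cell_r * rng.uniform(0.40, 0.48)
            cells.append(_Cell(cx, cy, nucleus_r, cell_r))
    return cells


def _grid(size: int):
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    return xx, yy


def _soft_disk(xx, yy, cx, cy, r, softness=1.2):
    d = np.hypot(xx - cx, yy - cy)
    return np.clip((r - d) / softness + 0.5, 0.0, 1.0)


def _ring(xx, yy, cx, cy, r, thickness):
    d = np.hypot(xx - cx, yy - cy)
    return np.clip(1.0 - np.abs(d - r) / thickness, 0.0, 1.0)


def _pattern_alpha(label: str, size: int, cells: list[_Cell], stained: np.ndarray,
                   rng: np.random.Generator, params: dict) -> np.ndarray:
    """Stain opacity field in [0,1] for one label over the stained cells."""
    xx, yy = _grid(size)
    alpha = np.zeros((size, size), dtype=np.float32)
    for use, cell in zip(stained, cells):
        if not use:
            continue
        if label == "Nuclear":
            alpha = np.maximum(alpha, _soft_disk(xx, yy, cell.cx, cell.cy, cell.nucleus_r))
        elif label == "Cytoplasm":
            body = _soft_disk(xx, yy, cell.cx, cell.cy, cell.cell_r, softness=2.5)
            hole = _soft_disk(xx, yy, cell.cx, cell.cy, cell.nucleus_r * 0.8)
            alpha = np.maximum(alpha, params.get("cyto_level", 0.55) * body * (1 - hole))
        elif label == "Plasma membrane":
            t = params.get("membrane_thickness", max(1.4, size / 70.0))
            alpha = np.maximum(alpha, _ring(xx, yy, cell.cx, cell.cy, cell.cell_r, t))
        elif label == "Mitochondria":
            n = params.get("granule_count", 24)
            r = params.get("granule_radius", max(1.0, size / 90.0))
            for _ in range(n):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(cell.nucleus_r * 1.05, cell.cell_r * 0.92)
                gx, gy = cell.cx + rad * np.cos(ang), cell.cy + rad * np.sin(ang)
                alpha = np.maximum(alpha, _soft_disk(xx, yy, gx, gy, r, softness=0.8))
        elif label == "Vesicles":
            n = params.get("vesicle_count", 7)
            r = params.get("vesicle_radius", max(1.8, size / 45.0))
            for _ in range(n):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(cell.cell_r * 0.6, cell.cell_r * 0.95)
                gx, gy = cell.cx + rad * np.cos(ang), cell.cy + rad * np.sin(ang)
                alpha = np.maximum(alpha, _soft_disk(xx, yy, gx, gy, r, softness=1.0))
        elif label == "Golgi apparatus":
            # half-moon capping one lobe of the nucleus: no other pattern
            # overlaps the nucleus, so a partially stained nucleus is the
            # Golgi signature
            ang = rng.uniform(0, 2 * np.pi)
            cap = _soft_disk(xx, yy, cell.cx, cell.cy,
                             cell.nucleus_r * params.get("golgi_cap_scale", 1.25),
                             softness=1.0)
            theta = np.arctan2(yy - cell.cy, xx - cell.cx)
            half = np.cos(theta - ang) > params.get("golgi_cap_cos", 0.15)
            alpha = np.maximum(alpha, cap * half)
        elif label == "Endoplasmic reticulum":
            # dense fine web of thin arcs through the whole cytoplasm
            n = params.get("strand_count", 16)
            for _ in range(n):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(cell.nucleus_r * 1.0, cell.cell_r * 0.98)
                width = params.get("strand_width", max(1.1, size / 80.0))
                arc = _ring(xx, yy, cell.cx + rng.uniform(-2, 2),
                            cell.cy + rng.uniform(-2, 2), rad, width)
                # mask to a random angular sector so strands look broken
                theta = np.arctan2(yy - cell.cy, xx - cell.cx)
                sector = np.cos(theta - ang) > rng.uniform(-0.6, -0.1)
                alpha = np.maximum(alpha, arc * sector)
        else:  # pragma: no cover - guarded by PatternSpec
            raise ValueError(f"no renderer for label {label!r}")
    return alpha


def render_image(spec: PatternSpec, size: int = 96, noise_sd: float = 0.05,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one IHC-like RGB image (uint8, size x size x 3).

    ``stained_quantity`` acts as the fraction of cells carrying the stain;
    ``stain_intensity`` scales the stain opacity.  Multi-label specs
    composite each label's pattern into the same image.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if size < 32:
        raise ValueError("image size must be >= 32 pixels")
    cells = _make_layout(size, rng)
    n_stained = int(round(len(cells) * spec.stained_quantity / 100.0))
    stained = np.zeros(len(cells), dtype=bool)
    stained[rng.choice(len(cells), size=n_stained, replace=False)] = True

    xx, yy = _grid(size)
    img = np.ones((size, size, 3), dtype=np.float32) * _BACKGROUND.astype(np.float32)

    # hematoxylin counterstain on every nucleus
    nuc = np.zeros((size, size), dtype=np.float32)
    for cell in cells:
        nuc = np.maximum(nuc, _soft_disk(xx, yy, cell.cx, cell.cy, cell.nucleus_r))
    nuc_alpha = 0.55 * nuc
    img = img * (1 - nuc_alpha[..., None]) + _HEMATOXYLIN * nuc_alpha[..., None]

    # DAB stain for each label, composited by max opacity
    stain = np.zeros((size, size), dtype=np.float32)
    for label in spec.labels:
        stain = np.maximum(
            stain, _pattern_alpha(label, size, cells, stained, rng, spec.render_params)
        )
    stain_alpha = _INTENSITY_ALPHA[spec.stain_intensity] * stain
    img = img * (1 - stain_alpha[..., None]) + _DAB * stain_alpha[..., None]

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def brownness(img: np.ndarray) -> np.ndarray:
    """DAB-channel proxy: how brown (stained) each pixel is, in [0,1].

    Brown has high red, mid green, low blue; the blue counterstain and the
    light background both score near zero.
    """
    f = img.astype(np.float32) / 255.0
    return np.clip(f[..., 0] - f[..., 2] + 0.35 * (f[..., 0] - f[..., 1]), 0.0, 1.0)
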