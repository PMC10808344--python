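"""Deterministic raster rendering of lattice states.

Cells are drawn as pointy-top hexagonal patches on a dark background, rows
offset by half a cell (the axial layout sheared back into a rectangle).
Boundary-box occupancy fills the red channel, informant polymers the green
channel; optional molecule layers render in blue.  Pixel output depends only
on the state and options, never on a random stream.
"""

from __future__ import annotations

import math

import numpy as np

from .state import LatticeState

#: recognised layer names -> channel index
_LAYERS = {"polymer2": 0, "polymer1": 1}

_BACKGROUND = 24  # dark grey


def _hex_stamp(scale: int) -> np.ndarray:
    """Boolean mask of a pointy-top hexagon inscribed in a square patch."""
    size = scale
    yy, xx = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    x = (xx - cx) / (size / 2.0)
    y = (yy - cy) / (size / 2.0)
    # pointy-top hexagon: |x| <= s3/2 and |y| <= 1 - |x| / s3... use half-plane form
    s3 = math.sqrt(3.0)
    return (np.abs(x) * s3 / 2 <= s3 / 2 + 1e-9) & (
        np.abs(y) + np.abs(x) / s3 <= 1.0 + 1e-9
    ) & (np.abs(x) <= s3 / 2 + 1e-9)


def render_frame(
    state: LatticeState,
    layers: tuple[str, ...] = ("polymer2", "polymer1"),
    scale: int = 6,
    molecule_layer: int | None = None,
) -> np.ndarray:
    """Rasterise selected layers to an RGB uint8 image.

    Intensity saturates at 4 boxes (red) / 4 polymers (green) per cell and,
    for a molecule layer, at that species' 99th-percentile count (blue).
    Image dimensions depend only on the grid and ``scale``.
    """
    for layer in layers:
        if layer not in _LAYERS:
            raise ValueError(f"unknown layer {layer!r}; choose from {sorted(_LAYERS)}")
    h, w = state.grid.height, state.grid.width
    img_h = int(h * scale * math.sqrt(3) / 2) + scale
    img_w = w * scale + scale
    img = np.full((img_h, img_w, 3), _BACKGROUND, dtype=np.uint8)

    fields: dict[int, np.ndarray] = {}
    if "polymer2" in layers:
        fields[0] = np.minimum(state.boxes2 / 4.0, 1.0)
    if "polymer1" in layers:
        pc = state.polymers.counts_per_cell(state.grid.n_cells).reshape(h, w)
        fields[1] = np.minimum(pc / 4.0, 1.0)
    if molecule_layer is not None:
        m = state.counts[state.species_index(molecule_layer)].astype(float)
        top = max(float(np.percentile(m, 99)), 1.0)
        fields[2] = np.minimum(m / top, 1.0)

    stamp = _hex_stamp(scale)
    sy, sx = stamp.shape
    row_pitch = scale * math.sqrt(3) / 2
    for r in range(h):
        y0 = int(r * row_pitch)
        xoff = int(((r * 0.5) % w) * scale)
        for c in range(w):
            vals = [fields.get(ch, None) for ch in range(3)]
            if not any(v is not None and v[r, c] > 0 for v in vals):
                continue
            x0 = (c * scale + xoff) % (w * scale)
            patch = img[y0 : y0 + sy, x0 : x0 + sx]
            m = stamp[: patch.shape[0], : patch.shape[1]]
            for ch, v in enumerate(vals):
                if v is not None and v[r, c] > 0:
                    patch[..., ch][m] = np.uint8(_BACKGROUND + v[r, c] * (255 - _BACKGROUND))
    return img


def save_frame(state: LatticeState, path, **kwargs) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, render_frame(state, **kwargs))
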