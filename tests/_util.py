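"""Shared helpers for building masks and scenes in tests."""

from __future__ import annotations

import numpy as np

from mitoquant.images import BinaryMask
from mitoquant.synth import SceneParams, spindle_mask_from_truth


def embryo_grid(params: SceneParams) -> tuple[np.ndarray, np.ndarray, float]:
    n = params.image_size_px
    xs = (np.arange(n) + 0.5) * params.pixel_size_um
    xg, yg = np.meshgrid(xs, xs)
    center = n * params.pixel_size_um / 2.0
    return xg, yg, center


def embryo_mask(params: SceneParams) -> BinaryMask:
    """Ground-truth whole-embryo (cell) mask: the embryo disk."""
    xg, yg, c = embryo_grid(params)
    return BinaryMask(np.hypot(xg - c, yg - c) <= params.embryo_radius_um)


def cytoplasm_mask(params: SceneParams) -> BinaryMask:
    """Embryo disk minus the organizer ellipse."""
    org = spindle_mask_from_truth(params)
    return BinaryMask(embryo_mask(params).pixels & ~org.pixels)
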