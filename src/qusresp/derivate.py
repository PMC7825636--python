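"""Texture-derivate analysis: second-pass texture of texture-encoded maps.

A 15x15-pixel window slides over a parametric image; at every centre whose
full neighbourhood is valid, the neighbourhood is quantized over its own
local range (16 levels) and the mean distance-1 GLCM feature over the four
directions becomes the map pixel.  A second-pass texture analysis (the
same distance 1-5 x four-angle protocol as the first pass) applied to each
of the four texture-encoded maps yields 4 x 4 = 16 texture-derivate
features per parametric image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .texture import (ANGLES, DISTANCES, FeatureUnavailableError,
                      N_GRAY_LEVELS, _ANGLE_OFFSETS, _as_masked,
                      averaged_texture, quantize_gray_levels)

TEXTURE_MAP_WINDOW_PX = 15
FEATURE_CODES = ("CON", "COR", "ENE", "HOM")


@dataclass
class TextureMap:
    """Texture-encoded map of a parametric image (one feature)."""

    feature: str
    values: np.ndarray
    valid: np.ndarray
    window_px: int = TEXTURE_MAP_WINDOW_PX


def _local_quantize(windows, n_levels=N_GRAY_LEVELS):
    """Per-window min-max quantization to 0..n_levels-1 (constant -> 0)."""
    vmin = windows.min(axis=(1, 2), keepdims=True)
    vmax = windows.max(axis=(1, 2), keepdims=True)
    rng = vmax - vmin
    u = np.where(rng > 0, (windows - vmin) / np.where(rng == 0, 1, rng), 0.0)
    return np.minimum(n_levels - 1,
                      np.floor(u * n_levels).astype(np.int32))


def _batch_glcm_features(levels, n_levels=N_GRAY_LEVELS):
    """Distance-1, angle-averaged GLCM features of many quantized windows.

    ``levels``: (n_win, h, w) int array of 0-based gray levels (all pixels
    valid).  Returns dict of feature arrays of length n_win, each the mean
    over the four directions of the symmetric-GLCM feature.
    """
    n_win = levels.shape[0]
    nn = n_levels * n_levels
    i_idx = (np.arange(nn) // n_levels).astype(float)
    j_idx = (np.arange(nn) % n_levels).astype(float)
    acc = {c: np.zeros(n_win) for c in FEATURE_CODES}
    win_base = np.arange(n_win)[:, None] * nn
    for angle in ANGLES:
        dr, dc = _ANGLE_OFFSETS[angle]
        h, w = levels.shape[1:]
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = levels[:, r0:r1, c0:c1].reshape(n_win, -1)
        b = levels[:, r0 + dr:r1 + dr, c0 + dc:c1 + dc].reshape(n_win, -1)
        codes = np.concatenate([a * n_levels + b, b * n_levels + a], axis=1)
        counts = np.bincount((win_base + codes).ravel(),
                             minlength=n_win * nn).reshape(n_win, nn)
        p = counts / counts.sum(axis=1, keepdims=True)
        diff = i_idx - j_idx
        acc["CON"] += p @ diff ** 2
        acc["ENE"] += np.sum(p ** 2, axis=1)
        acc["HOM"] += p @ (1.0 / (1.0 + np.abs(diff)))
        mu_i = p @ i_idx
        mu_j = p @ j_idx
        var_i = p @ i_idx ** 2 - mu_i ** 2
        var_j = p @ j_idx ** 2 - mu_j ** 2
        cov = p @ (i_idx * j_idx) - mu_i * mu_j
        denom = np.sqrt(np.maximum(var_i * var_j, 0.0))
        acc["COR"] += np.where(denom > 0, cov / np.where(denom == 0, 1, denom),
                               0.0)
    return {c: acc[c] / len(ANGLES) for c in FEATURE_CODES}


def texture_maps(image, window_px=TEXTURE_MAP_WINDOW_PX,
                 quantization="local"):
    """All four texture-encoded maps of a parametric image in one pass.

    Centres whose window exits the validity mask are dropped (no padding:
    padding would fabricate texture at the tumour rim).  Map extent is
    (H - w + 1) x (W - w + 1) for a w-pixel window.

    ``quantization``: 'local' (default) rescales each 15x15 neighbourhood
    over its own range; 'global' quantizes the whole image once and the
    windows reuse those levels.
    """
    values, valid = _as_masked(image)
    h, w = values.shape
    if h < window_px or w < window_px:
        raise FeatureUnavailableError(
            "image smaller than the texture-map window")
    eligible = sliding_window_view(valid, (window_px, window_px)) \
        .all(axis=(2, 3))
    if not eligible.any():
        raise FeatureUnavailableError(
            "no 15x15 neighbourhood lies fully inside the validity mask")
    if quantization == "local":
        windows = sliding_window_view(values, (window_px, window_px))[eligible]
        levels = _local_quantize(windows)
    elif quantization == "global":
        q = quantize_gray_levels(values, valid=valid)
        levels = sliding_window_view(q.levels.astype(np.int32) - 1,
                                     (window_px, window_px))[eligible]
    else:
        raise ValueError("quantization must be 'local' or 'global'")
    feats = _batch_glcm_features(levels)
    maps = {}
    for code in FEATURE_CODES:
        vals = np.full(eligible.shape, np.nan)
        vals[eligible] = feats[code]
        maps[code] = TextureMap(feature=code, values=vals,
                                valid=eligible.copy(), window_px=window_px)
    return maps


def texture_map(image, feature, window_px=TEXTURE_MAP_WINDOW_PX) -> TextureMap:
    """One texture-encoded map (CON, COR, ENE or HOM)."""
    if feature not in FEATURE_CODES:
        raise ValueError(f"feature must be one of {FEATURE_CODES}")
    return texture_maps(image, window_px=window_px)[feature]


def texture_of_texture(image, window_px=TEXTURE_MAP_WINDOW_PX,
                       distances=DISTANCES, angles=ANGLES):
    """The 16 texture-derivate features of a parametric image.

    For each of the four texture-encoded maps, the first-pass protocol
    (global quantization, distances 1-5, four angles, averaging) is applied
    again; names are '{MAP}-{FEATURE}', e.g. 'ENE-CON' is the contrast of
    the energy map.
    """
    maps = texture_maps(image, window_px=window_px)
    out = {}
    for map_code in FEATURE_CODES:
        t = averaged_texture(maps[map_code], distances=distances,
                             angles=angles)
        for feat_code, value in t.as_dict().items():
            out[f"{map_code}-{feat_code}"] = value
    return out
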