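"""Mask-aware GLCM texture analysis of QUS parametric images.

Each parametric image is linearly rescaled over its own valid-pixel range
into 16 gray levels; symmetric gray-level co-occurrence matrices are built
at inter-pixel distances 1-5 and directions 0/45/90/135 degrees, and the
four first-order features (contrast, correlation, energy, homogeneity) are
averaged over the 20 (distance, angle) combinations.

The pairing is mask-aware: a pixel pair contributes only when both pixels
are valid, which is required because ROIs are non-rectangular.  Angle
convention: 0 deg is horizontal (lateral axis), 90 deg axial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_GRAY_LEVELS = 16
DISTANCES = (1, 2, 3, 4, 5)
ANGLES = (0, 45, 90, 135)

#: (row, col) pixel offsets per angle at unit distance
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class FeatureUnavailableError(RuntimeError):
    """No valid pixel pairs exist to compute the requested texture."""


def _as_masked(image):
    """Accept a ParametricImage-like object or a plain array (+mask)."""
    if hasattr(image, "values") and hasattr(image, "valid"):
        return np.asarray(image.values, dtype=float), \
            np.asarray(image.valid, dtype=bool)
    values = np.asarray(image, dtype=float)
    return values, np.isfinite(values)


@dataclass
class QuantizedImage:
    levels: np.ndarray      # int, 1..n_levels where valid
    valid: np.ndarray
    n_levels: int = N_GRAY_LEVELS


def quantize_gray_levels(image, n_levels=N_GRAY_LEVELS,
                         valid=None) -> QuantizedImage:
    """Linear min-max quantization of the image's own valid range.

    The valid-pixel minimum maps to level 1 and the maximum to level
    ``n_levels``; a constant image maps everywhere to level 1 (documented
    convention for a degenerate range).
    """
    if valid is None:
        values, valid = _as_masked(image)
    else:
        values = np.asarray(image, dtype=float)
        valid = np.asarray(valid, dtype=bool) & np.isfinite(values)
    if not valid.any():
        raise FeatureUnavailableError("no valid pixels to quantize")
    vmin = values[valid].min()
    vmax = values[valid].max()
    levels = np.ones(values.shape, dtype=np.int16)
    if vmax > vmin:
        u = np.where(valid, (values - vmin) / (vmax - vmin), 0.0)
        levels = np.minimum(n_levels,
                            1 + np.floor(u * n_levels)).astype(np.int16)
    levels[~valid] = 0
    return QuantizedImage(levels=levels, valid=valid, n_levels=n_levels)


@dataclass
class GLCMMatrix:
    """Symmetric co-occurrence probability matrix at one (distance, angle)."""

    p: np.ndarray
    distance: int
    angle: int
    n_pairs: int

    @property
    def empty(self) -> bool:
        return self.n_pairs == 0


def compute_glcm(qimage: QuantizedImage, distance, angle,
                 symmetric=True) -> GLCMMatrix:
    """Mask-aware GLCM: count pairs at the (distance, angle) offset where
    both pixels are valid, symmetrize, normalize to probabilities."""
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")
    dr, dc = (o * distance for o in _ANGLE_OFFSETS[angle])
    lv, valid = qimage.levels, qimage.valid
    h, w = lv.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    n = qimage.n_levels
    counts = np.zeros((n, n), dtype=float)
    if r1 > r0 and c1 > c0:
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = valid[r0:r1, c0:c1] & valid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if ok.any():
            code = (a[ok] - 1) * n + (b[ok] - 1)
            counts = np.bincount(code, minlength=n * n).reshape(n, n).astype(float)
    n_pairs = int(counts.sum())
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return GLCMMatrix(p=p, distance=distance, angle=angle, n_pairs=n_pairs)


@dataclass
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    correlation_defined: bool = True

    def as_dict(self):
        return {"CON": self.contrast, "COR": self.correlation,
                "ENE": self.energy, "HOM": self.homogeneity}


def glcm_features(glcm: GLCMMatrix) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j); for a
    constant region sigma_i sigma_j = 0 and correlation is undefined: the
    conventional sentinel 0 is returned with ``correlation_defined=False``.
    """
    p = glcm.p
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)[:, None]
    j = np.arange(1, n + 1, dtype=float)[None, :]
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    var_i = float(np.sum((i - mu_i) ** 2 * p))
    var_j = float(np.sum((j - mu_j) ** 2 * p))
    denom = np.sqrt(var_i * var_j)
    if denom > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * p) / denom)
        defined = True
    else:
        corr, defined = 0.0, False
    return TextureFeatures(contrast=contrast, correlation=corr,
                           energy=energy, homogeneity=homogeneity,
                           correlation_defined=defined)


def averaged_texture(image, distances=DISTANCES,
                     angles=ANGLES) -> TextureFeatures:
    """Texture features averaged over distances and directions.

    The image is quantized once over its valid range; features are
    arithmetic means over the non-empty GLCMs of the distance x angle
    protocol (empty GLCMs — no valid pair at that offset — are skipped).
    """
    q = quantize_gray_levels(image)
    feats = []
    for d in distances:
        for a in angles:
            g = compute_glcm(q, d, a)
            if not g.empty:
                feats.append(glcm_features(g))
    if not feats:
        raise FeatureUnavailableError(
            "no valid pixel pair at any (distance, angle) offset")
    return TextureFeatures(
        contrast=float(np.mean([t.contrast for t in feats])),
        correlation=float(np.mean([t.correlation for t in feats])),
        energy=float(np.mean([t.energy for t in feats])),
        homogeneity=float(np.mean([t.homogeneity for t in feats])),
        correlation_defined=all(t.correlation_defined for t in feats))
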