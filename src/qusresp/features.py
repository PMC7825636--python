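"""Per-patient feature assembly: 105 features per region, 220 combined.

Per region (tumour core; 5-mm margin) and per parametric image the table
holds the mean value (5), the four averaged GLCM texture features (20) and
the sixteen texture-derivate features (80) — 105 named features per
region.  Ten image-quality features (core-to-margin ratio CMR and
core-to-margin contrast ratio CMCR per parametric image) complete the
220-column combined table:

    CMR  = mean(core) / std(margin)
    CMCR = [mean(core) - mean(margin)] / (0.5 [std(core) + std(margin)])

Feature names follow '{Region}-{PARAM}[-{MAP}][-{FEATURE}]' plus
'CMR-{PARAM}' / 'CMCR-{PARAM}', e.g. 'Core-SS-ENE-CON', 'Margin-ASD',
'CMR-SI'.  Per-plane features are averaged across a patient's scan planes
with weights proportional to each plane's valid ROI pixel count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .derivate import FEATURE_CODES, texture_of_texture
from .spectral import PARAM_NAMES, build_parametric_images
from .texture import FeatureUnavailableError, averaged_texture

logger = logging.getLogger(__name__)

REGIONS = ("Core", "Margin")


def feature_names():
    """Deterministic 220-column order: Core 105, Margin 105, quality 10."""
    names = []
    for region in REGIONS:
        for p in PARAM_NAMES:
            names.append(f"{region}-{p}")
        for p in PARAM_NAMES:
            for t in FEATURE_CODES:
                names.append(f"{region}-{p}-{t}")
        for p in PARAM_NAMES:
            for m in FEATURE_CODES:
                for t in FEATURE_CODES:
                    names.append(f"{region}-{p}-{m}-{t}")
    for p in PARAM_NAMES:
        names.append(f"CMR-{p}")
    for p in PARAM_NAMES:
        names.append(f"CMCR-{p}")
    return names


FEATURE_NAMES = feature_names()
N_FEATURES_PER_REGION = 105
N_FEATURES_COMBINED = 220


def mean_value(values, mask):
    """Arithmetic mean of the valid masked pixels of a parametric image."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(values)
    if not mask.any():
        raise ValueError("empty mask: no valid pixels to average")
    return float(values[mask].mean())


def cmr(core_pixels, margin_pixels):
    """Core-to-margin ratio: mean(core) / std(margin); NaN if std is 0."""
    core_pixels = np.asarray(core_pixels, dtype=float)
    margin_pixels = np.asarray(margin_pixels, dtype=float)
    if core_pixels.size == 0 or margin_pixels.size == 0:
        raise ValueError("both regions must be non-empty")
    s = margin_pixels.std()
    return float(core_pixels.mean() / s) if s > 0 else float("nan")


def cmcr(core_pixels, margin_pixels):
    """Core-to-margin contrast ratio with pooled-spread denominator."""
    core_pixels = np.asarray(core_pixels, dtype=float)
    margin_pixels = np.asarray(margin_pixels, dtype=float)
    if core_pixels.size == 0 or margin_pixels.size == 0:
        raise ValueError("both regions must be non-empty")
    denom = 0.5 * (core_pixels.std() + margin_pixels.std())
    if denom == 0:
        return float("nan")
    return float((core_pixels.mean() - margin_pixels.mean()) / denom)


class _RegionView:
    """Parametric-image view restricted to one region's mask."""

    def __init__(self, pimage, region_mask):
        self.values = pimage.values
        self.valid = pimage.valid & region_mask & np.isfinite(pimage.values)


def region_features(pimage_set, region):
    """The 105 named features of one region of a parametric-image set.

    Texture or derivate features that cannot be computed on this plane
    (e.g. a margin too thin for a full 15x15 window) are returned as NaN;
    plane averaging and cohort-level imputation handle them downstream.
    """
    if region not in REGIONS:
        raise ValueError(f"region must be one of {REGIONS}")
    out = {}
    for p in PARAM_NAMES:
        img = pimage_set[p]
        mask = img.core if region == "Core" else img.margin
        view = _RegionView(img, mask)
        out[f"{region}-{p}"] = mean_value(img.values, view.valid)
        try:
            tex = averaged_texture(view).as_dict()
        except FeatureUnavailableError:
            tex = {t: float("nan") for t in FEATURE_CODES}
        for t, v in tex.items():
            out[f"{region}-{p}-{t}"] = v
        try:
            deriv = texture_of_texture(view)
        except FeatureUnavailableError:
            deriv = {f"{m}-{t}": float("nan")
                     for m in FEATURE_CODES for t in FEATURE_CODES}
        for mt, v in deriv.items():
            out[f"{region}-{p}-{mt}"] = v
    return out


def quality_features(pimage_set):
    """CMR and CMCR per parametric image (10 features)."""
    out = {}
    for p in PARAM_NAMES:
        img = pimage_set[p]
        core_px = img.values[img.core & np.isfinite(img.values)]
        margin_px = img.values[img.margin & np.isfinite(img.values)]
        out[f"CMR-{p}"] = cmr(core_px, margin_px)
        out[f"CMCR-{p}"] = cmcr(core_px, margin_px)
    return out


def plane_features(pimage_set):
    """All 220 features of one scan plane plus its ROI weight."""
    feats = {}
    feats.update(region_features(pimage_set, "Core"))
    feats.update(region_features(pimage_set, "Margin"))
    feats.update(quality_features(pimage_set))
    weight = int(np.count_nonzero(pimage_set.valid))
    return feats, weight


def patient_features(record, **imaging_kwargs):
    """Weighted plane-average of the 220 features for one patient.

    Weights are proportional to each plane's valid ROI pixel count; a
    feature missing on some planes is averaged over the planes where it
    is available.  Returns None (with a logged reason) if no plane is
    analyzable.
    """
    per_plane, weights = [], []
    for k, plane in enumerate(record.planes):
        try:
            pset = build_parametric_images(plane.frame, plane.roi,
                                           record.reference,
                                           **imaging_kwargs)
            feats, w = plane_features(pset)
        except (ValueError, FeatureUnavailableError) as exc:
            logger.warning("patient %s plane %d not analyzable: %s",
                           record.id, k, exc)
            continue
        per_plane.append(feats)
        weights.append(w)
    if not per_plane:
        logger.warning("patient %s excluded: no analyzable scan plane",
                       record.id)
        return None
    return combine_planes(per_plane, weights)


def combine_planes(per_plane, weights):
    """ROI-area-weighted average of per-plane feature dicts; a feature
    missing on some planes is averaged over the planes that have it."""
    out = {}
    w = np.asarray(weights, dtype=float)
    for name in FEATURE_NAMES:
        vals = np.array([f[name] for f in per_plane], dtype=float)
        ok = np.isfinite(vals)
        out[name] = float(np.average(vals[ok], weights=w[ok])) if ok.any() \
            else float("nan")
    return out


def assemble_feature_table(records, **imaging_kwargs) -> pd.DataFrame:
    """Cohort feature table: patients x 220 named features + 'label'.

    Patients without an analyzable plane are excluded (logged).  Features
    left NaN after plane averaging (e.g. undefined CMR on every plane) are
    imputed with the cohort median, with a logged flag.
    """
    rows, ids, labels = [], [], []
    for record in records:
        feats = patient_features(record, **imaging_kwargs)
        if feats is None:
            continue
        rows.append(feats)
        ids.append(record.id)
        labels.append(record.label)
    if not rows:
        raise ValueError("no analyzable patients in the cohort")
    table = pd.DataFrame(rows, index=ids, columns=FEATURE_NAMES)
    for col in table.columns[table.isna().any()]:
        med = table[col].median()
        logger.info("imputing cohort median for feature %s "
                    "(%d missing)", col, int(table[col].isna().sum()))
        table[col] = table[col].fillna(0.0 if np.isnan(med) else med)
    table["label"] = labels
    return table
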