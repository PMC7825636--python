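"""Persistence helpers: HDF5 frames/images, CSV tables, YAML configs."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import yaml

from .spectral import PARAM_NAMES, PARAM_UNITS, ParametricImageSet
from .synthetic import CohortConfig, RFFrame, SystemProfile


def save_rf_frame(path, frame: RFFrame):
    """Write an RF frame to HDF5 (dataset ``samples``; geometry attrs)."""
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("samples", data=frame.samples)
        ds.attrs["fs_mhz"] = frame.system.sampling_rate
        ds.attrs["pitch_mm"] = frame.system.lateral_pitch
        ds.attrs["c_m_s"] = frame.system.speed_of_sound
        ds.attrs["depth_offset_mm"] = frame.depth_offset_mm
        ds.attrs["center_frequency_mhz"] = frame.system.center_frequency
        ds.attrs["band_mhz"] = np.asarray(frame.system.band)
        ds.attrs["system"] = frame.system.name


def load_rf_frame(path) -> RFFrame:
    with h5py.File(path, "r") as h5:
        ds = h5["samples"]
        system = SystemProfile(
            name=str(ds.attrs["system"]),
            center_frequency=float(ds.attrs["center_frequency_mhz"]),
            band=tuple(float(b) for b in ds.attrs["band_mhz"]),
            sampling_rate=float(ds.attrs["fs_mhz"]),
            lateral_pitch=float(ds.attrs["pitch_mm"]),
            speed_of_sound=float(ds.attrs["c_m_s"]))
        return RFFrame(samples=ds[()], system=system,
                       depth_offset_mm=float(ds.attrs["depth_offset_mm"]))


def save_parametric_images(path, pset: ParametricImageSet):
    """Write the five parametric images (values, masks, grid, units)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["ace_db_cm_mhz"] = pset.ace
        h5.attrs["window_mm"] = pset.window_mm
        for name in PARAM_NAMES:
            img = pset[name]
            grp = h5.create_group(name)
            grp.create_dataset("values", data=img.values)
            grp.create_dataset("valid", data=img.valid)
            grp.create_dataset("core", data=img.core)
            grp.create_dataset("margin", data=img.margin)
            grp.create_dataset("axial_centers_mm", data=img.axial_centers_mm)
            grp.create_dataset("lateral_centers_mm",
                               data=img.lateral_centers_mm)
            grp.attrs["units"] = PARAM_UNITS[name]


def save_feature_table(path, table: pd.DataFrame, schema_path=None):
    """Feature table to CSV, optionally with a JSON name/units sidecar."""
    table.to_csv(path, index_label="patient")
    if schema_path is not None:
        schema = {"columns": [c for c in table.columns if c != "label"],
                  "label_column": "label",
                  "parameter_units": PARAM_UNITS}
        with open(schema_path, "w") as fh:
            json.dump(schema, fh, indent=2)


def save_cohort_manifest(path, records):
    """Per-patient metadata (id, label, sizes, cellularity, system)."""
    rows = [{
        "id": r.id, "label": r.label, "mr_score": r.mr_score,
        "initial_size_cm": r.initial_size,
        "residual_size_cm": r.residual_size,
        "cellularity_pct": r.cellularity,
        "system": r.reference.system.name,
        "n_planes": len(r.planes),
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_cohort_config(path, config: CohortConfig):
    d = dataclasses.asdict(config)
    d["systems"] = [s.name for s in config.systems]
    d["phantom"] = {"attenuation_coefficient":
                    config.phantom.attenuation_coefficient,
                    "speed_of_sound": config.phantom.speed_of_sound,
                    "medium": dataclasses.asdict(config.phantom.medium)}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
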