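"""Shared fixtures: small synthetic cohorts and reference sets.

Problem sizes are deliberately small (few patients, single scan plane,
compact ROIs) so the full RF -> features -> classification chain runs at
desk scale; the scientific checks do not depend on these sizes.
"""

import numpy as np
import pytest

from qusresp import (CohortConfig, FrameGeometry, ReferenceSet, SONIX_RP,
                     ScatteringMediumSpec, assemble_feature_table,
                     default_reference_phantom, elliptical_roi,
                     generate_cohort, simulate_reference_frame,
                     simulate_rf_frame)

GEOM = FrameGeometry(depth_extent_mm=18.0, width_mm=16.0, depth_offset_mm=10.0)


@pytest.fixture(scope="session")
def phantom():
    return default_reference_phantom()


@pytest.fixture(scope="session")
def reference_set(phantom):
    """Six reference-phantom frames on the 6.5 MHz system."""
    frames = [simulate_reference_frame(phantom, SONIX_RP, GEOM, seed=100 + s)
              for s in range(6)]
    return ReferenceSet(system=SONIX_RP, phantom=phantom, frames=frames)


@pytest.fixture(scope="session")
def tumour_frame_and_roi():
    """Homogeneous 70-um-scatterer medium at 1.0 dB/cm/MHz with an
    elliptical core ROI and 3-mm ring, for round-trip recovery checks."""
    medium = ScatteringMediumSpec(scatterer_diameter=70.0,
                                  number_density=60.0,
                                  impedance_contrast=0.06,
                                  attenuation_coefficient=1.0)
    frame = simulate_rf_frame(medium, SONIX_RP, GEOM, seed=7,
                              overlying_attenuation=1.0)
    roi = elliptical_roi(frame.samples.shape, frame.system.axial_spacing_mm,
                         frame.system.lateral_pitch, (9.0, 8.0), (4.0, 4.0),
                         margin_mm=3.0)
    return medium, frame, roi


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four patients, one plane each — enough to audit feature accounting."""
    cfg = CohortConfig(n_patients=4, responder_fraction=0.5, seed=5,
                       n_planes=1, effect_size=1.0)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort):
    return assemble_feature_table(tiny_cohort)


@pytest.fixture(scope="session")
def separable_feature_table():
    """20-patient cohort with a strong class effect, full pipeline."""
    cfg = CohortConfig(n_patients=20, responder_fraction=0.5, seed=21,
                       n_planes=1, effect_size=1.0)
    return assemble_feature_table(generate_cohort(cfg))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
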