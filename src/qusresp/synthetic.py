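"""Synthetic RF data: system profiles, scattering media, frames, ROIs, cohorts.

Frames are synthesized with a 2-D point-scatterer convolution model: point
scatterers are placed uniformly at random in the imaging plane, each echo is
a band-limited pulse (Gaussian spectral envelope centred on the transducer
centre frequency) filtered by the scatterer's Gaussian form-factor response
and by frequency-dependent two-way attenuation along its depth path.  Lines
are synthesized in the frequency domain and inverse-FFT'd, which makes the
attenuation and form-factor filtering exact rather than approximated by a
depth-invariant convolution.

The generator is the package's stand-in for clinical acquisitions; its
defaults mirror the acquisition systems and reference phantom the analysis
assumes (6.5 MHz / 3-8 MHz and 6.0 MHz / 3.5-8.5 MHz linear arrays, both
sampled at 40 MHz; phantom at 0.8 dB/cm/MHz and 1540 m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .acoustics import attenuation_amplitude, scatterer_amplitude_response


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemProfile:
    """Acquisition-system description (frequencies in MHz, pitch in mm)."""

    name: str
    center_frequency: float
    band: tuple[float, float]
    sampling_rate: float = 40.0
    lateral_pitch: float = 0.23
    speed_of_sound: float = 1540.0

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (f_lo < self.center_frequency < f_hi):
            raise ValueError("center frequency must lie inside the band")
        if self.sampling_rate < 2.0 * f_hi:
            raise ValueError("sampling rate violates Nyquist for the band")

    @property
    def samples_per_mm(self) -> float:
        """Axial samples per mm of depth (round-trip time of flight)."""
        return 2e3 * self.sampling_rate / self.speed_of_sound

    @property
    def axial_spacing_mm(self) -> float:
        return 1.0 / self.samples_per_mm


#: 6.5 MHz centre frequency, 3-8 MHz band (multi-purpose linear array).
SONIX_RP = SystemProfile("sonix_rp", 6.5, (3.0, 8.0), 40.0, 0.30, 1540.0)
#: 6.0 MHz centre frequency, 3.5-8.5 MHz band (9L-class linear array).
GE_LOGIQ_E9 = SystemProfile("ge_logiq_e9", 6.0, (3.5, 8.5), 40.0, 0.23, 1540.0)


@dataclass(frozen=True)
class ScatteringMediumSpec:
    """Homogeneous scattering medium for the Gaussian form-factor model.

    ``number_density`` doubles as the per-mm^2 density of simulated point
    scatterers in the 2-D plane and as the nominal per-mm^3 density in the
    analytic BSC; the constant unit mismatch cancels under reference-phantom
    normalization.
    """

    scatterer_diameter: float          # um
    number_density: float              # per mm^2 (2-D simulation) / mm^3 (BSC)
    impedance_contrast: float          # gamma0, dimensionless
    attenuation_coefficient: float     # dB/cm/MHz
    speed_of_sound: float = 1540.0

    def __post_init__(self):
        if self.scatterer_diameter <= 0 or self.number_density < 0:
            raise ValueError("scatterer diameter must be > 0, density >= 0")
        if self.attenuation_coefficient < 0 or self.speed_of_sound <= 0:
            raise ValueError("attenuation and speed of sound must be >= 0")
        if not self.impedance_contrast ** 2 < 1:
            raise ValueError("gamma0^2 must be < 1 (weak-scattering model)")

    @property
    def gamma0_sq(self) -> float:
        return self.impedance_contrast ** 2


@dataclass(frozen=True)
class ReferencePhantomSpec:
    """Well-characterized reference phantom used for normalization."""

    medium: ScatteringMediumSpec
    attenuation_coefficient: float = 0.8   # dB/cm/MHz
    speed_of_sound: float = 1540.0


def default_reference_phantom() -> ReferencePhantomSpec:
    """Glass-bead-in-gel style phantom: 0.8 dB/cm/MHz, 1540 m/s."""
    medium = ScatteringMediumSpec(
        scatterer_diameter=25.0, number_density=35.0,
        impedance_contrast=0.06, attenuation_coefficient=0.8,
        speed_of_sound=1540.0)
    return ReferencePhantomSpec(medium=medium)


@dataclass(frozen=True)
class FrameGeometry:
    """Imaging-plane extents; ``depth_offset_mm`` is the distance from the
    transducer face to the first recorded sample."""

    depth_extent_mm: float
    width_mm: float
    depth_offset_mm: float = 10.0

    def __post_init__(self):
        if self.depth_extent_mm <= 0 or self.width_mm <= 0:
            raise ValueError("frame extents must be positive")
        if self.depth_offset_mm < 0:
            raise ValueError("depth offset must be >= 0")


@dataclass
class RFFrame:
    """Beamformed RF samples (axial x lateral) plus acquisition geometry."""

    samples: np.ndarray
    system: SystemProfile
    depth_offset_mm: float

    def __post_init__(self):
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (axial x lateral) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lines(self) -> int:
        return self.samples.shape[1]

    @property
    def depth_extent_mm(self) -> float:
        return self.n_samples * self.system.axial_spacing_mm

    def sample_depth_mm(self, sample_index) -> np.ndarray:
        """Depth (mm from the transducer face) of axial sample indices."""
        return self.depth_offset_mm + \
            np.asarray(sample_index) * self.system.axial_spacing_mm


@dataclass
class ROIMask:
    """Tumour-core mask and 5-mm margin ring, in RF-sample coordinates."""

    core: np.ndarray
    margin: np.ndarray
    axial_spacing_mm: float
    lateral_pitch_mm: float

    def __post_init__(self):
        if self.core.shape != self.margin.shape:
            raise ValueError("core and margin masks must share a shape")
        if np.any(self.core & self.margin):
            raise ValueError("core and margin must be disjoint")

    @property
    def union(self) -> np.ndarray:
        return self.core | self.margin


def elliptical_roi(shape, axial_spacing_mm, lateral_pitch_mm, center_mm,
                   axes_mm, margin_mm=5.0):
    """Elliptical tumour core plus a ``margin_mm``-wide surrounding ring.

    ``center_mm`` and ``axes_mm`` are (axial, lateral) positions/semi-axes
    measured from the frame top-left in mm.  The ring is built from the
    Euclidean distance (in mm, anisotropic pixels) to the core.
    """
    n_ax, n_lat = shape
    z = (np.arange(n_ax) + 0.5) * axial_spacing_mm
    x = (np.arange(n_lat) + 0.5) * lateral_pitch_mm
    zz, xx = np.meshgrid(z, x, indexing="ij")
    cz, cx = center_mm
    az, ax_ = axes_mm
    core = ((zz - cz) / az) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0
    dist = ndimage.distance_transform_edt(
        ~core, sampling=(axial_spacing_mm, lateral_pitch_mm))
    margin = (dist > 0) & (dist <= margin_mm)
    return ROIMask(core=core, margin=margin,
                   axial_spacing_mm=axial_spacing_mm,
                   lateral_pitch_mm=lateral_pitch_mm)


# ---------------------------------------------------------------------------
# pulse model
# ---------------------------------------------------------------------------

#: Band edges are interpreted as the -20 dB points of the two-way power
#: spectrum (the conventional pulse-echo -20 dB bandwidth); this keeps
#: >99% of the echo energy inside band +/- 1 MHz even after the f^4
#: backscatter rise shifts the spectrum upward.
BAND_EDGE_DB = 20.0


def pulse_amplitude_spectrum(freq_mhz, system: SystemProfile):
    """Gaussian (in frequency) pulse amplitude spectrum |P(f)|, peak 1."""
    f_lo, f_hi = system.band
    half_band = 0.5 * (f_hi - f_lo)
    # |P|^2 = exp(-(f-fc)^2 / (2 sf^2)) with -BAND_EDGE_DB at the edges
    sf = half_band / math.sqrt(2.0 * BAND_EDGE_DB / 10.0 * math.log(10.0))
    f = np.asarray(freq_mhz, dtype=float)
    return np.exp(-((f - system.center_frequency) ** 2) / (4.0 * sf ** 2))


# ---------------------------------------------------------------------------
# frame synthesis
# ---------------------------------------------------------------------------

def _draw_scatterers(rng, density_per_mm2, depth_extent_mm, width_mm,
                     mask=None, axial_spacing_mm=None, pitch_mm=None):
    """Uniform i.i.d. scatterer positions (z, x) in mm within the frame,
    optionally restricted to a boolean mask in sample coordinates."""
    area = depth_extent_mm * width_mm
    n = rng.poisson(density_per_mm2 * area)
    z = rng.uniform(0.0, depth_extent_mm, size=n)
    x = rng.uniform(0.0, width_mm, size=n)
    if mask is not None:
        iz = np.clip((z / axial_spacing_mm).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip((x / pitch_mm).astype(int), 0, mask.shape[1] - 1)
        keep = mask[iz, ix]
        z, x = z[keep], x[keep]
    return z, x


def _synthesize_lines(spectra, z_mm, x_mm, medium, system, geometry,
                      freqs_mhz, overlying_attenuation):
    """Add one scatterer population's echoes into per-line spectra.

    ``spectra`` is the (n_lines, n_freq) complex accumulator.  Each
    scatterer contributes pulse x form-factor response x two-way
    attenuation x propagation phase, assigned to its nearest scan line.
    """
    if z_mm.size == 0:
        return
    n_lines = spectra.shape[0]
    pitch = system.lateral_pitch
    line_idx = np.clip(np.round(x_mm / pitch - 0.5).astype(int), 0,
                       n_lines - 1)
    # per-population frequency response (pulse x scatterer x units)
    resp = pulse_amplitude_spectrum(freqs_mhz, system) * \
        scatterer_amplitude_response(freqs_mhz, medium.scatterer_diameter,
                                     medium.impedance_contrast,
                                     medium.speed_of_sound)
    spmm = system.samples_per_mm
    # attenuation path per MHz: overlying layer above the frame top plus
    # the in-frame medium down to the scatterer (one-way, dB/MHz)
    path_db_per_mhz = (overlying_attenuation * geometry.depth_offset_mm
                       + medium.attenuation_coefficient * z_mm) / 10.0
    order = np.argsort(line_idx, kind="stable")
    line_sorted = line_idx[order]
    z_sorted = z_mm[order]
    path_sorted = path_db_per_mhz[order]
    bounds = np.searchsorted(line_sorted, np.arange(n_lines + 1))
    two_pi_delay = -2j * np.pi / system.sampling_rate  # per (sample x MHz)
    for li in range(n_lines):
        lo, hi = bounds[li], bounds[li + 1]
        if lo == hi:
            continue
        s_pos = z_sorted[lo:hi] * spmm  # fractional sample delay
        att = attenuation_amplitude(freqs_mhz[None, :],
                                    path_sorted[lo:hi, None])
        phase = np.exp(two_pi_delay * s_pos[:, None] * freqs_mhz[None, :])
        spectra[li] += (att * phase).sum(axis=0) * resp


def simulate_rf_frame(medium, system: SystemProfile, geometry: FrameGeometry,
                      seed, *, regions=None, overlying_attenuation=None):
    """Simulate one beamformed RF frame of a scattering medium.

    Parameters
    ----------
    medium : ScatteringMediumSpec
        Base (background) medium; also sets the in-frame attenuation path.
    regions : list of (mask, ScatteringMediumSpec), optional
        Boolean masks in sample coordinates whose interior scatterers are
        drawn from the alternative medium instead of the base one
        (scattering properties only; the attenuation path uses the base
        medium, a deliberate simplification).
    overlying_attenuation : float, optional
        dB/cm/MHz of the tissue between the transducer face and the frame
        top; defaults to the base medium's coefficient (homogeneous
        half-space, the right choice for phantom frames).

    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    if overlying_attenuation is None:
        overlying_attenuation = medium.attenuation_coefficient
    n_ax = int(round(geometry.depth_extent_mm * system.samples_per_mm))
    n_lines = int(round(geometry.width_mm / system.lateral_pitch))
    if n_ax < 2 or n_lines < 2:
        raise ValueError("frame geometry too small for the system")
    freqs_mhz = np.fft.rfftfreq(n_ax, d=1.0 / system.sampling_rate)
    spectra = np.zeros((n_lines, freqs_mhz.size), dtype=complex)

    region_masks = [m for m, _ in (regions or [])]
    union = None
    if region_masks:
        union = np.zeros((n_ax, n_lines), dtype=bool)
        for m in region_masks:
            union |= m
    # background population (excluded from overridden regions)
    z, x = _draw_scatterers(rng, medium.number_density,
                            geometry.depth_extent_mm, geometry.width_mm)
    if union is not None and z.size:
        iz = np.clip((z * system.samples_per_mm).astype(int), 0, n_ax - 1)
        ix = np.clip((x / system.lateral_pitch).astype(int), 0, n_lines - 1)
        keep = ~union[iz, ix]
        z, x = z[keep], x[keep]
    _synthesize_lines(spectra, z, x, medium, system, geometry, freqs_mhz,
                      overlying_attenuation)
    for mask, med in (regions or []):
        z, x = _draw_scatterers(rng, med.number_density,
                                geometry.depth_extent_mm, geometry.width_mm,
                                mask=mask,
                                axial_spacing_mm=system.axial_spacing_mm,
                                pitch_mm=system.lateral_pitch)
        med_path = replace(med,
                           attenuation_coefficient=medium.attenuation_coefficient)
        _synthesize_lines(spectra, z, x, med_path, system, geometry,
                          freqs_mhz, overlying_attenuation)

    samples = np.fft.irfft(spectra, n=n_ax, axis=1).T.copy()
    return RFFrame(samples=samples, system=system,
                   depth_offset_mm=geometry.depth_offset_mm)


def simulate_reference_frame(phantom: ReferencePhantomSpec,
                             system: SystemProfile, geometry: FrameGeometry,
                             seed) -> RFFrame:
    """Simulate a frame of the homogeneous reference phantom."""
    medium = replace(phantom.medium,
                     attenuation_coefficient=phantom.attenuation_coefficient,
                     speed_of_sound=phantom.speed_of_sound)
    return simulate_rf_frame(medium, system, geometry, seed)


# ---------------------------------------------------------------------------
# response labelling
# ---------------------------------------------------------------------------

def assign_response_label(initial_size, residual_size, cellularity):
    """Clinical/pathological response label and modified-response score.

    Size change is RECIST-style on the longest dimension (cm); residual
    tumour cellularity is a percentage.  A patient is a responder ('R') if
    the size reduction exceeds 30% or cellularity is <= 5%; otherwise a
    non-responder ('NR').  The MR score grades the size change 1-5, with 5
    reserved for no residual tumour; a reduction of exactly 30% grades 2.
    """
    if initial_size < 0 or residual_size < 0:
        raise ValueError("tumour sizes must be >= 0")
    if not 0 <= cellularity <= 100:
        raise ValueError("cellularity must be in [0, 100]%")
    if initial_size == 0:
        raise ValueError("initial size must be > 0 to grade a size change")
    reduction = (initial_size - residual_size) / initial_size
    # strict ">30%"/" >90%" thresholds with a tiny tolerance so that an
    # exactly-30% reduction is graded 2 despite floating-point round-off
    eps = 1e-9
    if residual_size == 0:
        mr_score = 5
    elif reduction > 0.9 + eps:
        mr_score = 4
    elif reduction > 0.3 + eps:
        mr_score = 3
    elif reduction > 0:
        mr_score = 2
    else:
        mr_score = 1
    label = "R" if (reduction > 0.3 + eps or cellularity <= 5) else "NR"
    return label, mr_score


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSet:
    """Reference-phantom frames for one system, shared across a cohort."""

    system: SystemProfile
    phantom: ReferencePhantomSpec
    frames: list


@dataclass
class ScanPlane:
    frame: RFFrame
    roi: ROIMask


@dataclass
class PatientRecord:
    id: str
    planes: list            # of ScanPlane
    reference: ReferenceSet
    initial_size: float     # cm
    residual_size: float    # cm
    cellularity: float      # %
    label: str              # 'R' / 'NR'
    mr_score: int


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort parameters.

    Defaults follow the study conditions the pipeline is meant for: 74
    patients, 42 responders, two acquisition systems (the first covering
    the two sites that contributed 51 of 74 patients), tumour core plus a
    5-mm margin.  ``effect_size`` in [0, 1] scales the microstructural
    difference between responder and non-responder tumours; 0 makes the
    classes identical (null cohort).
    """

    n_patients: int = 74
    responder_fraction: float = 42.0 / 74.0
    seed: int = 0
    effect_size: float = 1.0
    n_planes: int = 3
    system_mix: float = 51.0 / 74.0      # fraction acquired on systems[0]
    systems: tuple = (SONIX_RP, GE_LOGIQ_E9)
    core_diameter_mm: float = 8.0
    margin_mm: float = 5.0
    depth_offset_mm: float = 10.0
    frame_pad_mm: float = 2.0
    n_reference_frames: int = 4
    phantom: ReferencePhantomSpec = field(
        default_factory=default_reference_phantom)
    # background (normal breast tissue) scattering properties
    background: ScatteringMediumSpec = field(default_factory=lambda:
        ScatteringMediumSpec(scatterer_diameter=25.0, number_density=45.0,
                             impedance_contrast=0.04,
                             attenuation_coefficient=1.0))


def _class_media(config: CohortConfig, label: str, rng):
    """Core and margin media for one patient of the given class.

    Responder tumours keep smaller effective scatterers and weaker
    contrast; non-responders drift towards larger scatterers, stronger
    contrast and a patchier margin as ``effect_size`` grows.  Per-patient
    lognormal jitter provides biological variability.
    """
    t = config.effect_size if label == "NR" else 0.0
    a_core = 30.0 * (1.0 + 0.5 * t)          # 30 -> 45 um
    g_core = 0.055 * (1.0 + 0.45 * t)        # 0.055 -> 0.080
    jitter = lambda s: float(np.exp(rng.normal(0.0, s)))
    core = ScatteringMediumSpec(
        scatterer_diameter=a_core * jitter(0.05),
        number_density=60.0 * jitter(0.05),
        impedance_contrast=min(0.5, g_core * jitter(0.07)),
        attenuation_coefficient=1.0)
    bg = config.background
    margin = ScatteringMediumSpec(
        scatterer_diameter=bg.scatterer_diameter * (1 + 0.15 * t) * jitter(0.05),
        number_density=bg.number_density * jitter(0.05),
        impedance_contrast=min(0.5, bg.impedance_contrast
                               * (1 + 0.25 * t) * jitter(0.07)),
        attenuation_coefficient=bg.attenuation_coefficient)
    n_patches = rng.poisson(1.0 + 4.0 * t)
    return core, margin, n_patches


def _sample_outcome(label: str, rng):
    """Sizes (cm) and cellularity (%) consistent with the intended label."""
    initial = float(rng.uniform(2.0, 5.0))
    if label == "R":
        u = rng.uniform()
        if u < 0.25:                       # complete response
            residual, cellularity = 0.0, float(rng.uniform(0.0, 3.0))
        elif u < 0.45:                     # responder on cellularity alone
            residual = initial * float(rng.uniform(0.75, 1.0))
            cellularity = float(rng.uniform(0.0, 5.0))
        else:                              # responder on size reduction
            residual = initial * float(rng.uniform(0.05, 0.65))
            cellularity = float(rng.uniform(0.0, 30.0))
    else:
        residual = initial * float(rng.uniform(0.75, 1.25))
        cellularity = float(rng.uniform(15.0, 90.0))
    return initial, residual, cellularity


def cohort_frame_geometry(config: CohortConfig) -> FrameGeometry:
    extent = (config.core_diameter_mm + 2.0 * config.margin_mm
              + 2.0 * config.frame_pad_mm)
    return FrameGeometry(depth_extent_mm=extent, width_mm=extent,
                         depth_offset_mm=config.depth_offset_mm)


def _patient_planes(config, system, geometry, core_med, margin_med,
                    n_patches, rng):
    """Simulate the patient's scan planes (frame + ROI per plane)."""
    spmm = system.samples_per_mm
    n_ax = int(round(geometry.depth_extent_mm * spmm))
    n_lines = int(round(geometry.width_mm / system.lateral_pitch))
    shape = (n_ax, n_lines)
    center = (geometry.depth_extent_mm / 2.0, geometry.width_mm / 2.0)
    planes = []
    for _ in range(config.n_planes):
        semi = config.core_diameter_mm / 2.0
        axes = (semi * float(rng.uniform(0.85, 1.0)),
                semi * float(rng.uniform(0.85, 1.0)))
        roi = elliptical_roi(shape, system.axial_spacing_mm,
                             system.lateral_pitch, center, axes,
                             margin_mm=config.margin_mm)
        regions = [(roi.core, core_med), (roi.margin, margin_med)]
        # patchy infiltration of the margin: core-like blobs in the ring
        z_idx, x_idx = np.nonzero(roi.margin)
        for _ in range(n_patches):
            if z_idx.size == 0:
                break
            j = int(rng.integers(z_idx.size))
            pz = (z_idx[j] + 0.5) * system.axial_spacing_mm
            px = (x_idx[j] + 0.5) * system.lateral_pitch
            pr = float(rng.uniform(0.8, 1.6))
            zg = (np.arange(n_ax) + 0.5) * system.axial_spacing_mm
            xg = (np.arange(n_lines) + 0.5) * system.lateral_pitch
            patch = ((zg[:, None] - pz) ** 2 + (xg[None, :] - px) ** 2
                     <= pr ** 2) & roi.margin
            regions.append((patch, core_med))
        frame = simulate_rf_frame(
            config.background, system, geometry,
            seed=int(rng.integers(2 ** 31)), regions=regions,
            overlying_attenuation=1.0)
        planes.append(ScanPlane(frame=frame, roi=roi))
    return planes


def generate_cohort(config: CohortConfig):
    """Generate a labelled synthetic cohort of PatientRecords.

    Class counts are exact: ``round(n_patients * responder_fraction)``
    responders.  Reference-phantom frames are simulated once per system
    and shared by every patient scanned on that system.
    """
    if config.n_patients < 4:
        raise ValueError("cohort too small: need n_patients >= 4")
    if not 0.0 < config.responder_fraction < 1.0:
        raise ValueError("responder_fraction must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    geometry = cohort_frame_geometry(config)
    references = {}
    for sys_idx, system in enumerate(config.systems):
        frames = [simulate_reference_frame(
            config.phantom, system, geometry,
            seed=int(rng.integers(2 ** 31)))
            for _ in range(config.n_reference_frames)]
        references[system.name] = ReferenceSet(
            system=system, phantom=config.phantom, frames=frames)

    n_r = int(round(config.n_patients * config.responder_fraction))
    labels = ["R"] * n_r + ["NR"] * (config.n_patients - n_r)
    records = []
    for i, intended in enumerate(labels):
        system = config.systems[0] if rng.uniform() < config.system_mix \
            else config.systems[1 % len(config.systems)]
        core_med, margin_med, n_patches = _class_media(config, intended, rng)
        initial, residual, cellularity = _sample_outcome(intended, rng)
        label, mr_score = assign_response_label(initial, residual,
                                                cellularity)
        assert label == intended, "outcome sampler inconsistent with rules"
        planes = _patient_planes(config, system, geometry, core_med,
                                 margin_med, n_patches, rng)
        records.append(PatientRecord(
            id=f"P{i + 1:03d}", planes=planes,
            reference=references[system.name],
            initial_size=initial, residual_size=residual,
            cellularity=cellularity, label=label, mr_score=mr_score))
    return records
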