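"""Sliding-window spectral estimation and QUS parametric imaging.

The chain per analysis window (2 mm x 2 mm, 94% overlap) is:

1. Hanning-gated per-line periodograms, averaged across the window's scan
   lines (``windowed_power_spectrum``).
2. Reference-phantom normalization with layered attenuation compensation
   (``normalize_and_correct``): the measured backscatter coefficient is

       sigma_m(f) = sigma_r(f) |S_m|^2/|S_r|^2 exp[4(alpha_m-alpha_r)(R+dz/2)]

   with the sample attenuation path composed of a fixed 1 dB/cm/MHz
   overlying-tissue segment and the tumour's estimated coefficient (ACE)
   below the ROI top.
3. Linear parametrization of the attenuation-corrected normalized power
   spectrum giving mid-band fit (MBF), spectral slope (SS) and 0-MHz
   intercept (SI); Gaussian form-factor fitting of the BSC giving average
   scatterer diameter (ASD) and average acoustic concentration (AAC).

The tumour attenuation coefficient is estimated with a spectral-difference
method: the depth-rate of the sample-minus-reference log power at each
in-band frequency is proportional to the excess attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .acoustics import bsc_gaussian
from .synthetic import ReferencePhantomSpec, ReferenceSet, RFFrame, ROIMask

DEFAULT_WINDOW_MM = 2.0
DEFAULT_OVERLAP = 0.94
DEFAULT_NFFT = 256
ASD_SEARCH_BOUNDS_UM = (1.0, 300.0)
OVERLYING_ATTENUATION = 1.0   # dB/cm/MHz assumed for intervening breast tissue

PARAM_NAMES = ("MBF", "SS", "SI", "ASD", "AAC")
PARAM_UNITS = {"MBF": "dB", "SS": "dB/MHz", "SI": "dB",
               "ASD": "um", "AAC": "dB/cm^3"}


# ---------------------------------------------------------------------------
# power spectra
# ---------------------------------------------------------------------------

@dataclass
class PowerSpectrum:
    """Line-averaged window power spectrum (linear power units)."""

    freq_mhz: np.ndarray
    power: np.ndarray
    depth_cm: float        # R: transducer face to window top
    window_len_cm: float   # dz
    n_lines: int

    @property
    def power_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.power)

    @property
    def valid(self) -> bool:
        return bool(np.all(self.power > 0))


def _window_power(samples, nfft):
    """Mean Hanning-gated periodogram across the window's lines.

    ``samples``: (..., n_lines, n_ax) array; returns (..., nfft//2+1).
    """
    gate = np.hanning(samples.shape[-1])
    spec = np.fft.rfft(samples * gate, n=nfft, axis=-1)
    return np.mean(np.abs(spec) ** 2, axis=-2)


def windowed_power_spectrum(frame: RFFrame, axial_start: int,
                            line_start: int, *, window_mm=DEFAULT_WINDOW_MM,
                            n_lines=None, nfft=DEFAULT_NFFT) -> PowerSpectrum:
    """Averaged power spectrum of one analysis window.

    A Hanning gate is applied to each RF line segment along depth, the
    periodogram is computed by FFT and averaged over the window's lines.
    All-zero windows yield zero power (``-inf`` dB; ``valid`` is False).
    """
    system = frame.system
    n_ax = int(round(window_mm * system.samples_per_mm))
    if n_lines is None:
        n_lines = max(2, int(round(window_mm / system.lateral_pitch)))
    if n_lines < 2:
        raise ValueError("window must span at least 2 RF lines")
    if axial_start < 0 or line_start < 0 \
            or axial_start + n_ax > frame.n_samples \
            or line_start + n_lines > frame.n_lines:
        raise ValueError("analysis window falls outside the frame")
    seg = frame.samples[axial_start:axial_start + n_ax,
                        line_start:line_start + n_lines].T
    power = _window_power(seg, max(nfft, n_ax))
    freqs = np.fft.rfftfreq(max(nfft, n_ax), d=1.0 / system.sampling_rate)
    return PowerSpectrum(freq_mhz=freqs, power=power,
                         depth_cm=frame.sample_depth_mm(axial_start) / 10.0,
                         window_len_cm=window_mm / 10.0, n_lines=n_lines)


def _row_batch_power(frame, ax_start, line_starts, n_ax, n_lat, nfft):
    """Window power spectra for one axial row of window positions."""
    idx = line_starts[:, None] + np.arange(n_lat)[None, :]
    seg = frame.samples[ax_start:ax_start + n_ax, :].T[idx]  # (nw, n_lat, n_ax)
    return _window_power(seg, nfft)


def reference_depth_spectra(reference: ReferenceSet, ax_starts, *,
                            window_mm=DEFAULT_WINDOW_MM, nfft=DEFAULT_NFFT):
    """Depth profile of the reference-phantom mean power spectrum.

    Averages laterally non-overlapping windows over every reference frame
    at each requested axial start, returning one PowerSpectrum per depth.
    """
    system = reference.system
    n_ax = int(round(window_mm * system.samples_per_mm))
    n_lat = max(2, int(round(window_mm / system.lateral_pitch)))
    spectra = []
    for a0 in np.atleast_1d(ax_starts):
        acc, count = 0.0, 0
        for frame in reference.frames:
            starts = np.arange(0, frame.n_lines - n_lat + 1, n_lat)
            p = _row_batch_power(frame, int(a0), starts, n_ax, n_lat, nfft)
            acc = acc + p.sum(axis=0)
            count += p.shape[0]
        freqs = np.fft.rfftfreq(nfft, d=1.0 / system.sampling_rate)
        spectra.append(PowerSpectrum(
            freq_mhz=freqs, power=acc / count,
            depth_cm=reference.frames[0].sample_depth_mm(int(a0)) / 10.0,
            window_len_cm=window_mm / 10.0, n_lines=n_lat))
    return spectra


def tumour_depth_spectra(frame: RFFrame, mask, *, window_mm=DEFAULT_WINDOW_MM,
                         nfft=DEFAULT_NFFT, axial_step=None):
    """Laterally-averaged window spectra at successive depths over a mask.

    Windows whose centre pixel lies inside ``mask`` are averaged per axial
    position, giving the depth profile used by the spectral-difference
    attenuation estimator.  Returns (spectra, ax_starts).
    """
    system = frame.system
    n_ax = int(round(window_mm * system.samples_per_mm))
    n_lat = max(2, int(round(window_mm / system.lateral_pitch)))
    if axial_step is None:
        axial_step = n_ax // 2
    spectra, starts_used = [], []
    for a0 in range(0, frame.n_samples - n_ax + 1, axial_step):
        centers_ok = []
        for l0 in range(0, frame.n_lines - n_lat + 1):
            if mask[a0 + n_ax // 2, l0 + n_lat // 2]:
                centers_ok.append(l0)
        if not centers_ok:
            continue
        p = _row_batch_power(frame, a0, np.asarray(centers_ok), n_ax, n_lat,
                             nfft).mean(axis=0)
        freqs = np.fft.rfftfreq(nfft, d=1.0 / system.sampling_rate)
        spectra.append(PowerSpectrum(
            freq_mhz=freqs, power=p,
            depth_cm=frame.sample_depth_mm(a0) / 10.0,
            window_len_cm=window_mm / 10.0, n_lines=n_lat))
        starts_used.append(a0)
    return spectra, np.asarray(starts_used)


# ---------------------------------------------------------------------------
# attenuation
# ---------------------------------------------------------------------------

@dataclass
class AttenuationModel:
    """Layered attenuation path: fixed overlying-tissue coefficient above
    the ROI top, tumour ACE below, and the reference-phantom coefficient
    (all dB/cm/MHz)."""

    tumour_ace: float
    roi_top_cm: float
    overlying: float = OVERLYING_ATTENUATION
    reference: float = 0.8

    def __post_init__(self):
        if min(self.tumour_ace, self.overlying, self.reference) < 0:
            raise ValueError("attenuation coefficients must be >= 0")

    def sample_path_db_per_mhz(self, depth_cm):
        """One-way attenuation per MHz to ``depth_cm`` (transducer face)."""
        z = np.asarray(depth_cm, dtype=float)
        return (self.overlying * np.minimum(z, self.roi_top_cm)
                + self.tumour_ace * np.maximum(0.0, z - self.roi_top_cm))

    def compensation_db(self, freq_mhz, depth_cm):
        """Two-way dB added back at the window centre depth, the dB form
        of the exp[4(alpha_m - alpha_r)(R + dz/2)] compensation factor."""
        f = np.asarray(freq_mhz, dtype=float)
        z = np.asarray(depth_cm, dtype=float)
        return 2.0 * f * (self.sample_path_db_per_mhz(z) - self.reference * z)


def estimate_attenuation_coefficient(sample_spectra, reference_spectra,
                                     band_mhz, reference_attenuation=0.8,
                                     weights=None):
    """Spectral-difference tumour attenuation-coefficient estimate (ACE).

    For each in-band frequency the depth-slope of the sample-minus-
    reference log power equals ``-2 (alpha_m - alpha_r) f`` (dB/cm); the
    per-frequency excess coefficients are averaged over the band and added
    to the reference coefficient.  Optional per-depth ``weights`` (e.g.
    the number of windows averaged at each depth) give a weighted
    least-squares slope.
    """
    if len(sample_spectra) < 3 or len(sample_spectra) != len(reference_spectra):
        raise ValueError(
            "spectral-difference ACE needs >= 3 matched window depths "
            "spanning the ROI (cf. the Labyed & Bigelow window-size "
            "recommendations for clinical linear arrays)")
    freqs = sample_spectra[0].freq_mhz
    band = (freqs >= band_mhz[0]) & (freqs <= band_mhz[1])
    z = np.array([s.depth_cm + s.window_len_cm / 2.0 for s in sample_spectra])
    delta_db = np.stack([s.power_db[band] - r.power_db[band]
                         for s, r in zip(sample_spectra, reference_spectra)])
    w = np.ones_like(z) if weights is None else np.asarray(weights, float)
    zc = z - np.average(z, weights=w)
    denom = np.sum(w * zc ** 2)
    if denom <= 0:
        raise ValueError("window depths must span a non-zero axial extent")
    slopes = (w * zc) @ delta_db / denom           # dB/cm per frequency
    excess = -slopes / (2.0 * freqs[band])         # dB/cm/MHz
    return reference_attenuation + float(np.mean(excess))


# ---------------------------------------------------------------------------
# normalization and spectral fits
# ---------------------------------------------------------------------------

@dataclass
class BSCCurve:
    """Attenuation-corrected normalized power spectrum and measured BSC."""

    freq_mhz: np.ndarray
    nps_db: np.ndarray     # |S_m|^2/|S_r|^2 in dB, attenuation corrected
    bsc: np.ndarray        # sigma_m(f), linear
    sigma_r: np.ndarray    # reference-phantom theoretical BSC

    @property
    def bsc_db(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.bsc)


def reference_bsc(phantom: ReferencePhantomSpec, freq_mhz):
    m = phantom.medium
    return bsc_gaussian(freq_mhz, m.scatterer_diameter, m.number_density,
                        m.gamma0_sq, phantom.speed_of_sound)


def normalize_and_correct(sample: PowerSpectrum, reference: PowerSpectrum,
                          att: AttenuationModel,
                          phantom: ReferencePhantomSpec, *,
                          R=None, dz=None) -> BSCCurve:
    """Reference-phantom normalization with attenuation compensation.

    Evaluates sigma_m(f) = sigma_r(f) |S_m|^2/|S_r|^2
    exp[4 (alpha_m - alpha_r)(R + dz/2)], with the exponent computed in dB
    from the layered sample path; R defaults to the sample window's depth
    and dz to its length.
    """
    if not np.array_equal(sample.freq_mhz, reference.freq_mhz):
        raise ValueError("sample and reference must share a frequency grid")
    if np.any(reference.power <= 0):
        raise ValueError("reference spectrum vanishes inside the grid")
    R = sample.depth_cm if R is None else R
    dz = sample.window_len_cm if dz is None else dz
    with np.errstate(divide="ignore"):
        ratio_db = 10.0 * np.log10(sample.power) \
            - 10.0 * np.log10(reference.power)
    comp = att.compensation_db(sample.freq_mhz, R + dz / 2.0)
    nps_db = ratio_db + comp
    sigma_r = reference_bsc(phantom, sample.freq_mhz)
    return BSCCurve(freq_mhz=sample.freq_mhz, nps_db=nps_db,
                    bsc=sigma_r * 10.0 ** (nps_db / 10.0), sigma_r=sigma_r)


@dataclass
class SpectralFit:
    """Linear-fit spectral parameters; MBF = SI + SS * f_center."""

    mbf: float    # dB, fitted value at the band centre
    ss: float     # dB/MHz
    si: float     # dB, 0-MHz intercept
    band: tuple


def fit_linear_spectrum(freq_mhz, nps_db, band_mhz) -> SpectralFit:
    """Least-squares line through the in-band NPS (dB vs MHz)."""
    freq_mhz = np.asarray(freq_mhz, dtype=float)
    nps_db = np.asarray(nps_db, dtype=float)
    sel = (freq_mhz >= band_mhz[0]) & (freq_mhz <= band_mhz[1])
    if np.count_nonzero(sel) < 5:
        raise ValueError("need >= 5 in-band frequency samples for the fit")
    ss, si = np.polyfit(freq_mhz[sel], nps_db[sel], 1)
    fc = 0.5 * (band_mhz[0] + band_mhz[1])
    return SpectralFit(mbf=float(si + ss * fc), ss=float(ss), si=float(si),
                       band=tuple(band_mhz))


@dataclass
class ScattererFit:
    """Gaussian form-factor fit: effective diameter and concentration."""

    asd_um: float
    aac_db: float          # 10 log10(n gamma0^2), n in mm^-3 convention
    n_gamma2: float
    residual: float        # mean squared dB residual
    at_bound: bool


def _model_db(freq_mhz, a_um, c):
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(bsc_gaussian(freq_mhz, a_um, 1.0, 1.0, c))


def fit_form_factor(freq_mhz, bsc, band_mhz, speed_of_sound=1540.0,
                    a_bounds=ASD_SEARCH_BOUNDS_UM) -> ScattererFit:
    """Fit the Gaussian form-factor BSC model in the log-spectral domain.

    The concentration term enters as a pure dB offset, so for each
    candidate diameter the optimal offset is the mean dB residual; the
    diameter is found by a log-spaced grid search refined with a bounded
    scalar minimization.  A diameter pinned at a search bound is flagged.
    """
    freq_mhz = np.asarray(freq_mhz, dtype=float)
    bsc = np.asarray(bsc, dtype=float)
    sel = (freq_mhz >= band_mhz[0]) & (freq_mhz <= band_mhz[1])
    f = freq_mhz[sel]
    if f.size < 3:
        raise ValueError("need >= 3 in-band frequencies to fit")
    meas = bsc[sel]
    if np.any(meas <= 0):
        raise ValueError("measured BSC must be > 0 over the fit band")
    meas_db = 10.0 * np.log10(meas)

    def cost(log_a):
        d = meas_db - _model_db(f, np.exp(log_a), speed_of_sound)
        return float(np.var(d))

    grid = np.linspace(np.log(a_bounds[0]), np.log(a_bounds[1]), 120)
    costs = [cost(g) for g in grid]
    i = int(np.argmin(costs))
    lo = grid[max(0, i - 1)]
    hi = grid[min(len(grid) - 1, i + 1)]
    if hi > lo:
        res = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        log_a = float(res.x)
    else:
        log_a = float(grid[i])
    a = float(np.exp(log_a))
    diff = meas_db - _model_db(f, a, speed_of_sound)
    offset = float(np.mean(diff))
    span = np.log(a_bounds[1]) - np.log(a_bounds[0])
    at_bound = (log_a - np.log(a_bounds[0]) < 0.01 * span
                or np.log(a_bounds[1]) - log_a < 0.01 * span)
    return ScattererFit(asd_um=a, aac_db=offset,
                        n_gamma2=10.0 ** (offset / 10.0),
                        residual=float(np.mean((diff - offset) ** 2)),
                        at_bound=at_bound)


# ---------------------------------------------------------------------------
# parametric imaging
# ---------------------------------------------------------------------------

def window_grid_1d(extent_mm, kernel_mm=DEFAULT_WINDOW_MM,
                   overlap=DEFAULT_OVERLAP):
    """Window start positions (mm) along one axis for a given overlap.

    step = (1 - overlap) * kernel; count = floor((extent-kernel)/step) + 1.
    """
    if extent_mm < kernel_mm:
        raise ValueError("extent smaller than the analysis kernel")
    step = (1.0 - overlap) * kernel_mm
    n = int(np.floor((extent_mm - kernel_mm) / step + 1e-9)) + 1
    return np.arange(n) * step


@dataclass
class ParametricImage:
    """Per-window map of one QUS parameter on the sliding-window grid."""

    name: str
    values: np.ndarray
    units: str
    valid: np.ndarray
    core: np.ndarray
    margin: np.ndarray
    axial_centers_mm: np.ndarray    # depth from transducer face
    lateral_centers_mm: np.ndarray


@dataclass
class ParametricImageSet:
    """The five QUS parametric images sharing one grid and validity mask."""

    images: dict
    ace: float
    att: AttenuationModel
    window_mm: float
    at_bound: np.ndarray = field(default=None)

    def __getitem__(self, name) -> ParametricImage:
        return self.images[name]

    def __iter__(self):
        return iter(self.images)

    @property
    def valid(self) -> np.ndarray:
        return next(iter(self.images.values())).valid


def _batch_form_factor(meas_db, f, speed_of_sound, a_bounds, n_grid=100):
    """Vectorized grid + parabolic-refinement form-factor fit.

    ``meas_db``: (n_win, n_f) in-band BSC in dB.  Returns (asd_um, aac_db,
    at_bound) arrays.
    """
    log_grid = np.linspace(np.log(a_bounds[0]), np.log(a_bounds[1]), n_grid)
    model = np.stack([_model_db(f, np.exp(g), speed_of_sound)
                      for g in log_grid])                    # (n_a, n_f)
    n_win = meas_db.shape[0]
    best_cost = np.full(n_win, np.inf)
    best_idx = np.zeros(n_win, dtype=int)
    costs = np.empty((n_win, n_grid))
    chunk = 2048
    for s in range(0, n_win, chunk):
        d = meas_db[s:s + chunk, None, :] - model[None, :, :]
        c = d.var(axis=2)
        costs[s:s + chunk] = c
        best_idx[s:s + chunk] = np.argmin(c, axis=1)
        best_cost[s:s + chunk] = np.min(c, axis=1)
    # parabolic refinement of log(a) on the three grid points around the min
    i = np.clip(best_idx, 1, n_grid - 2)
    c0, c1, c2 = (costs[np.arange(n_win), i - 1],
                  costs[np.arange(n_win), i],
                  costs[np.arange(n_win), i + 1])
    denom = c0 - 2 * c1 + c2
    shift = np.where(np.abs(denom) > 1e-30,
                     0.5 * (c0 - c2) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    h = log_grid[1] - log_grid[0]
    log_a = np.clip(log_grid[i] + shift * h,
                    np.log(a_bounds[0]), np.log(a_bounds[1]))
    asd = np.exp(log_a)
    model_best = np.stack([_model_db(f, a, speed_of_sound) for a in asd])
    aac = np.mean(meas_db - model_best, axis=1)
    at_bound = (best_idx == 0) | (best_idx == n_grid - 1)
    return asd, aac, at_bound


def build_parametric_images(frame: RFFrame, roi: ROIMask,
                            reference: ReferenceSet, *,
                            att: AttenuationModel = None,
                            window_mm=DEFAULT_WINDOW_MM,
                            overlap=DEFAULT_OVERLAP,
                            nfft=DEFAULT_NFFT) -> ParametricImageSet:
    """Run the full spectral chain over the ROI's sliding-window grid.

    Window centres must lie inside core-or-margin and the window fully
    inside the frame; other grid pixels are marked invalid.  When ``att``
    is not supplied the tumour ACE is first estimated from the core by the
    spectral-difference method.
    """
    system = frame.system
    band = system.band
    n_ax = int(round(window_mm * system.samples_per_mm))
    n_lat = max(2, int(round(window_mm / system.lateral_pitch)))
    step_mm = (1.0 - overlap) * window_mm
    ax_step = max(1, int(round(step_mm * system.samples_per_mm)))
    lat_step = max(1, int(round(step_mm / system.lateral_pitch)))
    ax_starts = np.arange(0, frame.n_samples - n_ax + 1, ax_step)
    lat_starts = np.arange(0, frame.n_lines - n_lat + 1, lat_step)
    if ax_starts.size == 0 or lat_starts.size == 0:
        raise ValueError("ROI/frame smaller than the analysis kernel")

    union = roi.union
    center_ax = ax_starts + n_ax // 2
    center_lat = lat_starts + n_lat // 2
    member = union[np.ix_(center_ax, center_lat)]
    core_m = roi.core[np.ix_(center_ax, center_lat)]
    margin_m = roi.margin[np.ix_(center_ax, center_lat)]
    if not member.any():
        raise ValueError("no analysis window centre falls inside the ROI")

    freqs = np.fft.rfftfreq(nfft, d=1.0 / system.sampling_rate)
    bsel = (freqs >= band[0]) & (freqs <= band[1])
    f = freqs[bsel]

    rows_needed = np.nonzero(member.any(axis=1))[0]
    ref_spectra = reference_depth_spectra(
        reference, ax_starts[rows_needed], window_mm=window_mm, nfft=nfft)
    ref_db_by_row = {int(r): s.power_db
                     for r, s in zip(rows_needed, ref_spectra)}

    # per-row sample spectra for the in-ROI windows
    pow_db = {}
    roi_row_power = {}
    for ri in rows_needed:
        cols = np.nonzero(member[ri])[0]
        p = _row_batch_power(frame, int(ax_starts[ri]), lat_starts[cols],
                             n_ax, n_lat, nfft)
        with np.errstate(divide="ignore"):
            pow_db[int(ri)] = (cols, 10.0 * np.log10(p))
        roi_row_power[int(ri)] = (p.mean(axis=0), p.shape[0])

    roi_top_cm = frame.sample_depth_mm(
        int(np.nonzero(union.any(axis=1))[0][0])) / 10.0
    if att is None:
        rows = sorted(roi_row_power)
        if len(rows) < 3:
            raise ValueError(
                "ROI spans too few window depths for ACE estimation")
        sample_sp = [PowerSpectrum(
            freq_mhz=freqs, power=roi_row_power[r][0],
            depth_cm=frame.sample_depth_mm(int(ax_starts[r])) / 10.0,
            window_len_cm=window_mm / 10.0, n_lines=n_lat) for r in rows]
        ref_sp = [PowerSpectrum(
            freq_mhz=freqs, power=10 ** (ref_db_by_row[r] / 10.0),
            depth_cm=frame.sample_depth_mm(int(ax_starts[r])) / 10.0,
            window_len_cm=window_mm / 10.0, n_lines=n_lat) for r in rows]
        ace = estimate_attenuation_coefficient(
            sample_sp, ref_sp, band,
            reference_attenuation=reference.phantom.attenuation_coefficient,
            weights=[roi_row_power[r][1] for r in rows])
        att = AttenuationModel(
            tumour_ace=max(0.0, ace), roi_top_cm=roi_top_cm,
            reference=reference.phantom.attenuation_coefficient)
    sigma_r_db = 10.0 * np.log10(reference_bsc(reference.phantom, f))

    shape = (ax_starts.size, lat_starts.size)
    maps = {name: np.full(shape, np.nan) for name in PARAM_NAMES}
    at_bound_map = np.zeros(shape, dtype=bool)
    fc = 0.5 * (band[0] + band[1])
    design = np.vstack([f, np.ones_like(f)]).T
    pinv = np.linalg.pinv(design)
    for ri in rows_needed:
        cols, pdb = pow_db[int(ri)]
        zc = frame.sample_depth_mm(int(ax_starts[ri])) / 10.0 \
            + window_mm / 20.0
        comp = att.compensation_db(f, zc)
        nps = pdb[:, bsel] - ref_db_by_row[int(ri)][bsel] + comp[None, :]
        coef = pinv @ nps.T                       # (2, n_cols)
        maps["SS"][ri, cols] = coef[0]
        maps["SI"][ri, cols] = coef[1]
        maps["MBF"][ri, cols] = coef[1] + coef[0] * fc
        bsc_db = nps + sigma_r_db[None, :]
        asd, aac, ab = _batch_form_factor(bsc_db, f, system.speed_of_sound,
                                          ASD_SEARCH_BOUNDS_UM)
        maps["ASD"][ri, cols] = asd
        maps["AAC"][ri, cols] = aac
        at_bound_map[ri, cols] = ab

    axial_centers = frame.sample_depth_mm(center_ax)
    lateral_centers = (center_lat + 0.5) * system.lateral_pitch
    images = {name: ParametricImage(
        name=name, values=maps[name], units=PARAM_UNITS[name],
        valid=member.copy(), core=core_m.copy(), margin=margin_m.copy(),
        axial_centers_mm=axial_centers, lateral_centers_mm=lateral_centers)
        for name in PARAM_NAMES}
    return ParametricImageSet(images=images, ace=att.tumour_ace, att=att,
                              window_mm=window_mm, at_bound=at_bound_map)
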