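"""Acoustic backscatter models shared by the simulator and the spectral fits.

The scattering model is the spherical Gaussian form-factor family: weak,
spatially-Gaussian impedance fluctuations of effective diameter ``a_eff``
embedded in a homogeneous background.  The theoretical backscatter
coefficient (BSC) is

    sigma(f) = C * f^4 * a_eff^6 * n * gamma0^2 * F(f, a_eff),
    C        = pi^2 / (36 * c^4),

where ``n`` is the scatterer number density, ``gamma0`` the fractional
acoustic-impedance contrast between scatterer and background, ``c`` the
speed of sound and ``F`` the Gaussian form factor describing the departure
from Rayleigh (f^4) scattering at finite scatterer size.
"""

from __future__ import annotations

import numpy as np

#: Gaussian form-factor shape constant (conventional value for the
#: spherical Gaussian scatterer model).
GAUSSIAN_FF_CONSTANT = 0.827

#: dB reference convention for acoustic concentration: n in mm^-3.
#: Absolute offsets are calibration-dependent; all recovery statements in
#: this package are relative, so the convention cancels.


def wavenumber(freq_mhz, speed_of_sound):
    """Acoustic wavenumber k = 2*pi*f/c in rad/m (f in MHz, c in m/s)."""
    return 2.0 * np.pi * np.asarray(freq_mhz, dtype=float) * 1e6 / speed_of_sound


def gaussian_form_factor(freq_mhz, diameter_um, speed_of_sound=1540.0):
    """Spherical Gaussian form factor F(f, a_eff).

    ``diameter_um`` is the effective scatterer *diameter* a_eff in microns;
    the conventional parameterization uses the effective radius a_eff/2:

        F = exp(-0.827 * k^2 * (a_eff/2)^2)

    F -> 1 as a_eff -> 0 (Rayleigh limit).
    """
    k = wavenumber(freq_mhz, speed_of_sound)
    radius_m = 0.5 * np.asarray(diameter_um, dtype=float) * 1e-6
    return np.exp(-GAUSSIAN_FF_CONSTANT * (k * radius_m) ** 2)


def bsc_gaussian(freq_mhz, diameter_um, number_density_mm3, gamma0_sq,
                 speed_of_sound=1540.0):
    """Theoretical BSC of the Gaussian form-factor model.

    Parameters
    ----------
    freq_mhz : array_like
        Frequencies in MHz.
    diameter_um : float
        Effective scatterer diameter a_eff (microns).
    number_density_mm3 : float
        Scatterer number density n (per mm^3 by convention).
    gamma0_sq : float
        Squared fractional impedance contrast gamma0^2.
    speed_of_sound : float
        Longitudinal speed of sound c_l (m/s).

    Returns
    -------
    ndarray
        sigma(f) in internally consistent units (1/(m sr) up to the n
        unit convention).  Ratios and dB differences are meaningful;
        absolute calibration is not claimed.
    """
    f_hz = np.asarray(freq_mhz, dtype=float) * 1e6
    a_m = float(diameter_um) * 1e-6
    n = float(number_density_mm3) * 1e9  # nominal mm^-3 -> m^-3
    prefac = np.pi ** 2 / 36.0
    ff = gaussian_form_factor(freq_mhz, diameter_um, speed_of_sound)
    return (prefac * (f_hz / speed_of_sound) ** 4 * a_m ** 6
            * n * float(gamma0_sq) * ff)


def scatterer_amplitude_response(freq_mhz, diameter_um, gamma0,
                                 speed_of_sound=1540.0):
    """Per-scatterer echo amplitude spectrum, sqrt of the unit-density BSC.

    Used by the RF simulator so that the ensemble-average power spectrum
    of a simulated medium is proportional to its theoretical BSC, with the
    same constant of proportionality for every medium (the constant then
    cancels in reference-phantom normalization).
    """
    sigma_unit = bsc_gaussian(freq_mhz, diameter_um, 1.0, gamma0 ** 2,
                              speed_of_sound)
    return np.sqrt(sigma_unit)


def attenuation_amplitude(freq_mhz, path_db_per_mhz):
    """Two-way attenuation amplitude factor.

    ``path_db_per_mhz`` is the accumulated one-way attenuation per MHz
    (sum over path segments of alpha[dB/cm/MHz] * length[cm]).
    """
    total_db = 2.0 * np.asarray(path_db_per_mhz, dtype=float) * \
        np.asarray(freq_mhz, dtype=float)
    return 10.0 ** (-total_db / 20.0)
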