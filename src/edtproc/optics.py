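"""Acquisition-planning utilities: electron wavelength, diffraction-limited
probe size, and equal-dose exposure scaling.

All three are small closed forms used when setting up a nano-beam
diffraction experiment: the relativistic de Broglie wavelength fixes the
Ewald-sphere radius, the Airy FWHM gives the smallest usable probe for a
given convergence semi-angle, and the quadratic exposure rule keeps the
dose per illuminated area constant when the probe diameter changes.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import constants

from .errors import ConfigurationError

__all__ = ["OpticsParams", "electron_wavelength", "probe_fwhm", "equal_dose_exposure"]

#: Airy-disk FWHM prefactor: FWHM = 0.51 * lambda / alpha (aberration-free).
AIRY_FWHM_CONST = 0.51


@dataclass
class OpticsParams:
    """Probe-forming parameters of a quasi-parallel STEM diffraction setup."""

    voltage_kV: float
    alpha_mrad: float
    probe_d_nm: float
    wavelength_A: float

    def __post_init__(self) -> None:
        if self.voltage_kV <= 0 or self.alpha_mrad <= 0:
            raise ConfigurationError("voltage and convergence angle must be positive")

    @classmethod
    def from_setup(cls, voltage_kV: float, alpha_mrad: float) -> "OpticsParams":
        lam = electron_wavelength(voltage_kV)
        return cls(voltage_kV, alpha_mrad, probe_fwhm(voltage_kV, alpha_mrad), lam)


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistically corrected electron wavelength in Angstrom.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2))), CODATA constants.
    """
    if not (1.0 <= voltage_kV <= 3000.0):
        raise ConfigurationError(f"voltage {voltage_kV} kV outside the supported 1-3000 kV range")
    V = voltage_kV * 1e3
    h = constants.h
    m0 = constants.m_e
    e = constants.e
    c = constants.c
    p = (2 * m0 * e * V * (1 + e * V / (2 * m0 * c * c))) ** 0.5
    return h / p * 1e10


def probe_fwhm(voltage_kV: float, alpha_mrad: float) -> float:
    """Diffraction-limited probe diameter (FWHM, nm) for convergence
    semi-angle ``alpha_mrad``."""
    if alpha_mrad <= 0:
        raise ConfigurationError("convergence semi-angle must be positive")
    lam_nm = electron_wavelength(voltage_kV) * 0.1
    return AIRY_FWHM_CONST * lam_nm / (alpha_mrad * 1e-3)


def equal_dose_exposure(t_ref_s: float, d_ref_nm: float, d_new_nm: float) -> float:
    """Exposure time giving the same dose per unit area when the probe
    diameter changes from ``d_ref_nm`` to ``d_new_nm`` at equal beam current:
    t_new = t_ref * (d_new / d_ref)**2."""
    if min(t_ref_s, d_ref_nm, d_new_nm) <= 0:
        raise ConfigurationError("exposure scaling needs positive inputs")
    return t_ref_s * (d_new_nm / d_ref_nm) ** 2
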