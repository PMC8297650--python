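"""Spectra, photon conversions, biological weighting and cumulative UV doses.

Irradiance is carried in W m^-2 (band-integrated) or W m^-2 nm^-1 (spectral);
doses in kJ m^-2. A biologically effective (BE) dose weights the spectral
irradiance by a plant action spectrum before time integration, so for a fixed
lamp spectrum the BE dose is a constant factor times the unweighted dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

# CODATA 2018 exact values
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m s^-1
AVOGADRO = 6.02214076e23  # mol^-1

__all__ = [
    "Band",
    "Spectrum",
    "ActionSpectrum",
    "ExposureSchedule",
    "DoseSummary",
    "UV_BAND",
    "UVB_BAND",
    "PAR_BAND",
    "gaussian_led_spectrum",
    "band_integrate",
    "photon_flux",
    "spectral_photon_flux",
    "plant_action_spectrum",
    "be_factor",
    "calibrate_be_factor",
    "effective_irradiance_from_dose",
    "cumulative_dose",
    "daily_light_integral",
    "treatment_grid",
]


@dataclass(frozen=True)
class Band:
    """Half-open wavelength interval [lo, hi) in nm."""

    lo: float
    hi: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band requires lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, wavelength_nm: float) -> bool:
        return self.lo <= wavelength_nm < self.hi


#: Simulation-reporting UV band (250-400 nm), UV-B dose band (280-315 nm) and
#: the photosynthetically active band (400-700 nm).
UV_BAND = Band(250.0, 400.0, "UV")
UVB_BAND = Band(280.0, 315.0, "UVB")
PAR_BAND = Band(400.0, 700.0, "PAR")


@dataclass(frozen=True)
class Spectrum:
    """Spectral irradiance E(lambda) on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    irradiance_W_m2_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ee = np.asarray(self.irradiance_W_m2_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least 2 wavelength points")
        if wl.shape != ee.shape:
            raise ValueError("wavelength and irradiance grids differ in length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(ee < 0):
            raise ValueError("spectral irradiance must be non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "irradiance_W_m2_nm", ee)

    def total(self) -> float:
        """Trapezoidal integral over the full native grid, W m^-2."""
        return float(np.trapezoid(self.irradiance_W_m2_nm, self.wavelengths_nm))

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1])

    def to_csv(self, path) -> None:
        header = "wavelength_nm,irradiance_W_m2_nm"
        np.savetxt(
            path,
            np.column_stack([self.wavelengths_nm, self.irradiance_W_m2_nm]),
            delimiter=",",
            header=header,
            comments="",
        )


@dataclass(frozen=True)
class ActionSpectrum:
    """Dimensionless biological weighting eps(lambda), eps(300 nm) = 1."""

    weight: Callable[[np.ndarray], np.ndarray]
    name: str = "generalized-plant"

    def __call__(self, wavelength_nm) -> np.ndarray:
        return self.weight(np.asarray(wavelength_nm, dtype=float))


@dataclass(frozen=True)
class ExposureSchedule:
    """UV exposure timing: hours per day over a number of days."""

    hours_per_day: float
    n_days: int
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.hours_per_day <= 24:
            raise ValueError("hours_per_day must lie in [0, 24]")
        if self.n_days < 0:
            raise ValueError("n_days must be >= 0")
        if not self.label:
            object.__setattr__(
                self, "label", f"{self.n_days} d {self.hours_per_day:g} h"
            )

    @property
    def total_seconds(self) -> float:
        return self.hours_per_day * 3600.0 * self.n_days


@dataclass(frozen=True)
class DoseSummary:
    """Cumulative unweighted and biologically effective doses, kJ m^-2."""

    unweighted_kJ_m2: float
    be_factor: float
    label: str = ""
    be_kJ_m2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.unweighted_kJ_m2 < 0:
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "be_kJ_m2", self.be_factor * self.unweighted_kJ_m2)


def gaussian_led_spectrum(
    peak_nm: float,
    fwhm_nm: float,
    total_irradiance_W_m2: float,
    lo_nm: float = 250.0,
    hi_nm: float = 400.0,
    step_nm: float = 0.25,
) -> Spectrum:
    """Gaussian emission line of an LED, normalised to a total irradiance.

    The grid spans [lo_nm, hi_nm]; the discrete trapezoidal integral is
    renormalised to ``total_irradiance_W_m2`` so the construction is exact on
    its own grid rather than only in the continuum limit.
    """
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    if total_irradiance_W_m2 < 0:
        raise ValueError("total irradiance must be non-negative")
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    wl = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm)
    if peak_nm not in wl:  # keep the argmax exactly at the peak
        wl = np.sort(np.append(wl, peak_nm))
    ee = np.exp(-0.5 * ((wl - peak_nm) / sigma) ** 2)
    area = np.trapezoid(ee, wl)
    ee *= total_irradiance_W_m2 / area if area > 0 else 0.0
    return Spectrum(wl, ee)


def band_integrate(spectrum: Spectrum, band: Band) -> float:
    """Trapezoidal integral of spectral irradiance over a band, W m^-2.

    The band edges are interpolated onto the spectrum grid; an empty overlap
    integrates to 0 with a warning.
    """
    wl = spectrum.wavelengths_nm
    ee = spectrum.irradiance_W_m2_nm
    lo = max(band.lo, wl[0])
    hi = min(band.hi, wl[-1])
    if lo >= hi:
        warnings.warn(
            f"band [{band.lo}, {band.hi}) does not overlap spectrum support",
            stacklevel=2,
        )
        return 0.0
    inside = (wl > lo) & (wl < hi)
    grid = np.concatenate([[lo], wl[inside], [hi]])
    vals = np.interp(grid, wl, ee)
    return float(np.trapezoid(vals, grid))


def photon_flux(irradiance_W_m2: float, wavelength_nm: float) -> float:
    """Monochromatic photon flux in umol m^-2 s^-1.

    flux = E * lambda / (h c N_A); 1 W m^-2 at 310 nm is 2.591 umol m^-2 s^-1.
    """
    if irradiance_W_m2 < 0:
        raise ValueError("irradiance must be non-negative")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    lam = wavelength_nm * 1e-9
    mol_per_J = lam / (PLANCK_H * SPEED_OF_LIGHT * AVOGADRO)
    return irradiance_W_m2 * mol_per_J * 1e6


def spectral_photon_flux(spectrum: Spectrum, band: Band) -> float:
    """Band photon flux in umol m^-2 s^-1, integrating E(l)*l/(h c N_A)."""
    wl = spectrum.wavelengths_nm
    weighted = Spectrum(wl, spectrum.irradiance_W_m2_nm * wl * 1e-9)
    integral = band_integrate(weighted, band)  # W m^-2 * m
    return integral / (PLANCK_H * SPEED_OF_LIGHT * AVOGADRO) * 1e6


# Generalized plant action spectrum (Caldwell), Green's analytic form:
# eps(l) = 2.618 [1 - (l/313.3)^2] exp(-(l-300)/31.08) for l < 313.3 nm else 0,
# renormalised here so eps(300) = 1.
_GREEN_CUTOFF_NM = 313.3


def _green_raw(wl: np.ndarray) -> np.ndarray:
    val = 2.618 * (1.0 - (wl / _GREEN_CUTOFF_NM) ** 2) * np.exp(-(wl - 300.0) / 31.08)
    return np.where(wl < _GREEN_CUTOFF_NM, np.maximum(val, 0.0), 0.0)


_GREEN_AT_300 = float(_green_raw(np.array([300.0]))[0])


def plant_action_spectrum(wavelength_nm) -> np.ndarray | float:
    """Generalized plant action spectrum weight, normalised to 1 at 300 nm.

    Zero at and above the 313.3 nm cutoff. Scalar in, scalar out.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    out = _green_raw(wl) / _GREEN_AT_300
    return float(out) if np.isscalar(wavelength_nm) else out


GENERALIZED_PLANT_SPECTRUM = ActionSpectrum(plant_action_spectrum)


def be_factor(
    spectrum: Spectrum, action: ActionSpectrum = GENERALIZED_PLANT_SPECTRUM
) -> float:
    """Spectrum-averaged biological effectiveness: int(eps E) / int(E)."""
    wl = spectrum.wavelengths_nm
    total = spectrum.total()
    if total <= 0:
        raise ValueError("spectrum integrates to zero")
    weighted = float(np.trapezoid(action(wl) * spectrum.irradiance_W_m2_nm, wl))
    return weighted / total


def calibrate_be_factor(unweighted_dose_kJ_m2: float, be_dose_kJ_m2: float) -> float:
    """Effectiveness factor implied by a printed (unweighted, BE) dose pair."""
    if unweighted_dose_kJ_m2 <= 0:
        raise ValueError("unweighted dose must be positive")
    return be_dose_kJ_m2 / unweighted_dose_kJ_m2


def effective_irradiance_from_dose(
    dose_kJ_m2: float, schedule: ExposureSchedule
) -> float:
    """Irradiance (W m^-2) implied by a cumulative dose over a schedule."""
    secs = schedule.total_seconds
    if secs <= 0:
        raise ValueError("schedule has zero exposure time")
    return dose_kJ_m2 * 1000.0 / secs


def cumulative_dose(
    effective_irradiance_W_m2: float, schedule: ExposureSchedule
) -> float:
    """Cumulative dose, kJ m^-2: irradiance x hours/day x 3600 x days / 1000."""
    if effective_irradiance_W_m2 < 0:
        raise ValueError("irradiance must be non-negative")
    return effective_irradiance_W_m2 * schedule.total_seconds / 1000.0


def daily_light_integral(ppfd_umol_m2_s: float, hours_per_day: float) -> float:
    """Daily light integral, mol m^-2 d^-1, from a constant photon flux."""
    return ppfd_umol_m2_s * hours_per_day * 3600.0 / 1e6


def treatment_grid() -> list[ExposureSchedule]:
    """The six-treatment cross {6, 12} h/day x {1, 2, 3} days."""
    return [
        ExposureSchedule(hours, days, f"{days} d {hours:g} h")
        for days in (1, 2, 3)
        for hours in (6.0, 12.0)
    ]


def dose_summary(
    effective_irradiance_W_m2: float,
    schedule: ExposureSchedule,
    be: float,
) -> DoseSummary:
    dose = cumulative_dose(effective_irradiance_W_m2, schedule)
    return DoseSummary(dose, be, label=schedule.label)
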