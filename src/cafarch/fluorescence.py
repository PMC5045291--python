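"""Fluorescence observables: anisotropy, quench correction, FRET-effect
spectral extraction, and the pyrene excimer-band ratio.

Anisotropy is computed from the four polarized intensities with the grating
factor G = I_HV / I_HH:

    r = (I_VV - G I_VH) / (I_VV + 2 G I_VH)

When binding quenches the fluorophore by more than ~10%, the raw anisotropy
is intensity-biased toward the brighter species; the correction inverts the
intensity weighting given the free/saturated endpoint anisotropies and
intensities.

The FRET Effect (acceptor-enhancement method) is the ratio F_385/F_491: the
acceptor emission extracted from a dual-labeled spectrum excited in the
donor band, over the acceptor emission under direct acceptor excitation.
Extraction fits the donor-only spectrum to the dual-labeled spectrum over a
donor-only window by a single scale factor and subtracts it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolarizedIntensities",
    "QuenchCorrectionInputs",
    "Spectrum",
    "SpectraSet",
    "FretResult",
    "anisotropy",
    "quench_corrected_anisotropy",
    "quench_flag",
    "fret_effect",
    "excimer_ratio",
]

#: Default wavelength window (nm) over which the donor-only spectrum is
#: scaled to the dual-labeled spectrum (donor band, below substantial
#: acceptor emission).
DONOR_FIT_WINDOW = (400.0, 480.0)
#: Default window (nm) over which acceptor emission is integrated.
ACCEPTOR_WINDOW = (500.0, 560.0)


@dataclass
class PolarizedIntensities:
    """Four polarizer-orientation intensities (V/H excitation x emission)."""

    i_vv: float
    i_vh: float
    i_hv: float
    i_hh: float

    def __post_init__(self) -> None:
        if min(self.i_vv, self.i_vh, self.i_hv, self.i_hh) < 0:
            raise ValueError("intensities must be nonnegative")
        if self.i_hh <= 0:
            raise ValueError("i_hh must be positive (grating factor undefined)")


@dataclass
class QuenchCorrectionInputs:
    """Observed anisotropy plus free/saturated endpoint anisotropies and intensities."""

    a_obs: float
    a_free: float
    a_bound: float
    q_free: float
    q_bound: float

    def __post_init__(self) -> None:
        if self.a_free == self.a_bound:
            raise ValueError("a_free and a_bound must differ")
        if self.q_free <= 0 or self.q_bound <= 0:
            raise ValueError("endpoint intensities must be positive")
        lo, hi = sorted((self.a_free, self.a_bound))
        if not (lo <= self.a_obs <= hi):
            raise ValueError("a_obs must lie between a_free and a_bound")


@dataclass
class Spectrum:
    """Paired wavelength (nm, strictly increasing) and intensity arrays."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValueError("spectrum needs at least two wavelength points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.intensity.shape != self.wavelength_nm.shape:
            raise ValueError("intensity length must match wavelength length")

    def resample(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(grid, np.interp(grid, self.wavelength_nm, self.intensity))


@dataclass
class SpectraSet:
    """The three emission spectra used by the acceptor-enhancement method.

    donor_only_ex_d : donor-only sample, donor-band excitation (385 nm)
    dual_ex_d       : dual-labeled sample, donor-band excitation (385 nm)
    dual_ex_a       : dual-labeled sample, direct acceptor excitation (491 nm)
    """

    donor_only_ex_d: Spectrum
    dual_ex_d: Spectrum
    dual_ex_a: Spectrum
    meta: dict = field(default_factory=dict)


@dataclass
class FretResult:
    fret_effect: float
    scale: float
    extracted: Spectrum
    f_385: float
    f_491: float
    warnings: list = field(default_factory=list)


def anisotropy(p: PolarizedIntensities) -> float:
    """Anisotropy from polarized intensities with grating-factor correction."""
    g = p.i_hv / p.i_hh
    denom = p.i_vv + 2.0 * g * p.i_vh
    if denom <= 0:
        raise ValueError("total intensity denominator is zero")
    return (p.i_vv - g * p.i_vh) / denom


def quench_flag(q_free: float, q_bound: float, *, threshold: float = 0.10) -> bool:
    """Advisory flag: True when binding changes the fluorophore intensity by
    more than ``threshold`` (fractional), i.e. quench correction is warranted."""
    if q_free <= 0:
        raise ValueError("q_free must be positive")
    return abs(q_bound - q_free) / q_free > threshold


def quench_corrected_anisotropy(q: QuenchCorrectionInputs) -> float:
    """Quench-corrected anisotropy.

    Inverts the intensity weighting of the observed anisotropy:

        x = ((A - A_f)/(A_b - A)) * (Q_f/Q_b)
        r = (x * A_b + A_f) / (1 + x)

    Identity r = A when Q_f = Q_b; r -> A_f at the free endpoint. A = A_b is
    singular (the ratio diverges at the saturation endpoint).
    """
    if q.a_obs == q.a_bound:
        raise ValueError("a_obs equals a_bound (saturation endpoint): correction is singular")
    x = ((q.a_obs - q.a_free) / (q.a_bound - q.a_obs)) * (q.q_free / q.q_bound)
    return (x * q.a_bound + q.a_free) / (1.0 + x)


def _window_mask(wl: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    mask = (wl >= lo) & (wl <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} not contained in spectrum range "
                         f"({wl[0]:g}-{wl[-1]:g} nm)")
    return mask


def fret_effect(
    s: SpectraSet,
    *,
    donor_fit_window: tuple[float, float] = DONOR_FIT_WINDOW,
    acceptor_window: tuple[float, float] = ACCEPTOR_WINDOW,
    negative_tol: float = 1e-6,
) -> FretResult:
    """Acceptor-enhancement FRET Effect = F_385 / F_491.

    The donor-only spectrum is fitted to the dual-labeled (donor-excited)
    spectrum by a least-squares scale over ``donor_fit_window``; the scaled
    donor is subtracted and the residual acceptor emission is integrated
    over ``acceptor_window`` (F_385). F_491 is the direct-excitation
    acceptor spectrum integrated over the same window.
    """
    grid = s.dual_ex_d.wavelength_nm
    donor = s.donor_only_ex_d.resample(grid)
    dual = s.dual_ex_d

    mask = _window_mask(grid, donor_fit_window)
    d = donor.intensity[mask]
    m = dual.intensity[mask]
    denom = float(np.dot(d, d))
    if denom <= 0:
        raise ValueError("donor-only spectrum is zero over the donor-fit window")
    scale = float(np.dot(d, m) / denom)

    extracted = Spectrum(grid, dual.intensity - scale * donor.intensity)

    amask = _window_mask(grid, acceptor_window)
    f385 = float(np.trapezoid(extracted.intensity[amask], grid[amask]))

    wa = s.dual_ex_a.wavelength_nm
    amask_a = _window_mask(wa, acceptor_window)
    f491 = float(np.trapezoid(s.dual_ex_a.intensity[amask_a], wa[amask_a]))
    if f491 <= 0:
        raise ValueError("no direct acceptor signal (F_491 <= 0)")

    warns: list[str] = []
    ratio = f385 / f491
    if ratio < -negative_tol:
        msg = f"extracted acceptor integral is negative (FRET Effect {ratio:.3g})"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)
    return FretResult(fret_effect=ratio, scale=scale, extracted=extracted,
                      f_385=f385, f_491=f491, warnings=warns)


def excimer_ratio(
    spectrum: Spectrum,
    band_center: float = 465.0,
    reference_center: float = 375.0,
    *,
    half_width: float = 5.0,
) -> float:
    """Ratio of mean intensity around the pyrene excimer band (~465 nm) to the
    monomer reference band (~375 nm); reports pyrene–pyrene proximity."""
    wl, inten = spectrum.wavelength_nm, spectrum.intensity
    band = inten[_window_mask(wl, (band_center - half_width, band_center + half_width))]
    ref = inten[_window_mask(wl, (reference_center - half_width, reference_center + half_width))]
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError("reference window mean intensity is not positive")
    return float(band.mean()) / ref_mean
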