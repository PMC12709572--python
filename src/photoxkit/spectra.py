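"""Optical spectra: containers, CSV I/O, indices, and light-absorption rate.

Absorbance spectra are decadic absorbance on a strictly increasing nm grid;
excitation-emission matrices (EEMs) carry an optional boolean mask marking
excised (e.g. scatter) cells.  All fluorescence indices are intensity ratios
and therefore invariant to the (arbitrary) linear units of the EEM.

The wavelength-integrated rate of light absorption

    Ra = integral  E(lambda) * (1 - 10**(-A(lambda) * path)) dlambda

couples an absorbance spectrum with a volumetric photon-flux spectrum
E (mol photons L-1 s-1 nm-1) and is the denominator of every apparent
quantum yield.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_INDEX_DEFS, IndexDefinitions

__all__ = [
    "AbsorbanceSpectrum",
    "EEMSpectrum",
    "PhotonFluxSpectrum",
    "OpticalIndices",
    "SpectrumParseError",
    "read_absorbance",
    "read_eem",
    "read_flux",
    "e2_e3",
    "suva254",
    "fluorescence_indices",
    "compute_indices",
    "rate_light_absorption",
    "irradiance_to_volumetric_flux",
]

AVOGADRO = 6.02214076e23
PLANCK = 6.62607015e-34
LIGHTSPEED = 2.99792458e8


class SpectrumParseError(ValueError):
    """Raised when a spectrum file violates the expected CSV dialect."""


def _check_grid(wavelengths: np.ndarray, what: str) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise SpectrumParseError(f"{what}: need at least two wavelengths")
    if not np.all(np.diff(w) > 0):
        raise SpectrumParseError(f"{what}: wavelengths must be strictly increasing")
    return w


@dataclass
class AbsorbanceSpectrum:
    """Decadic absorbance vs wavelength for a stated path length (cm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths, "absorbance spectrum")
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != self.wavelengths.shape:
            raise SpectrumParseError("absorbance/wavelength length mismatch")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectrumParseError("absorbance values must be finite")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be > 0")

    def at(self, nm: float | np.ndarray) -> np.ndarray:
        """Absorbance linearly interpolated at ``nm`` (per stated path)."""
        nm = np.asarray(nm, dtype=float)
        if np.any(nm < self.wavelengths[0]) or np.any(nm > self.wavelengths[-1]):
            raise ValueError("wavelength outside spectral coverage")
        return np.interp(nm, self.wavelengths, self.absorbance)

    def per_cm(self, nm: float | np.ndarray) -> np.ndarray:
        return self.at(nm) / self.path_length_cm

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "absorbance_per_cm": self.absorbance / self.path_length_cm}
        ).to_csv(path, index=False)


@dataclass
class EEMSpectrum:
    """Excitation-emission matrix; intensity[i, j] at (ex_grid[i], em_grid[j])."""

    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray | None = None  # True = excised/missing

    def __post_init__(self) -> None:
        self.ex_grid = _check_grid(self.ex_grid, "EEM excitation grid")
        self.em_grid = _check_grid(self.em_grid, "EEM emission grid")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.ex_grid.size, self.em_grid.size):
            raise SpectrumParseError("EEM matrix shape does not match grids")
        if self.mask is None:
            self.mask = np.zeros_like(self.intensity, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensity.shape:
                raise SpectrumParseError("EEM mask shape does not match matrix")
        if np.any(self.intensity[~self.mask] < 0):
            raise ValueError("EEM intensities must be >= 0 on unmasked cells")

    def write_csv(self, path: str | Path) -> None:
        # first row: emission grid; first column: excitation grid; masked -> empty
        vals = np.where(self.mask, np.nan, self.intensity)
        df = pd.DataFrame(vals, columns=[f"{em:g}" for em in self.em_grid])
        df.insert(0, "ex_nm\\em_nm", [f"{ex:g}" for ex in self.ex_grid])
        df.to_csv(path, index=False, na_rep="")


@dataclass
class PhotonFluxSpectrum:
    """Volumetric photon flux of the lamp, mol photons L-1 s-1 nm-1."""

    wavelengths: np.ndarray
    flux: np.ndarray
    cutoff_nm: float = 300.0

    def __post_init__(self) -> None:
        self.wavelengths = _check_grid(self.wavelengths, "photon flux spectrum")
        self.flux = np.asarray(self.flux, dtype=float)
        if self.flux.shape != self.wavelengths.shape:
            raise SpectrumParseError("flux/wavelength length mismatch")
        if np.any(self.flux < 0):
            raise ValueError("photon flux must be >= 0")
        below = self.wavelengths < self.cutoff_nm
        if np.any(self.flux[below] > 0):
            raise ValueError(f"flux must be zero below the {self.cutoff_nm} nm cutoff")

    def at(self, nm: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(nm, dtype=float), self.wavelengths, self.flux, left=0.0, right=0.0)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths, "photon_flux": self.flux}).to_csv(path, index=False)


@dataclass
class OpticalIndices:
    """Optical/fluorescence indices for one sample; NaN + flag when undefined."""

    e2_e3: float = math.nan
    suva254: float = math.nan
    bix: float = math.nan
    fix: float = math.nan
    hix: float = math.nan
    undefined: set = field(default_factory=set)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("e2_e3", "suva254", "bix", "fix", "hix")}
        for k in ("e2_e3", "suva254", "bix", "fix", "hix"):
            d[f"{k}_undefined"] = k in self.undefined
        return d


# ---------------------------------------------------------------- file I/O


def _read_two_column(path: str | Path, col0: str, col1_prefix: str) -> tuple[np.ndarray, np.ndarray]:
    p = Path(path)
    text = p.read_text()
    if not text.strip():
        raise SpectrumParseError(f"{p}: empty file")
    df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != col0 or not str(df.columns[1]).startswith(col1_prefix):
        raise SpectrumParseError(f"{p}: expected header '{col0},{col1_prefix}...'")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def read_absorbance(path: str | Path, path_length_cm: float = 1.0) -> AbsorbanceSpectrum:
    """Read a two-column ``wavelength_nm,absorbance_per_cm`` CSV."""
    w, a = _read_two_column(path, "wavelength_nm", "absorbance")
    return AbsorbanceSpectrum(w, a * path_length_cm, path_length_cm)


def read_flux(path: str | Path, cutoff_nm: float = 300.0) -> PhotonFluxSpectrum:
    """Read a two-column ``wavelength_nm,photon_flux`` CSV."""
    w, f = _read_two_column(path, "wavelength_nm", "photon_flux")
    return PhotonFluxSpectrum(w, f, cutoff_nm=cutoff_nm)


def read_eem(path: str | Path) -> EEMSpectrum:
    """Read an EEM CSV (emission grid in header, excitation grid in column 0)."""
    p = Path(path)
    text = p.read_text()
    if not text.strip():
        raise SpectrumParseError(f"{p}: empty file")
    df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
    if df.shape[1] < 2 or not str(df.columns[0]).startswith("ex_nm"):
        raise SpectrumParseError(f"{p}: expected 'ex_nm\\em_nm' header")
    try:
        em = np.array([float(c) for c in df.columns[1:]])
        ex = df.iloc[:, 0].to_numpy(float)
    except ValueError as exc:
        raise SpectrumParseError(f"{p}: non-numeric grid values") from exc
    vals = df.iloc[:, 1:].to_numpy(float)
    mask = ~np.isfinite(vals)
    vals = np.where(mask, 0.0, vals)
    return EEMSpectrum(ex, em, vals, mask)


# ---------------------------------------------------------------- indices


def e2_e3(spectrum: AbsorbanceSpectrum, defs: IndexDefinitions = DEFAULT_INDEX_DEFS) -> tuple[float, bool]:
    """A(250)/A(365) chromophore-size ratio; returns (value, undefined_flag)."""
    a250 = float(spectrum.at(defs.e2_nm))
    a365 = float(spectrum.at(defs.e3_nm))
    if a365 <= 0:
        return math.nan, True
    return a250 / a365, False


def suva254(spectrum: AbsorbanceSpectrum, doc_mg_l: float, defs: IndexDefinitions = DEFAULT_INDEX_DEFS) -> float:
    """DOC-normalized UV absorbance at 254 nm, L mg-C-1 m-1 (= 100*A_cm/DOC)."""
    if doc_mg_l <= 0:
        raise ValueError("DOC must be > 0 for SUVA254")
    return 100.0 * float(spectrum.per_cm(defs.suva_nm)) / doc_mg_l


def _nearest_index(grid: np.ndarray, nm: float) -> int:
    return int(np.argmin(np.abs(grid - nm)))


def _band_sum(eem: EEMSpectrum, ex_i: int, lo: float, hi: float) -> tuple[float, bool]:
    """Sum of intensity over an emission band at a fixed excitation row.

    Masked cells are excluded and the sum rescaled by total/unmasked cell
    count, so that a partially masked band estimates the full-band sum.
    Returns (sum, all_masked_flag).
    """
    sel = (eem.em_grid >= lo) & (eem.em_grid <= hi)
    vals = eem.intensity[ex_i, sel]
    m = eem.mask[ex_i, sel]
    n_tot = int(sel.sum())
    n_ok = int((~m).sum())
    if n_ok == 0:
        return math.nan, True
    return float(vals[~m].sum()) * n_tot / n_ok, False


def fluorescence_indices(
    eem: EEMSpectrum, defs: IndexDefinitions = DEFAULT_INDEX_DEFS
) -> tuple[float, float, float, set]:
    """Compute (BIX, FIX, HIX) from an EEM; positions snap to nearest grid line.

    BIX = I(ex 310, em 380) / I(ex 310, em 430)
    FIX = I(ex 370, em 470) / I(ex 370, em 520)
    HIX = sum I(ex 254, em 435-480) / sum I(ex 254, em 300-345)   (classic)
        = H / (H + L) when ``defs.hix_normalized``.

    Any index whose denominator is <= 0 (or fully masked) comes back NaN with
    its name in the returned flag set.
    """
    undefined: set = set()

    def point(ex_nm: float, em_nm: float) -> float:
        i = _nearest_index(eem.ex_grid, ex_nm)
        j = _nearest_index(eem.em_grid, em_nm)
        if eem.mask[i, j]:
            return math.nan
        return float(eem.intensity[i, j])

    bix_num = point(defs.bix_ex, defs.bix_em_num)
    bix_den = point(defs.bix_ex, defs.bix_em_den)
    if not (bix_den > 0) or math.isnan(bix_num):
        bix = math.nan
        undefined.add("bix")
    else:
        bix = bix_num / bix_den

    fix_num = point(defs.fix_ex, defs.fix_em_num)
    fix_den = point(defs.fix_ex, defs.fix_em_den)
    if not (fix_den > 0) or math.isnan(fix_num):
        fix = math.nan
        undefined.add("fix")
    else:
        fix = fix_num / fix_den

    ex_i = _nearest_index(eem.ex_grid, defs.hix_ex)
    high, high_bad = _band_sum(eem, ex_i, *defs.hix_em_high)
    low, low_bad = _band_sum(eem, ex_i, *defs.hix_em_low)
    denom = (high + low) if defs.hix_normalized else low
    if high_bad or low_bad or not (denom > 0):
        hix = math.nan
        undefined.add("hix")
    else:
        hix = high / denom

    return bix, fix, hix, undefined


def compute_indices(
    absorbance: AbsorbanceSpectrum,
    eem: EEMSpectrum,
    doc_mg_l: float,
    defs: IndexDefinitions = DEFAULT_INDEX_DEFS,
) -> OpticalIndices:
    """All five indices for one sample."""
    out = OpticalIndices()
    val, bad = e2_e3(absorbance, defs)
    out.e2_e3 = val
    if bad:
        out.undefined.add("e2_e3")
    out.suva254 = suva254(absorbance, doc_mg_l, defs)
    out.bix, out.fix, out.hix, fl_bad = fluorescence_indices(eem, defs)
    out.undefined |= fl_bad
    return out


# ------------------------------------------------- light absorption rate


def rate_light_absorption(
    absorbance: AbsorbanceSpectrum,
    flux: PhotonFluxSpectrum,
    lower_nm: float = 300.0,
    upper_nm: float = 600.0,
) -> float:
    """Wavelength-integrated rate of light absorption Ra, mol photons L-1 s-1.

    Trapezoidal integration of ``flux * (1 - 10**(-A*path))`` on the union of
    the two wavelength grids restricted to [lower_nm, upper_nm]; absorbance
    is interpolated linearly, flux linearly with zero extension.
    """
    if lower_nm >= upper_nm:
        raise ValueError("integration bounds must satisfy lower < upper")
    lo = max(lower_nm, absorbance.wavelengths[0])
    hi = min(upper_nm, absorbance.wavelengths[-1])
    if lo >= hi:
        raise ValueError("absorbance spectrum does not cover the integration range")
    grid = np.union1d(absorbance.wavelengths, flux.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    grid = np.union1d(grid, [lo, hi])
    # absorbed fraction uses the absorbance over the irradiated path as stated
    absorbed = 1.0 - np.power(10.0, -absorbance.at(grid))
    return float(np.trapezoid(flux.at(grid) * absorbed, grid))


def irradiance_to_volumetric_flux(
    wavelengths_nm: np.ndarray,
    irradiance_w_m2_nm: np.ndarray,
    depth_cm: float,
    cutoff_nm: float = 300.0,
) -> PhotonFluxSpectrum:
    """Convert a spectral irradiance (W m-2 nm-1) into volumetric photon flux.

    For a well-mixed layer of depth ``depth_cm`` illuminated from above,
    E_vol = E_irr * lambda / (N_A h c) photons m-2 s-1 nm-1 spread over
    10 * depth_cm litres per square metre.
    """
    w = np.asarray(wavelengths_nm, dtype=float)
    e = np.asarray(irradiance_w_m2_nm, dtype=float)
    photons_m2 = e * (w * 1e-9) / (PLANCK * LIGHTSPEED)  # photons m-2 s-1 nm-1
    mol_m2 = photons_m2 / AVOGADRO
    litres_per_m2 = 10.0 * depth_cm
    flux = mol_m2 / litres_per_m2
    flux = np.where(w < cutoff_nm, 0.0, flux)
    return PhotonFluxSpectrum(w, flux, cutoff_nm=cutoff_nm)
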