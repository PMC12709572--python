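"""Chemical-probe kinetics inversion: from irradiation time courses to
steady-state oxidant concentrations, production rates, and apparent quantum
yields.

Probe scheme
------------
* furfuryl alcohol (FFA) decay, with isopropanol quenching hydroxyl radical,
  reports singlet oxygen:  [1O2*]_ss = k_obs / k(FFA, 1O2*);
* benzene in large excess scavenges hydroxyl radical and yields phenol:
  P(OH) = R0(phenol) / Y_phenol,  [OH]_ss = P / (k(benzene,OH) * [benzene]);
* 2,4,6-trimethylphenol (TMP) decay reports oxidizing triplets after
  subtracting its loss to hydroxyl radical and singlet oxygen;
* t,t-2,4-hexadien-1-ol (HDO) photoisomerization at several initial
  concentrations reports the larger energy-transfer triplet pool via a
  double-reciprocal (saturation) extrapolation.

Every apparent quantum yield is production rate / Ra, with Ra the
wavelength-integrated rate of light absorption from :mod:`photoxkit.spectra`.
Replicates are fitted individually and averaged; uncertainties propagate in
quadrature through every ratio and difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import RateConstantTable

__all__ = [
    "ProbeTimeSeries",
    "KineticFit",
    "OxidantResult",
    "KineticFitError",
    "fit_first_order",
    "fit_formation_rate",
    "singlet_oxygen",
    "hydroxyl",
    "triplet_tmp",
    "triplet_hdo",
    "PROBES",
]

PROBES = ("FFA", "TMP", "benzene-phenol", "HDO")


class KineticFitError(RuntimeError):
    """Raised when a probe time series cannot support the requested fit."""


@dataclass
class ProbeTimeSeries:
    """One replicate of a probe (or product) irradiation time course."""

    sample_id: str
    probe: str
    times_s: np.ndarray
    concentrations_M: np.ndarray
    replicate: int = 0
    initial_conc_M: float | None = None  # probe (precursor) concentration
    analyte: str = "probe"  # "probe" (decay) or "product" (formation)

    def __post_init__(self) -> None:
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe kind {self.probe!r}; expected one of {PROBES}")
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        if self.times_s.shape != self.concentrations_M.shape:
            raise ValueError("time and concentration arrays differ in length")
        if self.times_s.size < 2 or self.times_s[0] != 0 or not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if np.any(self.concentrations_M < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class KineticFit:
    """First-order decay rate or initial formation rate with uncertainty.

    ``value`` is k_obs (s-1) for decay fits, R0 (M s-1) for formation fits.
    ``per_replicate`` holds each replicate's fitted value; ``stderr`` is the
    standard error of the replicate mean (or the regression slope error when
    only one replicate is available).
    """

    value: float
    stderr: float
    r_squared: float
    n_points: int
    kind: str  # "decay" | "formation"
    per_replicate: list = field(default_factory=list)

    def summary(self) -> str:
        unit = "s^-1" if self.kind == "decay" else "M s^-1"
        return (
            f"{self.kind} fit: {self.value:.6g} +/- {self.stderr:.3g} {unit} "
            f"(R^2={self.r_squared:.6f}, n={self.n_points}, "
            f"{len(self.per_replicate)} replicate(s))"
        )


@dataclass
class OxidantResult:
    """Steady-state concentration and apparent quantum yield of one oxidant."""

    sample_id: str
    channel: str  # "hydroxyl" | "singlet_oxygen" | "triplet_tmp" | "triplet_hdo"
    riss_M: float
    production_M_s: float
    ra_mol_photons_L_s: float
    phi: float
    riss_stderr: float = 0.0
    phi_stderr: float = 0.0
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "channel": self.channel,
            "riss_M": self.riss_M,
            "riss_stderr": self.riss_stderr,
            "production_M_s": self.production_M_s,
            "ra": self.ra_mol_photons_L_s,
            "phi": self.phi,
            "phi_stderr": self.phi_stderr,
            "flags": ";".join(self.flags),
        }


# ---------------------------------------------------------------- fitting


def _slope_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope with intercept; returns (slope, slope_se, r2)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise KineticFitError("degenerate time axis")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    resid = y - (ym + slope * (x - xm))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else 0.0
    return slope, se, r2


def _pool(values: list[float], ses: list[float]) -> tuple[float, float]:
    """Mean of replicate estimates with standard error."""
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return float(v[0]), float(ses[0])
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))


def fit_first_order(series: ProbeTimeSeries | list[ProbeTimeSeries]) -> KineticFit:
    """Fit k_obs from ln(C/C0) vs t; replicates fitted separately then pooled.

    Non-positive concentrations are excluded with a warning; a replicate with
    fewer than 3 usable points raises :class:`KineticFitError`.
    """
    reps = [series] if isinstance(series, ProbeTimeSeries) else list(series)
    vals, ses, r2s, n_tot = [], [], [], 0
    for s in reps:
        ok = s.concentrations_M > 0
        if not np.all(ok):
            warnings.warn(
                f"{s.sample_id}/{s.probe} rep {s.replicate}: "
                f"{int((~ok).sum())} non-positive point(s) excluded from ln fit",
                stacklevel=2,
            )
        t = s.times_s[ok]
        c = s.concentrations_M[ok]
        if t.size < 3:
            raise KineticFitError("fewer than 3 usable points for first-order fit")
        y = np.log(c / c[0])
        slope, se, r2 = _slope_fit(t, y)
        vals.append(-slope)
        ses.append(se)
        r2s.append(r2)
        n_tot += t.size
    value, stderr = _pool(vals, ses)
    return KineticFit(value, stderr, float(np.mean(r2s)), n_tot, "decay", vals)


def fit_formation_rate(
    series: ProbeTimeSeries | list[ProbeTimeSeries],
    precursor_initial_M: float | None = None,
    early_fraction: float = 0.10,
) -> KineticFit:
    """Initial product-formation rate R0 (M s-1) from the early linear segment.

    The segment keeps points where the product is below ``early_fraction`` of
    the precursor's initial concentration (all points when the precursor
    concentration is unknown), with a minimum of 3 points.
    """
    reps = [series] if isinstance(series, ProbeTimeSeries) else list(series)
    vals, ses, r2s, n_tot = [], [], [], 0
    for s in reps:
        c0 = precursor_initial_M if precursor_initial_M is not None else s.initial_conc_M
        t, p = s.times_s, s.concentrations_M
        if c0 is not None:
            keep = p < early_fraction * c0
            if keep.sum() < 3:  # fall back to the earliest 3 points
                keep = np.arange(p.size) < 3
            t, p = t[keep], p[keep]
        if t.size < 3:
            raise KineticFitError("fewer than 3 early points for formation fit")
        slope, se, r2 = _slope_fit(t, p)
        vals.append(slope)
        ses.append(se)
        r2s.append(r2)
        n_tot += t.size
    value, stderr = _pool(vals, ses)
    return KineticFit(value, stderr, float(np.mean(r2s)), n_tot, "formation", vals)


# ------------------------------------------------------------- inversion


def _phi(production: float, prod_se: float, ra: float) -> tuple[float, float, list]:
    if ra <= 0:
        raise ValueError("Ra must be > 0 to compute a quantum yield")
    phi = production / ra
    flags = []
    if not (0.0 <= phi <= 1.0):
        flags.append("phi_outside_unit_interval")
    return phi, prod_se / ra, flags


def singlet_oxygen(
    kfit: KineticFit, constants: RateConstantTable, ra: float, sample_id: str = ""
) -> OxidantResult:
    """Singlet-oxygen result from an FFA decay fit (OH-quenched design)."""
    k = constants.k_ffa_singlet_oxygen
    riss = kfit.value / k
    riss_se = kfit.stderr / k
    production = riss * constants.k_singlet_oxygen_deactivation
    prod_se = riss_se * constants.k_singlet_oxygen_deactivation
    phi, phi_se, flags = _phi(production, prod_se, ra)
    return OxidantResult(sample_id, "singlet_oxygen", riss, production, ra, phi, riss_se, phi_se, flags)


def hydroxyl(
    rfit: KineticFit,
    constants: RateConstantTable,
    benzene_conc_M: float,
    ra: float,
    sample_id: str = "",
) -> OxidantResult:
    """Hydroxyl-radical result from a phenol formation fit (benzene probe)."""
    if not (1e-4 <= benzene_conc_M <= 1e-1):
        warnings.warn(
            f"benzene concentration {benzene_conc_M:g} M is outside the 0.1-100 mM scavenging design",
            stacklevel=2,
        )
    production = rfit.value / constants.y_phenol
    prod_se = rfit.stderr / constants.y_phenol
    scav = constants.k_benzene_oh * benzene_conc_M
    riss = production / scav
    riss_se = prod_se / scav
    phi, phi_se, flags = _phi(production, prod_se, ra)
    return OxidantResult(sample_id, "hydroxyl", riss, production, ra, phi, riss_se, phi_se, flags)


def triplet_tmp(
    kfit_tmp: KineticFit,
    oh: OxidantResult,
    so: OxidantResult,
    constants: RateConstantTable,
    ra: float,
    sample_id: str = "",
) -> OxidantResult:
    """Oxidizing-triplet result from TMP decay, corrected for OH and 1O2* loss."""
    if oh is None or so is None:
        raise ValueError("triplet_tmp requires hydroxyl and singlet-oxygen results for the sample")
    correction = constants.k_tmp_oh * oh.riss_M + constants.k_tmp_singlet_oxygen * so.riss_M
    k_corr = kfit_tmp.value - correction
    corr_var = (constants.k_tmp_oh * oh.riss_stderr) ** 2 + (
        constants.k_tmp_singlet_oxygen * so.riss_stderr
    ) ** 2
    k_se = math.sqrt(kfit_tmp.stderr**2 + corr_var)
    flags = []
    if k_corr < 0:
        flags.append("negative_corrected_rate_floored")
        k_corr = 0.0
    riss = k_corr / constants.k_tmp_triplet
    riss_se = k_se / constants.k_tmp_triplet
    production = riss * constants.k_triplet_quench
    prod_se = riss_se * constants.k_triplet_quench
    phi, phi_se, phi_flags = _phi(production, prod_se, ra)
    return OxidantResult(
        sample_id, "triplet_tmp", riss, production, ra, phi, riss_se, phi_se, flags + phi_flags
    )


def triplet_hdo(
    series_by_conc: dict[float, list[ProbeTimeSeries]],
    constants: RateConstantTable,
    ra: float,
    sample_id: str = "",
) -> OxidantResult:
    """Energy-transfer-triplet result from HDO saturation kinetics.

    ``series_by_conc`` maps initial t,t-HDO concentrations (M) to replicate
    lists of c,c-HDO formation series.  A 1/R vs 1/[HDO]0 line is fitted; the
    saturation rate R_max = 1/intercept gives the triplet production rate
    R_max / f_iso.
    """
    concs = sorted(series_by_conc)
    if len(concs) < 3:
        raise ValueError("HDO inversion needs >= 3 distinct initial concentrations")
    if concs[-1] / concs[0] < 4:
        warnings.warn("HDO concentration levels span less than a 4x range", stacklevel=2)
    rates, rate_ses = [], []
    for c in concs:
        fit = fit_formation_rate(series_by_conc[c], precursor_initial_M=c)
        rates.append(fit.value)
        rate_ses.append(fit.stderr)
    rates_arr = np.asarray(rates)
    flags: list = []
    if np.any(rates_arr <= 0):
        return OxidantResult(
            sample_id, "triplet_hdo", math.nan, math.nan, ra, math.nan,
            flags=["nonpositive_formation_rate"],
        )
    x = 1.0 / np.asarray(concs)
    y = 1.0 / rates_arr
    slope, se_slope, _ = _slope_fit(x, y)
    intercept = float(y.mean() - slope * x.mean())
    n = x.size
    # intercept standard error of the straight-line fit
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2)) / (n - 2) if n > 2 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    se_int = math.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx)) if sxx > 0 else 0.0
    if intercept <= 0:
        return OxidantResult(
            sample_id, "triplet_hdo", math.nan, math.nan, ra, math.nan,
            flags=["extrapolation_failure_nonpositive_intercept"],
        )
    r_max = 1.0 / intercept
    r_max_se = se_int / intercept**2
    production = r_max / constants.f_iso
    prod_se = r_max_se / constants.f_iso
    riss = production / constants.k_triplet_quench
    riss_se = prod_se / constants.k_triplet_quench
    phi, phi_se, phi_flags = _phi(production, prod_se, ra)
    return OxidantResult(
        sample_id, "triplet_hdo", riss, production, ra, phi, riss_se, phi_se, flags + phi_flags
    )
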