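"""Synthetic datasets with known ground truth for the full analysis chain.

The generator emulates the laboratory study conditions end to end: a library
of six fluorophore components (flavin-, tyrosine-, tryptophan-like, HULIS-1,
fulvic-like, HULIS-2) on the instrument grids (excitation 200-500 nm / 10 nm,
emission 250-600 nm / 5 nm), bulk plus six molecular-weight (MW) ultrafiltration
fractions per COM/EPS series at a fixed DOC of 5 mg C/L, exponential absorbance
spectra whose E2/E3 and SUVA254 trend monotonically with MW, a lamp photon-flux
spectrum with a 300 nm cutoff, and triplicate chemical-probe time courses whose
observed rates are implied exactly by the truth quantum yields and the
rate-constant table.  Every numeric truth is recorded so each downstream stage
is testable by parameter recovery.

Truths are a function of the configuration only; the seed controls noise
realizations, so different seeds share identical truths.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import RateConstantTable
from .photokin import ProbeTimeSeries, PROBES
from .spectra import (
    AbsorbanceSpectrum,
    EEMSpectrum,
    PhotonFluxSpectrum,
    compute_indices,
    rate_light_absorption,
    read_absorbance,
    read_eem,
    read_flux,
)

__all__ = [
    "ComponentLibrary",
    "TrendConfig",
    "ProbeDesign",
    "SynthConfig",
    "SampleTruth",
    "TruthTable",
    "SyntheticDataset",
    "gen_component_library",
    "gen_sample_set",
    "gen_eem",
    "gen_probe_series",
    "gen_dataset",
    "default_lamp",
    "stage_rng",
    "tucker_congruence",
    "CHANNELS",
]

CHANNELS = ("hydroxyl", "singlet_oxygen", "triplet_tmp", "triplet_hdo")

DEFAULT_EX_GRID = np.arange(200.0, 501.0, 10.0)
DEFAULT_EM_GRID = np.arange(250.0, 601.0, 5.0)

# (name, [(ex_center, ex_sigma, weight), ...], (em_center, em_sigma))
_COMPONENT_SHAPES = [
    ("flavin-like", [(370.0, 30.0, 1.0), (450.0, 25.0, 0.6)], (520.0, 35.0)),
    ("tyrosine-like", [(275.0, 15.0, 1.0)], (305.0, 15.0)),
    ("tryptophan-like", [(280.0, 15.0, 1.0)], (340.0, 25.0)),
    ("HULIS-1", [(250.0, 20.0, 1.0)], (450.0, 45.0)),
    ("fulvic-like", [(320.0, 30.0, 1.0)], (420.0, 40.0)),
    ("HULIS-2", [(280.0, 50.0, 1.0)], (500.0, 50.0)),
]


def stage_rng(seed: int, name: str) -> np.random.Generator:
    """Independent random stream derived from a global seed and a stage name."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())]))


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity between two loading/profile vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(abs(a @ b) / (na * nb))


# ---------------------------------------------------------- component library


@dataclass
class ComponentLibrary:
    """Six peak-normalized fluorophore excitation/emission profiles."""

    names: list
    ex_grid: np.ndarray
    em_grid: np.ndarray
    ex_profiles: np.ndarray  # (6, n_ex), each max exactly 1
    em_profiles: np.ndarray  # (6, n_em), each max exactly 1

    @property
    def n_components(self) -> int:
        return len(self.names)

    def joint_congruence(self, i: int, j: int) -> float:
        """Tucker congruence of the rank-1 ex (x) em profiles of two components."""
        return tucker_congruence(self.ex_profiles[i], self.ex_profiles[j]) * tucker_congruence(
            self.em_profiles[i], self.em_profiles[j]
        )


def _gauss(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def gen_component_library(
    ex_grid: np.ndarray | None = None,
    em_grid: np.ndarray | None = None,
    seed: int = 0,
    jitter_nm: float = 0.0,
) -> ComponentLibrary:
    """Build the six-component library on the given instrument grids.

    Peak centers/widths are fixed literature-typical values; ``jitter_nm`` adds
    a seeded uniform perturbation to the centers (0 by default so that truths
    do not depend on the seed).
    """
    ex = DEFAULT_EX_GRID.copy() if ex_grid is None else np.asarray(ex_grid, dtype=float)
    em = DEFAULT_EM_GRID.copy() if em_grid is None else np.asarray(em_grid, dtype=float)
    for grid, what in ((ex, "excitation"), (em, "emission")):
        if grid.size < 5 or not np.all(np.diff(grid) > 0):
            raise ValueError(f"invalid {what} grid: need >= 5 strictly increasing wavelengths")
    rng = stage_rng(seed, "component_library")
    names, ex_profiles, em_profiles = [], [], []
    for name, ex_peaks, (em_c, em_s) in _COMPONENT_SHAPES:
        d_ex = rng.uniform(-jitter_nm, jitter_nm) if jitter_nm > 0 else 0.0
        d_em = rng.uniform(-jitter_nm, jitter_nm) if jitter_nm > 0 else 0.0
        exp = np.zeros_like(ex)
        for c, s, w in ex_peaks:
            exp = exp + w * _gauss(ex, c + d_ex, s)
        emp = _gauss(em, em_c + d_em, em_s)
        names.append(name)
        ex_profiles.append(exp / exp.max())
        em_profiles.append(emp / emp.max())
    return ComponentLibrary(names, ex, em, np.array(ex_profiles), np.array(em_profiles))


# ------------------------------------------------------------- trend config


@dataclass
class TrendConfig:
    """Monotone MW-trend parameters defining the synthetic truths.

    Quantum yields decrease log-linearly across fractions C1->C6 / E1->E6
    (slope per fraction step); optical indices and composition trend linearly.
    The default magnitudes place the bulk singlet-oxygen yield near 5% and the
    fraction maxima near 10%, with EPS a fixed factor below COM.
    """

    doc_mg_l: float = 5.0
    # apparent quantum yields at the lowest-MW fraction (C1/E1), per channel
    phi_c1: dict = field(
        default_factory=lambda: {
            "hydroxyl": 0.004,
            "singlet_oxygen": 0.10,
            "triplet_tmp": 0.045,
            "triplet_hdo": 0.030,
        }
    )
    phi_log_slope: float = 0.40  # per fraction step; 0 => flat truths
    eps_factor: float = 0.85  # EPS yields relative to COM
    suva_range: tuple = (1.5, 3.5)  # L mg-C^-1 m^-1, fraction 1 -> 6
    e2e3_range: tuple = (7.0, 4.0)  # unitless, fraction 1 -> 6
    protein_range: tuple = (20.0, 80.0)  # mg/L, increases with MW
    polysaccharide_range: tuple = (80.0, 20.0)  # mg/L, decreases with MW
    eps_suva_factor: float = 0.9  # EPS chromophores less aromatic than COM
    eps_protein_factor: float = 0.6
    eps_polysaccharide_factor: float = 1.5
    # component score mixing fractions at fraction 1 and fraction 6
    score_start: tuple = (0.30, 0.10, 0.10, 0.20, 0.20, 0.10)
    score_end: tuple = (0.15, 0.30, 0.35, 0.05, 0.05, 0.025)
    total_score: float = 100.0  # arbitrary fluorescence units

    def __post_init__(self) -> None:
        if self.doc_mg_l <= 0:
            raise ValueError("DOC must be positive")
        for ch, v in self.phi_c1.items():
            if not (0.0 <= v <= 0.2):
                raise ValueError(f"phi_c1[{ch}]={v} outside [0, 0.2]")


@dataclass
class ProbeDesign:
    """Sampling design for the probe irradiation experiments."""

    n_replicates: int = 3
    noise_sd: float = 0.0  # relative measurement noise
    ffa_initial_M: float = 1e-5
    tmp_initial_M: float = 1e-5
    benzene_conc_M: float = 2e-3
    hdo_levels_M: tuple = (2.5e-5, 5e-5, 1e-4, 2e-4, 5e-4)
    hdo_half_sat_M: float = 1e-4  # truth half-saturation of c,c-HDO formation
    ffa_times_s: tuple = tuple(np.linspace(0, 18000, 7))
    tmp_times_s: tuple = tuple(np.linspace(0, 1800, 7))
    benzene_times_s: tuple = tuple(np.linspace(0, 18000, 7))
    hdo_times_s: tuple = tuple(np.linspace(0, 1200, 7))


@dataclass
class SynthConfig:
    """Complete configuration of a synthetic dataset."""

    n_fractions: int = 6
    series: tuple = ("COM", "EPS")
    include_bulk: bool = True
    trend: TrendConfig = field(default_factory=TrendConfig)
    design: ProbeDesign = field(default_factory=ProbeDesign)
    eem_noise_sd: float = 0.0  # relative to EEM max
    scatter_halfwidths_nm: tuple = (0.0, 0.0)  # ridge injection off by default
    scatter_amplitude: float = 0.0  # relative to EEM max
    lamp_peak_flux: float = 3e-6  # mol photons L^-1 s^-1 nm^-1
    lamp_cutoff_nm: float = 300.0

    def __post_init__(self) -> None:
        if not (1 <= self.n_fractions <= 6):
            raise ValueError("n_fractions must be in 1..6")
        for s in self.series:
            if s not in ("COM", "EPS"):
                raise ValueError(f"unknown series {s!r}")

    def to_dict(self) -> dict:
        d = asdict(self)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return float(obj)
            return obj

        return clean(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if "trend" in d and isinstance(d["trend"], dict):
            t = dict(d["trend"])
            for k in ("suva_range", "e2e3_range", "protein_range", "polysaccharide_range",
                      "score_start", "score_end"):
                if k in t:
                    t[k] = tuple(t[k])
            d["trend"] = TrendConfig(**t)
        if "design" in d and isinstance(d["design"], dict):
            p = dict(d["design"])
            for k in ("hdo_levels_M", "ffa_times_s", "tmp_times_s", "benzene_times_s", "hdo_times_s"):
                if k in p:
                    p[k] = tuple(p[k])
            d["design"] = ProbeDesign(**p)
        for k in ("series", "scatter_halfwidths_nm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ------------------------------------------------------------ truth records


@dataclass
class SampleTruth:
    """Ground truth for one synthetic sample."""

    sample_id: str
    scores: np.ndarray  # six non-negative component weights
    phi: dict  # channel -> apparent quantum yield (fraction)
    production: dict  # channel -> mol L^-1 s^-1
    riss: dict  # channel -> mol L^-1
    ra: float  # mol photons L^-1 s^-1
    index_targets: dict  # e2_e3, suva254, bix, fix, hix implied by the spectra

    def as_json(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "scores": [float(s) for s in self.scores],
            "phi": {k: float(v) for k, v in self.phi.items()},
            "production": {k: float(v) for k, v in self.production.items()},
            "riss": {k: float(v) for k, v in self.riss.items()},
            "ra": float(self.ra),
            "index_targets": {k: float(v) for k, v in self.index_targets.items()},
        }


@dataclass
class TruthTable:
    """Per-sample truths, queryable by sample id."""

    samples: dict  # sample_id -> SampleTruth

    def __getitem__(self, sample_id: str) -> SampleTruth:
        return self.samples[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.samples

    def ids(self) -> list:
        return list(self.samples)

    def phi_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": s.sample_id, **{f"phi_{c}": s.phi[c] for c in CHANNELS}}
                for s in self.samples.values()]
        return pd.DataFrame(rows).set_index("sample_id")

    def to_json(self, path: str | Path) -> None:
        payload = {sid: t.as_json() for sid, t in self.samples.items()}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        samples = {
            sid: SampleTruth(
                sample_id=sid,
                scores=np.asarray(rec["scores"], dtype=float),
                phi=rec["phi"],
                production=rec["production"],
                riss=rec["riss"],
                ra=rec["ra"],
                index_targets=rec["index_targets"],
            )
            for sid, rec in payload.items()
        }
        return cls(samples)


# --------------------------------------------------------------- generators


def default_lamp(peak_flux: float = 3e-6, cutoff_nm: float = 300.0) -> PhotonFluxSpectrum:
    """Smooth xenon-like photon-flux spectrum with a long-pass cutoff.

    Flux rises from zero at the cutoff toward an asymptote ``peak_flux``
    (mol photons L^-1 s^-1 nm^-1) and is reported on a 2 nm grid to 650 nm.
    """
    w = np.arange(290.0, 651.0, 2.0)
    flux = np.where(w < cutoff_nm, 0.0, peak_flux * (1.0 - np.exp(-(np.maximum(w - cutoff_nm, 0.0)) / 40.0)))
    return PhotonFluxSpectrum(w, flux, cutoff_nm=cutoff_nm)


def _absorbance_from_targets(e2e3: float, suva: float, doc_mg_l: float) -> AbsorbanceSpectrum:
    """Exponential spectrum with exact A254 (from SUVA) and A250/A365 (=E2/E3)."""
    slope = np.log(e2e3) / 115.0  # nm^-1; E2/E3 = exp(slope * (365 - 250))
    a254 = suva * doc_mg_l / 100.0  # per cm
    w = np.arange(200.0, 801.0, 1.0)
    a = a254 * np.exp(-slope * (w - 254.0))
    return AbsorbanceSpectrum(w, a, path_length_cm=1.0)


def gen_sample_set(
    n_fractions: int = 6,
    series: tuple = ("COM", "EPS"),
    seed: int = 0,
    trend_config: TrendConfig | None = None,
    include_bulk: bool = True,
    lamp: PhotonFluxSpectrum | None = None,
    constants: RateConstantTable | None = None,
    design: ProbeDesign | None = None,
    library: ComponentLibrary | None = None,
) -> tuple[pd.DataFrame, TruthTable]:
    """Generate the sample metadata table and the full truth table.

    Truths are deterministic functions of the configuration (the seed only
    matters for noise applied later).  Within each series the quantum-yield
    truths are non-increasing across MW fractions, protein increases and
    polysaccharide decreases with MW, and [RI]_ss truths follow from
    production = phi * Ra with the probe-solution scavenging conventions.
    """
    trend = trend_config or TrendConfig()
    design = design or ProbeDesign()
    constants = constants or RateConstantTable()
    lamp = lamp or default_lamp()
    library = library or gen_component_library()
    if not (1 <= n_fractions <= 6):
        raise ValueError("n_fractions must be in 1..6")

    rows = []
    truths: dict[str, SampleTruth] = {}

    def interp(lo_hi: tuple, t: float) -> float:
        return lo_hi[0] + (lo_hi[1] - lo_hi[0]) * t

    for ser in series:
        prefix = "C" if ser == "COM" else "E"
        phi_factor = 1.0 if ser == "COM" else trend.eps_factor
        fractions = list(range(1, n_fractions + 1))
        per_fraction = {}
        for i in fractions:
            t = (i - 1) / max(n_fractions - 1, 1)
            phi = {
                ch: phi_factor * trend.phi_c1[ch] * np.exp(-trend.phi_log_slope * (i - 1))
                for ch in CHANNELS
            }
            suva = interp(trend.suva_range, t) * (trend.eps_suva_factor if ser == "EPS" else 1.0)
            e2e3 = interp(trend.e2e3_range, t)
            protein = interp(trend.protein_range, t) * (
                trend.eps_protein_factor if ser == "EPS" else 1.0
            )
            poly = interp(trend.polysaccharide_range, t) * (
                trend.eps_polysaccharide_factor if ser == "EPS" else 1.0
            )
            log_s = np.log(np.asarray(trend.score_start))
            log_e = np.log(np.asarray(trend.score_end))
            scores = trend.total_score * np.exp(log_s + (log_e - log_s) * t)
            per_fraction[i] = dict(
                phi=phi, suva=suva, e2e3=e2e3, protein=protein, poly=poly, scores=scores
            )
        entries = []
        if include_bulk:
            bulk = dict(
                phi={ch: float(np.mean([per_fraction[i]["phi"][ch] for i in fractions])) for ch in CHANNELS},
                suva=float(np.mean([per_fraction[i]["suva"] for i in fractions])),
                e2e3=float(np.mean([per_fraction[i]["e2e3"] for i in fractions])),
                protein=float(np.mean([per_fraction[i]["protein"] for i in fractions])),
                poly=float(np.mean([per_fraction[i]["poly"] for i in fractions])),
                scores=np.mean([per_fraction[i]["scores"] for i in fractions], axis=0),
            )
            entries.append((0, bulk))
        entries.extend((i, per_fraction[i]) for i in fractions)

        for frac, rec in entries:
            sid = f"{prefix}{frac}"
            absorbance = _absorbance_from_targets(rec["e2e3"], rec["suva"], trend.doc_mg_l)
            ra = rate_light_absorption(absorbance, lamp)
            production = {ch: rec["phi"][ch] * ra for ch in CHANNELS}
            riss = {
                "hydroxyl": production["hydroxyl"]
                / (constants.k_benzene_oh * design.benzene_conc_M),
                "singlet_oxygen": production["singlet_oxygen"]
                / constants.k_singlet_oxygen_deactivation,
                "triplet_tmp": production["triplet_tmp"] / constants.k_triplet_quench,
                "triplet_hdo": production["triplet_hdo"] / constants.k_triplet_quench,
            }
            eem = gen_eem(rec["scores"], library, noise_sd=0.0, seed=0)
            idx = compute_indices(absorbance, eem, trend.doc_mg_l)
            truths[sid] = SampleTruth(
                sample_id=sid,
                scores=np.asarray(rec["scores"], dtype=float),
                phi=rec["phi"],
                production=production,
                riss=riss,
                ra=ra,
                index_targets={
                    "e2_e3": idx.e2_e3,
                    "suva254": idx.suva254,
                    "bix": idx.bix,
                    "fix": idx.fix,
                    "hix": idx.hix,
                },
            )
            rows.append(
                {
                    "sample_id": sid,
                    "series": ser,
                    "fraction": frac,
                    "mw_label": "bulk" if frac == 0 else f"fraction {frac}",
                    "doc_mg_l": trend.doc_mg_l,
                    "protein_mg_l": rec["protein"],
                    "polysaccharide_mg_l": rec["poly"],
                }
            )

    return pd.DataFrame(rows), TruthTable(truths)


def gen_eem(
    scores: np.ndarray,
    library: ComponentLibrary,
    noise_sd: float = 0.0,
    seed: int = 0,
    scatter_halfwidths_nm: tuple = (0.0, 0.0),
    scatter_amplitude: float = 0.0,
) -> EEMSpectrum:
    """Trilinear EEM: sum_f score_f * ex_f (x) em_f, plus optional noise/ridges.

    Gaussian noise has sd = ``noise_sd`` x the signal maximum and the result is
    clipped at zero.  Rayleigh-like first/second-order scatter ridges (|em-ex|
    <= hw1, |em-2ex| <= hw2) of height ``scatter_amplitude`` x max can be
    injected for mask testing.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (library.n_components,):
        raise ValueError(f"expected {library.n_components} scores")
    if np.any(scores < 0):
        raise ValueError("component scores must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    m = np.einsum("f,fi,fj->ij", scores, library.ex_profiles, library.em_profiles)
    peak = m.max() if m.max() > 0 else 1.0
    if scatter_amplitude > 0:
        ex = library.ex_grid[:, None]
        em = library.em_grid[None, :]
        hw1, hw2 = scatter_halfwidths_nm
        ridge = (np.abs(em - ex) <= hw1) | (np.abs(em - 2.0 * ex) <= hw2)
        m = m + scatter_amplitude * peak * ridge
    if noise_sd > 0:
        rng = stage_rng(seed, "eem_noise")
        m = m + rng.normal(0.0, noise_sd * peak, size=m.shape)
    m = np.clip(m, 0.0, None)
    return EEMSpectrum(library.ex_grid.copy(), library.em_grid.copy(), m)


def gen_probe_series(
    truth: SampleTruth,
    probe: str,
    design: ProbeDesign,
    constants: RateConstantTable,
    seed: int = 0,
) -> dict:
    """Replicate probe time courses implied by a sample's truth record.

    Returns ``{"series": [ProbeTimeSeries, ...]}`` for FFA/TMP/benzene-phenol
    and ``{"series": [...], "by_conc": {hdo0: [...]}}`` for HDO.  Noiseless
    designs give bit-identical replicates.
    """
    if probe not in PROBES:
        raise ValueError(f"unknown probe kind {probe!r}; expected one of {PROBES}")
    rng = stage_rng(seed, f"kinetics:{truth.sample_id}:{probe}")

    def noisy(values: np.ndarray) -> np.ndarray:
        if design.noise_sd <= 0:
            return values
        return np.clip(values * (1.0 + rng.normal(0.0, design.noise_sd, size=values.shape)), 0.0, None)

    out: dict = {"series": []}
    if probe == "FFA":
        t = np.asarray(design.ffa_times_s)
        k_obs = constants.k_ffa_singlet_oxygen * truth.riss["singlet_oxygen"]
        clean = design.ffa_initial_M * np.exp(-k_obs * t)
        for r in range(design.n_replicates):
            out["series"].append(
                ProbeTimeSeries(truth.sample_id, "FFA", t, noisy(clean), r, design.ffa_initial_M, "probe")
            )
    elif probe == "TMP":
        t = np.asarray(design.tmp_times_s)
        k_obs = (
            constants.k_tmp_triplet * truth.riss["triplet_tmp"]
            + constants.k_tmp_oh * truth.riss["hydroxyl"]
            + constants.k_tmp_singlet_oxygen * truth.riss["singlet_oxygen"]
        )
        clean = design.tmp_initial_M * np.exp(-k_obs * t)
        for r in range(design.n_replicates):
            out["series"].append(
                ProbeTimeSeries(truth.sample_id, "TMP", t, noisy(clean), r, design.tmp_initial_M, "probe")
            )
    elif probe == "benzene-phenol":
        t = np.asarray(design.benzene_times_s)
        r0 = constants.y_phenol * truth.production["hydroxyl"]
        clean = r0 * t
        for r in range(design.n_replicates):
            out["series"].append(
                ProbeTimeSeries(
                    truth.sample_id, "benzene-phenol", t, noisy(clean), r, design.benzene_conc_M, "product"
                )
            )
    else:  # HDO
        t = np.asarray(design.hdo_times_s)
        r_max = constants.f_iso * truth.production["triplet_hdo"]
        out["by_conc"] = {}
        for h0 in design.hdo_levels_M:
            rate = r_max * h0 / (design.hdo_half_sat_M + h0)
            clean = rate * t
            reps = [
                ProbeTimeSeries(truth.sample_id, "HDO", t, noisy(clean), r, h0, "product")
                for r in range(design.n_replicates)
            ]
            out["by_conc"][h0] = reps
            out["series"].extend(reps)
    return out


# ------------------------------------------------------------ full dataset


@dataclass
class SyntheticDataset:
    """All artifacts of one synthetic study, with generator provenance."""

    samples: pd.DataFrame
    library: ComponentLibrary
    absorbance: dict  # sample_id -> AbsorbanceSpectrum
    eems: dict  # sample_id -> EEMSpectrum
    lamp: PhotonFluxSpectrum
    kinetics: dict  # (sample_id, probe) -> {"series": [...], ...}
    truth: TruthTable
    config: SynthConfig
    seed: int

    def sample_ids(self) -> list:
        return list(self.samples["sample_id"])

    def hdo_by_conc(self, sample_id: str) -> dict:
        return self.kinetics[(sample_id, "HDO")]["by_conc"]

    def write(self, out_dir: str | Path) -> None:
        """Write the dataset directory (CSV/JSON/YAML, plain text only)."""
        out = Path(out_dir)
        (out / "absorbance").mkdir(parents=True, exist_ok=True)
        (out / "eem").mkdir(exist_ok=True)
        (out / "kinetics").mkdir(exist_ok=True)
        self.samples.to_csv(out / "samples.csv", index=False)
        self.lamp.write_csv(out / "lamp.csv")
        for sid in self.sample_ids():
            self.absorbance[sid].write_csv(out / "absorbance" / f"{sid}.csv")
            self.eems[sid].write_csv(out / "eem" / f"{sid}.csv")
        for (sid, probe), rec in self.kinetics.items():
            rows = []
            for s in rec["series"]:
                for t, c in zip(s.times_s, s.concentrations_M):
                    rows.append(
                        {
                            "time_s": t,
                            "concentration_M": c,
                            "replicate": s.replicate,
                            "initial_conc_M": s.initial_conc_M,
                            "analyte": s.analyte,
                        }
                    )
            tag = probe.replace("-", "_")
            pd.DataFrame(rows).to_csv(out / "kinetics" / f"{sid}_{tag}.csv", index=False)
        self.truth.to_json(out / "truth.json")
        (out / "config.yaml").write_text(
            yaml.safe_dump({"seed": self.seed, "config": self.config.to_dict()}, sort_keys=False)
        )

    @classmethod
    def read(cls, in_dir: str | Path) -> "SyntheticDataset":
        """Load a dataset directory written by :meth:`write`."""
        src = Path(in_dir)
        meta = yaml.safe_load((src / "config.yaml").read_text())
        config = SynthConfig.from_dict(meta["config"])
        samples = pd.read_csv(src / "samples.csv")
        lamp_path = src / "lamp.csv"
        lamp = read_flux(lamp_path, cutoff_nm=config.lamp_cutoff_nm) if lamp_path.exists() else None
        absorbance = {
            sid: read_absorbance(src / "absorbance" / f"{sid}.csv") for sid in samples["sample_id"]
        }
        eems = {sid: read_eem(src / "eem" / f"{sid}.csv") for sid in samples["sample_id"]}
        kinetics = {}
        for sid in samples["sample_id"]:
            for probe in PROBES:
                path = src / "kinetics" / f"{sid}_{probe.replace('-', '_')}.csv"
                if not path.exists():
                    continue
                df = pd.read_csv(path, float_precision="round_trip")
                rec: dict = {"series": []}
                group_cols = ["replicate", "initial_conc_M"]
                for (rep, c0), g in df.groupby(group_cols, sort=True):
                    g = g.sort_values("time_s")
                    rec["series"].append(
                        ProbeTimeSeries(
                            sid,
                            probe,
                            g["time_s"].to_numpy(),
                            g["concentration_M"].to_numpy(),
                            int(rep),
                            float(c0),
                            str(g["analyte"].iloc[0]),
                        )
                    )
                if probe == "HDO":
                    by_conc: dict = {}
                    for s in rec["series"]:
                        by_conc.setdefault(s.initial_conc_M, []).append(s)
                    rec["by_conc"] = by_conc
                kinetics[(sid, probe)] = rec
        truth = TruthTable.from_json(src / "truth.json") if (src / "truth.json").exists() else None
        return cls(samples, gen_component_library(), absorbance, eems, lamp, kinetics, truth, config,
                   int(meta.get("seed", 0)))


def gen_dataset(config: SynthConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete synthetic dataset under the given configuration."""
    config = config or SynthConfig()
    constants = RateConstantTable()
    lamp = default_lamp(config.lamp_peak_flux, config.lamp_cutoff_nm)
    library = gen_component_library()
    samples, truth = gen_sample_set(
        n_fractions=config.n_fractions,
        series=config.series,
        seed=seed,
        trend_config=config.trend,
        include_bulk=config.include_bulk,
        lamp=lamp,
        constants=constants,
        design=config.design,
        library=library,
    )
    absorbance, eems, kinetics = {}, {}, {}
    for _, row in samples.iterrows():
        sid = row["sample_id"]
        t = truth[sid]
        absorbance[sid] = _absorbance_from_targets(
            t.index_targets["e2_e3"], t.index_targets["suva254"], config.trend.doc_mg_l
        )
        eems[sid] = gen_eem(
            t.scores,
            library,
            noise_sd=config.eem_noise_sd,
            seed=int(stage_rng(seed, f"eem:{sid}").integers(2**31)),
            scatter_halfwidths_nm=config.scatter_halfwidths_nm,
            scatter_amplitude=config.scatter_amplitude,
        )
        for probe in PROBES:
            kinetics[(sid, probe)] = gen_probe_series(t, probe, config.design, constants, seed=seed)
    return SyntheticDataset(samples, library, absorbance, eems, lamp, kinetics, truth, config, seed)
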