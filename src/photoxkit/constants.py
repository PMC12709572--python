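"""Physical constants and index definitions used across the toolkit.

Bimolecular rate constants for the chemical-probe scheme live in
:class:`RateConstantTable`.  Every entry is data, not code: the table can be
overridden wholesale from a YAML file so that alternative literature values
(or a lab's own calibrations) propagate through the whole inversion without
touching the equations.

Wavelength positions for the fluorescence indices (FIX, BIX, HIX) are
centralized here so that definitional variants can be switched in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RateConstantTable", "IndexDefinitions", "DEFAULT_CITATIONS"]

#: Literature sources for the default rate constants (informational).
DEFAULT_CITATIONS: dict[str, str] = {
    "k_ffa_singlet_oxygen": "FFA + 1O2* rate constant, ~1e8 M-1 s-1 (aqueous, 25 C)",
    "k_singlet_oxygen_deactivation": "1O2* deactivation by H2O, ~2.2e5 s-1",
    "y_phenol": "phenol yield from benzene + OH, ~0.53-0.69; 0.53 adopted",
    "k_benzene_oh": "benzene + OH, ~7.8e9 M-1 s-1",
    "k_tmp_oh": "TMP + OH, ~1.9e10 M-1 s-1 (diffusion limited)",
    "k_tmp_singlet_oxygen": "TMP + 1O2*, ~6e7 M-1 s-1",
    "k_tmp_triplet": "TMP + oxidizing 3C*, ~3e9 M-1 s-1 (model sensitizers)",
    "k_triplet_quench": "pseudo-first-order 3C* loss (O2 quenching), ~2.8e5 s-1",
    "f_iso": "fraction of 3C*+HDO encounters yielding c,c-HDO, ~0.22",
}


@dataclass(frozen=True)
class RateConstantTable:
    """Bimolecular and pseudo-first-order rate constants for probe inversion.

    Attributes
    ----------
    k_ffa_singlet_oxygen : float
        FFA + singlet oxygen rate constant, M-1 s-1.
    k_singlet_oxygen_deactivation : float
        Solvent deactivation rate of singlet oxygen (k_d), s-1.
    y_phenol : float
        Yield of phenol per benzene + hydroxyl-radical reaction, unitless (0, 1].
    k_benzene_oh : float
        Benzene + hydroxyl radical rate constant, M-1 s-1.
    k_tmp_oh, k_tmp_singlet_oxygen, k_tmp_triplet : float
        TMP loss rate constants toward OH, singlet oxygen, oxidizing triplets.
    k_triplet_quench : float
        Pseudo-first-order quenching rate of triplet states (k_q'), s-1; used
        to convert between triplet steady-state concentration and production
        rate.
    f_iso : float
        Fraction of triplet + t,t-HDO encounters producing c,c-HDO, (0, 1].
    citations : dict
        Free-text provenance per constant.
    """

    k_ffa_singlet_oxygen: float = 1.0e8
    k_singlet_oxygen_deactivation: float = 2.2e5
    y_phenol: float = 0.53
    k_benzene_oh: float = 7.8e9
    k_tmp_oh: float = 1.9e10
    k_tmp_singlet_oxygen: float = 6.0e7
    k_tmp_triplet: float = 3.0e9
    k_triplet_quench: float = 2.8e5
    f_iso: float = 0.22
    citations: dict = field(default_factory=lambda: dict(DEFAULT_CITATIONS))

    def __post_init__(self) -> None:
        for name in (
            "k_ffa_singlet_oxygen",
            "k_singlet_oxygen_deactivation",
            "k_benzene_oh",
            "k_tmp_oh",
            "k_tmp_singlet_oxygen",
            "k_tmp_triplet",
            "k_triplet_quench",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"rate constant {name} must be > 0")
        for name in ("y_phenol", "f_iso"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RateConstantTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def replace(self, **overrides) -> "RateConstantTable":
        data = asdict(self)
        data.update(overrides)
        return RateConstantTable(**data)


@dataclass(frozen=True)
class IndexDefinitions:
    """Wavelength positions (nm) defining the optical/fluorescence indices.

    ``hix_normalized`` selects between the classic humification index
    H/L (default) and the Ohno-normalized variant H/(H+L).
    """

    e2_nm: float = 250.0
    e3_nm: float = 365.0
    suva_nm: float = 254.0
    fix_ex: float = 370.0
    fix_em_num: float = 470.0
    fix_em_den: float = 520.0
    bix_ex: float = 310.0
    bix_em_num: float = 380.0
    bix_em_den: float = 430.0
    hix_ex: float = 254.0
    hix_em_high: tuple = (435.0, 480.0)
    hix_em_low: tuple = (300.0, 345.0)
    hix_normalized: bool = False


DEFAULT_INDEX_DEFS = IndexDefinitions()
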