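"""Small-molecule mass library and mass dialects.

All arithmetic in this package runs under one of three mass dialects:

``nominal``
    Integer masses built from the most abundant isotopes' integer masses.
    This is the dialect of MALDI-TOF peak tables for sodiated
    cello-oligosaccharides (anhydroglucose 162, water 18, glucose 180) and
    the default everywhere.
``monoisotopic``
    Exact masses of the most abundant isotopes, computed from molecular
    formulas; cationic charge carriers are corrected for the electron mass.
``average``
    Standard-atomic-weight masses, for deconvoluted/averaged data.

The library is closed: looking up a name it does not contain raises
``KeyError`` rather than guessing, and user extensions go through
:meth:`SmallMoleculeLibrary.extended` or a JSON overlay so provenance of
every mass is explicit.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping

from pyteomics import mass as _pmass

__all__ = [
    "MassMode",
    "SmallMoleculeLibrary",
    "ELECTRON_MASS",
    "WATER_NOMINAL",
    "ANHYDROGLUCOSE_NOMINAL",
]

ELECTRON_MASS = 0.00054858
WATER_NOMINAL = 18
ANHYDROGLUCOSE_NOMINAL = 162


class MassMode(str, enum.Enum):
    NOMINAL = "nominal"
    MONOISOTOPIC = "monoisotopic"
    AVERAGE = "average"


def _formula_mass(formula: str, mode: MassMode) -> float:
    if mode is MassMode.MONOISOTOPIC:
        return _pmass.calculate_mass(formula=formula)
    return _pmass.calculate_mass(formula=formula, average=True)


# name -> (nominal mass, molecular formula or None when no neutral formula
# applies).  Nominal masses are fixed integers, the integer arithmetic of
# MALDI/ESI peak assignment tables; higher dialects derive from the formula.
_NEUTRALS: dict[str, tuple[int, str]] = {
    # monosaccharides and their oxidation/lactonization products
    "glucose": (180, "C6H12O6"),
    "gluconic acid": (196, "C6H12O7"),
    "gluconic acid lactone": (178, "C6H10O6"),
    "glucuronic acid": (194, "C6H10O7"),
    "glucuronic acid lactone": (176, "C6H8O6"),
    "saccharic acid": (210, "C6H10O8"),
    "saccharic acid lactone": (192, "C6H8O7"),
    # ascorbate (the reductant feeding the monooxygenase) and its fates
    "reduced ascorbate": (176, "C6H8O6"),
    "oxidized ascorbate": (174, "C6H6O6"),
    "oxidized-dehydrated ascorbate": (156, "C6H4O5"),
    # solvents / neutral adducts
    "H2O": (18, "H2O"),
    "NH3": (17, "NH3"),
    "CH3OH": (32, "CH4O"),
    "HCOOH": (46, "CH2O2"),
    "CH3COOH": (60, "C2H4O2"),
}

# charge carriers: nominal integer, and the exact monoisotopic value with the
# electron mass folded in (only the monoisotopic dialect resolves electrons).
_PROTON_MONO = 1.00727646677
_CARRIERS: dict[str, tuple[int, float]] = {
    "proton": (1, _PROTON_MONO),
    "sodium": (23, 22.98976928 - ELECTRON_MASS),
    "ammonium": (18, _formula_mass("NH4", MassMode.MONOISOTOPIC) - ELECTRON_MASS),
    "deprotonation": (-1, -_PROTON_MONO),
}


@dataclass(frozen=True)
class SmallMoleculeLibrary:
    """Versioned, closed registry of neutral species and charge carriers."""

    version: str = "builtin-1"
    neutrals: Mapping[str, tuple[int, str]] = field(default_factory=lambda: dict(_NEUTRALS))
    carriers: Mapping[str, tuple[int, float]] = field(default_factory=lambda: dict(_CARRIERS))

    def mass(self, name: str, mode: MassMode = MassMode.NOMINAL) -> float:
        """Mass of a named species under ``mode``.

        Raises ``KeyError`` for unknown names — the library never guesses.
        """
        mode = MassMode(mode)
        if name in self.neutrals:
            nominal, formula = self.neutrals[name]
            if mode is MassMode.NOMINAL:
                return nominal
            return _formula_mass(formula, mode)
        if name in self.carriers:
            nominal, mono = self.carriers[name]
            if mode is MassMode.NOMINAL:
                return nominal
            if mode is MassMode.MONOISOTOPIC:
                return mono
            # carriers are single ions; average == monoisotopic to the
            # precision any averaged spectrum resolves
            return mono
        raise KeyError(f"unknown species {name!r} (library {self.version})")

    def __contains__(self, name: str) -> bool:
        return name in self.neutrals or name in self.carriers

    def neutral_names(self) -> list[str]:
        return list(self.neutrals)

    def names_for_nominal(self, nominal: int) -> list[str]:
        """All neutral names sharing a nominal mass (e.g. 176 is both
        glucuronic acid lactone and reduced ascorbate)."""
        return [n for n, (m, _) in self.neutrals.items() if m == nominal]

    def extended(self, extra: Mapping[str, tuple[int, str]], version: str | None = None) -> "SmallMoleculeLibrary":
        merged = dict(self.neutrals)
        merged.update(extra)
        return SmallMoleculeLibrary(
            version=version or self.version + "+ext",
            neutrals=merged,
            carriers=dict(self.carriers),
        )

    @classmethod
    def from_json(cls, path) -> "SmallMoleculeLibrary":
        """Overlay built-ins with a ``{"version": ..., "neutrals": {name:
        [nominal, formula]}}`` JSON config."""
        with open(path) as fh:
            cfg = json.load(fh)
        extra = {k: (int(v[0]), v[1]) for k, v in cfg.get("neutrals", {}).items()}
        return DEFAULT_LIBRARY.extended(extra, version=cfg.get("version"))


DEFAULT_LIBRARY = SmallMoleculeLibrary()
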