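"""Peptide/protein mass arithmetic.

Small utilities for the protein-level checks around the enzyme itself:
peptide neutral masses, multiply charged m/z (N-terminal peptide
identification from an LC-MS survey scan), and the apparent-vs-calculated
glycosylation percentage from SDS-PAGE.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

from .masses import MassMode

__all__ = ["peptide_mass", "charged_mz", "glycosylation_percent", "PROTON_MASS"]

PROTON_MASS = {"monoisotopic": 1.00727646677, "average": 1.00739, "nominal": 1}

_AA = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def peptide_mass(sequence: str, mode: MassMode | str = MassMode.MONOISOTOPIC) -> float:
    """Neutral mass of an unmodified peptide (residue masses + water)."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    if not _AA.match(sequence):
        raise ValueError(f"sequence contains non-standard letters: {sequence!r}")
    mode = MassMode(mode)
    if mode is MassMode.NOMINAL:
        # nominal = monoisotopic rounded per residue; rarely useful, but the
        # dialect is supported everywhere else so keep it total
        return round(_pmass.calculate_mass(sequence=sequence))
    return _pmass.calculate_mass(sequence=sequence, average=mode is MassMode.AVERAGE)


def charged_mz(neutral_mass: float, z: int, mode: MassMode | str = MassMode.MONOISOTOPIC) -> float:
    """m/z of the z-fold protonated species, (M + z·mH+)/z."""
    if z < 1:
        raise ValueError("charge z must be >= 1")
    mode = MassMode(mode)
    return (neutral_mass + z * PROTON_MASS[mode.value]) / z


def glycosylation_percent(apparent_kda: float, calculated_kda: float) -> float:
    """Mass fraction attributed to glycans: 100·(apparent − calculated)/apparent,
    one decimal — e.g. a 57.5 kDa band for a 34.89979 kDa polypeptide is
    39.3% glycosylated."""
    if not apparent_kda >= calculated_kda > 0:
        raise ValueError(
            f"need apparent >= calculated > 0, got {apparent_kda}, {calculated_kda}"
        )
    return round(100.0 * (apparent_kda - calculated_kda) / apparent_kda, 1)
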