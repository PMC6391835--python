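"""Adduct/cluster-ion enumeration and peak-list annotation.

ESI full-scan spectra of monosaccharide mixtures in acidified
methanol/water are dense with cluster ions: one or two analyte molecules
picking up protons, sodium or ammonium (positive mode) or losing protons
with optional sodium-for-proton substitution (negative mode), decorated
with neutral solvent adducts (H2O, NH3, CH3OH, HCOOH, CH3COOH), at charge
1 or 2.  This module enumerates *every* ion species within configurable
bounds whose m/z matches an observed peak — complete enumeration, no
pruning heuristics — and ranks candidates by parsimony.

It also builds theoretical MALDI series for sodiated oligosaccharides
(the "DPn+delta" ladder) and explains MS/MS fragments as small neutral
losses/gains from a parent ion.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .masses import DEFAULT_LIBRARY, ELECTRON_MASS, MassMode, SmallMoleculeLibrary

__all__ = [
    "IonSpecies",
    "AnnotationConfig",
    "PeakList",
    "Annotation",
    "ion_mz",
    "enumerate_candidates",
    "annotate_peaklist",
    "maldi_series",
    "explain_fragments",
    "FragmentExplanation",
]

_H_ATOM = {"nominal": 1, "monoisotopic": 1.00782503207, "average": 1.008}
_NA_ATOM = {"nominal": 23, "monoisotopic": 22.98976928, "average": 22.9898}

POSITIVE_CARRIERS = ("proton", "sodium", "ammonium")
NEGATIVE_CARRIERS = ("deprotonation", "sodium-replacing-proton")

#: default analyte set: the seven monosaccharide species released by
#: glucosidase/glucuronidase digestion plus the three ascorbate forms of
#: the reductant present in the reaction
DEFAULT_ANALYTES = (
    "glucose",
    "gluconic acid",
    "gluconic acid lactone",
    "glucuronic acid",
    "glucuronic acid lactone",
    "saccharic acid",
    "saccharic acid lactone",
    "reduced ascorbate",
    "oxidized ascorbate",
    "oxidized-dehydrated ascorbate",
)

DEFAULT_ADDUCTS = ("H2O", "NH3", "CH3OH", "HCOOH", "CH3COOH")


@dataclass(frozen=True)
class IonSpecies:
    """A decomposition of an observed m/z into analytes, charge carriers
    and neutral adducts.

    Positive mode: ``carriers`` counts cationic attachments (proton,
    sodium, ammonium); z = total carrier count.

    Negative mode: ``carriers`` counts ``deprotonation`` (each removes one
    proton) and ``sodium-replacing-proton`` (a sodium taking the place of
    one of the removed protons, neutralizing one charge); the net charge is
    deprotonations minus substitutions and must stay >= 1.
    """

    polarity: str  # "positive" | "negative"
    analytes: tuple[str, ...]
    carriers: tuple[tuple[str, int], ...]
    neutral_adducts: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "analytes", tuple(sorted(self.analytes)))
        object.__setattr__(self, "neutral_adducts", tuple(sorted(self.neutral_adducts)))
        carriers = tuple(sorted((k, v) for k, v in dict(self.carriers).items() if v))
        object.__setattr__(self, "carriers", carriers)
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if not self.analytes:
            raise ValueError("an ion needs at least one analyte")
        allowed = POSITIVE_CARRIERS if self.polarity == "positive" else NEGATIVE_CARRIERS
        for name, n in carriers:
            if name not in allowed:
                raise ValueError(f"carrier {name!r} not legal in {self.polarity} mode")
            if n < 0:
                raise ValueError("carrier counts must be >= 0")
        if self.z < 1:
            raise ValueError("net charge must be >= 1")

    def carrier_count(self, name: str) -> int:
        return dict(self.carriers).get(name, 0)

    @property
    def z(self) -> int:
        if self.polarity == "positive":
            return sum(n for _, n in self.carriers)
        return self.carrier_count("deprotonation") - self.carrier_count(
            "sodium-replacing-proton"
        )

    @property
    def component_count(self) -> int:
        """Total building blocks — the parsimony measure for ranking."""
        return (
            len(self.analytes)
            + sum(n for _, n in self.carriers)
            + len(self.neutral_adducts)
        )

    def describe(self, library: SmallMoleculeLibrary = DEFAULT_LIBRARY) -> str:
        """Decomposition string in peak-table style, e.g. ``194 − 2H+ + Na+ + HCOOH``."""
        parts = [
            " + ".join(str(int(library.mass(a))) for a in self.analytes)
        ]
        if self.polarity == "positive":
            sym = {"proton": "H+", "sodium": "Na+", "ammonium": "NH4+"}
            for name, n in self.carriers:
                parts.append(f"{n if n > 1 else ''}{sym[name]}")
            text = " + ".join(parts)
        else:
            n_dep = self.carrier_count("deprotonation")
            n_na = self.carrier_count("sodium-replacing-proton")
            text = parts[0] + f" − {n_dep if n_dep > 1 else ''}H+"
            if n_na:
                text += f" + {n_na if n_na > 1 else ''}Na+"
        for adduct, n in sorted(Counter(self.neutral_adducts).items()):
            text += f" + {n if n > 1 else ''}{adduct}"
        if self.z > 1:
            text += f"/{self.z}"
        return text


def ion_mz(
    ion: IonSpecies,
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
    mode: MassMode | str = MassMode.NOMINAL,
) -> float:
    """Charge-normalized mass of an ion species.

    Nominal mode is pure integer arithmetic (electrons ignored);
    monoisotopic mode books hydrogen/sodium as atoms and adds z electron
    masses for anions (cationic carrier masses are already
    electron-corrected in the library).
    """
    mode = MassMode(mode)
    m = mode.value
    total = sum(library.mass(a, mode) for a in ion.analytes)
    total += sum(library.mass(a, mode) for a in ion.neutral_adducts)
    z = ion.z
    if ion.polarity == "positive":
        for name, n in ion.carriers:
            total += n * library.mass(name, mode)
    else:
        n_dep = ion.carrier_count("deprotonation")
        n_na = ion.carrier_count("sodium-replacing-proton")
        total += -n_dep * _H_ATOM[m] + n_na * _NA_ATOM[m]
        if mode is MassMode.MONOISOTOPIC:
            total += z * ELECTRON_MASS
    mz = total / z
    if mode is MassMode.NOMINAL:
        # nominal m/z of a multiply charged ion may be half-integral
        return mz
    return mz


@dataclass(frozen=True)
class AnnotationConfig:
    """Bounds of the enumeration space and the matching rule.

    The default bounds (<=2 analytes, charge <=2, <=6 neutral adducts, one
    sodium substitution) are the smallest that cover every decomposition
    the full-scan cluster-ion tables print; the densest printed anions
    carry six neutral adducts (e.g. 4 H2O + CH3OH + HCOOH on a doubly
    deprotonated uronate).
    """

    polarity: str = "positive"
    mode: MassMode = MassMode.NOMINAL
    tolerance: Optional[float] = None  # None => nominal integer matching
    max_analytes: int = 2
    max_z: int = 2
    max_neutral_adducts: int = 6
    max_sodium_substitutions: int = 1
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    adducts: tuple[str, ...] = DEFAULT_ADDUCTS

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be positive|negative")
        object.__setattr__(self, "mode", MassMode(self.mode))
        if self.mode is not MassMode.NOMINAL and self.tolerance is None:
            raise ValueError("non-nominal modes need an explicit tolerance")


def _carrier_combos(config: AnnotationConfig) -> list[tuple[tuple[str, int], ...]]:
    combos = []
    if config.polarity == "positive":
        for z in range(1, config.max_z + 1):
            for combo in itertools.combinations_with_replacement(POSITIVE_CARRIERS, z):
                combos.append(tuple(sorted(Counter(combo).items())))
    else:
        for n_na in range(0, config.max_sodium_substitutions + 1):
            for z in range(1, config.max_z + 1):
                n_dep = z + n_na
                combos.append(
                    tuple(
                        sorted(
                            {
                                "deprotonation": n_dep,
                                "sodium-replacing-proton": n_na,
                            }.items()
                        )
                    )
                )
    return sorted(set(combos))


def _iter_ions(config: AnnotationConfig, library: SmallMoleculeLibrary) -> Iterable[IonSpecies]:
    """Exhaustive generator over the configured ion space."""
    analyte_sets = []
    for k in range(1, config.max_analytes + 1):
        analyte_sets.extend(itertools.combinations_with_replacement(config.analytes, k))
    adduct_sets = []
    for k in range(0, config.max_neutral_adducts + 1):
        adduct_sets.extend(itertools.combinations_with_replacement(config.adducts, k))
    carrier_sets = _carrier_combos(config)
    for analytes in analyte_sets:
        for carriers in carrier_sets:
            for adducts in adduct_sets:
                yield IonSpecies(config.polarity, analytes, carriers, adducts)


_INDEX_CACHE: dict = {}


def _ion_index(config: AnnotationConfig, library: SmallMoleculeLibrary):
    """Bucket every ion in the space by rounded nominal m/z (or keep a
    sorted list for tolerance matching in exact-mass modes)."""
    key = (config, library.version)
    if key in _INDEX_CACHE:
        return _INDEX_CACHE[key]
    if config.mode is MassMode.NOMINAL:
        index: dict[float, list[IonSpecies]] = {}
        for ion in _iter_ions(config, library):
            mz = ion_mz(ion, library, config.mode)
            index.setdefault(_round_half_up(mz), []).append(ion)
    else:
        index = sorted(
            (ion_mz(ion, library, config.mode), ion) for ion in _iter_ions(config, library)
        )
    _INDEX_CACHE[key] = index
    return index


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def _rank_key(ion: IonSpecies):
    return (ion.component_count, len(ion.analytes), ion.z, ion.describe())


def enumerate_candidates(
    target_mz: float,
    config: AnnotationConfig = AnnotationConfig(),
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> list[IonSpecies]:
    """All ion species within the configured bounds matching ``target_mz``.

    Nominal mode matches after half-up integer rounding of both target and
    candidate m/z (half-integral m/z of 2+ ions rounds up, matching how
    peak tables print them); other modes match within ``config.tolerance``.
    Output is complete w.r.t. the bounds and deterministically ordered by
    parsimony (fewest components, then fewest analytes, then lowest charge,
    then lexicographically).
    """
    index = _ion_index(config, library)
    if config.mode is MassMode.NOMINAL:
        hits = index.get(_round_half_up(target_mz), [])
    else:
        import bisect

        lo = bisect.bisect_left(index, (target_mz - config.tolerance, None))
        hits = [ion for mz, ion in index[lo:] if mz <= target_mz + config.tolerance]
    return sorted(hits, key=_rank_key)


# ---------------------------------------------------------------------------
# peak lists and annotation
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """An observed or theoretical spectrum."""

    mz: list[float]
    intensity: list[float]
    polarity: str = "positive"
    instrument: str = "esi"  # esi | maldi
    labels: Optional[list[str]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.mz) != len(self.intensity):
            raise ValueError("mz and intensity lengths differ")
        if any(m <= 0 for m in self.mz):
            raise ValueError("m/z values must be strictly positive")
        if any(i < 0 for i in self.intensity):
            raise ValueError("intensities must be nonnegative")
        order = sorted(range(len(self.mz)), key=lambda i: self.mz[i])
        self.mz = [self.mz[i] for i in order]
        self.intensity = [self.intensity[i] for i in order]
        if self.labels is not None:
            self.labels = [self.labels[i] for i in order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Annotation:
    peak_index: int
    mz: float
    candidates: list[IonSpecies]

    @property
    def assigned(self) -> bool:
        return bool(self.candidates)


def annotate_peaklist(
    peaks: PeakList,
    config: AnnotationConfig = AnnotationConfig(),
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> list[Annotation]:
    """One ranked candidate list per peak; empty list marks an unassigned peak."""
    if peaks.polarity != config.polarity:
        raise ValueError(
            f"peak list is {peaks.polarity} but config is {config.polarity}"
        )
    return [
        Annotation(i, mz, enumerate_candidates(mz, config, library))
        for i, mz in enumerate(peaks.mz)
    ]


# ---------------------------------------------------------------------------
# MALDI oligosaccharide series
# ---------------------------------------------------------------------------

#: oxidation delta classes observed in the sodiated MALDI ladder of a
#: monooxygenase digest (non-oxidized, −2 keto/aldehyde, +12 lactone of
#: +30, +14 uronate or C1+C4, +16 aldonic, +28 double, +30 C1+C6)
MALDI_DELTA_CLASSES = (0, -2, 12, 14, 16, 28, 30)


def maldi_series(
    dp_range: Sequence[int],
    delta_classes: Sequence[int] = MALDI_DELTA_CLASSES,
    cation: str = "sodium",
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
    mode: MassMode | str = MassMode.NOMINAL,
) -> PeakList:
    """Theoretical singly charged cationized peak ladder.

    m/z = 162·dp + 18 + delta + cation, labeled ``DP{n}{+/-delta}``
    (a DP3 chain in the −2 class is the "DP3-2" peak).
    """
    dps = list(dp_range)
    if not dps:
        raise ValueError("dp_range must be nonempty")
    cation_mass = library.mass(cation, mode)  # KeyError for unknown cations
    mode = MassMode(mode)
    from .composition import _ANHYDROGLUCOSE, _H2O  # shared dialect constants

    mzs, labels = [], []
    for dp in dps:
        for delta in delta_classes:
            mz = _ANHYDROGLUCOSE[mode.value] * dp + _H2O[mode.value] + delta + cation_mass
            mzs.append(int(mz) if mode is MassMode.NOMINAL else mz)
            labels.append(f"DP{dp}{delta:+d}")
    order = sorted(range(len(mzs)), key=lambda i: mzs[i])
    return PeakList(
        mz=[mzs[i] for i in order],
        intensity=[0.0] * len(mzs),
        polarity="positive",
        instrument="maldi",
        labels=[labels[i] for i in order],
        metadata={"cation": cation, "mode": mode.value},
    )


# ---------------------------------------------------------------------------
# MS/MS fragment explanation
# ---------------------------------------------------------------------------

DEFAULT_LOSSES: Mapping[str, int] = {"H": 1, "H2O": 18, "CHO": 29, "COOH": 45}
DEFAULT_GAINS: Mapping[str, int] = {"H": 1}


@dataclass
class FragmentExplanation:
    fragment_mz: float
    paths: list[tuple[tuple[str, ...], tuple[str, ...]]]  # (losses, gains)

    @property
    def explained(self) -> bool:
        return bool(self.paths)


def explain_fragments(
    parent_mz: float,
    fragment_mzs: Sequence[float],
    loss_set: Mapping[str, float] = DEFAULT_LOSSES,
    gain_set: Mapping[str, float] = DEFAULT_GAINS,
    max_steps: int = 3,
    tolerance: float = 0.5,
) -> list[FragmentExplanation]:
    """Explain MS/MS fragments as neutral losses/gains from the parent.

    Each fragment is searched for combinations of at most ``max_steps``
    total losses plus gains whose net mass shift matches
    ``fragment - parent``; paths are reported shortest first.  The default
    vocabulary is the common negative-mode carbohydrate set: loss of [H],
    [H2O], [CHO], [COOH] and addition of [H].
    """
    steps: list[tuple[str, str, float]] = [("loss", n, -m) for n, m in loss_set.items()]
    steps += [("gain", n, +m) for n, m in gain_set.items()]
    out = []
    for frag in fragment_mzs:
        target = frag - parent_mz
        paths = []
        for k in range(0, max_steps + 1):
            for combo in itertools.combinations_with_replacement(steps, k):
                if abs(sum(s[2] for s in combo) - target) <= tolerance:
                    losses = tuple(sorted(n for kind, n, _ in combo if kind == "loss"))
                    gains = tuple(sorted(n for kind, n, _ in combo if kind == "gain"))
                    if (losses, gains) not in paths:
                        paths.append((losses, gains))
        out.append(FragmentExplanation(frag, paths))
    return out
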