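"""Compositional model of oxidized cello-oligosaccharides.

A cello-oligosaccharide is an ordered chain of glucosyl residues
(index 0 = non-reducing end, NRE; last index = reducing end, RE).  Each
residue carries an oxidation state, and each state shifts the neutral mass
of the chain by an additive *delta* relative to the unmodified chain
(nominal mass 162·dp + 18):

=====================  =======  =====================================
state                  delta    chemistry
=====================  =======  =====================================
C1 carboxyl (``c1``)   +16      reducing-end aldonic acid
C4 ketone (``c4k``)    −2       4-ketoaldose (oxidative C4 cleavage)
C6 aldehyde (``c6d``)  −2       C6-hexodialdose
C6 carboxyl (``c6a``)  +14      glucuronosyl (uronic acid) residue
lactone (``L``)        −18      intramolecular ester of a carboxyl
Δ4,5 ene (``u``)       −18      unsaturated NRE left by lyase cleavage
=====================  =======  =====================================

The *delta class* of a chain is the sum of its residue deltas — the
quantity a MALDI peak series reads out directly (a "DP3−2" peak is a DP3
chain whose residue deltas sum to −2).  Because C4 ketones and C6
aldehydes share the −2 delta, and several multi-oxidation combinations
collide (+14 is both C1+C4 and a single C6 acid), a delta class generally
has several structural explanations; :func:`delta_explanations` enumerates
all of them.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .masses import (
    ANHYDROGLUCOSE_NOMINAL,
    WATER_NOMINAL,
    DEFAULT_LIBRARY,
    MassMode,
    SmallMoleculeLibrary,
)

__all__ = [
    "C6State",
    "OxidationState",
    "Oligosaccharide",
    "StateGrammar",
    "InvalidStateError",
    "residue_delta",
    "oligo_mass",
    "delta_explanations",
    "expand_positions",
    "monosaccharide_identity",
    "unmodified",
    "parse_oligo",
    "format_oligo",
]


class InvalidStateError(ValueError):
    """An oxidation state or chain violates a structural invariant."""


class C6State:
    NONE = "none"
    ALDEHYDE = "aldehyde"
    ACID = "acid"
    ALL = (NONE, ALDEHYDE, ACID)


# exact-mass deltas per dialect; nominal values are the integer arithmetic
# used throughout peak assignment
_O = {"nominal": 16, "monoisotopic": 15.99491462, "average": 15.999}
_H2 = {"nominal": 2, "monoisotopic": 2.01565007, "average": 2.016}
_H2O = {"nominal": 18, "monoisotopic": 18.01056468, "average": 18.015}
_ANHYDROGLUCOSE = {"nominal": 162, "monoisotopic": 162.05282343, "average": 162.1406}


@dataclass(frozen=True, order=True)
class OxidationState:
    """Per-residue oxidation flags.

    ``lactones`` counts intramolecular ester closures; each consumes one
    water and requires a carboxyl to esterify, so ``lactones`` can never
    exceed the number of carboxyls on the residue.
    """

    c1_acid: bool = False
    c4_keto: bool = False
    c6: str = C6State.NONE
    lactones: int = 0
    unsaturated_4_5: bool = False

    def __post_init__(self):
        if self.c6 not in C6State.ALL:
            raise InvalidStateError(f"c6 must be one of {C6State.ALL}, got {self.c6!r}")
        if self.lactones < 0:
            raise InvalidStateError("lactones must be >= 0")
        if self.lactones > self.carboxyl_count:
            raise InvalidStateError(
                f"lactones ({self.lactones}) exceed carboxyl groups "
                f"({self.carboxyl_count}): a lactone is the ester of a carboxyl"
            )

    @property
    def carboxyl_count(self) -> int:
        return int(self.c1_acid) + int(self.c6 == C6State.ACID)

    @property
    def oxidation_events(self) -> int:
        """Number of oxidation events on the residue (lactonization and the
        lyase-derived unsaturation are rearrangements, not oxidations)."""
        return int(self.c1_acid) + int(self.c4_keto) + int(self.c6 != C6State.NONE)

    @property
    def is_plain(self) -> bool:
        return self == OxidationState()

    def label(self) -> str:
        parts = []
        if self.c1_acid:
            parts.append("c1")
        if self.c4_keto:
            parts.append("c4k")
        if self.c6 == C6State.ALDEHYDE:
            parts.append("c6d")
        elif self.c6 == C6State.ACID:
            parts.append("c6a")
        parts.extend("L" * self.lactones)
        if self.unsaturated_4_5:
            parts.append("u")
        return "+".join(parts) if parts else "plain"


def residue_delta(state: OxidationState, mode: MassMode | str = MassMode.NOMINAL) -> float:
    """Additive mass delta contributed by one residue's oxidation state."""
    m = MassMode(mode).value
    d = 0.0
    if state.c1_acid:
        d += _O[m]
    if state.c4_keto:
        d -= _H2[m]
    if state.c6 == C6State.ALDEHYDE:
        d -= _H2[m]
    elif state.c6 == C6State.ACID:
        d += _O[m] - _H2[m]
    d -= _H2O[m] * state.lactones
    if state.unsaturated_4_5:
        d -= _H2O[m]
    if m == "nominal":
        return int(d)
    return d


@dataclass(frozen=True)
class Oligosaccharide:
    """Ordered chain of oxidation states, NRE first, RE last."""

    residues: tuple[OxidationState, ...]

    def __post_init__(self):
        residues = tuple(self.residues)
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise InvalidStateError("an oligosaccharide needs at least one residue")
        for i, r in enumerate(residues):
            if r.c1_acid and i != len(residues) - 1:
                raise InvalidStateError(
                    f"c1_acid on residue {i}: only the reducing-end residue "
                    "has a free C1 to oxidize"
                )
            if r.unsaturated_4_5 and i != 0:
                raise InvalidStateError(
                    f"unsaturated_4_5 on residue {i}: the Δ4,5 ene is a "
                    "non-reducing-end feature"
                )

    @property
    def dp(self) -> int:
        return len(self.residues)

    @property
    def nre(self) -> OxidationState:
        return self.residues[0]

    @property
    def re(self) -> OxidationState:
        return self.residues[-1]

    def mass(self, mode: MassMode | str = MassMode.NOMINAL) -> float:
        return oligo_mass(self, mode)

    @property
    def delta_class(self) -> int:
        """Nominal mass offset from the unmodified chain of the same DP."""
        return int(sum(residue_delta(r) for r in self.residues))

    def __str__(self) -> str:
        return format_oligo(self)


def unmodified(dp: int) -> Oligosaccharide:
    return Oligosaccharide(tuple(OxidationState() for _ in range(dp)))


def oligo_mass(oligo: Oligosaccharide, mode: MassMode | str = MassMode.NOMINAL) -> float:
    """Neutral mass: dp anhydroglucose units + one water + residue deltas."""
    m = MassMode(mode).value
    base = _ANHYDROGLUCOSE[m] * oligo.dp + _H2O[m]
    total = base + sum(residue_delta(r, mode) for r in oligo.residues)
    if m == "nominal":
        return int(total)
    return total


# ---------------------------------------------------------------------------
# delta-class explanation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateGrammar:
    """Which oxidation features :func:`delta_explanations` may use.

    The Δ4,5 unsaturation is off by default: it is a lyase product, not a
    monooxygenase product, so it does not belong in the explanation space
    of an oxidation peak series unless the sample saw a lyase.
    """

    c1_acid: bool = True
    c4_keto: bool = True
    c6_aldehyde: bool = True
    c6_acid: bool = True
    lactones: bool = True
    unsaturated: bool = False


def _legal_states(grammar: StateGrammar) -> list[OxidationState]:
    states = []
    c6_options = [C6State.NONE]
    if grammar.c6_aldehyde:
        c6_options.append(C6State.ALDEHYDE)
    if grammar.c6_acid:
        c6_options.append(C6State.ACID)
    for c1, c4, c6, u in itertools.product(
        (False, True) if grammar.c1_acid else (False,),
        (False, True) if grammar.c4_keto else (False,),
        c6_options,
        (False, True) if grammar.unsaturated else (False,),
    ):
        max_lact = (int(c1) + int(c6 == C6State.ACID)) if grammar.lactones else 0
        for lact in range(max_lact + 1):
            states.append(OxidationState(c1, c4, c6, lact, u))
    return states


Composition = tuple[OxidationState, ...]  # sorted multiset of modified residues


def delta_explanations(
    delta: int,
    dp: int,
    cap: int = 3,
    grammar: StateGrammar | None = None,
) -> set[Composition]:
    """Every multiset of residue oxidation states summing to ``delta``.

    Returns compositions — multisets of the *modified* residues' states,
    residue positions abstracted away (a chain offers several equivalent C6
    positions; a peak cannot tell them apart).  ``cap`` bounds the total
    oxidation events per chain.  Positional legality is respected: at most
    one C1 acid (there is one reducing end) and at most one Δ4,5 ene (one
    non-reducing end), the two coinciding only on a monosaccharide.
    """
    if dp < 1:
        raise ValueError("dp must be >= 1")
    grammar = grammar or StateGrammar()
    candidates = [s for s in _legal_states(grammar) if not s.is_plain]
    out: set[Composition] = set()
    max_modified = min(dp, cap)  # every modified residue carries >= 1 event
    for k in range(0, max_modified + 1):
        for combo in itertools.combinations_with_replacement(candidates, k):
            if sum(s.oxidation_events for s in combo) > cap:
                continue
            n_c1 = sum(s.c1_acid for s in combo)
            n_u = sum(s.unsaturated_4_5 for s in combo)
            if n_c1 > 1 or n_u > 1:
                continue
            # c1 sits on the RE, the ene on the NRE: one residue can hold
            # both only when the chain is a single residue
            if dp > 1 and any(s.c1_acid and s.unsaturated_4_5 for s in combo):
                continue
            if int(sum(residue_delta(s) for s in combo)) == int(delta):
                out.add(tuple(sorted(combo)))
    return out


def expand_positions(composition: Composition, dp: int) -> list[Oligosaccharide]:
    """All distinct positioned chains realizing a composition at length ``dp``."""
    if len(composition) > dp:
        return []
    pad = [OxidationState()] * (dp - len(composition))
    states = list(composition) + pad
    seen: set[tuple[OxidationState, ...]] = set()
    out = []
    for perm in set(itertools.permutations(states)):
        try:
            oligo = Oligosaccharide(perm)
        except InvalidStateError:
            continue
        if perm not in seen:
            seen.add(perm)
            out.append(oligo)
    return sorted(out, key=lambda o: tuple(r.label() for r in o.residues))


# ---------------------------------------------------------------------------
# monosaccharide naming
# ---------------------------------------------------------------------------

_MONOSACCHARIDE_NAMES = {
    # (c1_acid, c6 acid, lactones) -> name
    (False, False, 0): "glucose",
    (True, False, 0): "gluconic acid",
    (True, False, 1): "gluconic acid lactone",
    (False, True, 0): "glucuronic acid",
    (False, True, 1): "glucuronic acid lactone",
    (True, True, 0): "saccharic acid",
    (True, True, 1): "saccharic acid lactone",
}


def monosaccharide_identity(
    oligo: Oligosaccharide,
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> Optional[str]:
    """Standard name of a DP1 species, or ``None`` when no standard exists.

    C4-keto and C6-aldehyde monosaccharides have no named analytical
    standard, so they map to ``None`` (a result, not an error).
    """
    if oligo.dp != 1:
        raise ValueError(f"monosaccharide_identity needs dp == 1, got dp == {oligo.dp}")
    s = oligo.residues[0]
    if s.c4_keto or s.c6 == C6State.ALDEHYDE or s.unsaturated_4_5:
        return None
    name = _MONOSACCHARIDE_NAMES.get((s.c1_acid, s.c6 == C6State.ACID, s.lactones))
    if name is not None and name not in library:
        return None
    return name


# ---------------------------------------------------------------------------
# string grammar:  G-G(c6a)-G(c1,L)   NRE -> RE
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"^G(?:\(([^)]*)\))?$")


def format_oligo(oligo: Oligosaccharide) -> str:
    parts = []
    for r in oligo.residues:
        tokens = []
        if r.c1_acid:
            tokens.append("c1")
        if r.c4_keto:
            tokens.append("c4k")
        if r.c6 == C6State.ALDEHYDE:
            tokens.append("c6d")
        elif r.c6 == C6State.ACID:
            tokens.append("c6a")
        tokens.extend(["L"] * r.lactones)
        if r.unsaturated_4_5:
            tokens.append("u")
        parts.append("G({})".format(",".join(tokens)) if tokens else "G")
    return "-".join(parts)


def parse_oligo(text: str) -> Oligosaccharide:
    """Parse the compact chain grammar, e.g. ``"G(u,c6a)-G-G(c1)"``."""
    residues = []
    for part in text.strip().split("-"):
        m = _TOKEN_RE.match(part.strip())
        if not m:
            raise ValueError(f"bad residue token {part!r} (expected G or G(flags))")
        c1 = c4 = u = False
        c6 = C6State.NONE
        lact = 0
        if m.group(1):
            for tok in m.group(1).split(","):
                tok = tok.strip()
                if tok == "c1":
                    c1 = True
                elif tok == "c4k":
                    c4 = True
                elif tok == "c6d":
                    c6 = C6State.ALDEHYDE
                elif tok == "c6a":
                    c6 = C6State.ACID
                elif tok == "L":
                    lact += 1
                elif tok == "u":
                    u = True
                elif tok:
                    raise ValueError(f"unknown oxidation token {tok!r}")
        residues.append(OxidationState(c1, c4, c6, lact, u))
    return Oligosaccharide(tuple(residues))
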