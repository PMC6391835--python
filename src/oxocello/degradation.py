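"""Rule-based enzymatic degradation of oxidized cello-oligosaccharides.

Three actors:

* **PMO** — the monooxygenase itself, modeled as a discrete-step
  stochastic process on a pool of chains: oxidative chain cleavage at C1
  (leaving an aldonic-acid reducing end on the proximal fragment) or C4
  (leaving a 4-keto non-reducing end on the distal fragment), and on-chain
  C6 oxidation, hydroxymethyl → aldehyde → carboxyl.
* **Exo-hydrolases** — beta-glucosidase (BGL) releases an unmodified
  glucosyl from the non-reducing end; beta-glucuronidase (GUS) releases a
  C6-carboxyl (glucuronosyl) residue.  Alternating, they reduce a
  uronate-containing chain to glucose, glucuronic acid and — when the
  reducing end is doubly oxidized — saccharic acid.
* **PL (lyase)** — beta-eliminative cleavage at a uronate: the bond on the
  C4 side of the uronate breaks without water, the proximal fragment gains
  a new reducing end and the uronate becomes a Δ4,5-unsaturated
  non-reducing end.

Every operation keeps a mass ledger: hydrolysis adds one water (+18
nominal) per cleavage, beta-elimination adds none, and the ledger is
checked after each digest so a bookkeeping bug cannot pass silently.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .composition import (
    C6State,
    InvalidStateError,
    Oligosaccharide,
    OxidationState,
    monosaccharide_identity,
    oligo_mass,
    unmodified,
)
from .masses import DEFAULT_LIBRARY, SmallMoleculeLibrary, WATER_NOMINAL

__all__ = [
    "ProductCensus",
    "PmoEventModel",
    "SimulationResult",
    "RuleNotApplicableError",
    "digest",
    "pl_cleave",
    "pmo_simulate",
    "census_to_spectrum",
]


class RuleNotApplicableError(ValueError):
    """An enzyme rule was applied to a residue it does not accept."""


@dataclass
class ProductCensus:
    """Multiset of released monosaccharides plus stalled residual chains."""

    monosaccharides: Counter = field(default_factory=Counter)
    residuals: list[Oligosaccharide] = field(default_factory=list)
    hydrolytic_cleavages: int = 0
    input_mass: int = 0
    output_mass: int = 0

    def total_output_mass(self, library: SmallMoleculeLibrary = DEFAULT_LIBRARY) -> int:
        total = sum(
            int(library.mass(name)) * n for name, n in self.monosaccharides.items()
        )
        total += sum(int(oligo_mass(o)) for o in self.residuals)
        return total

    def check_ledger(self, library: SmallMoleculeLibrary = DEFAULT_LIBRARY) -> None:
        expected = self.input_mass + WATER_NOMINAL * self.hydrolytic_cleavages
        got = self.total_output_mass(library)
        if got != expected:
            raise RuntimeError(
                f"mass ledger violated: products {got} != parents {self.input_mass} "
                f"+ {self.hydrolytic_cleavages} waters"
            )


def _bgl_accepts(nre: OxidationState) -> bool:
    return nre.is_plain


def _gus_accepts(nre: OxidationState) -> bool:
    return nre == OxidationState(c6=C6State.ACID)


def digest(
    pool: Iterable[Oligosaccharide],
    enzymes: Sequence[str] = ("BGL", "GUS"),
    stall_policy: str = "stall",
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> ProductCensus:
    """Exo-digest a pool to fixed point with BGL and/or GUS.

    Both enzymes attack only the non-reducing end of chains with dp >= 2;
    the terminal dp=1 species is named by ``monosaccharide_identity``.
    A non-reducing end neither enzyme accepts (C4 ketone, C6 aldehyde,
    Δ4,5 ene, lactone) stalls the chain, which is reported as a residual;
    under ``stall_policy="pass-through"`` the blocked residue is released
    anyway and counted under an ``unnamed:`` key, letting digestion
    continue past it.  Deterministic and order-independent: chains are
    processed independently and the census is a sum.
    """
    enzymes = {e.upper() for e in enzymes}
    unknown = enzymes - {"BGL", "GUS"}
    if unknown:
        raise ValueError(f"unknown enzymes {sorted(unknown)}")
    if stall_policy not in ("stall", "pass-through"):
        raise ValueError("stall_policy must be 'stall' or 'pass-through'")

    census = ProductCensus()
    for oligo in pool:
        census.input_mass += int(oligo_mass(oligo))
        residues = list(oligo.residues)
        while len(residues) >= 2:
            nre = residues[0]
            if "BGL" in enzymes and _bgl_accepts(nre):
                census.monosaccharides["glucose"] += 1
            elif "GUS" in enzymes and _gus_accepts(nre):
                census.monosaccharides["glucuronic acid"] += 1
            elif stall_policy == "pass-through":
                census.monosaccharides[f"unnamed:{nre.label()}"] += 1
            else:
                census.residuals.append(Oligosaccharide(tuple(residues)))
                residues = []
                break
            census.hydrolytic_cleavages += 1
            residues = residues[1:]
        if len(residues) == 1:
            mono = Oligosaccharide((residues[0],))
            name = monosaccharide_identity(mono, library)
            if name is not None:
                census.monosaccharides[name] += 1
            else:
                census.residuals.append(mono)
    census.output_mass = census.total_output_mass(_library_for_census(census, library))
    census.check_ledger(_library_for_census(census, library))
    return census


def _library_for_census(census: ProductCensus, library: SmallMoleculeLibrary):
    """Extend the library with masses of pass-through ``unnamed:`` monomers
    so the mass ledger can still be balanced."""
    extra = {}
    for key in census.monosaccharides:
        if key.startswith("unnamed:") and key not in library:
            from .composition import parse_oligo, residue_delta

            label = key.split(":", 1)[1]
            # reconstruct the monomer mass from its state label
            state = parse_oligo("G" if label == "plain" else f"G({label.replace('+', ',')})").residues[0]
            extra[key] = (180 + int(residue_delta(state)), "")
    return library.extended(extra) if extra else library


def pl_cleave(
    oligo: Oligosaccharide, site_index: int
) -> tuple[Oligosaccharide, Oligosaccharide]:
    """Beta-eliminative (lyase) cleavage at the uronate at ``site_index``.

    ``site_index`` is the 0-based position of a C6-carboxyl residue with
    1 <= site_index <= dp−1: the glycosidic bond on its C4 side (toward
    the non-reducing end) breaks, no water is consumed, the proximal
    fragment acquires an ordinary reducing end and the uronate becomes the
    Δ4,5-unsaturated non-reducing end of the distal fragment.  Fragment
    masses sum exactly to the parent mass.
    """
    if not 1 <= site_index <= oligo.dp - 1:
        raise RuleNotApplicableError(
            f"site_index {site_index} outside 1..{oligo.dp - 1}"
        )
    target = oligo.residues[site_index]
    if target.c6 != C6State.ACID:
        raise RuleNotApplicableError(
            f"residue {site_index} ({target.label()}) bears no C6 carboxyl; "
            "lyase cleavage needs a uronate"
        )
    proximal = Oligosaccharide(oligo.residues[:site_index])
    distal_nre = replace(target, unsaturated_4_5=True)
    distal = Oligosaccharide((distal_nre,) + oligo.residues[site_index + 1:])
    return proximal, distal


# ---------------------------------------------------------------------------
# stochastic monooxygenase event model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PmoEventModel:
    """Per-site, per-step event probabilities of the monooxygenase.

    The enzyme's kinetics are not characterized; these are free parameters
    of a site-uniform Bernoulli process.  ``c1_cleavage`` and
    ``c4_cleavage`` act on glycosidic bonds, ``c6_to_aldehyde`` on
    residues with an unoxidized C6, ``c6_aldehyde_to_acid`` on residues
    whose C6 is already the aldehyde.
    """

    c1_cleavage: float = 0.0
    c4_cleavage: float = 0.0
    c6_to_aldehyde: float = 0.0
    c6_aldehyde_to_acid: float = 0.0
    steps: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("c1_cleavage", "c4_cleavage", "c6_to_aldehyde", "c6_aldehyde_to_acid"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.steps < 0:
            raise ValueError("steps must be >= 0")


@dataclass
class SimulationResult:
    pool: list[Oligosaccharide]
    event_counts: Counter
    opportunity_counts: Counter

    def delta_class_census(self) -> Counter:
        """Counter over (dp, delta_class) — the theoretical MALDI readout."""
        return Counter((o.dp, o.delta_class) for o in self.pool)


_EVENTS = ("c1_cleavage", "c4_cleavage", "c6_to_aldehyde", "c6_aldehyde_to_acid")


def pmo_simulate(
    chains: Sequence[int] | Sequence[Oligosaccharide],
    model: PmoEventModel,
) -> SimulationResult:
    """Run the stochastic oxidation/cleavage process.

    ``chains`` is either a list of chain lengths (unmodified cellulose
    chains) or a list of starting oligosaccharides.  Within a step all
    events are drawn against the step's starting state: C6 oxidations
    first (an aldehyde made this step cannot convert to the acid until the
    next step), then bond cleavages (at a bond where both cleavage
    chemistries could fire, C1 is drawn first and C4 is only offered the
    bond if C1 declined, so each event type stays an exact Bernoulli trial
    on its tallied opportunities).  Reproducible under ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    pool: list[list[OxidationState]] = []
    for c in chains:
        if isinstance(c, Oligosaccharide):
            pool.append(list(c.residues))
        else:
            pool.append(list(unmodified(int(c)).residues))

    events: Counter = Counter()
    opportunities: Counter = Counter()

    for _ in range(model.steps):
        next_pool: list[list[OxidationState]] = []
        for chain in pool:
            n = len(chain)
            # --- C6 oxidation events (on the step's starting state)
            new_chain = list(chain)
            for i, r in enumerate(chain):
                if r.unsaturated_4_5:
                    continue
                if r.c6 == C6State.NONE:
                    opportunities["c6_to_aldehyde"] += 1
                    if rng.random() < model.c6_to_aldehyde:
                        events["c6_to_aldehyde"] += 1
                        new_chain[i] = replace(r, c6=C6State.ALDEHYDE)
                elif r.c6 == C6State.ALDEHYDE:
                    opportunities["c6_aldehyde_to_acid"] += 1
                    if rng.random() < model.c6_aldehyde_to_acid:
                        events["c6_aldehyde_to_acid"] += 1
                        new_chain[i] = replace(r, c6=C6State.ACID)
            # --- cleavage events on bonds (bond i joins residues i-1, i)
            cuts: list[tuple[int, str]] = []
            for bond in range(1, n):
                opportunities["c1_cleavage"] += 1
                if rng.random() < model.c1_cleavage:
                    events["c1_cleavage"] += 1
                    cuts.append((bond, "c1"))
                    continue
                opportunities["c4_cleavage"] += 1
                if rng.random() < model.c4_cleavage:
                    events["c4_cleavage"] += 1
                    cuts.append((bond, "c4"))
            # apply cuts left to right
            start = 0
            for bond, kind in cuts:
                frag = new_chain[start:bond]
                if kind == "c1":
                    frag[-1] = replace(frag[-1], c1_acid=True)
                else:  # c4: the keto mark lands on the distal fragment's NRE
                    new_chain[bond] = replace(new_chain[bond], c4_keto=True)
                next_pool.append(frag)
                start = bond
            next_pool.append(new_chain[start:])
        pool = next_pool

    return SimulationResult(
        pool=[Oligosaccharide(tuple(c)) for c in pool],
        event_counts=events,
        opportunity_counts=opportunities,
    )


def census_to_spectrum(
    source: ProductCensus | Iterable[Oligosaccharide],
    cation: str = "sodium",
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
):
    """Theoretical singly cationized MALDI peak list of a pool or census;
    intensity = species count, peaks merged per m/z."""
    from .ions import PeakList

    cation_mass = int(library.mass(cation))
    acc: dict[int, float] = {}
    labels: dict[int, str] = {}

    def add(mz: int, label: str, count: float = 1.0):
        acc[mz] = acc.get(mz, 0.0) + count
        labels.setdefault(mz, label)

    if isinstance(source, ProductCensus):
        for name, n in source.monosaccharides.items():
            if name in library:
                add(int(library.mass(name)) + cation_mass, name, n)
        oligos: Iterable[Oligosaccharide] = source.residuals
    else:
        oligos = source
    for o in oligos:
        mz = int(oligo_mass(o)) + cation_mass
        add(mz, f"DP{o.dp}{o.delta_class:+d}")
    mzs = sorted(acc)
    return PeakList(
        mz=[float(m) for m in mzs],
        intensity=[acc[m] for m in mzs],
        polarity="positive",
        instrument="maldi",
        labels=[labels[m] for m in mzs],
        metadata={"cation": cation},
    )
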