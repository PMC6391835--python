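"""Bromine-water oxidation of oligosaccharide pools.

Saturated bromine water oxidizes free aldehydes to carboxyls and leaves
ketones untouched.  On an oxidized cello-oligosaccharide that means:

* every in-chain C6 aldehyde (hexodialdose) becomes a C6 carboxyl
  (uronate), +16 per site;
* the free anomeric aldehyde at the reducing end becomes a C1 carboxyl
  (aldonic acid), +16, unless it already was one;
* C4 ketones survive unchanged.

Comparing delta classes before and after treatment therefore separates
the mass-degenerate −2 candidates: a C6 aldehyde moves −2 → +30 while a
C4 ketone moves −2 → +14.  The transform is idempotent — after one pass
no aldehyde remains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .composition import (
    C6State,
    Composition,
    InvalidStateError,
    Oligosaccharide,
    OxidationState,
    residue_delta,
)

__all__ = ["Br2Options", "br2_transform", "br2_delta_map", "Br2Result"]

LACTONE_POLICIES = ("preserve", "open", "equilibrate-both")


@dataclass(frozen=True)
class Br2Options:
    """``oxidize_reducing_end`` is on by default (aldoses are bromine
    substrates); ``lactone_policy`` chooses whether existing lactones are
    kept (``preserve``), hydrolyzed back to the free acids (``open``), or
    both forms returned (``equilibrate-both``)."""

    oxidize_reducing_end: bool = True
    lactone_policy: str = "preserve"

    def __post_init__(self):
        if self.lactone_policy not in LACTONE_POLICIES:
            raise ValueError(
                f"lactone_policy must be one of {LACTONE_POLICIES}, "
                f"got {self.lactone_policy!r}"
            )


def _oxidize(oligo: Oligosaccharide, opts: Br2Options, open_lactones: bool) -> Oligosaccharide:
    residues = []
    last = oligo.dp - 1
    for i, r in enumerate(oligo.residues):
        changes = {}
        if r.c6 == C6State.ALDEHYDE:
            changes["c6"] = C6State.ACID
        if opts.oxidize_reducing_end and i == last and not r.c1_acid and not r.unsaturated_4_5:
            changes["c1_acid"] = True
        if open_lactones and r.lactones:
            changes["lactones"] = 0
        residues.append(replace(r, **changes) if changes else r)
    return Oligosaccharide(tuple(residues))


def br2_transform(
    oligo: Oligosaccharide, opts: Br2Options = Br2Options()
) -> Oligosaccharide | set[Oligosaccharide]:
    """Apply the bromine oxidation; under ``equilibrate-both`` returns the
    set {lactones preserved, lactones opened}."""
    if opts.lactone_policy == "equilibrate-both":
        return {_oxidize(oligo, opts, False), _oxidize(oligo, opts, True)}
    return _oxidize(oligo, opts, opts.lactone_policy == "open")


@dataclass(frozen=True)
class Br2Result:
    pre_delta: int
    post_delta: int
    aldehydes_oxidized: int


def br2_delta_map(
    pre_delta: int,
    composition: Composition,
    reducing_end_free: bool = True,
    post_lactones: int = 0,
) -> Br2Result:
    """Delta-class map of the bromine treatment for one structural
    explanation of a peak class.

    ``composition`` is a multiset of modified-residue states (as returned
    by ``delta_explanations``) and must actually sum to ``pre_delta``.
    ``reducing_end_free`` states whether the chain still carries the free
    anomeric aldehyde (false once any state in the composition is a C1
    acid).  ``post_lactones`` books ester closures of the product acids —
    e.g. the di-aldehyde class −4 maps to +44 as the free triacid and to
    +26 as its mono-lactone.
    """
    total = int(sum(residue_delta(s) for s in composition))
    if total != int(pre_delta):
        raise InvalidStateError(
            f"composition sums to {total}, not the stated pre-delta {pre_delta}"
        )
    has_c1 = any(s.c1_acid for s in composition)
    n_ald = sum(1 for s in composition if s.c6 == C6State.ALDEHYDE)
    if reducing_end_free and not has_c1:
        n_ald += 1
    n_acids_after = (
        sum(s.carboxyl_count for s in composition) + n_ald
    )
    if post_lactones > n_acids_after:
        raise InvalidStateError(
            f"{post_lactones} lactones exceed the {n_acids_after} carboxyls "
            "present after oxidation"
        )
    post = int(pre_delta) + 16 * n_ald - 18 * post_lactones
    return Br2Result(int(pre_delta), post, n_ald)


def br2_pool(
    pool: Iterable[Oligosaccharide], opts: Br2Options = Br2Options()
) -> list[Oligosaccharide]:
    """Bromine-oxidize every chain in a pool (lactone sets flattened)."""
    out: list[Oligosaccharide] = []
    for oligo in pool:
        res = br2_transform(oligo, opts)
        out.extend(res if isinstance(res, set) else [res])
    return out
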