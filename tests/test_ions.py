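"""Adduct/cluster-ion arithmetic, enumeration completeness against a
naive oracle, annotation, the MALDI ladder and fragment explanation."""

import itertools

import pytest
from hypothesis import given, strategies as st

from oxocello import (
    AnnotationConfig,
    IonSpecies,
    MassMode,
    PeakList,
    annotate_peaklist,
    enumerate_candidates,
    explain_fragments,
    ion_mz,
    maldi_series,
)
from oxocello.ions import _carrier_combos, _iter_ions, _round_half_up
from oxocello.masses import DEFAULT_LIBRARY


def pos(analytes, carriers, adducts=()):
    return IonSpecies("positive", tuple(analytes), tuple(carriers.items()), tuple(adducts))


def neg(analytes, dep, na=0, adducts=()):
    carriers = {"deprotonation": dep, "sodium-replacing-proton": na}
    return IonSpecies("negative", tuple(analytes), tuple(carriers.items()), tuple(adducts))


@pytest.mark.parametrize(
    "ion, mz",
    [
        (pos(["glucose"], {"proton": 1, "sodium": 1}), 102),  # (180+Na+H)/2
        (pos(["glucuronic acid"], {"proton": 1}), 195),
        (neg(["oxidized ascorbate"], dep=1), 173),
        (pos(["glucuronic acid"], {"ammonium": 2}, ["CH3COOH"]), 145),
        (pos(["saccharic acid"], {"ammonium": 1}), 228),
        (neg(["saccharic acid lactone"], dep=2, na=1, adducts=["HCOOH"]), 259),
        (neg(["glucose", "gluconic acid lactone"], dep=3, na=1), 189),
    ],
)
def test_ion_mz_table_rows(ion, mz):
    assert ion_mz(ion) == pytest.approx(mz)


def test_ion_invariants():
    with pytest.raises(ValueError, match="charge"):
        neg(["glucose"], dep=1, na=1)  # z would be 0
    with pytest.raises(ValueError, match="analyte"):
        IonSpecies("positive", (), (("proton", 1),))
    with pytest.raises(ValueError, match="not legal"):
        IonSpecies("negative", ("glucose",), (("proton", 1),))
    with pytest.raises(KeyError):
        ion_mz(pos(["unobtainium"], {"proton": 1}))


def test_ion_mz_multiset_symmetry():
    a = pos(["glucose", "glucuronic acid"], {"proton": 2}, ["H2O", "HCOOH"])
    b = pos(["glucuronic acid", "glucose"], {"proton": 2}, ["HCOOH", "H2O"])
    assert a == b and ion_mz(a) == ion_mz(b)


def test_describe_paper_style():
    assert pos(["saccharic acid"], {"ammonium": 1}).describe() == "210 + NH4+"
    assert (
        neg(["saccharic acid lactone"], dep=2, na=1, adducts=["HCOOH"]).describe()
        == "192 − 2H+ + Na+ + HCOOH"
    )
    assert pos(["glucose"], {"proton": 1, "sodium": 1}).describe() == "180 + H+ + Na+/2"


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_enumerate_contains_printed_species():
    cands = enumerate_candidates(228)
    assert pos(["saccharic acid"], {"ammonium": 1}) in cands
    cands = enumerate_candidates(193)
    assert pos(["saccharic acid lactone"], {"proton": 1}) in cands
    assert enumerate_candidates(5) == []


def test_enumerate_ranking_parsimonious_and_deterministic():
    cands = enumerate_candidates(195)
    assert cands[0] == pos(["glucuronic acid"], {"proton": 1})
    assert cands == enumerate_candidates(195)
    counts = [c.component_count for c in cands]
    assert counts == sorted(counts)


@pytest.mark.parametrize("polarity", ["positive", "negative"])
def test_enumeration_complete_vs_naive_oracle(polarity):
    """Every target 50..300 must yield exactly the candidate set a naive
    exhaustive nested enumeration produces (nominal matching)."""
    config = AnnotationConfig(polarity=polarity)
    lib = DEFAULT_LIBRARY

    # oracle: plain nested loops, no indexing, no ranking
    oracle: dict[int, set] = {}
    analyte_sets = [
        c
        for k in range(1, config.max_analytes + 1)
        for c in itertools.combinations_with_replacement(config.analytes, k)
    ]
    adduct_sets = [
        c
        for k in range(0, config.max_neutral_adducts + 1)
        for c in itertools.combinations_with_replacement(config.adducts, k)
    ]
    for analytes in analyte_sets:
        for carriers in _carrier_combos(config):
            for adducts in adduct_sets:
                ion = IonSpecies(polarity, analytes, carriers, adducts)
                key = _round_half_up(ion_mz(ion, lib))
                oracle.setdefault(key, set()).add(ion)

    for target in range(50, 301):
        got = set(enumerate_candidates(target, config, lib))
        assert got == oracle.get(target, set()), f"target {target}"


@given(st.data())
def test_enumeration_round_trip(data):
    """Any ion drawn from the bounds is recovered at its own m/z."""
    config = AnnotationConfig()
    analytes = data.draw(
        st.lists(st.sampled_from(config.analytes), min_size=1, max_size=2)
    )
    carriers = data.draw(st.sampled_from(_carrier_combos(config)))
    adducts = data.draw(
        st.lists(st.sampled_from(config.adducts), min_size=0, max_size=4)
    )
    ion = IonSpecies("positive", tuple(analytes), carriers, tuple(adducts))
    assert ion in enumerate_candidates(ion_mz(ion), config)


# ---------------------------------------------------------------------------
# peak lists and annotation
# ---------------------------------------------------------------------------

def test_peaklist_validation_and_sorting():
    pl = PeakList(mz=[228.0, 195.0, 217.0], intensity=[1.0, 2.0, 3.0])
    assert pl.mz == [195.0, 217.0, 228.0]
    assert pl.intensity == [2.0, 3.0, 1.0]
    with pytest.raises(ValueError, match="positive"):
        PeakList(mz=[-1.0], intensity=[1.0])
    with pytest.raises(ValueError, match="lengths"):
        PeakList(mz=[1.0], intensity=[])


def test_annotate_uronate_peaks():
    """195/217/228: the protonated and sodiated uronate and the
    ammoniated saccharic acid all annotate; candidate sets match the
    single-target enumerator peak by peak."""
    pl = PeakList(mz=[195.0, 217.0, 228.0], intensity=[1.0] * 3)
    anns = annotate_peaklist(pl)
    assert all(a.assigned for a in anns)
    for a in anns:
        assert a.candidates == enumerate_candidates(a.mz)
    assert pos(["glucuronic acid"], {"proton": 1}) in anns[0].candidates
    assert pos(["glucuronic acid"], {"sodium": 1}) in anns[1].candidates
    assert pos(["saccharic acid"], {"ammonium": 1}) in anns[2].candidates


def test_annotate_edge_cases():
    assert annotate_peaklist(PeakList(mz=[], intensity=[])) == []
    anns = annotate_peaklist(PeakList(mz=[9999.0], intensity=[1.0]))
    assert not anns[0].assigned
    with pytest.raises(ValueError, match="negative but config is positive"):
        annotate_peaklist(PeakList(mz=[195.0], intensity=[1.0], polarity="negative"))


# ---------------------------------------------------------------------------
# MALDI series
# ---------------------------------------------------------------------------

def test_maldi_series_dp3_ladder():
    pl = maldi_series([3], [-2, 0])
    assert dict(zip(pl.labels, pl.mz)) == {"DP3-2": 525, "DP3+0": 527}


def test_maldi_series_dp4_plus16():
    pl = maldi_series([4], [16])
    assert pl.mz == [162 * 4 + 18 + 16 + 23]


def test_maldi_series_errors():
    with pytest.raises(ValueError, match="nonempty"):
        maldi_series([], [0])
    with pytest.raises(KeyError):
        maldi_series([3], [0], cation="unobtainium")


# ---------------------------------------------------------------------------
# fragment explanation
# ---------------------------------------------------------------------------

def test_explain_fragments_neutral_losses():
    out = explain_fragments(193, [175, 193, 148])
    # 193-18: water loss
    assert (("H2O",), ()) in out[0].paths
    # identity: empty path
    assert ((), ()) in out[1].paths
    # 193-45: carboxyl radical loss
    assert (("COOH",), ()) in out[2].paths


def test_explain_fragments_gain_and_unexplained():
    out = explain_fragments(191, [146, 192, 50])
    assert (("COOH",), ()) in out[0].paths  # 191-45
    assert ((), ("H",)) in out[1].paths  # 191+1
    assert not out[2].explained  # 141 Da below parent: beyond any 3-step path
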