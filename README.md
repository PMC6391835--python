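# oxocello

Mass-spectrometric inference for **oxidized cello-oligosaccharides** — the
reaction products of cellulose-active lytic polysaccharide monooxygenases
(LPMOs, CAZy family AA9) and their downstream enzymatic digests.

Fungal AA9 monooxygenases oxidize cellulose at C1, C4 and C6 of the
glucosyl unit. C1 and C4 oxidation cleave the chain (aldonic acids and
4-ketoaldoses); C6 oxidation converts the hydroxymethyl group stepwise to
an aldehyde (hexodialdose) and on to a carboxyl, producing glucuronic
acid-containing cello-oligosaccharides. None of these species is observed
directly: everything is read off mass spectra — MALDI-TOF ladders of
sodiated oligosaccharides, and ESI full scans of monosaccharide digests
dense with adduct and cluster ions. `oxocello` implements the inference
calculus that turns those spectra into chemistry, plus a simulator of the
degradation process itself.

## The model

An oligosaccharide of degree of polymerization *n* (DP*n*) has nominal
neutral mass 162·*n* + 18. Each residue's oxidation state shifts that
mass by an additive **delta**:

| state | delta | chemistry |
|---|---|---|
| C1 carboxyl | +16 | reducing-end aldonic acid |
| C4 ketone | −2 | 4-ketoaldose |
| C6 aldehyde | −2 | C6-hexodialdose |
| C6 carboxyl | +14 | glucuronosyl (uronate) residue |
| lactone | −18 | intramolecular ester of a carboxyl |
| Δ4,5 ene | −18 | unsaturated end left by lyase cleavage |

The **delta class** of a chain (sum of residue deltas) is what a MALDI
peak reads out: the sodiated DP3 peak of the −2 class sits at
162·3 + 18 − 2 + 23 = **525**. Delta classes are degenerate — +14 is both
C1+C4 and a lone C6 carboxyl; −2 is either a ketone or an aldehyde — so
the package provides:

* `delta_explanations` — complete enumeration of the oxidation-state
  multisets explaining a delta class;
* `br2_transform` / `br2_delta_map` — the bromine-water treatment that
  resolves the −2 degeneracy chemically (aldehydes → acids, +16 per site;
  ketones inert), e.g. −2 → +30 for a C6 aldehyde vs −2 → +14 for a C4
  ketone;
* `enumerate_candidates` — complete adduct/cluster-ion decomposition of
  ESI peaks: 1–2 analytes, H⁺/Na⁺/NH₄⁺ attachment or deprotonation with
  sodium substitution, up to six neutral adducts
  (H₂O, NH₃, CH₃OH, HCOOH, CH₃COOH), charge 1–2;
* `digest` / `pl_cleave` / `pmo_simulate` — rule-based degradation:
  exo-hydrolysis by beta-glucosidase (BGL) and beta-glucuronidase (GUS)
  to glucose, gluconic, glucuronic and saccharic (glucaric) acid;
  polysaccharide-lyase beta-elimination; and a seeded stochastic event
  model of the monooxygenase itself, with a hard mass-conservation ledger.

A 137-row golden fixture transcribes the published positive- and
negative-mode full-scan assignment tables; every high-confidence row is
re-derived by the enumerator in the test suite (`oxocello golden-check`).

## Worked example

Chains are written in a compact grammar, non-reducing end first:
`G(c6d)-G-G` is cellotriose with one C6 aldehyde.

```
$ oxocello series --dp 3:4 --deltas -2,0,14,16 --cation Na
DP3-2   525
DP3+0   527
DP3+14  541
DP3+16  543
DP4-2   687
...
```

525 is the −2 (C4-keto or C6-aldehyde) DP3 peak; 541/543 are the uronate
and aldonic classes. Bromine oxidation then separates the −2 candidates:

```
$ oxocello br2 --oligo "G(c6d)-G-G"
pre   G(c6d)-G-G    delta -2   mass 502
post  G(c6a)-G-G(c1)  delta +30  mass 534
```

the C6 aldehyde and the free reducing end both gained +16, so a peak
moving −2 → +30 proves C6 (not C4) oxidation. Annotating an ESI full
scan of the digest:

```
$ oxocello annotate --peaks peaks.csv --mode pos
195.0   194 + H+
195.0   176 + H+ + H2O
...
```

reads m/z 195 as protonated glucuronic acid (nominal 194) first — ranked
by parsimony — ahead of hydrated cluster alternatives. Digesting a
uronate-containing chain:

```python
>>> from oxocello import digest, parse_oligo
>>> dict(digest([parse_oligo("G(c6a)-G-G(c1,c6a)")]).monosaccharides)
{'glucuronic acid': 1, 'glucose': 1, 'saccharic acid': 1}
```

is the doubly oxidized pathway: GUS strips the uronate, BGL the glucose,
and the C1/C6-dioxidized reducing end is saccharic acid. The peptide
utility reproduces instrument-level arithmetic:

```
$ oxocello peptide --seq HGHVSHIIVNGVQYR --z 3
M        1714.9016
[M+3H]3+ 572.6411
```

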