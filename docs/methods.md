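# Methods

## Mass dialects

All reference arithmetic is **nominal**: integer masses from the most
abundant isotopes (anhydroglucose 162, water 18, glucose 180, Na⁺ 23).
This is deliberately the dialect of the published peak tables, where an
ion is "194 + H⁺" and nothing carries decimals. Monoisotopic and average
dialects are provided for real data — species masses are derived from
molecular formulas via pyteomics, cationic carriers are electron-mass
corrected in monoisotopic mode — but no reference check depends on them.
Nominal candidate matching is exact integer equality after half-up
rounding of both sides; half-integral m/z of doubly charged ions rounds
the way the tables print them.

## The oxidation-state model

A residue state is (C1 acid?, C4 keto?, C6 ∈ {none, aldehyde, acid},
lactone count, Δ4,5 ene?). Deltas are additive: +16, −2, −2, +14, −18
per lactone, −18 for the ene. Structural invariants are enforced at
construction: a lactone needs a carboxyl to esterify (lactones ≤
carboxyls per residue); C1 oxidation only on the reducing-end residue;
the Δ4,5 ene only on the non-reducing end. Lactones are modeled as −18
modifiers on acid-bearing residues rather than separate residue types:
this keeps the delta algebra additive and reproduces the acid→lactone
footnote masses (196→178, 194→176, 210→192) with no special cases.

C4 ketone and C6 aldehyde share the −2 delta and are **never collapsed**:
a −2 peak is genuinely ambiguous until bromine treatment. The hydrated
form of the C6 aldehyde (gem-diol, +16 relative to the aldehyde),
discussed for AA5-family oxidases, is not modeled as a distinct state.

`delta_explanations` enumerates multisets of modified-residue states
(compositions) rather than positioned chains, because a chain offers
several equivalent C6 positions that a peak cannot distinguish;
`expand_positions` optionally expands a composition into positioned
chains. The event cap (default 3 oxidation events per chain, matching
the largest combination the ladder shows) counts oxidations only —
lactonization and the ene are rearrangements. Enumeration is complete
within the grammar: it returns every mass-degenerate combination, which
is a superset of the combinations a figure caption names (e.g. +14 is
also C1 + C6-aldehyde, not only C1 + C4-keto or a lone uronate). The
Δ4,5 ene is excluded from the default explanation grammar since it is a
lyase product, not a monooxygenase product.

## Ion enumeration

Bounds (all configurable): ≤2 analyte molecules, charge ≤2, positive
carriers from {H⁺, Na⁺, NH₄⁺}, negative ionization as deprotonation with
at most one sodium-for-proton substitution (net charge ≥ 1), and ≤6
neutral adducts from {H₂O, NH₃, CH₃OH, HCOOH, CH₃COOH}. Six is the
smallest adduct cap that covers every transcribed table row — the
densest anions carry 4 H₂O plus two solvent molecules. The enumerator
precomputes the whole bounded ion space once per configuration and
buckets it by rounded m/z, so per-target lookup is O(1); completeness is
tested against an independent naive nested-loop enumeration over all
targets 50–300. Candidates are ranked by parsimony — total component
count, then analyte count, then charge, then lexicographic on the
decomposition string — because no principled ranking exists for nominal
full scans; the tie-break exists purely for determinism. Electron mass
is ignored in nominal mode and included only monoisotopically.

The golden fixture carries a per-row transcription-confidence flag
because the published table typesetting runs columns together. One
positive-mode row (m/z 103, "182 + Na⁺ + H⁺/2") names an analyte mass
(182) outside the monosaccharide/ascorbate library and is flagged low
confidence, loaded and arithmetic-checked but excluded from recovery
assertions; one negative-mode adduct printed as "CH₃O" is read as CH₃OH,
the unique integer fit, with a note in the fixture.

## Bromine-water transform

Every free aldehyde — in-chain C6 aldehydes and the anomeric reducing
end — gains +16 (→ carboxyl); C4 ketones are untouched (ketones resist
Br₂ under these conditions), which is exactly what makes the post-
treatment classes diagnostic: −2 maps to +30 (aldehyde) or +14 (ketone).
Reducing-end oxidation is on by default and toggleable. The +26
post-treatment class is modeled as the mono-lactone of the +44 triacid
(44 − 18); both the raw class label and the lactone reading are
surfaced, since the source material labels +26 and +44 identically
without explaining the 18-unit gap. Lactone handling during treatment is
a policy: preserve (default), open, or return both forms.

## Degradation rules

BGL releases an exactly unmodified non-reducing-end glucosyl; GUS
releases an exactly C6-carboxyl one. Both act only at the non-reducing
end of chains with dp ≥ 2; the final monomer is named by
`monosaccharide_identity` (C4-keto/C6-aldehyde monomers have no standard
name and are reported as residuals). Ends neither enzyme accepts stall
the chain by default — they are not these hydrolases' natural substrates
— with a `pass-through` policy that releases the blocked residue as an
`unnamed:` census entry for sensitivity analysis. Whether release is
gated by anything beyond the terminal residue's own state is unknown;
here only the terminal state gates.

Lyase (PL-family) cleavage takes the 0-based index of a uronate residue,
breaks the bond on its C4 side, and moves the uronate to the distal
fragment as a Δ4,5-unsaturated non-reducing end; no water is consumed,
so fragment masses sum exactly to the parent.

A mass ledger (Σ products = Σ parents + 18 per hydrolytic cleavage) is
asserted inside `digest` after every run, not only in tests.

## Monooxygenase event model

A discrete-step, site-uniform Bernoulli process with four per-site
per-step probabilities: C1 cleavage (aldonic end on the proximal
fragment), C4 cleavage (keto end on the distal fragment's new NRE), C6
hydroxymethyl → aldehyde, and C6 aldehyde → acid. No kinetics are
published for this chemistry, so the rates are free parameters. Within a
step, events are drawn against the step's starting state; where both
cleavage chemistries could fire at one bond, C1 draws first and C4 is
offered the bond only if C1 declined — so each event type is an exact
Bernoulli trial on its tallied opportunity count, and the calibration
test checks observed counts against the binomial expectation (±3σ) on
those logged opportunities. The C4 polarity convention (keto on the
distal fragment) follows the general AA9 literature.

## Synthetic data

Scenarios fix the study conditions for testing: `C1-only`, `C6-only`,
and `paper-like-mixed` (20 chains of DP60, 120 steps, rates C1 0.002,
C4 0.002, C6→aldehyde 0.004, aldehyde→acid 0.02). The mixed rates were
chosen once to emulate a partially depolymerized digest: roughly 40% of
bonds cleaved, giving the DP-few ladder a MALDI spectrum actually shows,
with C6 oxidation frequent enough that the uronate-bearing classes
(+12, +14, +28) populate alongside −2, +16 and non-oxidized chains.

Rendering plants theoretical peaks with Gaussian m/z jitter (0 by
default — nominal work is exact), log-normal intensities (exp N(7, 0.8),
median ≈ 1100 counts, the order of magnitude of a positive-mode full
scan; there is no published intensity model, this is generic MS
practice), uniform-random noise peaks, and a detection threshold. Ground
truth is a sidecar keyed by peak index, stamped with a run id and never
embedded in the peak list, so a recovery benchmark cannot read answers
from its input. The generator does not attempt MALDI matrix effects,
detector saturation, or isotope envelopes — synthetic recall therefore
demonstrates correctness of the inference calculus under the stated
noise model, not instrument-level performance on real spectra.

## Protein utilities

Peptide masses come from pyteomics' standard residue tables; charged m/z
is (M + z·1.00728)/z; the theoretical 3+ ion of the N-terminal tryptic
peptide agrees with the instrument-printed value within 10 ppm (the
printed value differs from theory in the fourth decimal, as survey-scan
values do). The glycosylation percentage is 100·(apparent −
calculated)/apparent on SDS-PAGE vs sequence masses, reported to one
decimal. No utility here attempts PTM handling or glycosite prediction.
The mature-protein mass cross-check against the deposited coding
sequence is not shipped: the sequence is not printed in the source
material, and the package carries no downloaded data.

## Problem sizes and numerical choices

All reference computations are desk-scale: the ion index is ~10⁵ species
per polarity, built once in about a second; oracle-equivalence tests run
dp ≤ 4 chains and targets 50–300; the ledger property uses 1000 random
digests; the calibration run is 20 chains of DP100 for 200 steps. The
whole suite completes in well under a minute. Ties everywhere break
lexicographically; degenerate inputs (empty peak lists, dp=1 boundary
cleavages, zero rates) are covered by explicit tests.
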