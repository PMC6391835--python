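"""Synthetic-data generation with ground truth.

Two synthetic regimes mirror the two instruments the analysis reads:

* **MALDI** — a sodiated oligosaccharide ladder from a simulated
  monooxygenase digest (``generate_pool`` + ``render_spectrum``): peaks at
  162·dp + 18 + delta + 23 with log-normal intensities.
* **ESI full scan** — monosaccharide cluster ions: each planted analyte
  appears as one or more adduct ions sampled from the enumeration bounds
  (``render_esi_spectrum``), the regime of acidified methanol/water
  full-scan spectra.

Both renderers emit a ground-truth sidecar keyed by peak index and
stamped with a run identifier, kept separate from the peak list itself so
a recovery benchmark cannot accidentally read the answers out of its
input.  Everything is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .composition import Oligosaccharide
from .degradation import (
    PmoEventModel,
    SimulationResult,
    census_to_spectrum,
    pmo_simulate,
)
from .ions import (
    Annotation,
    AnnotationConfig,
    IonSpecies,
    PeakList,
    _iter_ions,
    ion_mz,
)
from .masses import DEFAULT_LIBRARY, SmallMoleculeLibrary

__all__ = [
    "SpectrumNoiseModel",
    "GroundTruth",
    "SCENARIOS",
    "generate_pool",
    "render_spectrum",
    "render_esi_spectrum",
    "recovery_benchmark",
]


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Noise applied when rendering theoretical peaks into a 'spectrum'.

    ``mz_jitter_sd`` is Gaussian m/z error in mass units (0 in nominal
    work); intensities are log-normal (generic practice for MS peak
    heights — exp(N(mu, sigma)), so mu=7, sigma=0.8 gives a median around
    1100 counts, the order of magnitude a positive-mode full scan shows);
    ``noise_peaks`` uniform-random peaks are sprinkled over
    ``noise_mz_range``; peaks below ``detection_threshold`` are dropped.
    """

    mz_jitter_sd: float = 0.0
    intensity_mu: float = 7.0
    intensity_sigma: float = 0.8
    noise_peaks: int = 0
    noise_mz_range: tuple[float, float] = (100.0, 300.0)
    noise_intensity_mu: float = 4.5
    noise_intensity_sigma: float = 0.8
    detection_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mz_jitter_sd < 0 or self.intensity_sigma < 0 or self.noise_intensity_sigma < 0:
            raise ValueError("dispersions must be >= 0")
        if self.noise_peaks < 0:
            raise ValueError("noise_peaks must be >= 0")


@dataclass
class GroundTruth:
    """Sidecar mapping peak index -> planted species descriptor."""

    run_id: str
    entries: dict[int, dict]

    def to_json_dict(self) -> dict:
        return {"run_id": self.run_id, "entries": {str(k): v for k, v in self.entries.items()}}


def _run_id(*parts) -> str:
    h = hashlib.sha256("|".join(str(p) for p in parts).encode()).hexdigest()
    return h[:12]


# ---------------------------------------------------------------------------
# oxidized-product pools
# ---------------------------------------------------------------------------

# Named scenarios: (chain lengths, event model kwargs).  The mixed scenario
# is calibrated to a partially depolymerized digest: ~40% of bonds cleaved
# (mean fragment DP a few units, the ladder MALDI actually shows) with C6
# oxidation frequent enough that uronate-bearing classes (+12, +14, +28)
# all populate alongside −2 and +16.
SCENARIOS: dict[str, dict] = {
    "C1-only": {
        "chains": [60] * 20,
        "model": dict(c1_cleavage=0.004, steps=120),
    },
    "C6-only": {
        "chains": [60] * 20,
        "model": dict(c6_to_aldehyde=0.004, c6_aldehyde_to_acid=0.02, steps=120),
    },
    "paper-like-mixed": {
        "chains": [60] * 20,
        "model": dict(
            c1_cleavage=0.002,
            c4_cleavage=0.002,
            c6_to_aldehyde=0.004,
            c6_aldehyde_to_acid=0.02,
            steps=120,
        ),
    },
}


def generate_pool(
    scenario: Optional[str] = None,
    seed: int = 0,
    model: Optional[PmoEventModel] = None,
    chains: Optional[Sequence[int]] = None,
) -> SimulationResult:
    """Pool of oxidized oligosaccharides from a named scenario or an
    explicit event model; ``seed`` overrides the model's seed."""
    if model is None:
        if scenario is None:
            raise ValueError("give a named scenario or an explicit model")
        if scenario not in SCENARIOS:
            raise KeyError(
                f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}"
            )
        cfg = SCENARIOS[scenario]
        model = PmoEventModel(seed=seed, **cfg["model"])
        chains = chains if chains is not None else cfg["chains"]
    else:
        model = PmoEventModel(**{**asdict(model), "seed": seed})
        if chains is None:
            raise ValueError("explicit model needs explicit chains")
    return pmo_simulate(chains, model)


# ---------------------------------------------------------------------------
# spectrum rendering
# ---------------------------------------------------------------------------

def render_spectrum(
    pool: Iterable[Oligosaccharide],
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    cation: str = "sodium",
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> tuple[PeakList, GroundTruth]:
    """Render a pool as a sodiated MALDI spectrum plus ground truth.

    With zero jitter and zero noise the peak m/z set equals the
    theoretical ``census_to_spectrum`` output exactly.
    """
    pool = list(pool)
    rng = np.random.default_rng(noise.seed)
    theo = census_to_spectrum(pool, cation=cation, library=library)
    run_id = _run_id("maldi", noise, cation, len(pool))

    records = []  # (mz, intensity, truth-or-None)
    for mz, count, label in zip(theo.mz, theo.intensity, theo.labels):
        jmz = mz + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0)
        inten = count * float(np.exp(rng.normal(noise.intensity_mu, noise.intensity_sigma)))
        records.append((jmz, inten, {"label": label, "theoretical_mz": mz, "count": count}))
    for _ in range(noise.noise_peaks):
        nmz = float(rng.uniform(*noise.noise_mz_range))
        inten = float(np.exp(rng.normal(noise.noise_intensity_mu, noise.noise_intensity_sigma)))
        records.append((nmz, inten, None))

    records = [r for r in records if r[1] >= noise.detection_threshold]
    records.sort(key=lambda r: r[0])
    peaks = PeakList(
        mz=[r[0] for r in records],
        intensity=[r[1] for r in records],
        polarity="positive",
        instrument="maldi",
        metadata={"run_id": run_id, "cation": cation},
    )
    truth = GroundTruth(
        run_id, {i: r[2] for i, r in enumerate(records) if r[2] is not None}
    )
    return peaks, truth


def render_esi_spectrum(
    analytes: Sequence[str],
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    config: AnnotationConfig = AnnotationConfig(),
    ions_per_analyte: int = 2,
    library: SmallMoleculeLibrary = DEFAULT_LIBRARY,
) -> tuple[PeakList, GroundTruth]:
    """Render an ESI full scan of a monosaccharide mixture.

    Each planted analyte is given ``ions_per_analyte`` ion species sampled
    (seeded) from the single-analyte slice of the enumeration bounds, so
    the spectrum has the multi-adduct structure of a real full scan; the
    truth sidecar records each peak's generating ion species.
    """
    rng = np.random.default_rng(noise.seed)
    run_id = _run_id("esi", noise, config, tuple(analytes))

    records = []
    for name in analytes:
        sub = AnnotationConfig(
            polarity=config.polarity,
            mode=config.mode,
            tolerance=config.tolerance,
            max_analytes=1,
            max_z=config.max_z,
            max_neutral_adducts=min(config.max_neutral_adducts, 2),
            max_sodium_substitutions=config.max_sodium_substitutions,
            analytes=(name,),
            adducts=config.adducts,
        )
        candidates = list(_iter_ions(sub, library))
        picks = rng.choice(len(candidates), size=min(ions_per_analyte, len(candidates)), replace=False)
        for idx in picks:
            ion = candidates[int(idx)]
            mz = ion_mz(ion, library, config.mode)
            jmz = mz + (rng.normal(0.0, noise.mz_jitter_sd) if noise.mz_jitter_sd else 0.0)
            inten = float(np.exp(rng.normal(noise.intensity_mu, noise.intensity_sigma)))
            records.append((jmz, inten, ion))
    for _ in range(noise.noise_peaks):
        nmz = float(rng.uniform(*noise.noise_mz_range))
        inten = float(np.exp(rng.normal(noise.noise_intensity_mu, noise.noise_intensity_sigma)))
        records.append((nmz, inten, None))

    records = [r for r in records if r[1] >= noise.detection_threshold]
    records.sort(key=lambda r: r[0])
    peaks = PeakList(
        mz=[r[0] for r in records],
        intensity=[r[1] for r in records],
        polarity=config.polarity,
        instrument="esi",
        metadata={"run_id": run_id},
    )
    truth_entries = {}
    for i, (_, _, ion) in enumerate(records):
        if ion is not None:
            truth_entries[i] = {
                "ion": ion,
                "theoretical_mz": ion_mz(ion, library, config.mode),
            }
    return peaks, GroundTruth(run_id, truth_entries)


# ---------------------------------------------------------------------------
# recovery benchmark
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    recall: float
    precision: float
    n_planted: int
    n_assigned: int


def recovery_benchmark(
    truth: GroundTruth,
    annotations: Sequence[Annotation],
    peaks: PeakList,
) -> RecoveryReport:
    """Recall/precision of planted-ion recovery.

    Recall: fraction of planted species whose true decomposition appears
    in the candidate set of their peak.  Precision: among peaks the
    annotator assigned, the fraction that are planted peaks correctly
    explained.  ``truth`` and ``peaks`` must come from the same render run.
    """
    if peaks.metadata.get("run_id") != truth.run_id:
        raise ValueError(
            f"run id mismatch: peaks {peaks.metadata.get('run_id')!r} "
            f"vs truth {truth.run_id!r}"
        )
    by_index = {a.peak_index: a for a in annotations}
    hits = 0
    for idx, entry in truth.entries.items():
        ann = by_index.get(idx)
        if ann is not None and entry["ion"] in ann.candidates:
            hits += 1
    n_planted = len(truth.entries)
    recall = hits / n_planted if n_planted else 0.0

    assigned = [a for a in annotations if a.assigned]
    good = sum(
        1
        for a in assigned
        if a.peak_index in truth.entries
        and truth.entries[a.peak_index]["ion"] in a.candidates
    )
    precision = good / len(assigned) if assigned else 0.0
    return RecoveryReport(recall, precision, n_planted, len(assigned))
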