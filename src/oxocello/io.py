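"""File formats: peak lists as CSV/TSV, pools/censuses/annotations as JSON.

Peak lists are two-column tables with a required ``mz,intensity`` header
(tab- or comma-delimited, sniffed from the extension); polarity and
instrument ride in a JSON metadata sidecar or as keyword overrides.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .composition import Oligosaccharide, format_oligo, parse_oligo
from .degradation import ProductCensus
from .ions import Annotation, PeakList
from .masses import DEFAULT_LIBRARY

__all__ = [
    "read_peaklist",
    "write_peaklist",
    "read_pool",
    "write_pool",
    "write_census",
    "write_annotations",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_peaklist(
    path,
    polarity: Optional[str] = None,
    instrument: Optional[str] = None,
) -> PeakList:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower().strip(): c for c in df.columns}
    if "mz" not in cols or "intensity" not in cols:
        raise ValueError(f"{path}: need 'mz' and 'intensity' columns, got {list(df.columns)}")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return PeakList(
        mz=df[cols["mz"]].astype(float).tolist(),
        intensity=df[cols["intensity"]].astype(float).tolist(),
        polarity=polarity or meta.get("polarity", "positive"),
        instrument=instrument or meta.get("instrument", "esi"),
        metadata=meta,
    )


def write_peaklist(peaks: PeakList, path) -> None:
    path = Path(path)
    pd.DataFrame({"mz": peaks.mz, "intensity": peaks.intensity}).to_csv(
        path, sep=_sep(path), index=False
    )
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = dict(peaks.metadata)
    meta.update({"polarity": peaks.polarity, "instrument": peaks.instrument})
    if peaks.labels is not None:
        meta["labels"] = peaks.labels
    sidecar.write_text(json.dumps(meta, indent=1))


def read_pool(path) -> list[Oligosaccharide]:
    data = json.loads(Path(path).read_text())
    chains = data["chains"] if isinstance(data, dict) else data
    return [parse_oligo(c) for c in chains]


def write_pool(pool: Iterable[Oligosaccharide], path) -> None:
    Path(path).write_text(
        json.dumps({"chains": [format_oligo(o) for o in pool]}, indent=1)
    )


def write_census(census: ProductCensus, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "monosaccharides": dict(census.monosaccharides),
                "residuals": [format_oligo(o) for o in census.residuals],
                "hydrolytic_cleavages": census.hydrolytic_cleavages,
                "input_mass": census.input_mass,
                "output_mass": census.output_mass,
            },
            indent=1,
        )
    )


def write_annotations(
    annotations: Sequence[Annotation], path, library=DEFAULT_LIBRARY, fmt: str = "tsv"
) -> None:
    """Annotations as TSV (peak m/z, rank, decomposition string in the
    peak-table style, e.g. ``210 + NH4+``) or JSON."""
    path = Path(path)
    if fmt == "json":
        payload = [
            {
                "peak_index": a.peak_index,
                "mz": a.mz,
                "assigned": a.assigned,
                "candidates": [ion.describe(library) for ion in a.candidates],
            }
            for a in annotations
        ]
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = []
    for a in annotations:
        if not a.candidates:
            rows.append({"mz": a.mz, "rank": "", "decomposition": "unassigned"})
        for rank, ion in enumerate(a.candidates, start=1):
            rows.append({"mz": a.mz, "rank": rank, "decomposition": ion.describe(library)})
    pd.DataFrame(rows, columns=["mz", "rank", "decomposition"]).to_csv(
        path, sep="\t", index=False
    )
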