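"""TSV round-trips for every table the pipeline reads or writes.

All on-disk formats are plain tab-separated text: counts (gene rows,
sample columns), sample metadata, the ortholog pair table, stage
profiles, screen records and enrichment records.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .containers import CountMatrix, OrthologMap, StageProfile


def write_counts(counts: CountMatrix, path: str | Path) -> None:
    counts.counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(
    counts_path: str | Path,
    metadata_path: str | Path,
    stage_order: Sequence[str] | None = None,
) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    meta = read_metadata(metadata_path)
    return CountMatrix(counts, meta, stage_order=tuple(stage_order) if stage_order else None)


def write_metadata(counts: CountMatrix, path: str | Path) -> None:
    counts.samples.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "species": str, "stage": str})
    return meta


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.to_frame().to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path, provenance: str | None = None) -> OrthologMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return OrthologMap.from_frame(frame, provenance=provenance or str(path))


def write_profile(profile: StageProfile, path: str | Path) -> None:
    out = profile.values.copy()
    out.insert(0, "constant", [g in set(profile.constant_genes) for g in out.index])
    out.to_csv(path, sep="\t", index_label="gene")


def read_profile(path: str | Path, scaled: bool = False) -> StageProfile:
    frame = pd.read_csv(path, sep="\t", index_col="gene")
    constant: tuple[str, ...] = ()
    if "constant" in frame.columns:
        constant = tuple(frame.index[frame["constant"].astype(bool)])
        frame = frame.drop(columns="constant")
    return StageProfile(frame, scaled=scaled, constant_genes=constant)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
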