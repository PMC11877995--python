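"""Core in-memory containers shared across the pipeline.

The pipeline operates on three kinds of objects: raw per-sample read
counts with their sample annotations (:class:`CountMatrix`), per-gene
expression profiles ordered along a developmental stage axis
(:class:`StageProfile`), and the cross-species gene pairing
(:class:`OrthologMap`) together with the screen configuration
(:class:`ReferenceSpec`).  All tabular payloads are plain pandas
DataFrames so they interoperate with the TSV round-trip helpers in
:mod:`orthoscreen.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("sample_id", "species", "stage", "replicate")


@dataclass
class CountMatrix:
    """Gene x sample read counts plus per-sample annotations.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with one column per sample;
        values are non-negative integer read counts (the product of a
        quantifier such as salmon).
    samples
        DataFrame with columns ``sample_id``, ``species``, ``stage`` and
        ``replicate``; row order defines the sample order and must match
        the columns of ``counts``.
    stage_order
        Optional declared developmental ordering of the stage labels.
        When given, every sample's stage must be drawn from it.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    stage_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        meta_ids = list(self.samples["sample_id"])
        if meta_ids != list(self.counts.columns):
            raise ValueError("sample metadata order does not match count matrix columns")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("count matrix contains negative values")
        if self.stage_order is not None:
            self.stage_order = tuple(self.stage_order)
            unknown = set(self.samples["stage"]) - set(self.stage_order)
            if unknown:
                raise ValueError(f"samples with stage labels outside the declared order: {sorted(unknown)}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def species(self) -> str:
        labels = self.samples["species"].unique()
        if len(labels) != 1:
            raise ValueError(f"count matrix mixes species: {labels.tolist()}")
        return str(labels[0])


@dataclass
class StageProfile:
    """Per-gene expression profile along an ordered stage axis.

    ``values`` is a genes x stages DataFrame of log2-normalized
    expression (replicate-averaged unless the profile was built in
    all-samples mode, in which case columns are individual samples in
    stage order).  ``scaled`` records whether per-gene across-stage
    z-scaling was applied; ``constant_genes`` lists genes whose profile
    had zero across-stage variance (left all-zero when scaled, and
    excluded from screening downstream).
    """

    values: pd.DataFrame
    scaled: bool = False
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in profile")
        self.constant_genes = tuple(self.constant_genes)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.values.columns)


@dataclass
class OrthologMap:
    """Cross-species gene pairing, possibly one-to-many or many-to-many.

    Pairs are (species-A gene, species-B gene) tuples; duplicates are
    rejected.  One species-A gene may legitimately map to several
    species-B genes (zebrafish retains duplicated paralogs such as
    sox9a/sox9b for a single mouse Sox9), and each such pair is screened
    independently downstream.
    """

    pairs: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pairs = [(str(a), str(b)) for a, b in self.pairs]
        seen = set()
        for p in self.pairs:
            if p in seen:
                raise ValueError(f"duplicate ortholog pair: {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def genes_a(self) -> list[str]:
        out, seen = [], set()
        for a, _ in self.pairs:
            if a not in seen:
                seen.add(a)
                out.append(a)
        return out

    def genes_b(self) -> list[str]:
        out, seen = [], set()
        for _, b in self.pairs:
            if b not in seen:
                seen.add(b)
                out.append(b)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["gene_a", "gene_b"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "OrthologMap":
        return cls(list(zip(frame["gene_a"], frame["gene_b"])), provenance=provenance)


@dataclass
class ReferenceSpec:
    """Reference gene per species and the correlation cut-off.

    The screen anchors every gene to one reference per species (the
    Sox9 / sox9b roles) and requires Pearson r strictly greater than
    ``threshold`` in both species.  The default cut-off is 0.7.
    """

    gene_a: str
    gene_b: str
    threshold: float = 0.7

    def __post_init__(self) -> None:
        if not (-1.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must lie strictly inside (-1, 1), got {self.threshold}")
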