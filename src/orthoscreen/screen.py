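"""Reference-anchored cross-species co-expression screen.

Every gene is correlated with its species' reference gene over the
ordered developmental stages (Pearson, within species only — the two
species' stage axes differ in length and are never concatenated).  An
ortholog pair passes when the correlation strictly exceeds the
threshold in *both* species.  One-to-many pairs are screened
independently, so a divergent zebrafish duplicate can fail while its
sibling passes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import OrthologMap, ReferenceSpec, StageProfile

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = ("gene_a", "gene_b", "r_a", "r_b", "pass_a", "pass_b", "pass_both")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two stage vectors.

    Vectors must have equal length >= 3.  Returns NaN (the
    undefined-correlation flag) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 stages to correlate, got {x.size}")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def _profile_frame(profiles: StageProfile | pd.DataFrame) -> pd.DataFrame:
    return profiles.values if isinstance(profiles, StageProfile) else profiles


def correlate_with_reference(
    profiles: StageProfile | pd.DataFrame, reference_gene: str
) -> pd.Series:
    """Pearson r of every gene's profile against the reference gene's.

    Vectorized over genes; rows with zero variance get NaN, as does
    every row if the reference itself is constant.
    """
    frame = _profile_frame(profiles)
    if reference_gene not in frame.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from profiles")
    mat = frame.to_numpy(dtype=float)
    ref = frame.loc[reference_gene].to_numpy(dtype=float)
    dm = mat - mat.mean(axis=1, keepdims=True)
    dr = ref - ref.mean()
    ssm = (dm * dm).sum(axis=1)
    ssr = (dr * dr).sum()
    denom = np.sqrt(ssm * ssr)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (dm @ dr) / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(np.clip(r, -1.0, 1.0), index=frame.index)


def screen(
    profiles_a: StageProfile | pd.DataFrame,
    profiles_b: StageProfile | pd.DataFrame,
    ortholog_map: OrthologMap,
    reference: ReferenceSpec,
) -> pd.DataFrame:
    """Screen every ortholog pair against the per-species reference.

    Returns one record per pair with columns ``gene_a, gene_b, r_a,
    r_b, pass_a, pass_b, pass_both``, sorted by min(r_a, r_b)
    descending then lexicographically by gene names.  A pair passes a
    species when its correlation is defined and strictly greater than
    the threshold; undefined correlations (constant profiles) fail.
    Pairs referencing genes missing from either profile matrix are
    dropped with a logged count.
    """
    frame_a = _profile_frame(profiles_a)
    frame_b = _profile_frame(profiles_b)
    if reference.gene_a not in frame_a.index:
        raise ValueError(f"reference gene {reference.gene_a!r} absent from species-A profiles")
    if reference.gene_b not in frame_b.index:
        raise ValueError(f"reference gene {reference.gene_b!r} absent from species-B profiles")
    if len(ortholog_map) == 0:
        raise ValueError("ortholog map is empty")

    r_a = correlate_with_reference(frame_a, reference.gene_a)
    r_b = correlate_with_reference(frame_b, reference.gene_b)

    kept, dropped = [], 0
    for a, b in ortholog_map.pairs:
        if a in r_a.index and b in r_b.index:
            kept.append((a, b))
        else:
            dropped += 1
    if dropped:
        logger.warning("%d ortholog pair(s) named genes missing from the profiles; dropped", dropped)
    if not kept:
        raise ValueError("no ortholog pair maps into the supplied profiles")

    ra = np.array([r_a[a] for a, _ in kept])
    rb = np.array([r_b[b] for _, b in kept])
    t = reference.threshold
    pass_a = np.nan_to_num(ra, nan=-2.0) > t
    pass_b = np.nan_to_num(rb, nan=-2.0) > t
    records = pd.DataFrame(
        {
            "gene_a": [a for a, _ in kept],
            "gene_b": [b for _, b in kept],
            "r_a": ra,
            "r_b": rb,
            "pass_a": pass_a,
            "pass_b": pass_b,
            "pass_both": pass_a & pass_b,
        }
    )
    min_r = np.fmin(np.nan_to_num(ra, nan=-2.0), np.nan_to_num(rb, nan=-2.0))
    records = (
        records.assign(_min_r=min_r)
        .sort_values(["_min_r", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort")
        .drop(columns="_min_r")
        .reset_index(drop=True)
    )
    n_undefined = int(np.isnan(ra).sum() + np.isnan(rb).sum())
    if n_undefined:
        logger.warning("%d undefined correlation(s) (constant profiles); these fail the screen", n_undefined)
    return records


def passing_gene_list(records: pd.DataFrame, side: str) -> list[str]:
    """Deduplicated genes of one species among pass-both records.

    ``side`` is ``"a"`` or ``"b"``.  A gene counts as passing if any of
    its pairs passes in both species; order of first appearance is kept.
    """
    if side not in ("a", "b"):
        raise ValueError(f"side must be 'a' or 'b', got {side!r}")
    col = f"gene_{side}"
    out: list[str] = []
    seen: set[str] = set()
    for g in records.loc[records["pass_both"], col]:
        if g not in seen:
            seen.add(g)
            out.append(g)
    return out


def screen_summary(records: pd.DataFrame) -> dict:
    """Headline counts of a screen: pairs tested and passing."""
    return {
        "n_pairs": int(len(records)),
        "n_pass_a": int(records["pass_a"].sum()),
        "n_pass_b": int(records["pass_b"].sum()),
        "n_pass_both": int(records["pass_both"].sum()),
        "n_pass_both_genes_a": len(passing_gene_list(records, "a")),
        "n_pass_both_genes_b": len(passing_gene_list(records, "b")),
    }


def pair_by_name(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    mode: str = "name",
    table: pd.DataFrame | OrthologMap | None = None,
) -> OrthologMap:
    """Build the cross-species ortholog map.

    ``mode="name"`` pairs genes whose symbols are equal
    case-insensitively, and additionally pairs a species-A symbol with
    species-B symbols formed by appending a single ``a`` or ``b`` (the
    zebrafish duplicated-paralog naming convention), yielding
    one-to-many pairs such as Sox9 -> {sox9a, sox9b}.
    ``mode="table"`` validates an externally supplied pair table; rows
    naming genes absent from either list are dropped with a logged
    count.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    if not genes_a or not genes_b:
        raise ValueError("gene lists must be non-empty")
    if mode == "table":
        if table is None:
            raise ValueError("table mode requires a pair table")
        raw = table.pairs if isinstance(table, OrthologMap) else list(zip(table["gene_a"], table["gene_b"]))
        set_a, set_b = set(genes_a), set(genes_b)
        kept = [(a, b) for a, b in raw if a in set_a and b in set_b]
        dropped = len(raw) - len(kept)
        if dropped:
            logger.warning("%d pair table row(s) referenced absent genes; dropped", dropped)
        return OrthologMap(kept, provenance="table")
    if mode != "name":
        raise ValueError(f"unknown pairing mode {mode!r} (use 'name' or 'table')")
    by_lower: dict[str, list[str]] = {}
    for b in genes_b:
        by_lower.setdefault(b.lower(), []).append(b)
    pairs: list[tuple[str, str]] = []
    for a in genes_a:
        key = a.lower()
        for candidate in (key, key + "a", key + "b"):
            for b in by_lower.get(candidate, []):
                pairs.append((a, b))
    return OrthologMap(pairs, provenance="name-matching")
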