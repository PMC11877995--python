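"""Count normalization and stage-profile construction.

Raw counts are converted to log2 counts-per-million with a pseudocount
(the "log2 normalized" expression on which the screen correlates), then
averaged within each developmental stage to a :class:`StageProfile`.
Per-gene z-scaling across stages is available for display parity; it is
an affine per-gene transform and therefore never changes a Pearson
correlation or a screen verdict.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, StageProfile

logger = logging.getLogger(__name__)


def cpm_log2(counts: CountMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount) per gene and sample.

    value(g, s) = log2(count(g, s) / total(s) * 1e6 + pseudocount).
    A sample whose total count is zero cannot be normalized and raises
    an error naming it.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mat = counts.counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    zero = np.where(totals == 0)[0]
    if zero.size:
        bad = [str(counts.counts.columns[i]) for i in zero]
        raise ValueError(f"samples with zero total count cannot be normalized: {bad}")
    cpm = mat / totals[None, :] * 1e6
    return pd.DataFrame(
        np.log2(cpm + pseudocount), index=counts.counts.index, columns=counts.counts.columns
    )


def stage_mean_profile(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    stage_order: Sequence[str],
) -> StageProfile:
    """Average normalized expression over replicates within each stage.

    Columns of the result follow ``stage_order``; every declared stage
    must have at least one sample.  The mean is arithmetic on the log2
    scale, so the profile is invariant to sample ordering and replicate
    labelling.
    """
    stage_order = list(stage_order)
    by_sample = dict(zip(samples["sample_id"], samples["stage"]))
    cols = {}
    for stage in stage_order:
        members = [s for s in normalized.columns if by_sample.get(s) == stage]
        if not members:
            raise ValueError(f"declared stage {stage!r} has no samples")
        # explicit contiguous copy: the mean must depend only on the values,
        # not on the frame's internal block layout
        block = np.ascontiguousarray(normalized[members].to_numpy(dtype=float))
        cols[stage] = pd.Series(block.mean(axis=1), index=normalized.index)
    values = pd.DataFrame(cols)[stage_order]
    return StageProfile(values, scaled=False)


def ordered_sample_matrix(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    stage_order: Sequence[str],
) -> StageProfile:
    """All-samples profile: one column per sample, ordered by stage.

    The replicate-level alternative to :func:`stage_mean_profile` —
    correlations are then computed over samples rather than stage
    means, which weights stages by their replicate counts.
    """
    stage_order = list(stage_order)
    order = samples.copy()
    order["_stage_rank"] = order["stage"].map({s: i for i, s in enumerate(stage_order)})
    if order["_stage_rank"].isna().any():
        bad = sorted(set(order.loc[order["_stage_rank"].isna(), "stage"]))
        raise ValueError(f"samples with stage labels outside the declared order: {bad}")
    order = order.sort_values(["_stage_rank", "replicate", "sample_id"], kind="mergesort")
    return StageProfile(normalized[list(order["sample_id"])], scaled=False)


def zscale_profile(profile: StageProfile) -> StageProfile:
    """Per-gene centring to mean 0 and scaling to sd 1 across stages.

    Genes with zero across-stage variance cannot be scaled; they are
    flagged in ``constant_genes`` and left as all-zero rows (downstream
    screening excludes them rather than assigning r = 0).  Scaling uses
    the sample standard deviation (ddof=1), matching the convention of
    R's ``scale()``.
    """
    vals = profile.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    safe_sd = np.where(constant[:, None], 1.0, sd)
    scaled = (vals - mean) / safe_sd
    scaled[constant, :] = 0.0
    const_genes = tuple(profile.values.index[constant])
    if const_genes:
        logger.warning("%d constant gene(s) flagged during scaling", len(const_genes))
    return StageProfile(
        pd.DataFrame(scaled, index=profile.values.index, columns=profile.values.columns),
        scaled=True,
        constant_genes=const_genes,
    )
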