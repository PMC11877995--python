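"""Gene-set over-representation analysis.

The over-representation statistic is the hypergeometric upper tail:
with a universe of N genes, K of them annotated to a set, and a query
of n genes, the p-value of observing an overlap of at least k is
P(X >= k) for X ~ Hypergeom(N, K, n).  Tails are computed in log space
via log-binomial coefficients so genome-scale arguments do not
overflow.  Multiple testing across sets is controlled with the
Benjamini-Hochberg step-up procedure; a set is called significant when
its adjusted value falls below the FDR level (0.05 by default).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

ENRICH_COLUMNS = ("term", "name", "k", "K", "n", "N", "p", "q", "significant")


def _log_choose(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N total, K marked, n drawn).

    Computed as a log-space sum of the exact point masses from k up to
    min(K, n); k = 0 returns exactly 1.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"K and n may not exceed N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValueError(f"k may not exceed min(K, n) (k={k}, K={K}, n={n})")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    logp = _log_choose(float(K), i) + _log_choose(float(N - K), n - i) - _log_choose(float(N), float(n))
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1; tied p-values
    share an adjusted value.  An empty input yields an empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Parse a GMT file: one tab-separated set per line.

    Each line is ``term<TAB>description<TAB>gene1<TAB>gene2...``.
    Duplicate members within a set are collapsed (first occurrence
    kept); duplicate terms raise an error.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description and >=1 member")
        term, name, members = fields[0], fields[1], fields[2:]
        if term in sets:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        uniq: list[str] = []
        seen: set[str] = set()
        for g in members:
            if g and g not in seen:
                seen.add(g)
                uniq.append(g)
        sets[term] = (name, uniq)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([term, name, *members]) for term, (name, members) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(
    query: Sequence[str],
    universe: Sequence[str],
    collection: Mapping[str, tuple[str, Sequence[str]]],
    fdr_level: float = 0.05,
    min_set: int = 10,
    max_set: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each gene set.

    Sets are intersected with the universe and filtered to sizes in
    [min_set, max_set]; query genes outside the universe are dropped
    with a logged count.  Returns one record per surviving set with the
    overlap counts, raw p, BH-adjusted q and the significance call at
    ``fdr_level``, sorted by p ascending then term identifier.
    """
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must lie in (0, 1)")
    uni: list[str] = []
    seen: set[str] = set()
    for g in universe:
        if g not in seen:
            seen.add(g)
            uni.append(g)
    if not uni:
        raise ValueError("universe is empty")
    uni_set = set(uni)
    q_in = [g for g in dict.fromkeys(query) if g in uni_set]
    dropped = len(set(query)) - len(q_in)
    if dropped:
        logger.warning("%d query gene(s) outside the universe; dropped", dropped)
    if not q_in:
        logger.warning("query is empty after universe intersection; no enrichment computed")
        return pd.DataFrame(columns=list(ENRICH_COLUMNS))
    N = len(uni)
    n = len(q_in)
    q_set = set(q_in)
    rows = []
    for term, (name, members) in collection.items():
        in_uni = [g for g in dict.fromkeys(members) if g in uni_set]
        K = len(in_uni)
        if not min_set <= K <= max_set:
            continue
        k = sum(1 for g in in_uni if g in q_set)
        rows.append((term, name, k, K, n, N, hypergeom_upper(k, K, n, N)))
    if not rows:
        return pd.DataFrame(columns=list(ENRICH_COLUMNS))
    out = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_level
    out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out
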