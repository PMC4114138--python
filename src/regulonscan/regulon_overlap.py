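"""Threshold gene sets and exact hypergeometric overlap statistics.

Gene sets are carved out of contrast results by strict logFC / p thresholds
(e.g. up-regulated: logFC > 1 and adjusted p < 0.05). Overlaps between sets
are scored with the exact upper-tail hypergeometric probability

    P(X >= k),  X ~ Hypergeometric(N, K, n)

computed in log space (log-gamma terms combined with logsumexp), which stays
accurate far below the double-precision underflow threshold of the naive sum
(at least down to 1e-300).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .expression_pipeline import ContrastResult

__all__ = [
    "GeneSetRule",
    "GeneSet",
    "OverlapResult",
    "define_gene_set",
    "hypergeometric_upper_tail",
    "log_hypergeometric_upper_tail",
    "overlap_analysis",
    "venn_regions",
]


@dataclass(frozen=True)
class GeneSetRule:
    """Strict-inequality selection rule on a contrast.

    direction "up": logFC > logfc_threshold; "down": logFC < -logfc_threshold.
    ``p_threshold`` (optional) additionally requires p < p_threshold, where p
    is the raw or BH-adjusted p per ``p_kind``.
    """

    direction: str
    logfc_threshold: float
    p_threshold: float | None = None
    p_kind: str = "adjusted"

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.logfc_threshold < 0:
            raise ValueError("logfc_threshold is an absolute magnitude, >= 0")
        if self.p_kind not in ("raw", "adjusted"):
            raise ValueError("p_kind must be 'raw' or 'adjusted'")
        if self.p_threshold is not None and not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class GeneSet:
    label: str
    members: frozenset[str]
    rule: GeneSetRule | None = None
    source_contrast: str | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two gene sets in a universe of size N."""

    label_a: str
    label_b: str
    N: int
    K: int
    n: int
    k: int
    expected_k: float
    p_hyper: float
    log10_p: float

    def as_dict(self) -> dict:
        return {
            "set_a": self.label_a,
            "set_b": self.label_b,
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "expected_k": self.expected_k,
            "p_hyper": self.p_hyper,
            "log10_p": self.log10_p,
        }


def define_gene_set(
    contrast: ContrastResult, rule: GeneSetRule, label: str
) -> GeneSet:
    """Apply a strict threshold rule to a contrast's table."""
    t = contrast.table
    if len(t) == 0:
        raise ValueError("contrast is empty")
    if rule.direction == "up":
        mask = t["logFC"] > rule.logfc_threshold
    else:
        mask = t["logFC"] < -rule.logfc_threshold
    if rule.p_threshold is not None:
        col = "p_raw" if rule.p_kind == "raw" else "p_adj"
        mask &= t[col] < rule.p_threshold
    return GeneSet(
        label=label,
        members=frozenset(t.index[mask]),
        rule=rule,
        source_contrast=contrast.label,
    )


def _check_sizes(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")


def log_hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k), X ~ Hypergeometric(N, K, n)."""
    _check_sizes(N, K, n, k)
    lo = max(k, max(0, n + K - N))
    hi = min(K, n)
    if k <= max(0, n + K - N):
        return 0.0  # the tail is the whole support
    i = np.arange(lo, hi + 1)
    log_terms = (
        gammaln(K + 1) - gammaln(i + 1) - gammaln(K - i + 1)
        + gammaln(N - K + 1) - gammaln(n - i + 1) - gammaln(N - K - n + i + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return min(0.0, float(logsumexp(log_terms)))


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k); exact 1.0 for k = 0, tiny tails accurate via the
    log-space path (see log_hypergeometric_upper_tail for values that
    underflow a float)."""
    return float(np.exp(log_hypergeometric_upper_tail(N, K, n, k)))


def pair_overlap(a: GeneSet, b: GeneSet, N: int) -> OverlapResult:
    K, n = len(a), len(b)
    k = len(a.members & b.members)
    logp = log_hypergeometric_upper_tail(N, K, n, k)
    return OverlapResult(
        label_a=a.label,
        label_b=b.label,
        N=N,
        K=K,
        n=n,
        k=k,
        expected_k=K * n / N if N else 0.0,
        p_hyper=float(np.exp(logp)),
        log10_p=logp / np.log(10.0),
    )


def venn_regions(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Cardinality of every exclusive Venn region for up to 3 sets.

    Keys are '|'-joined membership patterns of the labels, e.g. 'A', 'A|B'.
    """
    if not 1 <= len(sets) <= 3:
        raise ValueError("venn_regions supports 1-3 sets")
    labels = [s.label for s in sets]
    regions: dict[str, int] = {}
    idx = range(len(sets))
    for r in range(1, len(sets) + 1):
        for combo in combinations(idx, r):
            inside = frozenset.intersection(*(sets[i].members for i in combo))
            outside = [sets[i].members for i in idx if i not in combo]
            exclusive = inside.difference(*outside) if outside else inside
            regions["|".join(labels[i] for i in combo)] = len(exclusive)
    return regions


def overlap_analysis(
    sets: Sequence[GeneSet], universe: Iterable[str]
) -> tuple[list[OverlapResult], dict[str, int]]:
    """All pairwise hypergeometric overlaps plus (for <= 3 sets) exclusive
    Venn region counts. Members outside the universe are clipped with a
    warning; N = |universe|."""
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe is empty")
    clipped: list[GeneSet] = []
    for s in sets:
        outside = s.members - universe
        if outside:
            warnings.warn(
                f"set {s.label!r}: {len(outside)} members outside the "
                "universe were clipped",
                stacklevel=2,
            )
        clipped.append(
            GeneSet(s.label, s.members & universe, s.rule, s.source_contrast)
        )
    results = [
        pair_overlap(a, b, len(universe)) for a, b in combinations(clipped, 2)
    ]
    regions = venn_regions(clipped) if 1 <= len(clipped) <= 3 else {}
    return results, regions


def write_overlap_report(
    results: Sequence[OverlapResult], regions: dict[str, int], tsv_path, json_path
) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("set_a\tset_b\tN\tK\tn\tk\texpected_k\tp_hyper\n")
        for r in results:
            fh.write(
                f"{r.label_a}\t{r.label_b}\t{r.N}\t{r.K}\t{r.n}\t{r.k}\t"
                f"{r.expected_k:.6g}\t{r.p_hyper:.6e}\n"
            )
    with open(json_path, "w") as fh:
        json.dump(
            {"overlaps": [r.as_dict() for r in results], "venn_regions": regions},
            fh,
            indent=2,
        )
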