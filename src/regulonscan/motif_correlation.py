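"""The binned motif-count / expression-change correlation statistic.

Genes are ordered by log2 fold change and split into ``n_bins`` contiguous,
(as near as possible) equally sized bins; per bin, each motif's promoter hits
are summed and correlated (Pearson) against the bin's mean logFC. A motif
whose promoter occurrence tracks the expression response of its targets —
e.g. a forkhead-box motif enriched among genes de-repressed by knockdown of
the repressing oncoprotein — stands out with a large |r| against the bulk of
motifs, which hover near zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_pipeline import ContrastResult

logger = logging.getLogger(__name__)

__all__ = [
    "Binning",
    "MotifCorrelation",
    "bin_by_logfc",
    "correlate_motifs",
    "rank_motifs",
]


@dataclass
class Binning:
    """Assignment of genes to contiguous logFC-ordered bins.

    When N is not divisible by n_bins, the first ``N mod n_bins`` bins
    (lowest logFC) receive one extra gene. Ties in logFC break by gene label
    so the partition is deterministic.
    """

    n_bins: int
    assignment: dict[str, int]
    bin_mean_logfc: np.ndarray
    bin_sizes: np.ndarray

    def genes_in_bin(self, b: int) -> list[str]:
        return [g for g, i in self.assignment.items() if i == b]


@dataclass
class MotifCorrelation:
    motif_id: str
    pearson_r: float  # NaN when undefined (zero variance on either axis)
    n_bins_used: int
    per_bin_counts: np.ndarray
    per_bin_mean_logfc: np.ndarray

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pearson_r)


def bin_by_logfc(logfc: Mapping[str, float] | pd.Series, n_bins: int = 100) -> Binning:
    """Order genes by logFC (ascending, ties by label) and split into
    ``n_bins`` contiguous near-equal bins."""
    if isinstance(logfc, pd.Series):
        items = list(logfc.items())
    else:
        items = list(logfc.items())
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = len(items)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} genes, got {n}")
    items.sort(key=lambda kv: (kv[1], kv[0]))
    base, extra = divmod(n, n_bins)
    sizes = np.array([base + 1 if b < extra else base for b in range(n_bins)])
    assignment: dict[str, int] = {}
    means = np.empty(n_bins)
    pos = 0
    for b, size in enumerate(sizes):
        chunk = items[pos : pos + size]
        for g, _ in chunk:
            assignment[g] = b
        means[b] = float(np.mean([v for _, v in chunk]))
        pos += size
    return Binning(
        n_bins=n_bins, assignment=assignment, bin_mean_logfc=means, bin_sizes=sizes
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = math.sqrt(float(xs @ xs) * float(ys @ ys))
    if denom == 0.0:
        return math.nan
    return float(xs @ ys) / denom


def correlate_motifs(
    counts: pd.DataFrame,
    contrast: ContrastResult,
    n_bins: int = 100,
) -> list[MotifCorrelation]:
    """Per-motif Pearson r between per-bin summed counts and per-bin mean
    logFC. Genes absent from either the count matrix or the contrast are
    dropped (count logged); zero-variance correlations are NaN, not 0."""
    genes = [g for g in contrast.genes if g in counts.index]
    n_dropped = (len(contrast.genes) - len(genes)) + (len(counts.index) - len(genes))
    if n_dropped:
        logger.info("correlate_motifs: dropped %d unshared genes", n_dropped)
    if not genes:
        raise ValueError("no genes shared between count matrix and contrast")
    logfc = contrast.table.loc[genes, "logFC"]
    binning = bin_by_logfc(logfc, n_bins=n_bins)
    bin_of = np.array([binning.assignment[g] for g in genes])
    sub = counts.loc[genes].to_numpy()
    # per-bin column sums via index accumulation
    per_bin = np.zeros((n_bins, sub.shape[1]))
    np.add.at(per_bin, bin_of, sub)
    out: list[MotifCorrelation] = []
    for j, motif in enumerate(counts.columns):
        out.append(
            MotifCorrelation(
                motif_id=str(motif),
                pearson_r=_pearson(per_bin[:, j], binning.bin_mean_logfc),
                n_bins_used=n_bins,
                per_bin_counts=per_bin[:, j].copy(),
                per_bin_mean_logfc=binning.bin_mean_logfc.copy(),
            )
        )
    return out


def rank_motifs(correlations: Sequence[MotifCorrelation]) -> pd.DataFrame:
    """Motifs sorted by Pearson r descending; undefined r last; ties break
    by motif id. Columns: rank, motif_id, pearson_r, n_bins_used."""
    def key(mc: MotifCorrelation):
        return (math.isnan(mc.pearson_r), -(mc.pearson_r if mc.defined else 0.0),
                mc.motif_id)

    ordered = sorted(correlations, key=key)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "motif_id": [m.motif_id for m in ordered],
            "pearson_r": [m.pearson_r for m in ordered],
            "n_bins_used": [m.n_bins_used for m in ordered],
        }
    )
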