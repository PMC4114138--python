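"""UCSC-dialect gene models, conserved TFBS records, promoter windows and
per-gene motif-hit counting.

All genomic coordinates are 0-based half-open throughout, as in the UCSC
database dumps (``refGene.txt``, ``tfbsConsSites.txt``). The transcription
start site of a minus-strand transcript is ``txEnd``; promoter windows extend
``upstream_bp`` bases upstream of the TSS, strand-aware, clipped at 0, and
windows of transcripts sharing a gene symbol on one chromosome are merged
into a union of intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "TFBSRecord",
    "PromoterWindow",
    "PositionWeightMatrix",
    "read_gene_models",
    "read_tfbs_sites",
    "promoter_windows",
    "count_motif_hits",
    "pwm_information_content",
    "windows_to_bed",
    "write_count_matrix",
    "read_count_matrix",
]


@dataclass(frozen=True)
class GeneModel:
    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError("txStart must be < txEnd")


@dataclass(frozen=True)
class TFBSRecord:
    chrom: str
    start: int
    end: int
    motif_id: str
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("start must be < end")
        if not self.motif_id:
            raise ValueError("motif_id must be non-empty")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PromoterWindow:
    """Union of upstream intervals for one gene symbol on one chromosome."""

    gene_symbol: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str

    def __post_init__(self):
        for s, e in self.intervals:
            if s < 0 or s >= e:
                raise ValueError(f"bad interval ({s}, {e})")
        for (a, b), (c, _) in zip(self.intervals, self.intervals[1:]):
            if c < b:
                raise ValueError("intervals must be sorted and non-overlapping")

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.intervals)


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities (columns over A, C, G, T)."""

    motif_id: str
    columns: np.ndarray  # shape (n_positions, 4)

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("columns must be (n_positions, 4)")
        if (self.columns < 0).any():
            raise ValueError("probabilities must be >= 0")
        if not np.allclose(self.columns.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each column must sum to 1")


def _split_rows(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def _has_bin_column(rows: list[list[str]], strand_idx_nobin: int) -> bool:
    """UCSC dumps optionally carry a leading integer bin column; detect it by
    where the strand field lands."""
    first = rows[0]
    if len(first) > strand_idx_nobin + 1 and first[strand_idx_nobin + 1] in "+-.":
        try:
            int(first[0])
            return True
        except ValueError:
            return False
    return False


def read_gene_models(path) -> list[GeneModel]:
    """Parse a refGene-dialect table: optional bin, then
    name, chrom, strand, txStart, txEnd, ..., name2 (gene symbol)."""
    rows = _split_rows(path)
    if not rows:
        return []
    offset = 1 if _has_bin_column(rows, strand_idx_nobin=2) else 0
    models: list[GeneModel] = []
    n_rejected = 0
    for row in rows:
        f = row[offset:]
        try:
            name, chrom, strand = f[0], f[1], f[2]
            tx_start, tx_end = int(f[3]), int(f[4])
            symbol = f[11] if len(f) > 11 and f[11] else name
            if strand not in ("+", "-"):
                raise ValueError(f"unparseable strand {strand!r}")
            if tx_start >= tx_end:
                raise ValueError("txStart >= txEnd")
            models.append(GeneModel(name, symbol, chrom, strand, tx_start, tx_end))
        except (ValueError, IndexError) as exc:
            n_rejected += 1
            logger.warning("rejected gene-model row %r: %s", row, exc)
    if n_rejected:
        logger.warning("read_gene_models: rejected %d rows", n_rejected)
    return models


def read_tfbs_sites(path) -> list[TFBSRecord]:
    """Parse a tfbsConsSites-dialect table: optional bin, then
    chrom, chromStart, chromEnd, name (motif id), score, strand."""
    rows = _split_rows(path)
    if not rows:
        return []
    offset = 1 if _has_bin_column(rows, strand_idx_nobin=5) else 0
    records: list[TFBSRecord] = []
    n_rejected = 0
    for row in rows:
        f = row[offset:]
        try:
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            score = float(f[4]) if len(f) > 4 and f[4] else 0.0
            strand = f[5] if len(f) > 5 and f[5] in "+-." else "."
            if start >= end:
                raise ValueError("start >= end")
            records.append(TFBSRecord(chrom, start, end, name, score, strand))
        except (ValueError, IndexError) as exc:
            n_rejected += 1
            logger.warning("rejected TFBS row %r: %s", row, exc)
    if n_rejected:
        logger.warning("read_tfbs_sites: rejected %d rows", n_rejected)
    return records


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def promoter_windows(
    models: Sequence[GeneModel],
    upstream_bp: int = 1000,
    per_gene: str = "union",
) -> list[PromoterWindow]:
    """Strand-aware upstream windows, one PromoterWindow per (gene, chrom).

    + strand: [tx_start - upstream_bp, tx_start); - strand:
    [tx_end, tx_end + upstream_bp); clipped at coordinate 0. ``per_gene``
    is "union" (merge all transcripts of a symbol) or "first" (first
    transcript encountered only).
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be > 0")
    if per_gene not in ("union", "first"):
        raise ValueError("per_gene must be 'union' or 'first'")
    grouped: dict[tuple[str, str], list[GeneModel]] = {}
    order: list[tuple[str, str]] = []
    for m in models:
        key = (m.gene_symbol, m.chrom)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        if per_gene == "first" and grouped[key]:
            continue
        grouped[key].append(m)
    windows: list[PromoterWindow] = []
    for key in order:
        symbol, chrom = key
        ivs = []
        for m in grouped[key]:
            if m.strand == "+":
                s, e = m.tx_start - upstream_bp, m.tx_start
            else:
                s, e = m.tx_end, m.tx_end + upstream_bp
            s = max(s, 0)
            if s < e:
                ivs.append((s, e))
        if not ivs:
            continue
        windows.append(
            PromoterWindow(
                gene_symbol=symbol,
                chrom=chrom,
                intervals=_merge_intervals(ivs),
                strand=grouped[key][0].strand,
            )
        )
    return windows


def count_motif_hits(
    windows: Sequence[PromoterWindow],
    sites: Sequence[TFBSRecord],
    rule: str = "midpoint",
) -> pd.DataFrame:
    """Count motif hits per gene and motif id.

    ``rule`` decides site membership in a window segment:
    "midpoint" (default) — floor((start+end)/2) lies in the segment;
    "contained" — the whole site lies in one segment;
    "any" — any overlap with a segment.
    Site strand is ignored. A site may count toward several genes when their
    windows overlap, but at most once per gene. Returns an integer DataFrame,
    genes (window order) x sorted motif ids.
    """
    if rule not in ("midpoint", "contained", "any"):
        raise ValueError("rule must be 'midpoint', 'contained' or 'any'")
    gene_order: list[str] = []
    seen = set()
    for w in windows:
        if w.gene_symbol not in seen:
            seen.add(w.gene_symbol)
            gene_order.append(w.gene_symbol)
    gene_row = {g: i for i, g in enumerate(gene_order)}
    motif_ids = sorted({s.motif_id for s in sites})
    motif_col = {m: j for j, m in enumerate(motif_ids)}
    mat = np.zeros((len(gene_order), len(motif_ids)), dtype=int)

    segs: dict[str, list[tuple[int, int, int]]] = {}
    for w in windows:
        row = gene_row[w.gene_symbol]
        for s, e in w.intervals:
            segs.setdefault(w.chrom, []).append((s, e, row))
    disjoint = True
    for chrom, lst in segs.items():
        lst.sort()
        if any(b[0] < a[1] for a, b in zip(lst, lst[1:])):
            disjoint = False

    if rule == "midpoint" and disjoint:
        # vectorized path: non-overlapping segments admit a searchsorted lookup
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for i, s in enumerate(sites):
            by_chrom.setdefault(s.chrom, []).append(
                ((s.start + s.end) // 2, motif_col[s.motif_id])
            )
        for chrom, pairs in by_chrom.items():
            if chrom not in segs:
                continue
            starts = np.array([x[0] for x in segs[chrom]])
            ends = np.array([x[1] for x in segs[chrom]])
            rows = np.array([x[2] for x in segs[chrom]])
            mids = np.array([p[0] for p in pairs])
            cols = np.array([p[1] for p in pairs])
            pos = np.searchsorted(starts, mids, side="right") - 1
            ok = (pos >= 0) & (mids < ends[np.clip(pos, 0, None)])
            np.add.at(mat, (rows[pos[ok]], cols[ok]), 1)
    else:
        trees: dict[str, IntervalTree] = {}
        for chrom, lst in segs.items():
            tree = trees.setdefault(chrom, IntervalTree())
            for s, e, row in lst:
                tree.addi(s, e, row)
        for site in sites:
            tree = trees.get(site.chrom)
            if tree is None:
                continue
            if rule == "midpoint":
                hit_rows = {iv.data for iv in tree[site.midpoint]}
            elif rule == "contained":
                hit_rows = {
                    iv.data
                    for iv in tree[site.start : site.end]
                    if iv.begin <= site.start and site.end <= iv.end
                }
            else:  # any overlap
                hit_rows = {iv.data for iv in tree[site.start : site.end]}
            col = motif_col[site.motif_id]
            for r in hit_rows:
                mat[r, col] += 1
    return pd.DataFrame(
        mat, index=pd.Index(gene_order, name="gene"), columns=motif_ids
    )


def pwm_information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information content in bits: IC_j = 2 + sum_b p log2 p,
    with 0 * log2(0) taken as 0. Values lie in [0, 2]."""
    cols = np.asarray(pwm.columns, dtype=float)
    if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("PWM columns must each sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(cols > 0, cols * np.log2(np.where(cols > 0, cols, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    return np.clip(ic, 0.0, 2.0)


def windows_to_bed(windows: Sequence[PromoterWindow], path) -> None:
    """BED export (chrom, start, end, gene_symbol, 0, strand), one line per
    interval segment."""
    with open(path, "w") as fh:
        for w in windows:
            for s, e in w.intervals:
                fh.write(f"{w.chrom}\t{s}\t{e}\t{w.gene_symbol}\t0\t{w.strand}\n")


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("gene")
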