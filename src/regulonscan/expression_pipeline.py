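"""Differential expression for knockdown time courses.

Reads log2 expression matrices with a sample sheet, filters features with
uniformly low expression, collapses probe-level features to one row per gene,
and scores contrasts with an empirical-Bayes moderated t-statistic followed by
Benjamini-Hochberg adjustment.

Coordinates and conventions
---------------------------
* Expression values are log2 intensities; ``logFC = mean(group B) - mean(group A)``.
* The moderated t shrinks each gene's pooled residual variance ``s_g^2``
  (``d_g = nA + nB - 2`` df) toward a prior ``s0^2`` carrying ``d0`` prior df:

      s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
      t_g    = logFC_g / (s~_g * sqrt(1/nA + 1/nB))

  with two-sided p-values from a t distribution on ``d0 + d_g`` df.
  If ``(d0, s0^2)`` are not supplied they are estimated from the observed
  distribution of ``s_g^2`` by matching the first two moments of
  ``log s_g^2`` to a scaled-F model (digamma/trigamma moment equations).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ContrastResult",
    "ModerationParams",
    "ExpressionFormatError",
    "read_expression_table",
    "write_expression_table",
    "filter_low_expression",
    "collapse_to_genes",
    "moderated_t_test",
    "bh_adjust",
    "timecourse_contrasts",
]


class ExpressionFormatError(ValueError):
    """Raised when an expression matrix or sample sheet violates its schema."""


SAMPLE_SHEET_COLUMNS = ("sample_id", "condition", "time_h", "replicate")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (features x samples) plus sample annotations.

    ``values`` is a float DataFrame indexed by unique feature ids; ``samples``
    is indexed by sample id with columns ``condition``, ``time_h``,
    ``replicate`` and covers exactly the matrix columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ExpressionFormatError(f"duplicate feature id: {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ExpressionFormatError("expression values must all be finite")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ExpressionFormatError(
                f"samples missing from sample sheet: {missing}"
            )
        # keep annotation rows aligned with (and restricted to) matrix columns
        self.samples = self.samples.loc[list(self.values.columns)]
        if self.samples["condition"].isna().any():
            raise ExpressionFormatError("every sample needs a condition label")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_at_time(self, time_h: float) -> list[str]:
        mask = self.samples["time_h"].astype(float) == float(time_h)
        return list(self.samples.index[mask])


@dataclass
class ModerationParams:
    """Empirical-Bayes prior for the moderated t.

    d0 : prior degrees of freedom (``math.inf`` = full shrinkage; 0 may be
        forced to recover the ordinary pooled-variance t).
    s0_sq : prior variance in (log2)^2 units.
    """

    d0: float
    s0_sq: float
    estimated_from_data: bool = False

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0 (or inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group contrast.

    ``table`` is indexed by gene with columns
    ``logFC, t_mod, df_total, p_raw, p_adj, mean_expr``.
    """

    label: str
    table: pd.DataFrame
    params: ModerationParams | None = None

    def __post_init__(self) -> None:
        required = {"logFC", "t_mod", "df_total", "p_raw", "p_adj", "mean_expr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"contrast table missing columns: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, label: str | None = None) -> "ContrastResult":
        df = pd.read_csv(path, sep="\t").set_index("gene")
        return cls(label=label or str(path), table=df)


def read_expression_table(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a tab-delimited log2 matrix (first column = feature id) and its
    sample sheet (columns ``sample_id, condition, time_h, replicate``)."""
    raw = pd.read_csv(matrix_path, sep="\t", dtype={0: str})
    feat_col = raw.columns[0]
    raw = raw.set_index(feat_col)
    dups = raw.index[raw.index.duplicated()].unique().tolist()
    if dups:
        raise ExpressionFormatError(
            f"duplicate feature id(s) in {matrix_path}: {dups}"
        )
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ExpressionFormatError(
            f"non-numeric cell at feature {values.index[r]!r}, "
            f"sample {values.columns[c]!r} in {matrix_path}"
        )
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    missing_cols = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise ExpressionFormatError(f"sample sheet missing columns: {missing_cols}")
    sheet = sheet.set_index("sample_id")
    orphans = [c for c in values.columns if c not in sheet.index]
    if orphans:
        raise ExpressionFormatError(
            f"samples in matrix but not in sample sheet: {orphans}"
        )
    return ExpressionMatrix(values=values.astype(float), samples=sheet)


def write_expression_table(em: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    out = em.values.copy()
    out.insert(0, "feature_id", out.index)
    out.to_csv(matrix_path, sep="\t", index=False)
    sheet = em.samples.copy()
    sheet.insert(0, "sample_id", sheet.index)
    sheet.to_csv(sample_sheet_path, sep="\t", index=False)


def filter_low_expression(
    em: ExpressionMatrix,
    min_value: float | None = None,
    min_fraction: float = 1.0,
) -> ExpressionMatrix:
    """Drop features that sit below ``min_value`` too often.

    A feature is kept when its value is >= ``min_value`` in at least
    ``min_fraction`` of samples; the default removes features that are low
    *everywhere* (``min_fraction=1``), with ``min_value`` defaulting to the
    20th percentile of the pooled value distribution. Row order is preserved.
    """
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    if min_value is None:
        min_value = float(np.percentile(em.values.to_numpy(), 20))
    frac_ok = (em.values >= min_value).mean(axis=1)
    keep = frac_ok >= min_fraction
    if not keep.any():
        warnings.warn("filter_low_expression removed every feature", stacklevel=2)
    return ExpressionMatrix(values=em.values.loc[keep], samples=em.samples)


def collapse_to_genes(
    em: ExpressionMatrix, feature_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse to one row per gene, keeping the most informative feature.

    The retained feature is the one with the largest interquartile range
    across samples; ties break to the lexicographically smallest feature id.
    Features absent from the mapping are dropped (count logged).
    """
    if not feature_to_gene:
        raise ValueError("feature_to_gene mapping is empty")
    mapped = [f for f in em.feature_ids if f in feature_to_gene]
    n_dropped = em.n_features - len(mapped)
    if n_dropped:
        logger.info("collapse_to_genes: dropped %d unmapped features", n_dropped)
    vals = em.values.loc[mapped]
    iqr = vals.quantile(0.75, axis=1) - vals.quantile(0.25, axis=1)
    best: dict[str, str] = {}
    for feat in mapped:
        gene = feature_to_gene[feat]
        cur = best.get(gene)
        if cur is None:
            best[gene] = feat
        else:
            better = iqr[feat] > iqr[cur] or (iqr[feat] == iqr[cur] and feat < cur)
            if better:
                best[gene] = feat
    # gene order follows first appearance in the feature order (deterministic)
    genes, rows = [], []
    seen = set()
    for feat in mapped:
        gene = feature_to_gene[feat]
        if gene not in seen:
            seen.add(gene)
            genes.append(gene)
            rows.append(best[gene])
    collapsed = vals.loc[rows]
    collapsed.index = pd.Index(genes, name="gene")
    return ExpressionMatrix(values=collapsed, samples=em.samples)


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_moderation_params(s2: np.ndarray, d_g: float) -> ModerationParams:
    """Moment-match (d0, s0^2) from observed gene variances.

    Works on ``e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2)`` whose mean and
    excess variance identify ``s0^2`` and ``trigamma(d0/2)`` under the
    scaled-F sampling model for gene variances.
    """
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all gene variances are zero; cannot estimate prior")
    z = np.log(pos)
    e = z - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return ModerationParams(d0=d0, s0_sq=s0_sq, estimated_from_data=True)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_test(
    em: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: ModerationParams | None = None,
    label: str | None = None,
) -> ContrastResult:
    """Moderated two-sample t for ``group_b - group_a`` on every gene."""
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    a = em.values[group_a].to_numpy(dtype=float)
    b = em.values[group_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    d_g = n_a + n_b - 2
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    logfc = mean_b - mean_a
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / d_g
    if params is None:
        try:
            params = estimate_moderation_params(s2, d_g)
        except ValueError:
            logger.warning(
                "all gene variances zero; falling back to fixed prior "
                "(d0=inf, s0_sq=1)"
            )
            params = ModerationParams(d0=math.inf, s0_sq=1.0)
    d0, s0_sq = params.d0, params.s0_sq
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = float(d0 + d_g)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                         np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
    if math.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p_raw = np.clip(p_raw, 0.0, 1.0)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "mean_expr": np.concatenate([a, b], axis=1).mean(axis=1),
        },
        index=em.values.index,
    )
    return ContrastResult(label=label or "B_vs_A", table=table, params=params)


def timecourse_contrasts(
    em: ExpressionMatrix,
    baseline_time: float = 0.0,
    params: ModerationParams | None = None,
) -> dict[float, ContrastResult]:
    """One contrast per post-baseline time point versus baseline (BH within
    each contrast). Keys are the later time points, ascending."""
    times = sorted(set(em.samples["time_h"].astype(float)))
    if float(baseline_time) not in times:
        raise ValueError(f"baseline time {baseline_time} not present in samples")
    base = em.samples_at_time(baseline_time)
    results: dict[float, ContrastResult] = {}
    for t in times:
        if t == float(baseline_time):
            continue
        grp = em.samples_at_time(t)
        results[t] = moderated_t_test(
            em, base, grp, params=params,
            label=f"{t:g}h_vs_{baseline_time:g}h",
        )
    return results
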