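"""Ground-truth simulators for every stage of the pipeline.

Three generators with planted, fully known structure:

* a knockdown expression time course — genes activated by the silenced
  regulator fall over time, repressed genes rise, null genes drift only by
  homoscedastic Gaussian noise on the log2 scale;
* a promoter landscape — one synthetic gene model per gene with alternating
  strands on a single chromosome, plus conserved-TFBS records whose per-gene,
  per-motif counts are Poisson, with the planted motif's rate elevated in the
  regulon (the repressed gene group);
* two-arm exponential tumor growth with a treatment multiplier on the growth
  rate and multiplicative lognormal noise.

Every generator draws from its own seed-derived stream, so adding a call to
one never perturbs another, and identical configs give bit-identical output.
Enrichment is planted at the count level: no sequences are emitted and no
PWM scanning is simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_pipeline import ExpressionMatrix
from .growth_stats import GrowthCurveSet

__all__ = [
    "SimConfig",
    "PromoterSimConfig",
    "GrowthSimConfig",
    "SyntheticTruth",
    "ConfigError",
    "simulate_timecourse",
    "simulate_promoter_landscape",
    "simulate_growth_curves",
    "write_gene_models",
    "write_tfbs_sites",
]

# sub-stream tags so each generator owns an independent stream
_STREAM_TIMECOURSE = 101
_STREAM_PROMOTER = 202
_STREAM_GROWTH = 303


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


@dataclass
class SimConfig:
    """Knockdown time-course design.

    The default grid (0, 18, 36, 53, 72 h) mirrors a five-point silencing
    course with duplicate arrays per point. ``effect_logfc`` is the full
    planted |log2 FC| reached at the final time point; ``effect_ramp`` maps
    each time to the fraction of the full effect (default: linear from 0 at
    t=0 to 1 at the last point).
    """

    seed: int = 0
    n_genes: int = 2000
    time_points_h: tuple[float, ...] = (0.0, 18.0, 36.0, 53.0, 72.0)
    n_replicates_per_point: int = 2
    frac_activated: float = 0.15
    frac_repressed: float = 0.15
    effect_logfc: float = 1.5
    effect_ramp: Mapping[float, float] | None = None
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_activated + self.frac_repressed <= 1.0):
            raise ConfigError("frac_activated + frac_repressed must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        tp = tuple(float(t) for t in self.time_points_h)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("time_points_h must be strictly increasing")
        if tp[0] != 0.0:
            raise ConfigError("time_points_h must include 0")
        self.time_points_h = tp
        if self.effect_ramp is not None and self.effect_ramp.get(0.0, 0.0) != 0.0:
            raise ConfigError("effect_ramp(0) must be 0")

    def ramp(self, t: float) -> float:
        if self.effect_ramp is not None:
            return float(self.effect_ramp[float(t)])
        t_max = self.time_points_h[-1]
        return float(t) / t_max if t_max > 0 else 0.0


@dataclass
class PromoterSimConfig:
    """Promoter landscape with count-level planted motif enrichment.

    ``n_motifs`` background motifs are drawn at ``lambda_background`` per
    promoter everywhere; each motif in ``planted_motif_ids`` is drawn at
    ``lambda_planted`` in regulon genes and ``lambda_background`` elsewhere.
    """

    seed: int = 0
    n_motifs: int = 50
    planted_motif_ids: tuple[str, ...] = ("V$FOXO1_01",)
    lambda_background: float = 1.0
    lambda_planted: float = 3.0
    upstream_bp: int = 1000
    gene_spacing_bp: int = 10000
    chrom_name: str = "chrSim"
    transcripts_per_gene: int = 1

    def __post_init__(self) -> None:
        if not (self.lambda_planted >= self.lambda_background >= 0):
            raise ConfigError("need lambda_planted >= lambda_background >= 0")
        if self.upstream_bp <= 0:
            raise ConfigError("upstream_bp must be > 0")
        if self.gene_spacing_bp <= 2 * self.upstream_bp:
            raise ConfigError("gene_spacing_bp must exceed 2 * upstream_bp")
        if self.transcripts_per_gene < 1:
            raise ConfigError("transcripts_per_gene must be >= 1")
        self.planted_motif_ids = tuple(self.planted_motif_ids)


@dataclass
class GrowthSimConfig:
    """Two-arm exponential xenograft growth.

    volume(i, t) = v0 * exp(rate_i * t) * LogNormal(0, sigma), with the
    treated arm's rate multiplied by ``treatment_multiplier`` and
    sigma = sqrt(log(1 + noise_cv^2)).
    """

    seed: int = 0
    n_per_arm: int = 10
    days: tuple[float, ...] = (0.0, 3.0, 7.0, 10.0, 12.0, 14.0, 17.0, 19.0, 21.0)
    v0_mm3: float = 100.0
    growth_rate_per_day: float = 0.15
    treatment_multiplier: float = 0.5
    noise_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.v0_mm3 <= 0:
            raise ConfigError("v0_mm3 must be > 0")
        days = tuple(float(d) for d in self.days)
        if any(d < 0 for d in days) or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("days must be non-negative and increasing")
        self.days = days
        if not (0 < self.treatment_multiplier <= 1):
            raise ConfigError("treatment_multiplier must be in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")


@dataclass
class SyntheticTruth:
    """Planted structure shared by the simulators: which genes respond, the
    regulon carrying the motif enrichment, and the exact noiseless logFC of
    every gene at every time point."""

    seed: int
    activated_genes: frozenset[str]
    repressed_genes: frozenset[str]
    regulon_genes: frozenset[str]
    planted_motif_ids: tuple[str, ...]
    trajectory: dict[str, dict[float, float]]

    def __post_init__(self) -> None:
        if self.activated_genes & self.repressed_genes:
            raise ValueError("activated and repressed gene sets must be disjoint")
        if not self.regulon_genes <= self.repressed_genes:
            raise ValueError("regulon_genes must be a subset of repressed_genes")

    @property
    def genes(self) -> list[str]:
        return sorted(self.trajectory)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "activated_genes": sorted(self.activated_genes),
                    "repressed_genes": sorted(self.repressed_genes),
                    "regulon_genes": sorted(self.regulon_genes),
                    "planted_motif_ids": list(self.planted_motif_ids),
                    "trajectory": {
                        g: {f"{t:g}": v for t, v in traj.items()}
                        for g, traj in self.trajectory.items()
                    },
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            activated_genes=frozenset(d["activated_genes"]),
            repressed_genes=frozenset(d["repressed_genes"]),
            regulon_genes=frozenset(d["regulon_genes"]),
            planted_motif_ids=tuple(d["planted_motif_ids"]),
            trajectory={
                g: {float(t): v for t, v in traj.items()}
                for g, traj in d["trajectory"].items()
            },
        )


def simulate_timecourse(cfg: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Planted knockdown course: activated genes fall, repressed genes rise.

    value(g, sample at t) = baseline(g) + sign(g) * effect_logfc * ramp(t)
                            + Normal(0, noise_sd)
    with sign -1 / +1 / 0 for activated / repressed / null genes.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_TIMECOURSE])
    n = cfg.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    n_act = int(round(cfg.frac_activated * n))
    n_rep = int(round(cfg.frac_repressed * n))
    if n_act + n_rep > n:
        n_rep = n - n_act
    perm = rng.permutation(n)
    activated = frozenset(genes[i] for i in perm[:n_act])
    repressed = frozenset(genes[i] for i in perm[n_act : n_act + n_rep])
    sign = np.zeros(n)
    sign[perm[:n_act]] = -1.0
    sign[perm[n_act : n_act + n_rep]] = 1.0

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    cols, col_time, col_cond, col_rep = [], [], [], []
    blocks = []
    for t in cfg.time_points_h:
        effect = sign * cfg.effect_logfc * cfg.ramp(t)
        for r in range(1, cfg.n_replicates_per_point + 1):
            noise = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
            blocks.append(baseline + effect + noise)
            cols.append(f"t{t:g}_r{r}")
            col_time.append(float(t))
            col_cond.append(f"{t:g}h")
            col_rep.append(r)
    values = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(genes, name="feature_id"),
        columns=cols,
    )
    samples = pd.DataFrame(
        {"condition": col_cond, "time_h": col_time, "replicate": col_rep},
        index=pd.Index(cols, name="sample_id"),
    )
    trajectory = {
        g: {
            float(t): float(sign[i] * cfg.effect_logfc * cfg.ramp(t))
            for t in cfg.time_points_h
        }
        for i, g in enumerate(genes)
    }
    truth = SyntheticTruth(
        seed=cfg.seed,
        activated_genes=activated,
        repressed_genes=repressed,
        regulon_genes=repressed,  # default regulon: the whole repressed group
        planted_motif_ids=(),
        trajectory=trajectory,
    )
    return ExpressionMatrix(values=values, samples=samples), truth


def _motif_universe(cfg: PromoterSimConfig) -> list[str]:
    background = [f"V$BG{i:03d}_01" for i in range(cfg.n_motifs)]
    return list(cfg.planted_motif_ids) + background


def simulate_promoter_landscape(
    truth: SyntheticTruth, cfg: PromoterSimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Gene-model and conserved-TFBS tables with Poisson-planted counts.

    One gene per truth gene on one chromosome, alternating strands, TSS
    spaced ``gene_spacing_bp`` apart. Per gene g and motif m the emitted
    record count is Poisson(lambda_planted) when m is planted and g is in
    the regulon, else Poisson(lambda_background); each record lies wholly
    inside g's 1-kb (``upstream_bp``) upstream window. Returns (gene table in
    the refGene dialect, TFBS table in the tfbsConsSites dialect, truth with
    planted_motif_ids filled in).
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_PROMOTER])
    genes = truth.genes
    motifs = _motif_universe(cfg)
    planted = set(cfg.planted_motif_ids)
    in_regulon = np.array([g in truth.regulon_genes for g in genes])

    site_len = 10
    tx_len = 2000
    offset = cfg.upstream_bp + site_len  # keeps every window above coord 0
    gene_rows = []
    tss = np.empty(len(genes), dtype=int)
    win_start = np.empty(len(genes), dtype=int)
    for i, g in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        pos = offset + i * cfg.gene_spacing_bp + cfg.upstream_bp
        tss[i] = pos
        if strand == "+":
            tx_start, tx_end = pos, pos + tx_len
            w = pos - cfg.upstream_bp
        else:
            tx_start, tx_end = pos - tx_len, pos
            w = pos
        if w < 0:  # shift the whole gene right rather than dropping it
            shift = -w
            tx_start, tx_end, w = tx_start + shift, tx_end + shift, 0
        win_start[i] = w
        for k in range(cfg.transcripts_per_gene):
            # extra transcripts shift by +200 bp each: their upstream windows
            # overlap the first transcript's, exercising the per-gene merge
            d = 200 * k
            gene_rows.append((f"NM_{i:05d}_{k}", cfg.chrom_name, strand,
                              tx_start + d, tx_end + d, g))
    gene_df = pd.DataFrame(
        gene_rows, columns=["name", "chrom", "strand", "txStart", "txEnd", "name2"]
    )

    chroms, starts, ends, names, scores, strands = [], [], [], [], [], []
    for m in motifs:
        lam = np.where(
            in_regulon & (m in planted), cfg.lambda_planted, cfg.lambda_background
        )
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        gene_idx = np.repeat(np.arange(len(genes)), counts)
        # place each record wholly inside its gene's upstream window
        rel = rng.integers(0, cfg.upstream_bp - site_len + 1, size=total)
        s = win_start[gene_idx] + rel
        chroms.extend([cfg.chrom_name] * total)
        starts.extend(s.tolist())
        ends.extend((s + site_len).tolist())
        names.extend([m] * total)
        scores.extend(rng.integers(500, 1000, size=total).tolist())
        strands.extend(np.where(rng.random(total) < 0.5, "+", "-").tolist())
    tfbs_df = pd.DataFrame(
        {
            "chrom": chroms,
            "chromStart": starts,
            "chromEnd": ends,
            "name": names,
            "score": scores,
            "strand": strands,
        }
    )
    new_truth = SyntheticTruth(
        seed=truth.seed,
        activated_genes=truth.activated_genes,
        repressed_genes=truth.repressed_genes,
        regulon_genes=truth.regulon_genes,
        planted_motif_ids=tuple(cfg.planted_motif_ids),
        trajectory=truth.trajectory,
    )
    return gene_df, tfbs_df, new_truth


def simulate_growth_curves(cfg: GrowthSimConfig) -> GrowthCurveSet:
    """Exponential two-arm growth with lognormal multiplicative noise."""
    rng = np.random.default_rng([cfg.seed, _STREAM_GROWTH])
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2)) if cfg.noise_cv > 0 else 0.0
    rows = []
    for group, rate_mult, prefix in (
        ("control", 1.0, "C"),
        ("treated", cfg.treatment_multiplier, "T"),
    ):
        rate = cfg.growth_rate_per_day * rate_mult
        for i in range(1, cfg.n_per_arm + 1):
            animal = f"{prefix}{i:02d}"
            for day in cfg.days:
                noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
                rows.append(
                    (animal, group, day, cfg.v0_mm3 * math.exp(rate * day) * noise)
                )
    return GrowthCurveSet(
        pd.DataFrame(rows, columns=["animal_id", "group", "day", "volume_mm3"])
    )


def write_gene_models(gene_df: pd.DataFrame, path, with_bin: bool = False) -> None:
    """Emit the refGene dialect: [bin,] name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds, score, name2."""
    with open(path, "w") as fh:
        for i, row in enumerate(gene_df.itertuples(index=False)):
            fields = [
                row.name, row.chrom, row.strand, str(row.txStart), str(row.txEnd),
                str(row.txStart), str(row.txEnd), "1",
                f"{row.txStart},", f"{row.txEnd},", "0", row.name2,
            ]
            if with_bin:
                fields.insert(0, str(585 + i % 10))
            fh.write("\t".join(fields) + "\n")


def write_tfbs_sites(tfbs_df: pd.DataFrame, path, with_bin: bool = False) -> None:
    """Emit the tfbsConsSites dialect: [bin,] chrom, chromStart, chromEnd,
    name, score, strand."""
    with open(path, "w") as fh:
        for i, row in enumerate(tfbs_df.itertuples(index=False)):
            fields = [
                row.chrom, str(row.chromStart), str(row.chromEnd),
                row.name, str(row.score), row.strand,
            ]
            if with_bin:
                fields.insert(0, str(585 + i % 10))
            fh.write("\t".join(fields) + "\n")
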