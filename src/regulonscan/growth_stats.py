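"""Two-arm tumor growth-curve statistics.

A distribution-free permutation test compares whole growth curves between a
treated and a control arm: the statistic is the absolute difference in
trapezoidal area under the arm-mean log(volume+1) curve, and the null is
built by permuting animal group labels. Day-wise comparisons use an exact
two-sample rank-sum (Mann-Whitney) test, enumerated for small samples.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurveSet",
    "PermResult",
    "read_growth_table",
    "curve_permutation_test",
    "rank_sum_test",
    "per_day_rank_tests",
]

GROWTH_COLUMNS = ("animal_id", "group", "day", "volume_mm3")


@dataclass
class GrowthCurveSet:
    """Long-format per-animal tumor volumes with exactly two group labels."""

    data: pd.DataFrame  # columns animal_id, group, day, volume_mm3

    def __post_init__(self) -> None:
        missing = [c for c in GROWTH_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"growth table missing columns: {missing}")
        if (self.data["volume_mm3"] < 0).any():
            raise ValueError("volumes must be >= 0")
        groups = sorted(self.data["group"].unique())
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, got {groups}")

    @property
    def groups(self) -> tuple[str, str]:
        return tuple(sorted(self.data["group"].unique()))

    @property
    def days(self) -> list[float]:
        return sorted(self.data["day"].unique())

    def animals(self, group: str | None = None) -> list[str]:
        d = self.data if group is None else self.data[self.data["group"] == group]
        return sorted(d["animal_id"].unique())

    def volume_matrix(self) -> tuple[np.ndarray, list[str], np.ndarray, list[float]]:
        """(animals x days volume matrix with NaN gaps, animal ids,
        group-label array aligned to rows, day grid)."""
        piv = self.data.pivot_table(
            index="animal_id", columns="day", values="volume_mm3", aggfunc="mean"
        )
        labels = (
            self.data.drop_duplicates("animal_id")
            .set_index("animal_id")["group"]
            .loc[piv.index]
            .to_numpy()
        )
        return piv.to_numpy(), list(piv.index), labels, [float(d) for d in piv.columns]

    def write(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_growth_table(path) -> GrowthCurveSet:
    df = pd.read_csv(path, sep="\t")
    return GrowthCurveSet(df)


@dataclass
class PermResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    seed: int
    statistic: str = "auc_log"


def _arm_auc(logv: np.ndarray, in_arm: np.ndarray, days: np.ndarray) -> float:
    """Trapezoidal AUC of the per-day arm mean of log volumes; days with no
    observed animal in the arm contribute via the surviving animals only
    (NaN-mean), never by imputation."""
    with np.errstate(invalid="ignore"):
        mean_curve = np.nanmean(logv[in_arm], axis=0)
    ok = ~np.isnan(mean_curve)
    if ok.sum() < 2:
        return float(mean_curve[ok][0]) if ok.any() else math.nan
    return float(np.trapezoid(mean_curve[ok], days[ok]))


def curve_permutation_test(
    gcs: GrowthCurveSet,
    n_permutations: int = 999,
    seed: int = 0,
    statistic: str = "auc_log",
) -> PermResult:
    """Permutation test for an overall two-arm growth-curve difference.

    statistic "auc_log" (default): T = |AUC(mean log(V+1), arm 1) -
    AUC(mean log(V+1), arm 2)| over the common measured days;
    "final": absolute difference of arm-mean log(V+1) on the last common day.
    p = (1 + #{T_perm >= T_obs}) / (1 + n_permutations).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if statistic not in ("auc_log", "final"):
        raise ValueError("statistic must be 'auc_log' or 'final'")
    vols, animal_ids, labels, days = gcs.volume_matrix()
    g1, g2 = gcs.groups
    if (labels == g1).sum() < 2 or (labels == g2).sum() < 2:
        raise ValueError("need at least 2 animals per arm")
    # restrict to days measured in both arms
    measured = ~np.isnan(vols)
    common = measured[labels == g1].any(axis=0) & measured[labels == g2].any(axis=0)
    if not common.any():
        raise ValueError("no common measured days between the arms")
    logv = np.log(vols[:, common] + 1.0)
    day_arr = np.asarray(days, dtype=float)[common]

    def stat(mask: np.ndarray) -> float:
        if statistic == "auc_log":
            return abs(_arm_auc(logv, mask, day_arr) - _arm_auc(logv, ~mask, day_arr))
        with np.errstate(invalid="ignore"):
            last = np.nanmean(logv[mask, -1]) - np.nanmean(logv[~mask, -1])
        return abs(float(last))

    obs_mask = labels == g1
    t_obs = stat(obs_mask)
    rng = np.random.default_rng(seed)
    complete = not np.isnan(logv).any()
    if complete:
        # balanced-information case: vectorize over permutations
        n1 = int(obs_mask.sum())
        n2 = logv.shape[0] - n1
        perms = np.empty((n_permutations, logv.shape[0]), dtype=bool)
        for i in range(n_permutations):
            perms[i] = rng.permutation(obs_mask)
        m1 = perms.astype(float) @ logv / n1
        m2 = (~perms).astype(float) @ logv / n2
        diff = m1 - m2
        if statistic == "auc_log":
            t_perm = np.abs(np.trapezoid(diff, day_arr, axis=1))
        else:
            t_perm = np.abs(diff[:, -1])
        n_ge = int((t_perm >= t_obs - 1e-12).sum())
    else:
        n_ge = 0
        for _ in range(n_permutations):
            if stat(rng.permutation(obs_mask)) >= t_obs - 1e-12:
                n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return PermResult(
        observed_stat=t_obs,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        statistic=statistic,
    )


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided two-sample rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration of the C(nA+nB, nA) label assignments when
    nA + nB <= 12 (ties averaged over the observed tie pattern; no mid-p);
    normal approximation with tie and continuity corrections otherwise.
    Two-sided p = min(1, 2 * min(P(W <= w_obs), P(W >= w_obs))).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[:n_a].sum())
    if n <= 12:
        total = 0
        le = 0
        ge = 0
        eps = 1e-9
        for combo in itertools.combinations(range(n), n_a):
            w = float(ranks[list(combo)].sum())
            total += 1
            if w <= w_obs + eps:
                le += 1
            if w >= w_obs - eps:
                ge += 1
        return min(1.0, 2.0 * min(le / total, ge / total))
    mean_w = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    sd = math.sqrt(var_w)
    p_ge = stats.norm.sf((w_obs - 0.5 - mean_w) / sd)
    p_le = stats.norm.cdf((w_obs + 0.5 - mean_w) / sd)
    return min(1.0, 2.0 * min(p_le, p_ge))


def per_day_rank_tests(gcs: GrowthCurveSet) -> dict[float, float]:
    """Exact/approximate rank-sum p per day on which both arms were measured."""
    g1, g2 = gcs.groups
    out: dict[float, float] = {}
    for day in gcs.days:
        d = gcs.data[gcs.data["day"] == day]
        a = d.loc[d["group"] == g1, "volume_mm3"].to_numpy()
        b = d.loc[d["group"] == g2, "volume_mm3"].to_numpy()
        if a.size and b.size:
            out[float(day)] = rank_sum_test(a, b)
    return out


def write_growth_report(
    perm: PermResult, day_p: dict[float, float], path
) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "statistic": perm.statistic,
                "observed_stat": perm.observed_stat,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
                "per_day_rank_p": {f"{d:g}": p for d, p in day_p.items()},
            },
            fh,
            indent=2,
        )
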