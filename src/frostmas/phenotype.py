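"""Injury-score phenotyping and extreme-bulk construction.

Frost damage is scored visually per replicate plant on a 0-6 scale (0 =
undamaged, 6 = dead).  The average injury score (AS) of a genotype is the mean
of its replicate scores; equivalently, with Ni plants at scale value Xi,
AS = sum(Xi * Ni) / sum(Ni).  The two extreme DNA bulks (RP, resistant pool;
SP, sensitive pool) are the lowest- and highest-AS individuals, subject to a
balance constraint that keeps the progeny of each frost-tolerant parent
represented in roughly equal proportion in both bulks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PhenotypeRecord",
    "PoolAssignment",
    "average_injury_score",
    "as_from_tally",
    "as_table",
    "summarize_environment",
    "build_extreme_pools",
    "parent_frequency_report",
    "compare_pools",
]


@dataclass(frozen=True)
class PhenotypeRecord:
    genotype_id: str
    environment_id: str
    replicate_scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.replicate_scores) == 0:
            raise ValueError("at least one replicate score required")
        if any(s not in range(7) for s in self.replicate_scores):
            raise ValueError("scores must be integers in 0..6")


@dataclass
class PoolAssignment:
    """Membership of one extreme bulk with parent-of-origin bookkeeping."""

    pool: str  # "RP" | "SP"
    member_ids: list[str]
    parent_contribution: dict[str, int] = field(default_factory=dict)

    def total_contribution(self, parent_ids: Iterable[str]) -> int:
        return sum(self.parent_contribution.get(p, 0) for p in parent_ids)


def average_injury_score(record: PhenotypeRecord | Sequence[int]) -> float:
    """AS of one genotype: the arithmetic mean of its replicate scores."""
    scores = (
        record.replicate_scores
        if isinstance(record, PhenotypeRecord)
        else tuple(record)
    )
    if len(scores) == 0:
        raise ValueError("empty replicate list")
    if any(s not in range(7) for s in scores):
        raise ValueError("scores must be integers in 0..6")
    return float(np.mean(scores))


def as_from_tally(tally: Sequence[int]) -> float:
    """AS from the scale-value tally (N0..N6): sum(Xi*Ni) / sum(Ni).

    Algebraically identical to :func:`average_injury_score`; kept as an
    independent route for cross-checking.
    """
    if len(tally) != 7:
        raise ValueError("tally must have seven entries N0..N6")
    n = int(np.sum(tally))
    if n == 0:
        raise ValueError("empty tally")
    return float(np.dot(np.arange(7), tally) / n)


def as_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype AS by environment from a tidy score table.

    ``phenotypes`` needs columns genotype_id, environment_id, score.
    """
    return (
        phenotypes.groupby(["genotype_id", "environment_id"])["score"]
        .mean()
        .unstack("environment_id")
    )


def summarize_environment(
    as_values: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Mean, sample SD (ddof=1) and CV% of AS per group.

    CV is flagged as NaN when the group mean is zero (undefined).
    """
    if isinstance(as_values, pd.DataFrame):
        groups = {c: as_values[c].dropna().to_numpy() for c in as_values.columns}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in as_values.items()}
    rows = []
    for name, vals in groups.items():
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        rows.append({"group": name, "n": vals.size, "mean": mean, "sd": sd,
                     "cv_pct": cv})
    return pd.DataFrame(rows).set_index("group")


def _contributions(
    members: Sequence[str], pedigree: Mapping[str, tuple[str, str]]
) -> Counter:
    c: Counter = Counter()
    for m in members:
        mother, father = pedigree[m]
        c[mother] += 1
        c[father] += 1
    return c


def build_extreme_pools(
    as_by_genotype: Mapping[str, float] | pd.Series,
    pedigree: Mapping[str, tuple[str, str]],
    pool_size: int,
    tolerant_parent_ids: Iterable[str],
    balance: bool = True,
    rank_tolerance: int = 10,
) -> tuple[PoolAssignment, PoolAssignment]:
    """Select the two extreme bulks of ``pool_size`` individuals each.

    RP takes the lowest-AS (most tolerant) individuals and SP the highest-AS.
    With ``balance=True``, boundary members may be swapped with candidates
    within ``rank_tolerance`` ranks whenever that reduces the absolute
    difference in total tolerant-parent contribution between the pools -- the
    goal of drawing the progeny of each tolerant parent in equal proportion
    stated by the bulking protocol, which gives no algorithm.  Ties in AS are
    broken by genotype id for determinism.
    """
    series = pd.Series(dict(as_by_genotype), dtype=float)
    if len(series) < 2 * pool_size:
        raise ValueError("need at least 2 * pool_size phenotyped genotypes")
    order = series.sort_values(kind="mergesort").index.to_list()
    order = sorted(order, key=lambda g: (series[g], g))
    if series[order[pool_size - 1]] >= series[order[-pool_size]]:
        raise ValueError(
            "extremes not distinguishable: the pools would overlap in AS rank"
        )
    tolerant = set(tolerant_parent_ids)

    rp = order[:pool_size]
    sp = order[-pool_size:]

    def imbalance(rp_members: Sequence[str], sp_members: Sequence[str]) -> int:
        t_rp = sum(
            v for k, v in _contributions(rp_members, pedigree).items() if k in tolerant
        )
        t_sp = sum(
            v for k, v in _contributions(sp_members, pedigree).items() if k in tolerant
        )
        return abs(t_rp - t_sp)

    if balance:
        improved = True
        while improved:
            improved = False
            current = imbalance(rp, sp)
            if current == 0:
                break
            best: tuple[int, str, str, str] | None = None
            # candidate swaps near the RP boundary
            rp_edge = [g for g in rp if order.index(g) >= pool_size - rank_tolerance]
            rp_out = order[pool_size : pool_size + rank_tolerance]
            for a in rp_edge:
                for b in rp_out:
                    if b in sp or b in rp:
                        continue
                    trial = [b if g == a else g for g in rp]
                    val = imbalance(trial, sp)
                    if val < current and (best is None or val < best[0]):
                        best = (val, "RP", a, b)
            # candidate swaps near the SP boundary
            sp_edge = [
                g for g in sp if order.index(g) < len(order) - pool_size + rank_tolerance
            ]
            sp_out = order[-pool_size - rank_tolerance : -pool_size]
            for a in sp_edge:
                for b in sp_out:
                    if b in rp or b in sp:
                        continue
                    trial = [b if g == a else g for g in sp]
                    val = imbalance(rp, trial)
                    if val < current and (best is None or val < best[0]):
                        best = (val, "SP", a, b)
            if best is not None:
                _, which, a, b = best
                if which == "RP":
                    rp = [b if g == a else g for g in rp]
                else:
                    sp = [b if g == a else g for g in sp]
                improved = True

    rp_assign = PoolAssignment("RP", list(rp), dict(_contributions(rp, pedigree)))
    sp_assign = PoolAssignment("SP", list(sp), dict(_contributions(sp, pedigree)))
    return rp_assign, sp_assign


def parent_frequency_report(
    rp: PoolAssignment | Mapping[str, int],
    sp: PoolAssignment | Mapping[str, int],
    tolerant_parent_ids: Sequence[str],
    sensitive_parent_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-parent pool frequency table plus totals and mean +/- sample SD.

    Returns ``(table, summary)``: one row per parent (class, RP count, SP
    count), and per class/pool the total and mean/sample-SD -- the shape used
    to check that the genome dose of the tolerant parents is balanced between
    bulks.
    """
    rp_counts = rp.parent_contribution if isinstance(rp, PoolAssignment) else dict(rp)
    sp_counts = sp.parent_contribution if isinstance(sp, PoolAssignment) else dict(sp)
    rows = []
    for cls, parents in (
        ("tolerant", tolerant_parent_ids),
        ("sensitive", sensitive_parent_ids),
    ):
        for p in parents:
            rows.append(
                {"parent": p, "class": cls, "rp": rp_counts.get(p, 0),
                 "sp": sp_counts.get(p, 0)}
            )
    table = pd.DataFrame(rows)
    summaries = []
    for cls in ("tolerant", "sensitive"):
        sub = table[table["class"] == cls]
        for col in ("rp", "sp"):
            vals = sub[col].to_numpy(dtype=float)
            summaries.append(
                {"class": cls, "pool": col.upper(), "total": int(vals.sum()),
                 "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
            )
    summary = pd.DataFrame(summaries)
    return table, summary


def compare_pools(
    as_values_rp: Sequence[float], as_values_sp: Sequence[float]
) -> dict[str, float]:
    """Student's two-sample t comparison of the bulk phenotypes."""
    a = np.asarray(as_values_rp, dtype=float)
    b = np.asarray(as_values_sp, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each pool needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0  # degenerate: identical constant pools
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "mean_rp": float(a.mean()),
        "mean_sp": float(b.mean()),
        "mean_diff": float(a.mean() - b.mean()),
        "t": float(t),
        "p_value": float(p),
    }
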