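"""Two-bulk BSA genome scan: ED and SNP-index statistics, window smoothing,
threshold and candidate-region calling.

For a biallelic site with alternate-allele read fractions f_RP and f_SP in the
two bulks, the Euclidean distance between the bulks' allele-frequency vectors
is

    ED = sqrt((f_RP - f_SP)^2 + ((1 - f_RP) - (1 - f_SP))^2)
       = sqrt(2) * |f_RP - f_SP|,

so ED and the delta SNP-index carry identical information at biallelic sites;
both are computed and cross-checked.  Per-variant ED is smoothed with a
sliding window (default 1 Mb, step 100 kb), the genome-wide threshold is the
median plus three standard deviations of the windowed statistic, and maximal
runs of super-threshold windows are merged into candidate regions.

Window and region arithmetic is 0-based half-open; variant positions are
1-based as in a VCF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CandidateRegion",
    "euclidean_distance",
    "snp_index",
    "compute_variant_stats",
    "sliding_window_scan",
    "genome_threshold",
    "call_regions",
    "regions_to_frame",
]

logger = logging.getLogger(__name__)

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal run of super-threshold windows (0-based half-open bounds)."""

    chromosome: str
    start: int
    end: int
    peak_stat: float
    n_windows: int

    def contains(self, chromosome: str, position_1based: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start < position_1based <= self.end
        )


def snp_index(depths: tuple[int, int]) -> float:
    """Alternate-allele read fraction alt / (ref + alt) in one bulk."""
    ref, alt = depths
    total = ref + alt
    if total <= 0:
        raise ValueError("SNP-index undefined at zero total depth")
    return alt / total


def euclidean_distance(
    rp_depths: tuple[int, int], sp_depths: tuple[int, int]
) -> float:
    """ED between the two bulks' biallelic allele-frequency vectors."""
    f_rp = snp_index(rp_depths)
    f_sp = snp_index(sp_depths)
    return math.hypot(f_rp - f_sp, (1.0 - f_rp) - (1.0 - f_sp))


def compute_variant_stats(
    variants: pd.DataFrame, min_depth: int = 8
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Vectorized ED / SNP-index per site, with a per-bulk depth filter.

    ``variants`` needs columns chromosome, position, rp_ref, rp_alt, sp_ref,
    sp_alt.  Sites where either bulk is below ``min_depth`` total reads are
    excluded and tallied in the returned counts dict.
    """
    df = variants.copy()
    rp_total = df["rp_ref"] + df["rp_alt"]
    sp_total = df["sp_ref"] + df["sp_alt"]
    keep = (rp_total >= max(min_depth, 1)) & (sp_total >= max(min_depth, 1))
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d sites below min_depth=%d", n_excluded, min_depth)
    df = df.loc[keep].reset_index(drop=True)
    f_rp = df["rp_alt"] / (df["rp_ref"] + df["rp_alt"])
    f_sp = df["sp_alt"] / (df["sp_ref"] + df["sp_alt"])
    df["snp_index_rp"] = f_rp
    df["snp_index_sp"] = f_sp
    df["delta_snp_index"] = (f_rp - f_sp).abs()
    df["ed"] = SQRT2 * df["delta_snp_index"]
    return df, {"input": len(variants), "kept": len(df), "depth_filtered": n_excluded}


def sliding_window_scan(
    stats: pd.DataFrame,
    window_size: int = 1_000_000,
    step: int = 100_000,
    chromosome_lengths: Mapping[str, int] | None = None,
    ed_power: float = 1.0,
    min_window_variants: int = 3,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Windowed ED along each chromosome.

    Windows are [k*step, k*step + window_size) in 0-based half-open
    coordinates; the window statistic is the mean (or median) of ed**ed_power
    over variants falling in the window.  Windows holding fewer than
    ``min_window_variants`` variants are emitted with a missing stat so sparse
    windows cannot masquerade as signal.
    """
    if window_size < step:
        raise ValueError("window_size must be >= step")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    required = {"chromosome", "position", "ed"}
    if not required <= set(stats.columns):
        raise ValueError(f"stats must have columns {sorted(required)}")
    for _, grp in stats.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("variants must be sorted by (chromosome, position)")

    agg = np.mean if statistic == "mean" else np.median
    out = []
    for chrom, grp in stats.groupby("chromosome", sort=True):
        pos0 = grp["position"].to_numpy() - 1  # 0-based
        ed = grp["ed"].to_numpy() ** ed_power
        length = (
            chromosome_lengths[chrom]
            if chromosome_lengths is not None
            else int(pos0.max()) + 1
        )
        n_windows = max(1, math.ceil(max(length - window_size, 0) / step) + 1)
        for k in range(n_windows):
            start = k * step
            end = min(start + window_size, length)
            lo, hi = np.searchsorted(pos0, [start, end])
            n = hi - lo
            stat = agg(ed[lo:hi]) if n >= max(min_window_variants, 1) else np.nan
            out.append(
                {"chromosome": chrom, "start": start, "end": end,
                 "n_variants": int(n), "stat": stat}
            )
    return pd.DataFrame(out)


def genome_threshold(window_stats: pd.DataFrame | Sequence[float]) -> float:
    """Genome-wide call threshold: median + 3 * sample SD of window stats."""
    vals = (
        window_stats["stat"].to_numpy()
        if isinstance(window_stats, pd.DataFrame)
        else np.asarray(window_stats, dtype=float)
    )
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise ValueError("need at least two non-missing windows")
    return float(np.median(vals) + 3.0 * np.std(vals, ddof=1))


def call_regions(
    window_stats: pd.DataFrame, threshold: float, merge_gap: int = 0
) -> list[CandidateRegion]:
    """Merge overlapping/adjacent super-threshold windows into regions.

    Windows with stat >= threshold are grouped per chromosome; two runs are
    merged when separated by at most ``merge_gap`` bp.  Region bounds are the
    union of member windows and ``peak_stat`` the maximum window statistic.
    """
    regions: list[CandidateRegion] = []
    hits = window_stats.dropna(subset=["stat"])
    hits = hits[hits["stat"] >= threshold]
    for chrom, grp in hits.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        cur_start = cur_end = None
        cur_peak = -np.inf
        cur_n = 0
        for row in grp.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
                cur_peak, cur_n = row.stat, 1
            elif row.start <= cur_end + merge_gap:
                cur_end = max(cur_end, row.end)
                cur_peak = max(cur_peak, row.stat)
                cur_n += 1
            else:
                regions.append(
                    CandidateRegion(chrom, int(cur_start), int(cur_end),
                                    float(cur_peak), cur_n)
                )
                cur_start, cur_end = row.start, row.end
                cur_peak, cur_n = row.stat, 1
        if cur_start is not None:
            regions.append(
                CandidateRegion(chrom, int(cur_start), int(cur_end),
                                float(cur_peak), cur_n)
            )
    return regions


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chromosome": r.chromosome, "start": r.start, "end": r.end,
             "peak_stat": r.peak_stat, "n_windows": r.n_windows}
            for r in regions
        ],
        columns=["chromosome", "start", "end", "peak_stat", "n_windows"],
    )
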