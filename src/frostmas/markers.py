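"""SNP marker selection, parental screening, binarization and validation.

Candidate marker sites are variants inside a called region whose delta
SNP-index between the bulks exceeds a threshold (strictly greater than 0.25
by default), thinned to a requested count by greedy farthest-point selection
so the panel covers the region as uniformly as possible.  Parents are then
screened for class-diagnostic polymorphism: a genotype call observed only in
frost-tolerant parents codes '1', one observed only in sensitive parents --
or shared by both classes -- codes '0'.  Markers are validated against the
average injury score by Spearman rank correlation (pass: p < alpha and |rho| >
rho_min in every required environment) and by the goodness of fit, the
percentage of pooled individuals whose binary code matches their pool class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scan import CandidateRegion

__all__ = [
    "MarkerSite",
    "MarkerValidation",
    "ScreenResult",
    "select_target_sites",
    "extract_flanks",
    "screen_parent_polymorphism",
    "binarize_genotypes",
    "spearman_validate",
    "goodness_of_fit",
]

MISSING = {None, "", ".", "./.", "-"}


@dataclass(frozen=True)
class MarkerSite:
    name: str
    chromosome: str
    position: int
    delta_snp_index: float
    flank_sequence: str | None = None


@dataclass
class MarkerValidation:
    marker_name: str
    rho_by_environment: dict[str, float]
    p_by_environment: dict[str, float]
    goodness_of_fit_pct: float | None = None
    passed: bool = False
    reason: str = ""
    sign_consistent: bool | None = None  # tolerant code expected to lower injury


@dataclass
class ScreenResult:
    """Outcome of the parental polymorphism screen."""

    coding: dict[str, dict[str, int]]  # marker -> genotype string -> 0/1
    rejected: dict[str, str]  # marker -> reason
    summary: dict[str, float] = field(default_factory=dict)


def _farthest_point_subset(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices of k positions spread as uniformly as possible (greedy).

    Seeds with the two extremes, then repeatedly adds the point maximising the
    minimum distance to the chosen set; for points on a line this keeps the
    largest gap at most ~2x the ideal spacing.
    """
    n = positions.size
    if k >= n:
        return np.arange(n)
    chosen = [int(np.argmin(positions)), int(np.argmax(positions))]
    mindist = np.minimum(
        np.abs(positions - positions[chosen[0]]),
        np.abs(positions - positions[chosen[1]]),
    )
    while len(chosen) < k:
        nxt = int(np.argmax(mindist))
        chosen.append(nxt)
        mindist = np.minimum(mindist, np.abs(positions - positions[nxt]))
    return np.sort(np.array(chosen[:k]))


def select_target_sites(
    variant_stats: pd.DataFrame,
    regions: Sequence[CandidateRegion],
    n_per_region: int = 40,
    delta_threshold: float = 0.25,
) -> list[MarkerSite]:
    """Pick marker target sites inside each candidate region.

    Only variants with delta SNP-index strictly above ``delta_threshold``
    qualify ("exceeded 0.25"); within each region, ``n_per_region`` sites are
    chosen by farthest-point thinning.  If fewer qualify, all are returned and
    the shortfall is reported via a warning.  Names follow the chrNNVk
    convention with k assigned by ascending position within each chromosome.
    """
    if len(regions) == 0:
        raise ValueError("no candidate regions supplied")
    picked: list[tuple[str, int, float]] = []
    for region in regions:
        inside = variant_stats[
            (variant_stats["chromosome"] == region.chromosome)
            & (variant_stats["position"] - 1 >= region.start)
            & (variant_stats["position"] - 1 < region.end)
            & (variant_stats["delta_snp_index"] > delta_threshold)
        ].sort_values("position")
        if len(inside) < n_per_region:
            warnings.warn(
                f"{region.chromosome}:{region.start}-{region.end}: only "
                f"{len(inside)} of {n_per_region} requested sites qualify",
                stacklevel=2,
            )
        pos = inside["position"].to_numpy()
        idx = _farthest_point_subset(pos, n_per_region)
        for _, row in inside.iloc[idx].iterrows():
            picked.append(
                (region.chromosome, int(row["position"]), float(row["delta_snp_index"]))
            )
    sites: list[MarkerSite] = []
    frame = pd.DataFrame(picked, columns=["chromosome", "position", "delta"])
    frame = frame.drop_duplicates(["chromosome", "position"])
    for chrom, grp in frame.groupby("chromosome", sort=True):
        grp = grp.sort_values("position").reset_index(drop=True)
        for k, row in grp.iterrows():
            sites.append(
                MarkerSite(
                    name=f"{chrom}V{k + 1}",
                    chromosome=chrom,
                    position=int(row["position"]),
                    delta_snp_index=float(row["delta"]),
                )
            )
    return sites


def extract_flanks(site: MarkerSite, reference, flank: int = 75) -> str:
    """Uppercase sequence of up to 2*flank+1 bp centred on the site.

    ``reference`` is a pyfaidx.Fasta (or any mapping of chromosome to
    sequence).  Truncated with a warning when the site sits within ``flank``
    of a contig end.
    """
    try:
        seq = reference[site.chromosome]
    except KeyError as exc:
        raise ValueError(f"chromosome {site.chromosome!r} absent from reference") from exc
    contig = str(seq[:])
    lo = max(1, site.position - flank)
    hi = min(len(contig), site.position + flank)
    if lo > site.position - flank or hi < site.position + flank:
        warnings.warn(
            f"{site.name}: flank truncated to [{lo}, {hi}] at contig edge",
            stacklevel=2,
        )
    return contig[lo - 1 : hi].upper()


def _is_missing(g) -> bool:
    return g is None or (isinstance(g, float) and np.isnan(g)) or g in MISSING


def screen_parent_polymorphism(
    parent_genotypes: pd.DataFrame,
    tolerant_ids: Iterable[str],
    sensitive_ids: Iterable[str],
) -> ScreenResult:
    """Derive a 0/1 coding map per marker from the 16 parents' genotype calls.

    ``parent_genotypes`` is tidy: columns marker, individual_id, genotype.  A
    genotype string codes 1 when observed only among frost-tolerant parents,
    0 when only among sensitive parents or shared by both classes.  A marker
    is accepted (polymorphic) when at least one genotype codes 1 and one codes
    0; markers with no genotyped parent are rejected as "not detected".  Both
    the heterozygous and homozygous-alternate forms may code 1.  The summary
    reports detection and polymorphism rates over the input panel.
    """
    tolerant = set(tolerant_ids)
    sensitive = set(sensitive_ids)
    if not tolerant or not sensitive:
        raise ValueError("need at least one parent id per class")
    coding: dict[str, dict[str, int]] = {}
    rejected: dict[str, str] = {}
    n_markers = parent_genotypes["marker"].nunique()
    for marker, grp in parent_genotypes.groupby("marker", sort=True):
        seen_tol: set[str] = set()
        seen_sen: set[str] = set()
        for row in grp.itertuples(index=False):
            if _is_missing(row.genotype):
                continue
            if row.individual_id in tolerant:
                seen_tol.add(row.genotype)
            elif row.individual_id in sensitive:
                seen_sen.add(row.genotype)
        if not seen_tol and not seen_sen:
            rejected[marker] = "not detected"
            continue
        cmap = {g: 1 for g in seen_tol - seen_sen}
        cmap.update({g: 0 for g in seen_sen})
        if 1 not in cmap.values() or 0 not in cmap.values():
            rejected[marker] = "monomorphic"
            continue
        coding[marker] = cmap
    n_detected = n_markers - sum(1 for r in rejected.values() if r == "not detected")
    summary = {
        "n_markers": n_markers,
        "n_detected": n_detected,
        "n_polymorphic": len(coding),
        "detection_rate_pct": 100.0 * n_detected / n_markers if n_markers else np.nan,
        "polymorphism_rate_pct": (
            100.0 * len(coding) / n_detected if n_detected else np.nan
        ),
    }
    return ScreenResult(coding=coding, rejected=rejected, summary=summary)


def binarize_genotypes(
    genotypes: pd.DataFrame, coding: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Apply per-marker coding maps to a tidy genotype table.

    Returns columns marker, individual_id, code; genotype strings absent from
    a marker's coding map (or missing calls) yield a missing code (NaN).
    """
    def code_of(marker: str, genotype) -> float:
        if _is_missing(genotype):
            return np.nan
        return float(coding.get(marker, {}).get(genotype, np.nan))

    out = genotypes.copy()
    out["code"] = [
        code_of(m, g) for m, g in zip(out["marker"], out["genotype"])
    ]
    return out[["marker", "individual_id", "code"]]


def _spearman(codes: np.ndarray, phenos: np.ndarray, exact_permutation: bool):
    if exact_permutation:
        res = stats.permutation_test(
            (codes,),
            lambda c: stats.spearmanr(c, phenos).statistic,
            permutation_type="pairings",
            n_resamples=10_000,
            random_state=0,
        )
        rho = float(stats.spearmanr(codes, phenos).statistic)
        return rho, float(res.pvalue)
    res = stats.spearmanr(codes, phenos)
    return float(res.statistic), float(res.pvalue)


def spearman_validate(
    codes: Mapping[str, float] | pd.Series,
    as_by_environment: pd.DataFrame,
    marker_name: str = "",
    alpha: float = 0.05,
    rho_min: float = 0.3,
    require_all_environments: bool = True,
    exact_permutation: bool = False,
) -> MarkerValidation:
    """Spearman validation of one marker's binary codes against injury scores.

    ``as_by_environment`` is a genotype x environment AS table.  Rank ties are
    handled by midranks and p-values come from the t approximation (an exact
    permutation option exists for very small n).  The marker passes when
    p < alpha and |rho| > rho_min in every supplied environment (or any, with
    ``require_all_environments=False``).  The expected sign is negative --
    code 1 marks the tolerant allele, which lowers injury -- and is reported
    separately rather than enforced.
    """
    codes = pd.Series(dict(codes), dtype=float).dropna()
    common = codes.index.intersection(as_by_environment.index)
    if len(common) < 5:
        raise ValueError("need >= 5 individuals with both code and phenotype")
    codes = codes.loc[common]
    rho_by_env: dict[str, float] = {}
    p_by_env: dict[str, float] = {}
    if codes.nunique() < 2:
        return MarkerValidation(
            marker_name, {}, {}, passed=False, reason="zero variance in codes"
        )
    for env in as_by_environment.columns:
        phenos = as_by_environment.loc[common, env].to_numpy(dtype=float)
        if np.all(phenos == phenos[0]):
            return MarkerValidation(
                marker_name, rho_by_env, p_by_env, passed=False,
                reason=f"zero variance in phenotypes ({env})",
            )
        rho, p = _spearman(codes.to_numpy(), phenos, exact_permutation)
        rho_by_env[env] = rho
        p_by_env[env] = p
    ok = [
        p_by_env[e] < alpha and abs(rho_by_env[e]) > rho_min
        for e in rho_by_env
    ]
    passed = all(ok) if require_all_environments else any(ok)
    sign_consistent = all(r < 0 for r in rho_by_env.values())
    return MarkerValidation(
        marker_name, rho_by_env, p_by_env, passed=passed,
        reason="" if passed else "correlation criteria not met",
        sign_consistent=sign_consistent,
    )


def goodness_of_fit(
    pool_of: Mapping[str, str], codes: Mapping[str, float | int | None]
) -> float:
    """Percent of pooled individuals whose binary code matches their pool.

    A resistant-pool (RP) member matches when coded 1, a sensitive-pool (SP)
    member when coded 0; individuals with a missing code are excluded from
    both numerator and denominator.
    """
    matches = 0
    genotyped = 0
    for ind, pool in pool_of.items():
        if pool not in ("RP", "SP"):
            raise ValueError(f"unknown pool {pool!r} for {ind!r}")
        code = codes.get(ind)
        if code is None or (isinstance(code, float) and np.isnan(code)):
            continue
        genotyped += 1
        if (pool == "RP" and code == 1) or (pool == "SP" and code == 0):
            matches += 1
    if genotyped == 0:
        raise ValueError("no genotyped pool members")
    return 100.0 * matches / genotyped
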