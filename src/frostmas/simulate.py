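"""Synthetic tetraploid half-diallel population generator.

This module emulates the study design behind the frost-tolerance mapping
pipeline: 16 tetraploid potato parents (8 frost-tolerant interspecific lines,
8 frost-sensitive cultivars) crossed in a 16 x 16 half-diallel, a subset of
viable crosses yielding an F1 population, visual injury scores on a 0-6 scale
in two field environments, and pooled whole-genome sequencing of two extreme
bulks at ~23x depth.  Ground truth (causal loci, founder haplotypes, every
progeny dosage) is retained so every downstream stage can be tested without
any external data.

Inheritance is tetrasomic: a gamete receives 2 of the parent's 4 homologous
chromosomes drawn without replacement (no double reduction), so the number of
alternate-allele copies transmitted is hypergeometric(4, dosage, 2).  Loci
segregate independently, except inside the linkage block around each causal
locus, where founder haplotypes are explicit and one 2-of-4 homolog draw per
block and meiosis co-transmits every member variant -- the no-recombination
limit for co-located sites, which is what lets a causal *region*, not just a
point, carry a bulk allele-frequency signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHROMOSOME_LENGTHS",
    "CausalLocus",
    "Founder",
    "Progeny",
    "Population",
    "SimulationConfig",
    "default_causal_loci",
    "default_progeny_counts",
    "enumerate_half_diallel",
    "simulate_gamete",
    "simulate_population",
    "simulate_injury_scores",
    "simulate_phenotypes",
    "simulate_bulk_depths",
    "dosage_to_genotype_string",
]

#: Approximate chromosome lengths (bp) of the DM potato reference assembly,
#: used as the coordinate system of the synthetic genome.
CHROMOSOME_LENGTHS: dict[str, int] = {
    "chr01": 88_600_000,
    "chr02": 46_100_000,
    "chr03": 60_200_000,
    "chr04": 69_300_000,
    "chr05": 55_600_000,
    "chr06": 59_100_000,
    "chr07": 57_600_000,
    "chr08": 59_200_000,
    "chr09": 67_600_000,
    "chr10": 61_000_000,
    "chr11": 46_800_000,
    "chr12": 59_700_000,
}

_BASES = np.array(["A", "C", "G", "T"])

# P(gamete alt copies = k | parent dosage d): hypergeometric(4, d, 2),
# enumerated exactly from the C(4,2)=6 equally likely chromosome pairs.
_GAMETE_PMF = np.array(
    [
        [
            math.comb(d, k) * math.comb(4 - d, 2 - k) / math.comb(4, 2)
            if 2 - k <= 4 - d and k <= d
            else 0.0
            for k in range(3)
        ]
        for d in range(5)
    ]
)
_GAMETE_CDF = np.cumsum(_GAMETE_PMF, axis=1)


@dataclass(frozen=True)
class CausalLocus:
    """A frost-tolerance locus with known truth.

    ``effect`` is the reduction in expected injury score (0-6 units) for
    carriers of the tolerant (alternate) allele; ``tolerant_allele_freq_by_class``
    gives the alternate-allele frequency among tolerant- and sensitive-class
    founders.  ``n_linked_variants`` flanking variants spread over
    ``linked_span`` bp co-segregate with the locus (one homolog draw per
    block and meiosis -- the no-recombination limit); a ``tag_fraction`` of
    them ride the same founder homologs as the causal allele (haplotype
    tagging, hence class-diagnostic), while the rest carry background
    variation with class-independent allele frequencies.
    """

    chromosome: str
    position: int
    effect: float
    tolerant_allele_freq_by_class: tuple[float, float]
    linked_span: int = 6_000_000
    n_linked_variants: int = 60
    tag_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("causal effect must be >= 0")
        length = CHROMOSOME_LENGTHS.get(self.chromosome)
        if length is not None and not (1 <= self.position <= length):
            raise ValueError(
                f"position {self.position} outside {self.chromosome} (length {length})"
            )
        for f in self.tolerant_allele_freq_by_class:
            if not 0.0 <= f <= 1.0:
                raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class Founder:
    id: str
    class_label: str  # "tolerant" | "sensitive"
    genotypes: np.ndarray  # dosage 0-4 per variant, aligned with Population.variants


@dataclass(frozen=True)
class Progeny:
    id: str
    mother_id: str
    father_id: str
    genotypes: np.ndarray  # dosage 0-4 per variant


def default_causal_loci() -> tuple[CausalLocus, ...]:
    """Three causal regions on chromosomes II, V and IX.

    Effects of 1.2 injury units per carried locus, a tolerant-class allele
    frequency of 0.5 (simplex-triplex carriers) and noise SD 1.0 give an F1 injury
    distribution with mean ~2.2-2.7 and CV near 50% -- the regime of a
    segregating quantitative frost-tolerance trait scored under natural field
    frost.
    """
    freq = (0.5, 0.0)
    return (
        CausalLocus("chr02", 41_000_000, 1.2, freq),
        CausalLocus("chr05", 33_500_000, 1.2, freq),
        CausalLocus("chr09", 40_500_000, 1.2, freq),
    )


def default_progeny_counts(total: int = 406, n_crosses: int = 23) -> tuple[int, ...]:
    """Split ``total`` progeny over ``n_crosses`` crosses as evenly as possible."""
    base, extra = divmod(total, n_crosses)
    return tuple(base + 1 if i < extra else base for i in range(n_crosses))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic population.

    Defaults mirror the mapping study: 8 tolerant + 8 sensitive parents, 23
    viable crosses out of the 136 half-diallel combinations, 406 F1 progeny,
    five replicate plants per genotype per environment, and two-bulk pooled
    sequencing at a mean depth of 23.47x.
    """

    n_parents_per_class: int = 8
    n_viable_crosses: int = 23
    progeny_per_cross: int | tuple[int, ...] = default_progeny_counts()
    n_neutral_variants: int = 12_000
    mean_depth: float = 23.47
    depth_dispersion: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    n_replicates: int = 5
    environment_severity: Mapping[str, float] = field(
        default_factory=lambda: {"EnvI": 4.8, "EnvIV": 5.3}
    )
    causal_loci: tuple[CausalLocus, ...] = field(default_factory=default_causal_loci)
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(CHROMOSOME_LENGTHS)
    )
    additive_effects: bool = True  # False: carrier (dosage >= 1) coding

    def __post_init__(self) -> None:
        for name in ("n_parents_per_class", "n_viable_crosses", "n_neutral_variants",
                     "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if isinstance(self.progeny_per_cross, int):
            if self.progeny_per_cross <= 0:
                raise ValueError("progeny_per_cross must be positive")
        elif len(self.progeny_per_cross) != self.n_viable_crosses:
            raise ValueError(
                "progeny_per_cross sequence must have one entry per viable cross"
            )

    def progeny_counts(self) -> tuple[int, ...]:
        if isinstance(self.progeny_per_cross, int):
            return (self.progeny_per_cross,) * self.n_viable_crosses
        return tuple(self.progeny_per_cross)


@dataclass
class Population:
    """A simulated half-diallel population with full ground truth.

    ``variants`` has one row per site (chromosome, position, ref, alt,
    is_causal, region) sorted by genomic coordinate; the dosage matrices are
    aligned column-wise with it.
    """

    founders: list[Founder]
    progeny: list[Progeny]
    causal_loci: tuple[CausalLocus, ...]
    variants: pd.DataFrame
    founder_dosage: np.ndarray  # (n_founders, n_variants)
    progeny_dosage: np.ndarray  # (n_progeny, n_variants)
    causal_index: np.ndarray  # column index of each causal locus
    config: SimulationConfig

    @property
    def founder_ids(self) -> list[str]:
        return [f.id for f in self.founders]

    @property
    def progeny_ids(self) -> list[str]:
        return [p.id for p in self.progeny]

    @property
    def tolerant_parent_ids(self) -> set[str]:
        return {f.id for f in self.founders if f.class_label == "tolerant"}

    @property
    def pedigree(self) -> dict[str, tuple[str, str]]:
        return {p.id: (p.mother_id, p.father_id) for p in self.progeny}

    def dosage_of(self, individual_id: str) -> np.ndarray:
        for f in self.founders:
            if f.id == individual_id:
                return f.genotypes
        for p in self.progeny:
            if p.id == individual_id:
                return p.genotypes
        raise KeyError(individual_id)


def enumerate_half_diallel(
    parent_ids: Sequence[str], include_selfs: bool = False
) -> list[tuple[str, str]]:
    """All unordered parent pairs of a half-diallel mating design.

    With selfs, n parents give n(n+1)/2 crosses; without, n(n-1)/2.
    """
    ids = list(parent_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("parent ids must be unique")
    pairs = list(itertools.combinations(ids, 2))
    if include_selfs:
        pairs = [(p, p) for p in ids] + pairs
        pairs.sort(key=lambda pr: (ids.index(pr[0]), ids.index(pr[1])))
    return pairs


def simulate_gamete(parent_dosage: int, rng: np.random.Generator) -> int:
    """Alternate-allele copies in one gamete from a tetraploid parent.

    Two of the parent's four homologues are drawn without replacement, so the
    result is hypergeometric(4, parent_dosage, 2).
    """
    if not 0 <= parent_dosage <= 4:
        raise ValueError("parent dosage must be in [0, 4]")
    return int(np.searchsorted(_GAMETE_CDF[parent_dosage], rng.random(), side="right"))


def _gamete_matrix(
    dosages: np.ndarray, n_gametes: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_gametes, n_loci) alt-copy counts; inverse-CDF sampling per dosage."""
    cdf = _GAMETE_CDF[dosages]  # (n_loci, 3)
    u = rng.random((n_gametes, dosages.size))
    return (u > cdf[None, :, 0]).astype(np.int8) + (u > cdf[None, :, 1])


def _unique_positions(
    rng: np.random.Generator, n: int, lengths: Mapping[str, int]
) -> tuple[np.ndarray, np.ndarray]:
    chroms = np.array(list(lengths))
    sizes = np.array([lengths[c] for c in chroms], dtype=float)
    taken: set[tuple[int, int]] = set()
    chrom_idx = np.empty(n, dtype=int)
    pos = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        k = n - filled
        ci = rng.choice(chroms.size, size=k, p=sizes / sizes.sum())
        pp = rng.integers(1, sizes[ci].astype(np.int64) + 1)
        for c, p in zip(ci, pp):
            key = (int(c), int(p))
            if key in taken:
                continue
            taken.add(key)
            chrom_idx[filled] = c
            pos[filled] = p
            filled += 1
    return chroms[chrom_idx], pos


def simulate_population(config: SimulationConfig) -> Population:
    """Simulate founders, viable crosses and F1 progeny with known causal loci.

    Tolerant-class founders carry the tolerant (alternate) allele at each
    causal locus at the class frequency; neutral variants have a single,
    class-independent frequency drawn uniform on [0.05, 0.95].  Viable crosses
    are sampled uniformly among half-diallel pairs with at least one tolerant
    parent (cross failure in the study is attributed to incompatibility, which
    is not modelled mechanistically).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    npc = config.n_parents_per_class
    tolerant_ids = [f"FT{i + 1:02d}" for i in range(npc)]
    sensitive_ids = [f"CV{i + 1:02d}" for i in range(npc)]
    all_ids = tolerant_ids + sensitive_ids
    n_founders = len(all_ids)

    # --- variant scaffold -------------------------------------------------
    lengths = config.chromosome_lengths
    chroms_neutral, pos_neutral = _unique_positions(
        rng, config.n_neutral_variants, lengths
    )
    rows: list[dict] = []
    for li, locus in enumerate(config.causal_loci):
        length = lengths.get(locus.chromosome)
        if length is None:
            raise ValueError(f"unknown chromosome {locus.chromosome!r}")
        half = locus.linked_span // 2
        lo, hi = max(1, locus.position - half), min(length, locus.position + half)
        linked = rng.integers(lo, hi + 1, size=max(0, locus.n_linked_variants - 1))
        rows.append(
            {"chromosome": locus.chromosome, "position": locus.position,
             "is_causal": True, "region": f"{locus.chromosome}:{locus.position}",
             "cluster": li}
        )
        rows.extend(
            {"chromosome": locus.chromosome, "position": int(p), "is_causal": False,
             "region": f"{locus.chromosome}:{locus.position}", "cluster": li}
            for p in linked
        )
    # Causal-cluster rows first so a coordinate collision never drops one.
    # A neutral variant landing inside a causal linkage block joins the block:
    # with no recombination, everything co-located with the locus co-segregates.
    for c, p in zip(chroms_neutral, pos_neutral):
        cl = -1
        region = ""
        for li, locus in enumerate(config.causal_loci):
            if (
                c == locus.chromosome
                and abs(int(p) - locus.position) <= locus.linked_span // 2
            ):
                cl = li
                region = f"{locus.chromosome}:{locus.position}"
                break
        rows.append(
            {"chromosome": c, "position": int(p), "is_causal": False,
             "region": region, "cluster": cl}
        )
    variants = pd.DataFrame(rows)
    variants = variants.drop_duplicates(subset=["chromosome", "position"])
    variants = variants.sort_values(["chromosome", "position"]).reset_index(drop=True)
    n_variants = len(variants)

    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    variants["ref"] = _BASES[ref_idx]
    variants["alt"] = _BASES[alt_idx]
    variants = variants[
        ["chromosome", "position", "ref", "alt", "is_causal", "region", "cluster"]
    ]

    # --- founder genotypes ------------------------------------------------
    cluster = variants["cluster"].to_numpy()
    is_causal = variants["is_causal"].to_numpy()
    founder_dosage = np.zeros((n_founders, n_variants), dtype=np.int8)

    neutral_mask = cluster < 0
    freqs = rng.uniform(0.05, 0.95, size=int(neutral_mask.sum()))
    founder_dosage[:, neutral_mask] = rng.binomial(
        4, freqs[None, :], size=(n_founders, freqs.size)
    )
    # Each linkage block is modelled at the homolog level: a founder's block
    # is four haplotypes over the member variants.  Haplotype-tagging variants
    # sit on exactly the homologs that carry the causal allele; background
    # variants are scattered over homologs at a class-independent frequency.
    # Gametes later draw 2 of the 4 homologs per block and meiosis, so every
    # member variant co-segregates with the causal locus.
    causal_index = np.full(len(config.causal_loci), -1, dtype=int)
    combos = np.array(list(itertools.combinations(range(4), 2)))
    homologs: list[np.ndarray] = []  # per cluster: (n_founders, 4, m)
    member_cols: list[np.ndarray] = []
    for li, locus in enumerate(config.causal_loci):
        members = np.flatnonzero(cluster == li)
        member_cols.append(members)
        m = members.size
        causal_local = int(np.flatnonzero(is_causal[members])[0])
        causal_index[li] = int(members[causal_local])
        tagging = rng.random(m) < locus.tag_fraction
        tagging[causal_local] = True
        bg_cols = np.flatnonzero(~tagging)
        q_bg = rng.uniform(0.05, 0.95, size=m)

        f_tol, f_sen = locus.tolerant_allele_freq_by_class
        # Tolerant lines were selected for the trait and share the introgressed
        # haplotype: each carries the tolerant allele in simplex-triplex dosage
        # (1 + Binomial(2, p) with 1 + 2p = 4 * f_tol), so the locus always
        # segregates in the tolerant class.  Sensitive cultivars carry it only
        # at the background frequency.
        if f_tol >= 0.25:
            p_extra = min((4.0 * f_tol - 1.0) / 2.0, 1.0)
            tol_dos = 1 + rng.binomial(2, p_extra, size=npc)
        else:
            tol_dos = rng.binomial(4, f_tol, size=npc)
        sen_dos = rng.binomial(4, f_sen, size=n_founders - npc)
        dosages = np.concatenate([tol_dos, sen_dos])

        block = np.zeros((n_founders, 4, m), dtype=np.int8)
        for i in range(n_founders):
            hi = np.zeros((4, m), dtype=np.int8)
            if bg_cols.size:
                hi[:, bg_cols] = rng.random((4, bg_cols.size)) < q_bg[bg_cols]
            carrier_homs = rng.permutation(4)[: dosages[i]]
            hi[np.ix_(carrier_homs, np.flatnonzero(tagging))] = 1
            block[i] = hi
        homologs.append(block)
        founder_dosage[:, members] = block.sum(axis=1)

    founders = [
        Founder(pid, "tolerant" if i < npc else "sensitive", founder_dosage[i])
        for i, pid in enumerate(all_ids)
    ]

    # --- viable crosses and progeny ---------------------------------------
    candidates = [
        pair
        for pair in enumerate_half_diallel(all_ids, include_selfs=True)
        if pair[0] in tolerant_ids or pair[1] in tolerant_ids
    ]
    if config.n_viable_crosses > len(candidates):
        raise ValueError(
            f"n_viable_crosses={config.n_viable_crosses} exceeds the "
            f"{len(candidates)} candidate pairs"
        )
    chosen = rng.choice(len(candidates), size=config.n_viable_crosses, replace=False)
    crosses = [candidates[i] for i in sorted(chosen)]

    parent_index = {pid: i for i, pid in enumerate(all_ids)}
    counts = config.progeny_counts()
    neutral_cols = np.flatnonzero(neutral_mask)

    progeny: list[Progeny] = []
    blocks: list[np.ndarray] = []
    for ci, ((mother, father), k) in enumerate(zip(crosses, counts), start=1):
        mi, fi = parent_index[mother], parent_index[father]
        dosage = np.zeros((k, n_variants), dtype=np.int8)
        # unlinked loci: independent hypergeometric gametes
        gm = _gamete_matrix(founder_dosage[mi, neutral_cols], k, rng)
        gf = _gamete_matrix(founder_dosage[fi, neutral_cols], k, rng)
        dosage[:, neutral_cols] = gm + gf
        # linkage blocks: one 2-of-4 homolog draw per block, parent and meiosis
        for li, members in enumerate(member_cols):
            gam_m = homologs[li][mi][combos[rng.integers(0, 6, size=k)]].sum(axis=1)
            gam_f = homologs[li][fi][combos[rng.integers(0, 6, size=k)]].sum(axis=1)
            dosage[:, members] = gam_m + gam_f
        blocks.append(dosage)
        progeny.extend(
            Progeny(f"X{ci:02d}-{j + 1:02d}", mother, father, dosage[j])
            for j in range(k)
        )
    progeny_dosage = np.vstack(blocks) if blocks else np.empty((0, n_variants), np.int8)

    return Population(
        founders=founders,
        progeny=progeny,
        causal_loci=tuple(config.causal_loci),
        variants=variants,
        founder_dosage=founder_dosage,
        progeny_dosage=progeny_dosage,
        causal_index=causal_index,
        config=config,
    )


def simulate_injury_scores(
    causal_dosages: np.ndarray,
    causal_loci: Sequence[CausalLocus],
    environment_severity: float,
    noise_sd: float,
    n_replicates: int,
    rng: np.random.Generator,
    additive: bool = False,
) -> np.ndarray:
    """Per-replicate integer injury scores (0-6) for a set of individuals.

    The latent score is ``severity - sum(effect * carrier)`` plus Gaussian
    noise per replicate plant, rounded to the nearest integer and clamped to
    the 0-6 visual scale.  Carrier status is dosage >= 1 (dominant-style
    coding, matching the 1/0 marker convention); with ``additive=True`` the
    contribution is ``effect * dosage / 2`` instead.
    """
    if not 0.0 <= environment_severity <= 10.0:
        raise ValueError("environment_severity outside the sane range [0, 10]")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    dosages = np.atleast_2d(np.asarray(causal_dosages))
    effects = np.array([l.effect for l in causal_loci], dtype=float)
    if dosages.shape[1] != effects.size:
        raise ValueError("one dosage column per causal locus required")
    if additive:
        genetic = dosages / 2.0 @ effects
    else:
        genetic = (dosages >= 1) @ effects
    latent = environment_severity - genetic
    noisy = latent[:, None] + rng.normal(0.0, noise_sd, size=(latent.size, n_replicates))
    return np.clip(np.rint(noisy), 0, 6).astype(np.int8)


def simulate_phenotypes(
    population: Population, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Injury-score table for all founders and progeny in every environment.

    Returns a tidy frame (genotype_id, environment_id, replicate, score); the
    caller usually feeds it straight into :mod:`frostmas.phenotype`.
    """
    cfg = population.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    ids = population.founder_ids + population.progeny_ids
    dosages = np.vstack(
        [population.founder_dosage, population.progeny_dosage]
    )[:, population.causal_index]
    frames = []
    for env, severity in cfg.environment_severity.items():
        scores = simulate_injury_scores(
            dosages, population.causal_loci, severity, cfg.noise_sd,
            cfg.n_replicates, rng, additive=cfg.additive_effects,
        )
        frames.append(
            pd.DataFrame(
                {
                    "genotype_id": np.repeat(ids, cfg.n_replicates),
                    "environment_id": env,
                    "replicate": np.tile(
                        np.arange(1, cfg.n_replicates + 1), len(ids)
                    ),
                    "score": scores.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_bulk_depths(
    member_dosages: np.ndarray,
    mean_depth: float,
    rng: np.random.Generator,
    dispersion: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-sequencing read depths (ref, alt) per variant for one bulk.

    Total depth per site is Poisson(``mean_depth``) (negative-binomial with
    variance mean*(1+dispersion) when ``dispersion`` > 0); alternate reads are
    binomial with the pool allele frequency mean(dosage)/4 across members.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    members = np.atleast_2d(np.asarray(member_dosages))
    if members.shape[0] == 0:
        raise ValueError("pool must be non-empty")
    freq = members.mean(axis=0) / 4.0
    n_sites = members.shape[1]
    if dispersion > 0:
        total = rng.negative_binomial(
            mean_depth / dispersion, 1.0 / (1.0 + dispersion), size=n_sites
        )
    else:
        total = rng.poisson(mean_depth, size=n_sites)
    alt = rng.binomial(total, freq)
    return total - alt, alt


def dosage_to_genotype_string(dosage: int, ref: str, alt: str) -> str:
    """Collapse a tetraploid dosage to the diploid-style call of capture GBS.

    Target-capture genotyping reports presence patterns, not dosage: 0 ->
    homozygous reference, 4 -> homozygous alternate, anything between ->
    heterozygous.
    """
    if not 0 <= dosage <= 4:
        raise ValueError("dosage must be in [0, 4]")
    if dosage == 0:
        return f"{ref}/{ref}"
    if dosage == 4:
        return f"{alt}/{alt}"
    return f"{ref}/{alt}"
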