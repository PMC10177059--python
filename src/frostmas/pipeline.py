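"""End-to-end pipeline: phenotyping -> pooling -> scan -> markers -> MAS.

The pipeline runs either on a synthetic population (the default; the
generator supplies ground truth and pooled depths) or on user files (two-bulk
VCF plus phenotype/genotype TSVs).  Every stage writes its outputs and a run
log (version, seed, config hash, per-stage record counts) to the output
directory; a rerun with the same config and inputs is bit-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as fio
from . import markers as mk
from . import mas
from . import phenotype as ph
from . import scan as sc
from . import simulate as sim

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """One structured config for the whole pipeline; CLI flags override it."""

    out_dir: str = "frostmas_out"
    # inputs (None -> simulate)
    vcf: str | None = None
    phenotypes: str | None = None
    parent_genotypes: str | None = None
    progeny_genotypes: str | None = None
    tolerant_parent_ids: tuple[str, ...] = ()
    rp_sample: str = "RP"
    sp_sample: str = "SP"
    # scan parameters
    window: int = 1_000_000
    step: int = 100_000
    min_depth: int = 8
    ed_power: float = 1.0
    merge_gap: int = 0
    min_window_variants: int = 3
    # marker parameters
    delta_threshold: float = 0.25
    n_per_region: int = 40
    alpha: float = 0.05
    rho_min: float = 0.3
    # pooling / MAS
    pool_size: int = 30
    rule_markers: tuple[str, ...] = tuple(sorted(mas.DEFAULT_RULE.required_markers))
    seed: int = 1
    simulation: sim.SimulationConfig | None = None

    def validate(self) -> None:
        if self.window < self.step:
            raise ValueError("window must be >= step")
        if self.min_depth < 0 or self.pool_size < 1:
            raise ValueError("min_depth must be >= 0 and pool_size >= 1")
        for name in ("delta_threshold", "alpha", "rho_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_cfg is not None:
            if "causal_loci" in sim_cfg:
                sim_cfg["causal_loci"] = tuple(
                    sim.CausalLocus(**c) for c in sim_cfg["causal_loci"]
                )
            if "progeny_per_cross" in sim_cfg and not isinstance(
                sim_cfg["progeny_per_cross"], int
            ):
                sim_cfg["progeny_per_cross"] = tuple(sim_cfg["progeny_per_cross"])
            cfg.simulation = sim.SimulationConfig(**sim_cfg)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), default=str, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    pools: tuple[ph.PoolAssignment, ph.PoolAssignment] | None
    threshold: float | None
    regions: list[sc.CandidateRegion]
    validations: list[mk.MarkerValidation]
    selection: pd.DataFrame | None
    counts: dict[str, int] = field(default_factory=dict)


def _stage(log: list[str], name: str, **info) -> None:
    log.append(f"[{name}] " + " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order, writing per-stage outputs and a run log."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"frostmas {__version__} seed={config.seed} config_hash={config.config_hash()}"
    ]
    rng = np.random.default_rng(config.seed)
    counts: dict[str, int] = {}

    synthetic = config.vcf is None
    population = None
    if synthetic:
        sim_cfg = config.simulation or sim.SimulationConfig(seed=config.seed)
        population = sim.simulate_population(sim_cfg)
        phenotypes = sim.simulate_phenotypes(population)
        tolerant_ids = population.tolerant_parent_ids
        pedigree = population.pedigree
        _stage(log, "simulate", founders=len(population.founders),
               progeny=len(population.progeny), variants=len(population.variants))
    else:
        phenotypes = fio.read_phenotypes_tsv(config.phenotypes)
        tolerant_ids = set()
        pedigree = {}
        _stage(log, "load", phenotype_rows=len(phenotypes))

    # --- phenotyping -------------------------------------------------------
    as_env = ph.as_table(phenotypes)
    fio.write_phenotypes_tsv(phenotypes, out / "phenotypes.tsv")
    as_env.to_csv(out / "as_by_environment.tsv", sep="\t")
    _stage(log, "phenotyping", genotypes=len(as_env), environments=as_env.shape[1])

    # --- pooling -----------------------------------------------------------
    pools = None
    if synthetic:
        progeny_ids = [p.id for p in population.progeny]
        ranking = as_env.loc[as_env.index.intersection(progeny_ids)].mean(axis=1)
        rp, sp = ph.build_extreme_pools(
            ranking, pedigree, config.pool_size, tolerant_ids
        )
        pools = (rp, sp)
        table, summary = ph.parent_frequency_report(
            rp, sp,
            sorted(tolerant_ids),
            sorted({f.id for f in population.founders} - tolerant_ids),
        )
        table.to_csv(out / "pool_report.tsv", sep="\t", index=False)
        summary.to_csv(out / "pool_summary.tsv", sep="\t", index=False)
        cmp = ph.compare_pools(
            ranking.loc[rp.member_ids], ranking.loc[sp.member_ids]
        )
        _stage(log, "pools", rp=len(rp.member_ids), sp=len(sp.member_ids),
               t=f"{cmp['t']:.3f}", p=f"{cmp['p_value']:.3g}")

    # --- variants ----------------------------------------------------------
    if synthetic:
        idx = {pid: i for i, pid in enumerate(population.progeny_ids)}
        rp_dos = population.progeny_dosage[[idx[m] for m in pools[0].member_ids]]
        sp_dos = population.progeny_dosage[[idx[m] for m in pools[1].member_ids]]
        mean_depth = population.config.mean_depth
        rp_ref, rp_alt = sim.simulate_bulk_depths(
            rp_dos, mean_depth, rng, population.config.depth_dispersion
        )
        sp_ref, sp_alt = sim.simulate_bulk_depths(
            sp_dos, mean_depth, rng, population.config.depth_dispersion
        )
        variants = population.variants[["chromosome", "position", "ref", "alt"]].copy()
        variants["rp_ref"], variants["rp_alt"] = rp_ref, rp_alt
        variants["sp_ref"], variants["sp_alt"] = sp_ref, sp_alt
        fio.write_bulk_vcf(
            variants, out / "bulks.vcf",
            contig_lengths=population.config.chromosome_lengths,
            rp_sample=config.rp_sample, sp_sample=config.sp_sample,
        )
        chrom_lengths = dict(population.config.chromosome_lengths)
    else:
        variants, vcf_counts = fio.read_bulk_vcf(
            config.vcf, config.rp_sample, config.sp_sample
        )
        counts.update(vcf_counts)
        chrom_lengths = variants.attrs.get("contig_lengths") or None

    # --- scan --------------------------------------------------------------
    stats, stat_counts = sc.compute_variant_stats(variants, config.min_depth)
    counts.update(stat_counts)
    windows = sc.sliding_window_scan(
        stats, config.window, config.step, chrom_lengths,
        ed_power=config.ed_power, min_window_variants=config.min_window_variants,
    )
    threshold = sc.genome_threshold(windows)
    regions = sc.call_regions(windows, threshold, config.merge_gap)
    fio.write_variants_tsv(stats, out / "variant_stats.tsv")
    windows.to_csv(out / "window_stats.tsv", sep="\t", index=False)
    fio.write_regions_bed(regions, out / "regions.bed")
    sc.regions_to_frame(regions).to_csv(out / "regions.tsv", sep="\t", index=False)
    _stage(log, "scan", variants=len(stats), windows=len(windows),
           threshold=f"{threshold:.4f}", regions=len(regions))

    # --- markers -----------------------------------------------------------
    validations: list[mk.MarkerValidation] = []
    selection = None
    sites: list[mk.MarkerSite] = []
    if regions:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            sites = mk.select_target_sites(
                stats, regions, config.n_per_region, config.delta_threshold
            )
        pd.DataFrame(
            [dataclasses.asdict(s) for s in sites]
        ).to_csv(out / "marker_sites.tsv", sep="\t", index=False)
        _stage(log, "marker_select", sites=len(sites))

    if not synthetic and config.parent_genotypes:
        parent_table = fio.read_genotypes_tsv(config.parent_genotypes)
        tolerant_ids = set(config.tolerant_parent_ids or ())
        sensitive_ids = set(parent_table["individual_id"]) - tolerant_ids
        screen = mk.screen_parent_polymorphism(
            parent_table, tolerant_ids, sensitive_ids
        )
        _stage(log, "marker_screen", **{
            k: (f"{v:.2f}" if isinstance(v, float) else v)
            for k, v in screen.summary.items()
        })
        if config.progeny_genotypes:
            progeny_table = fio.read_genotypes_tsv(config.progeny_genotypes)
            codes_all = mk.binarize_genotypes(progeny_table, screen.coding)
            for marker, grp in codes_all.groupby("marker"):
                try:
                    v = mk.spearman_validate(
                        grp.set_index("individual_id")["code"], as_env,
                        marker_name=marker, alpha=config.alpha,
                        rho_min=config.rho_min,
                    )
                except ValueError:
                    continue
                validations.append(v)
            pd.DataFrame(
                [
                    {"marker": v.marker_name, "passed": v.passed,
                     **{f"rho_{e}": r for e, r in v.rho_by_environment.items()},
                     **{f"p_{e}": p for e, p in v.p_by_environment.items()}}
                    for v in validations
                ]
            ).to_csv(out / "marker_validation.tsv", sep="\t", index=False)
            _stage(log, "marker_validate", tested=len(validations),
                   passed=sum(v.passed for v in validations))
            passed = sorted(v.marker_name for v in validations if v.passed)
            if passed:
                order = tuple(passed)
                strings, excluded = mas.build_genotype_strings(codes_all, order)
                chrom_of = {m: m.split("V")[0] for m in order}
                classes = mas.classify_population(strings, chrom_of)
                classes.to_csv(out / "genotype_strings.tsv", sep="\t", index=False)
                rule_markers = frozenset(config.rule_markers) & set(order)
                rule = mas.SelectionRule(rule_markers or frozenset(order))
                selection = mas.select_individuals(strings, rule)
                selection.to_csv(out / "selection.tsv", sep="\t", index=False)
                _stage(log, "mas", strings=len(strings), excluded=len(excluded),
                       selected=int(selection["selected"].sum()))

    if sites and synthetic:
        site_cols = {
            s.name: population.variants.index[
                (population.variants["chromosome"] == s.chromosome)
                & (population.variants["position"] == s.position)
            ][0]
            for s in sites
        }
        meta = population.variants

        def genotype_rows(ids, dosage_matrix, order):
            rows = []
            for name, col in site_cols.items():
                ref, alt = meta.at[col, "ref"], meta.at[col, "alt"]
                for ind in ids:
                    d = int(dosage_matrix[order[ind], col])
                    rows.append(
                        {"marker": name, "individual_id": ind,
                         "genotype": sim.dosage_to_genotype_string(d, ref, alt)}
                    )
            return pd.DataFrame(rows)

        f_order = {pid: i for i, pid in enumerate(population.founder_ids)}
        parent_table = genotype_rows(
            population.founder_ids, population.founder_dosage, f_order
        )
        screen = mk.screen_parent_polymorphism(
            parent_table, tolerant_ids,
            set(population.founder_ids) - tolerant_ids,
        )
        _stage(log, "marker_screen", **{
            k: (f"{v:.2f}" if isinstance(v, float) else v)
            for k, v in screen.summary.items()
        })

        pool_members = pools[0].member_ids + pools[1].member_ids
        p_order = {pid: i for i, pid in enumerate(population.progeny_ids)}
        member_table = genotype_rows(
            pool_members, population.progeny_dosage, p_order
        )
        member_codes = mk.binarize_genotypes(member_table, screen.coding)
        pool_of = {m: "RP" for m in pools[0].member_ids}
        pool_of.update({m: "SP" for m in pools[1].member_ids})
        for marker, grp in member_codes.groupby("marker"):
            codes = grp.set_index("individual_id")["code"]
            try:
                v = mk.spearman_validate(
                    codes, as_env.loc[as_env.index.intersection(pool_members)],
                    marker_name=marker, alpha=config.alpha, rho_min=config.rho_min,
                )
            except ValueError:
                continue
            try:
                v.goodness_of_fit_pct = mk.goodness_of_fit(
                    pool_of, codes.to_dict()
                )
            except ValueError:
                pass
            validations.append(v)
        pd.DataFrame(
            [
                {"marker": v.marker_name, "passed": v.passed,
                 "goodness_of_fit_pct": v.goodness_of_fit_pct,
                 **{f"rho_{e}": r for e, r in v.rho_by_environment.items()},
                 **{f"p_{e}": p for e, p in v.p_by_environment.items()}}
                for v in validations
            ]
        ).to_csv(out / "marker_validation.tsv", sep="\t", index=False)
        _stage(log, "marker_validate", tested=len(validations),
               passed=sum(v.passed for v in validations))

        # --- MAS ------------------------------------------------------------
        passed = [v.marker_name for v in validations if v.passed]
        if passed:
            progeny_table = genotype_rows(
                population.progeny_ids, population.progeny_dosage, p_order
            )
            codes_all = mk.binarize_genotypes(progeny_table, screen.coding)
            order = tuple(sorted(passed))
            strings, excluded = mas.build_genotype_strings(codes_all, order)
            chrom_of = {m: m.split("V")[0] for m in order}
            classes = mas.classify_population(strings, chrom_of)
            classes.to_csv(out / "genotype_strings.tsv", sep="\t", index=False)
            class_of = dict(
                zip(classes["individual_id"], classes["combination_class"])
            )
            report = mas.class_phenotype_comparison(class_of, as_env)
            report.to_csv(out / "class_report.tsv", sep="\t", index=False)
            rule_markers = frozenset(config.rule_markers) & set(order)
            rule = mas.SelectionRule(rule_markers or frozenset(order))
            selection = mas.select_individuals(strings, rule)
            selection.to_csv(out / "selection.tsv", sep="\t", index=False)
            _stage(log, "mas", strings=len(strings), excluded=len(excluded),
                   selected=int(selection["selected"].sum()))

    (out / "run.log").write_text("\n".join(log) + "\n")
    return PipelineResult(
        out_dir=out,
        pools=pools,
        threshold=threshold,
        regions=regions,
        validations=validations,
        selection=selection,
        counts=counts,
    )
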