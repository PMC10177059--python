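"""File-format adapters: VCF (two-bulk allele depths), TSV tables, BED.

Conventions: VCF positions are 1-based; window/region arithmetic inside the
package is 0-based half-open; BED output is 0-based half-open.  The helpers
here centralise every conversion.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scan import CandidateRegion, regions_to_frame

__all__ = [
    "one_based_to_zero_half_open",
    "zero_half_open_to_one_based",
    "read_bulk_vcf",
    "write_bulk_vcf",
    "write_regions_bed",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_genotypes_tsv",
    "write_variants_tsv",
    "read_variants_tsv",
]

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "chromosome", "position", "ref", "alt", "rp_ref", "rp_alt", "sp_ref", "sp_alt",
]


def one_based_to_zero_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open (BED) interval."""
    if start < 1 or end < start:
        raise ValueError("invalid 1-based inclusive interval")
    return start - 1, end


def zero_half_open_to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive interval."""
    if start < 0 or end <= start:
        raise ValueError("invalid 0-based half-open interval")
    return start + 1, end


def read_bulk_vcf(
    path: str | Path,
    rp_sample: str = "RP",
    sp_sample: str = "SP",
    multiallelic: str = "skip",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a two-sample VCF carrying per-sample allelic depths (AD).

    Returns (variants, counts): variants has the internal two-bulk columns;
    counts tallies skipped multiallelic records.  A record missing AD in
    either sample raises with the sample and site named.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic policy must be 'skip' or 'error'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (rp_sample, sp_sample):
        if s not in samples:
            raise ValueError(f"sample {s!r} not in VCF ({samples})")
    i_rp, i_sp = samples.index(rp_sample), samples.index(sp_sample)
    rows = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at {rec.CHROM}:{rec.POS}"
                )
            n_multi += 1
            continue
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"AD missing at {rec.CHROM}:{rec.POS}")
        for idx, name in ((i_rp, rp_sample), (i_sp, sp_sample)):
            if ad[idx] is None or np.any(np.asarray(ad[idx]) < 0):
                raise ValueError(
                    f"AD missing for sample {name!r} at {rec.CHROM}:{rec.POS}"
                )
        rows.append(
            {
                "chromosome": rec.CHROM,
                "position": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "rp_ref": int(ad[i_rp][0]),
                "rp_alt": int(ad[i_rp][1]),
                "sp_ref": int(ad[i_sp][0]),
                "sp_alt": int(ad[i_sp][1]),
            }
        )
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    df = df.sort_values(["chromosome", "position"]).reset_index(drop=True)
    try:  # contig lengths from the header, when declared
        df.attrs["contig_lengths"] = dict(zip(vcf.seqnames, vcf.seqlens))
    except Exception:
        df.attrs["contig_lengths"] = {}
    return df, {"records": len(df), "multiallelic_skipped": n_multi}


def write_bulk_vcf(
    variants: pd.DataFrame,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
    rp_sample: str = "RP",
    sp_sample: str = "SP",
) -> Path:
    """Write the two-bulk allele depths as a minimal uncompressed VCF."""
    import pysam

    path = Path(path)
    header = pysam.VariantHeader()
    chroms = (
        dict(contig_lengths)
        if contig_lengths is not None
        else {
            c: int(g["position"].max()) + 1
            for c, g in variants.groupby("chromosome", sort=True)
        }
    )
    for chrom, length in chroms.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(rp_sample)
    header.add_sample(sp_sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in variants.sort_values(["chromosome", "position"]).itertuples():
            rec = out.new_record(
                contig=row.chromosome,
                start=row.position - 1,
                alleles=(row.ref, row.alt),
            )
            rec.samples[rp_sample]["AD"] = (int(row.rp_ref), int(row.rp_alt))
            rec.samples[sp_sample]["AD"] = (int(row.sp_ref), int(row.sp_alt))
            out.write(rec)
    return path


def write_regions_bed(
    regions: Sequence[CandidateRegion], path: str | Path
) -> Path:
    """Candidate regions as BED (0-based half-open), 4th column = peak stat."""
    path = Path(path)
    frame = regions_to_frame(list(regions)).sort_values(["chromosome", "start"])
    with open(path, "w") as fh:
        fh.write("# candidate regions: chrom\tstart\tend\tpeak_stat\n")
        for row in frame.itertuples(index=False):
            fh.write(
                f"{row.chromosome}\t{row.start}\t{row.end}\t{row.peak_stat:.6g}\n"
            )
    return path


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cols = ["genotype_id", "environment_id", "replicate", "score"]
    phenotypes[cols].to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"genotype_id": str,
                                            "environment_id": str})
    missing = {"genotype_id", "environment_id", "replicate", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype TSV missing columns {sorted(missing)}")
    return df


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    """Tidy marker-genotype table: individual_id, marker, genotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"individual_id", "marker", "genotype"} - set(df.columns)
    if missing:
        raise ValueError(f"genotype TSV missing columns {sorted(missing)}")
    return df


def write_variants_tsv(variants: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    variants.to_csv(path, sep="\t", index=False)
    return path


def read_variants_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant TSV missing columns {sorted(missing)}")
    return df
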