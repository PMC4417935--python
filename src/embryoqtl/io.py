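"""Readers and writers for the pipeline's file formats.

SNP tables travel as VCF (INFO carries the quality flag and indel distance),
gene annotations as BED12, matrices and vote tables as TSV, reads as FASTQ.
Coordinates are 0-based half-open internally; VCF positions are converted on
read and write.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import ExpressionMatrix, MarkerRegionSet, SimulationTruth
from .reads import Read

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=HQ,Number=0,Type=Flag,Description="High-quality strain-distinguishing SNP">
##INFO=<ID=IDIST,Number=1,Type=Integer,Description="Distance to nearest Cast indel (bp)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Overlapping gene id">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_snp_vcf(snp_table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for _, row in snp_table.iterrows():
            info = [f"IDIST={int(row['indel_distance'])}", f"GENE={row['gene']}"]
            if row["high_quality"]:
                info.insert(0, "HQ")
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t.\t{row['b6_allele']}\t"
                f"{row['cast_allele']}\t.\tPASS\t{';'.join(info)}\n"
            )


def read_snp_vcf(path) -> pd.DataFrame:
    """Read the SNP VCF back to the internal 0-based table (via cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for v in VCF(str(path)):
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS - 1,
                "b6_allele": v.REF,
                "cast_allele": v.ALT[0] if v.ALT else ".",
                "high_quality": bool(v.INFO.get("HQ", False)),
                "indel_distance": int(v.INFO.get("IDIST", 10**9)),
                "gene": v.INFO.get("GENE", ""),
            }
        )
    return pd.DataFrame(rows)


def write_bed12(annotation: pd.DataFrame, path) -> None:
    """Single-block BED12 per gene (the generator emits single-exon genes)."""
    with open(path, "w") as fh:
        for gene, row in annotation.iterrows():
            size = int(row["end"]) - int(row["start"])
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        row["chrom"],
                        int(row["start"]),
                        int(row["end"]),
                        gene,
                        0,
                        row["strand"],
                        int(row["start"]),
                        int(row["end"]),
                        "0,0,0",
                        1,
                        f"{size},",
                        "0,",
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> pd.DataFrame:
    cols = [
        "chrom", "start", "end", "gene", "score", "strand",
        "thick_start", "thick_end", "rgb", "n_blocks", "block_sizes", "block_starts",
    ]
    ann = pd.read_csv(path, sep="\t", header=None, names=cols)
    ann = ann.set_index("gene")[["chrom", "start", "end", "strand", "n_blocks", "block_sizes", "block_starts"]]
    return ann


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: ExpressionMatrix, counts_path, library_path) -> None:
    write_matrix(expr.counts, counts_path)
    expr.library_size.rename("library_size").to_csv(library_path, sep="\t", index_label="embryo")


def read_expression(counts_path, library_path) -> ExpressionMatrix:
    counts = read_matrix(counts_path)
    lib = pd.read_csv(library_path, sep="\t", index_col=0)["library_size"]
    return ExpressionMatrix(counts, lib)


def write_votes(votes: pd.DataFrame, path) -> None:
    votes.to_csv(path, sep="\t", index=False)


def read_votes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "cis_fold": truth.cis_fold,
        "maternal_fold": truth.maternal_fold,
        "imprinted": {g: list(v) for g, v in truth.imprinted.items()},
        "somite_slope_expr": truth.somite_slope_expr,
        "somite_slope_allele": truth.somite_slope_allele,
        "hotspot": None
        if truth.hotspot is None
        else {"locus": truth.hotspot[0], "targets": truth.hotspot[1]},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    hotspot = payload.get("hotspot")
    return SimulationTruth(
        cis_fold=payload.get("cis_fold", {}),
        maternal_fold=payload.get("maternal_fold", {}),
        imprinted={g: (o, r) for g, (o, r) in payload.get("imprinted", {}).items()},
        somite_slope_expr=payload.get("somite_slope_expr", {}),
        somite_slope_allele=payload.get("somite_slope_allele", {}),
        hotspot=None if hotspot is None else (hotspot["locus"], hotspot["targets"]),
    )


def write_marker_regions(markers: MarkerRegionSet, regions_path, genotypes_path) -> None:
    markers.regions.to_csv(regions_path, sep="\t", index_label="region")
    markers.genotypes.to_csv(genotypes_path, sep="\t", index_label="region")


def read_fastq(path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(Read(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(reads: list[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
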