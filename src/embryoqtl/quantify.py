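"""Allele-vote counting, expression quantification, gene filters and sex calls.

The allele-specific substrate is a vote table: a read covering n usable
strain-distinguishing SNPs contributes 1/n vote per SNP to the B6, Cast or
"other" total of its gene, so every read carries total vote mass 1 regardless
of how many SNPs it spans.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, empty_vote_table


def usable_snp_mask(snp_table: pd.DataFrame, min_indel_distance: int = 50) -> pd.Series:
    """High-quality SNPs at least ``min_indel_distance`` bp from any Cast indel.

    Indel proximity causes local misalignment that corrupts allele calls, so
    nearby SNPs are masked from ASE entirely.
    """
    return snp_table["high_quality"] & (snp_table["indel_distance"] >= min_indel_distance)


def count_allele_votes(
    read_snp_calls: pd.DataFrame,
    snp_table: pd.DataFrame,
    min_indel_distance: int = 50,
) -> pd.DataFrame:
    """Tally fractional allele votes per (gene, embryo).

    ``read_snp_calls`` has one row per (read, SNP) observation with columns
    embryo, read_id, gene, chrom, pos, observed_base.  The observed base is
    compared against the SNP table's strain alleles; each of a read's n usable
    SNPs contributes 1/n vote to the matching category (B6 / Cast / other).
    Reads overlapping zero usable SNPs contribute nothing.
    """
    usable = snp_table[usable_snp_mask(snp_table, min_indel_distance)]
    calls = read_snp_calls.merge(
        usable[["chrom", "pos", "b6_allele", "cast_allele"]], on=["chrom", "pos"], how="inner"
    )
    if calls.empty:
        return empty_vote_table()
    calls["is_b6"] = calls["observed_base"] == calls["b6_allele"]
    calls["is_cast"] = calls["observed_base"] == calls["cast_allele"]
    per_read = calls.groupby(["embryo", "gene", "read_id"], sort=False).agg(
        n_snps=("pos", "size"), n_b6=("is_b6", "sum"), n_cast=("is_cast", "sum")
    )
    per_read["b6_votes"] = per_read["n_b6"] / per_read["n_snps"]
    per_read["cast_votes"] = per_read["n_cast"] / per_read["n_snps"]
    per_read["other_votes"] = 1.0 - per_read["b6_votes"] - per_read["cast_votes"]
    out = (
        per_read.groupby(["gene", "embryo"])
        .agg(
            b6_votes=("b6_votes", "sum"),
            cast_votes=("cast_votes", "sum"),
            other_votes=("other_votes", "sum"),
            snp_read_count=("n_snps", "size"),
        )
        .reset_index()
    )
    return out


def quantify_expression(
    alignments: pd.DataFrame,
    gene_annotation: pd.DataFrame,
    library_size: pd.Series | None = None,
) -> ExpressionMatrix:
    """Count exon-overlapping reads per (gene, embryo) and normalise to RPM.

    ``alignments`` has columns embryo, chrom, position (0-based read start);
    a read is assigned to the gene whose exon span contains its position.
    ``gene_annotation`` is indexed by gene with columns chrom, start, end.
    """
    counts = {}
    embryos = sorted(alignments["embryo"].unique())
    for chrom, genes in gene_annotation.groupby("chrom", sort=False):
        sub = alignments[alignments["chrom"] == chrom]
        if sub.empty:
            continue
        starts = genes["start"].to_numpy()
        ends = genes["end"].to_numpy()
        order = np.argsort(starts)
        idx = np.searchsorted(starts[order], sub["position"].to_numpy(), side="right") - 1
        valid = idx >= 0
        gene_hit = np.full(len(sub), -1)
        gene_hit[valid] = order[idx[valid]]
        inside = valid & (sub["position"].to_numpy() < ends[np.clip(gene_hit, 0, None)])
        hit = sub[inside].assign(gene=genes.index.to_numpy()[gene_hit[inside]])
        for (g, e), n in hit.groupby(["gene", "embryo"]).size().items():
            counts[(g, e)] = n
    mat = pd.DataFrame(0, index=gene_annotation.index, columns=pd.Index(embryos, name="embryo"))
    for (g, e), n in counts.items():
        mat.loc[g, e] = n
    if library_size is None:
        library_size = alignments.groupby("embryo").size().reindex(embryos)
    return ExpressionMatrix(mat, library_size)


def apply_gene_filters(
    expr: ExpressionMatrix,
    gene_annotation: pd.DataFrame,
    filtered_read_fraction: pd.Series | None = None,
    retrogene_list=(),
    min_rpm: float = 5.0,
    max_filtered_fraction: float = 0.05,
    autosomes: set[str] | None = None,
) -> pd.Series:
    """Boolean gene mask for the downstream analyses.

    A gene is kept iff mean RPM >= ``min_rpm``, at most
    ``max_filtered_fraction`` of its mapped reads were discarded by the
    ambiguous-alignment filter, it is not a retrotransposed copy, and it is
    autosomal.  ``autosomes`` defaults to all chrom values not named chrX /
    chrY / chrM.
    """
    mask = expr.rpm.mean(axis=1) >= min_rpm
    if filtered_read_fraction is not None:
        frac = filtered_read_fraction.reindex(expr.genes).fillna(0.0)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("filtered_read_fraction outside [0,1]")
        mask &= frac <= max_filtered_fraction
    if len(retrogene_list):
        mask &= ~expr.genes.isin(set(retrogene_list))
    chroms = gene_annotation["chrom"].reindex(expr.genes)
    if autosomes is None:
        mask &= ~chroms.isin({"chrX", "chrY", "chrM", "X", "Y", "MT"})
    else:
        mask &= chroms.isin(autosomes)
    mask.name = "pass_filters"
    return mask


def assign_sex(expr: ExpressionMatrix, xist_gene: str, max_iter: int = 100) -> pd.Series:
    """Call embryo sex from the bimodal Xist distribution by 1-D 2-means.

    Xist is robustly expressed from the inactive X in females and silent in
    males.  Embryos above the midpoint of the two cluster means are called
    female.  If the distribution is not clearly bimodal (the split explains
    under half the variance), all embryos are returned unknown with a warning.
    """
    if xist_gene not in expr.genes:
        raise KeyError(f"{xist_gene!r} not in expression matrix")
    x = expr.rpm.loc[xist_gene]
    values = x.to_numpy(dtype=float)
    unknown = pd.Series("unknown", index=x.index, name="sex")
    if len(values) < 2 or np.ptp(values) == 0:
        warnings.warn("Xist expression is not bimodal; sex left unknown")
        return unknown
    lo, hi = values.min(), values.max()
    for _ in range(max_iter):
        thr = (lo + hi) / 2.0
        high = values > thr
        if high.all() or not high.any():
            break
        new_lo, new_hi = values[~high].mean(), values[high].mean()
        if np.isclose(new_lo, lo) and np.isclose(new_hi, hi):
            lo, hi = new_lo, new_hi
            break
        lo, hi = new_lo, new_hi
    thr = (lo + hi) / 2.0
    high = values > thr
    if not high.any() or high.all():
        warnings.warn("Xist expression is not bimodal; sex left unknown")
        return unknown
    between_ss = (~high).sum() * (values[~high].mean() - values.mean()) ** 2 + high.sum() * (
        values[high].mean() - values.mean()
    ) ** 2
    total_ss = ((values - values.mean()) ** 2).sum()
    if total_ss == 0 or between_ss / total_ss < 0.5:
        warnings.warn("Xist expression is not bimodal; sex left unknown")
        return unknown
    return pd.Series(np.where(high, "F", "M"), index=x.index, name="sex")
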