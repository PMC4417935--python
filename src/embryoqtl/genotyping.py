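"""Genotype inference along each autosome from sparse allele votes.

An N2 embryo is B6/B6 or B6/Cast at every autosomal locus, in blocks delimited
by the crossovers of the F1 gamete.  Genes are first given preliminary calls
from their B6 vote fraction, then smoothed with a two-state hidden Markov
model that penalises het<->hom transitions; low-coverage genes near inferred
recombination sites are masked, and adjacent genes with identical genotype
vectors across all embryos are merged into marker regions — the unit of eQTL
testing.

HMM parameterisation: known preliminary calls emit their observed call with
probability 1-epsilon, unknown genes emit uniformly, and the chain switches
state with probability t per gene step (genetic distance between adjacent
genes is not modelled).  Defaults: epsilon = 0.02, t = 1e-4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HET, HOM, UNKNOWN, MarkerRegionSet

_STATES = (HET, HOM)


def preliminary_genotype(
    votes: pd.DataFrame, min_votes: int = 20, hom_fraction: float = 0.9
) -> pd.DataFrame:
    """Per (gene, embryo) preliminary call from the B6 vote fraction.

    Genes with fewer than ``min_votes`` SNP-covering reads are 'unknown';
    otherwise the call is homozygous when the B6 fraction reaches
    ``hom_fraction`` and heterozygous below it (a backcross has no Cast/Cast
    class, so one boundary suffices).
    """
    total = votes["b6_votes"] + votes["cast_votes"] + votes["other_votes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = (votes["b6_votes"] / total).to_numpy()
    call = np.where(
        votes["snp_read_count"].to_numpy() < min_votes,
        UNKNOWN,
        np.where(frac >= hom_fraction, HOM, HET),
    )
    out = votes[["gene", "embryo", "snp_read_count"]].copy()
    out["b6_fraction"] = frac
    out["call"] = call
    return out


def prelim_matrix(
    prelim: pd.DataFrame, annotation: pd.DataFrame, embryos
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot preliminary calls to genes x embryos (annotation order), plus the
    matching informative-vote matrix.  Genes with no votes are 'unknown'."""
    calls = prelim.pivot(index="gene", columns="embryo", values="call")
    calls = calls.reindex(index=annotation.index, columns=embryos).fillna(UNKNOWN)
    nvotes = prelim.pivot(index="gene", columns="embryo", values="snp_read_count")
    nvotes = nvotes.reindex(index=annotation.index, columns=embryos).fillna(0)
    return calls, nvotes


def viterbi_chain(
    observations: np.ndarray, epsilon: float = 0.02, transition: float = 1e-4
) -> np.ndarray:
    """Most probable het/hom state path for one embryo along one chromosome.

    ``observations`` is an object/str array over {het, hom, unknown}.  Initial
    state probabilities are uniform.  Returns the state path as an array over
    {het, hom}; raises ValueError on an empty chain.  A chromosome without a
    single confident call has no information — the caller maps that case to
    all-unknown.
    """
    n = len(observations)
    if n == 0:
        raise ValueError("empty chromosome")
    # log emission per position for states (het, hom)
    log_e = np.empty((n, 2))
    for i, obs in enumerate(observations):
        if obs == HET:
            log_e[i] = (np.log1p(-epsilon), np.log(epsilon))
        elif obs == HOM:
            log_e[i] = (np.log(epsilon), np.log1p(-epsilon))
        else:
            log_e[i] = (np.log(0.5), np.log(0.5))
    log_stay = np.log1p(-transition)
    log_switch = np.log(transition)

    score = np.log(0.5) + log_e[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        for s in (0, 1):
            from_same = score[s] + log_stay
            from_other = score[1 - s] + log_switch
            if from_same >= from_other:  # tie -> no transition
                back[i, s] = s
            else:
                back[i, s] = 1 - s
        new0 = max(score[0] + log_stay, score[1] + log_switch) + log_e[i, 0]
        new1 = max(score[1] + log_stay, score[0] + log_switch) + log_e[i, 1]
        score = np.array([new0, new1])
    path = np.empty(n, dtype=np.int8)
    path[-1] = 0 if score[0] >= score[1] else 1
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return np.asarray(_STATES, dtype=object)[path]


def smooth_genotypes_hmm(
    prelim_calls: pd.DataFrame,
    annotation: pd.DataFrame,
    epsilon: float = 0.02,
    transition: float = 1e-4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Viterbi-smooth preliminary calls per embryo per chromosome.

    Unknown genes inherit the smoothed path state.  Returns (genotype matrix,
    breakpoints) where breakpoints has one row per state change with columns
    embryo, chrom, left_gene, right_gene (the genes flanking the change).
    Chromosomes with zero confident calls for an embryo stay all-unknown.
    """
    chroms = annotation["chrom"].reindex(prelim_calls.index)
    smoothed = prelim_calls.copy()
    bp_rows = []
    for chrom, gene_idx in prelim_calls.groupby(chroms, sort=False).groups.items():
        genes = list(gene_idx)
        block = prelim_calls.loc[genes]
        for embryo in prelim_calls.columns:
            obs = block[embryo].to_numpy(dtype=object)
            if not ((obs == HET) | (obs == HOM)).any():
                smoothed.loc[genes, embryo] = UNKNOWN
                continue
            path = viterbi_chain(obs, epsilon, transition)
            smoothed.loc[genes, embryo] = path
            changes = np.nonzero(path[1:] != path[:-1])[0]
            for i in changes:
                bp_rows.append(
                    {"embryo": embryo, "chrom": chrom, "left_gene": genes[i], "right_gene": genes[i + 1]}
                )
    breakpoints = pd.DataFrame(bp_rows, columns=["embryo", "chrom", "left_gene", "right_gene"])
    return smoothed, breakpoints


def mask_near_breakpoints(
    matrix: pd.DataFrame,
    prelim_calls: pd.DataFrame,
    nvotes: pd.DataFrame,
    breakpoints: pd.DataFrame,
    annotation: pd.DataFrame,
    low_votes_threshold: int = 20,
) -> pd.DataFrame:
    """Set low-coverage genes near putative recombination sites to unknown.

    Around each breakpoint, genes with fewer than ``low_votes_threshold``
    informative votes lying between the two confident preliminary calls that
    flank the state change cannot be placed on either side reliably and are
    masked.  Confident, well-covered genes keep their calls.
    """
    out = matrix.copy()
    if breakpoints.empty:
        return out
    order = {g: i for i, g in enumerate(annotation.index)}
    gene_arr = annotation.index.to_numpy()
    for _, bp in breakpoints.iterrows():
        embryo = bp["embryo"]
        chrom_genes = annotation.index[annotation["chrom"] == bp["chrom"]]
        lo, hi = order[bp["left_gene"]], order[bp["right_gene"]]
        confident = (
            (prelim_calls[embryo] != UNKNOWN)
            & (nvotes[embryo] >= low_votes_threshold)
        )
        left_conf = [g for g in chrom_genes if order[g] <= lo and confident[g]]
        right_conf = [g for g in chrom_genes if order[g] >= hi and confident[g]]
        start = order[left_conf[-1]] + 1 if left_conf else order[chrom_genes[0]]
        stop = order[right_conf[0]] if right_conf else order[chrom_genes[-1]] + 1
        for g in gene_arr[start:stop]:
            if nvotes.loc[g, embryo] < low_votes_threshold:
                out.loc[g, embryo] = UNKNOWN
    return out


def build_marker_regions(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    max_recombs: int = 0,
    tie_margin: int = 1,
) -> MarkerRegionSet:
    """Greedy left-to-right merge of adjacent genes into marker regions.

    In exact-identity mode (``max_recombs = 0``) adjacent genes are merged
    while their genotype vectors agree across all embryos (unknown calls are
    wildcards).  The relaxed mode tolerates up to ``max_recombs`` per-embryo
    disagreements with the running consensus summed across the region.  The
    consensus call per (region, embryo) is the majority of known calls, or
    unknown when homozygous and heterozygous counts are within ``tie_margin``
    of each other.
    """
    genes = annotation.index
    matrix = matrix.reindex(genes)
    embryos = matrix.columns
    codes = np.full(matrix.shape, -1, dtype=np.int8)  # -1 unknown, 0 het, 1 hom
    vals = matrix.to_numpy()
    codes[vals == HET] = 0
    codes[vals == HOM] = 1
    chrom_arr = annotation["chrom"].to_numpy()

    region_rows = []
    consensus_rows = []
    gene_region = pd.Series(index=genes, dtype=object)

    def flush(chrom, members, het_count, hom_count):
        rid = f"mr{len(region_rows):04d}"
        region_rows.append(
            {
                "region": rid,
                "chrom": chrom,
                "start_gene": members[0],
                "end_gene": members[-1],
                "n_genes": len(members),
            }
        )
        cons = np.where(
            np.abs(hom_count - het_count) <= tie_margin,
            UNKNOWN,
            np.where(hom_count > het_count, HOM, HET),
        )
        # a region of one confidently genotyped gene should keep that call
        single = het_count + hom_count == 1
        cons[single & (het_count == 1)] = HET
        cons[single & (hom_count == 1)] = HOM
        consensus_rows.append(cons)
        gene_region.loc[members] = rid

    i = 0
    n_genes = len(genes)
    while i < n_genes:
        chrom = chrom_arr[i]
        members = [genes[i]]
        het_count = (codes[i] == 0).astype(int)
        hom_count = (codes[i] == 1).astype(int)
        mismatches = 0
        j = i + 1
        while j < n_genes and chrom_arr[j] == chrom:
            row = codes[j]
            known = row >= 0
            maj = np.where(hom_count > het_count, 1, np.where(het_count > hom_count, 0, -1))
            disagree = known & (maj >= 0) & (row != maj)
            new_mismatches = mismatches + int(disagree.sum())
            if new_mismatches > max_recombs:
                break
            mismatches = new_mismatches
            members.append(genes[j])
            het_count = het_count + (row == 0)
            hom_count = hom_count + (row == 1)
            j += 1
        flush(chrom, members, het_count, hom_count)
        i = j

    regions = pd.DataFrame(region_rows).set_index("region")
    genotypes = pd.DataFrame(
        np.vstack(consensus_rows), index=regions.index, columns=embryos
    )
    gene_region.name = "region"
    return MarkerRegionSet(regions=regions, genotypes=genotypes, gene_to_region=gene_region)


def genotype_pipeline(
    votes: pd.DataFrame,
    annotation: pd.DataFrame,
    embryos,
    min_votes: int = 20,
    epsilon: float = 0.02,
    transition: float = 1e-4,
    max_recombs: int = 0,
):
    """Preliminary calls -> HMM smoothing -> breakpoint masking -> regions.

    Returns (genotype matrix, breakpoints, MarkerRegionSet).
    """
    prelim = preliminary_genotype(votes, min_votes=min_votes)
    calls, nvotes = prelim_matrix(prelim, annotation, embryos)
    smoothed, breakpoints = smooth_genotypes_hmm(calls, annotation, epsilon, transition)
    masked = mask_near_breakpoints(smoothed, calls, nvotes, breakpoints, annotation, min_votes)
    regions = build_marker_regions(masked, annotation, max_recombs=max_recombs)
    return masked, breakpoints, regions
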