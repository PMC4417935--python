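"""Expression QTL mapping on marker-region genotypes.

Expression is first residualised against known covariates (sex, sequencing
batch, somite count) plus the top principal factors of the residual matrix —
a linear stand-in for factor-based normalisers that absorbs unknown batch
structure while leaving genotype signal (which is not a dominant global
factor in a backcross) intact.  Each gene is then tested against every marker
region with a two-sided Wilcoxon rank-sum test comparing heterozygous and
homozygous embryos; downstream analyses keep the most significant marker per
chromosome per gene, and false discovery rates come from embryo-label
permutations of the genotype matrix, which preserve the inter-gene expression
correlation structure.

cis is defined by chromosome identity: an eQTL is cis iff its marker region
lies on the same chromosome as the target gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HET, HOM, MarkerRegionSet


def normalize_expression(
    expr_rpm: pd.DataFrame,
    metadata: pd.DataFrame,
    k_hidden_factors: int = 5,
) -> pd.DataFrame:
    """Residualise log(RPM+1) on known covariates and k hidden factors.

    Missing somite counts are mean-imputed.  With ``k_hidden_factors = 0``
    and no covariate structure this reduces to per-gene centering.
    """
    embryos = expr_rpm.columns
    meta = metadata.reindex(embryos)
    if k_hidden_factors >= len(embryos):
        raise ValueError("k_hidden_factors must be smaller than the number of embryos")
    y = np.log(expr_rpm.to_numpy(dtype=float) + 1.0)

    cols = [np.ones(len(embryos))]
    sex = meta["sex"].map({"F": 1.0, "M": 0.0}).fillna(0.5).to_numpy()
    cols.append(sex)
    somites = meta["somites"].astype(float)
    somites = somites.fillna(somites.mean()).to_numpy()
    cols.append(somites - somites.mean())
    batches = pd.get_dummies(meta["batch"], drop_first=True, dtype=float)
    for c in batches.columns:
        cols.append(batches[c].to_numpy())
    x = np.column_stack(cols)

    proj = x @ np.linalg.pinv(x)
    resid = y - (proj @ y.T).T
    if k_hidden_factors > 0:
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        v = vt[:k_hidden_factors]  # embryo-space factors
        resid = resid - (resid @ v.T) @ v
    return pd.DataFrame(resid, index=expr_rpm.index, columns=embryos)


def encode_marker_genotypes(genotypes: pd.DataFrame) -> np.ndarray:
    """regions x embryos int8 codes: 1 het, 0 hom, -1 unknown."""
    codes = np.full(genotypes.shape, -1, dtype=np.int8)
    vals = genotypes.to_numpy()
    codes[vals == HET] = 1
    codes[vals == HOM] = 0
    return codes


def _tie_terms(values: np.ndarray) -> np.ndarray:
    """Per-row sum of t^3 - t over runs of tied values (0 when untied)."""
    s = np.sort(values, axis=1)
    tied_rows = np.nonzero((np.diff(s, axis=1) == 0).any(axis=1))[0]
    ts = np.zeros(values.shape[0])
    for i in tied_rows:
        _, counts = np.unique(s[i], return_counts=True)
        ts[i] = float((counts**3 - counts).sum())
    return ts


def ranksum_scan_matrix(
    expr: np.ndarray,
    marker_codes: np.ndarray,
    min_per_class: int = 5,
) -> np.ndarray:
    """Two-sided rank-sum p-value for every (gene, marker) pair.

    Normal approximation with tie correction and continuity correction
    (matching scipy's asymptotic Mann-Whitney).  Markers are grouped by their
    unknown-embryo pattern so expression is ranked once per pattern.  Entries
    where either genotype class has fewer than ``min_per_class`` embryos are
    NaN.
    """
    n_genes = expr.shape[0]
    n_regions = marker_codes.shape[0]
    p = np.full((n_genes, n_regions), np.nan)
    include = marker_codes >= 0
    patterns: dict[bytes, list[int]] = {}
    for r in range(n_regions):
        patterns.setdefault(include[r].tobytes(), []).append(r)
    for key, region_idx in patterns.items():
        inc = np.frombuffer(key, dtype=bool)
        n = int(inc.sum())
        if n < 2 * min_per_class:
            continue
        sub = expr[:, inc]
        ranks = stats.rankdata(sub, axis=1)
        ts = _tie_terms(sub)
        h = (marker_codes[np.ix_(region_idx, np.nonzero(inc)[0])] == 1).astype(float)
        n1 = h.sum(axis=1)
        n2 = n - n1
        valid = (n1 >= min_per_class) & (n2 >= min_per_class)
        if not valid.any():
            continue
        w = ranks @ h.T  # sum of het-group ranks, genes x regions_in_group
        u = w - n1[None, :] * (n1[None, :] + 1) / 2.0
        mu = n1 * n2 / 2.0
        var = n1[None, :] * n2[None, :] / 12.0 * ((n + 1) - ts[:, None] / (n * (n - 1)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (np.abs(u - mu[None, :]) - 0.5) / np.sqrt(var)
        pv = 2.0 * stats.norm.sf(np.clip(z, 0.0, None))
        pv = np.minimum(pv, 1.0)
        pv[:, ~valid] = np.nan
        p[:, region_idx] = pv
    return p


def best_marker_per_chromosome(
    pmat: np.ndarray,
    genes: pd.Index,
    gene_chrom: pd.Series,
    markers: MarkerRegionSet,
) -> pd.DataFrame:
    """Keep the most significant marker region per chromosome per gene."""
    marker_chrom = markers.regions["chrom"].to_numpy()
    region_ids = markers.regions.index.to_numpy()
    frames = []
    for chrom in pd.unique(marker_chrom):
        cols = np.nonzero(marker_chrom == chrom)[0]
        sub = pmat[:, cols]
        all_nan = np.isnan(sub).all(axis=1)
        filled = np.where(np.isnan(sub), np.inf, sub)
        arg = filled.argmin(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "marker": region_ids[cols[arg]],
                    "marker_chrom": chrom,
                    "p_value": sub[np.arange(len(genes)), arg],
                }
            )[~all_nan]
        )
    res = pd.concat(frames, ignore_index=True)
    res["gene_chrom"] = gene_chrom.reindex(res["gene"]).to_numpy()
    res["classification"] = np.where(res["gene_chrom"] == res["marker_chrom"], "cis", "trans")
    return res


def permute_marker_codes(marker_codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One global embryo-label permutation of the genotype matrix."""
    perm = rng.permutation(marker_codes.shape[1])
    return marker_codes[:, perm]


def permutation_q_values(observed_p: np.ndarray, permuted_p: list[np.ndarray]) -> np.ndarray:
    """Permutation FDR: q(p0) = mean permuted count at p<=p0 / observed count.

    Monotonized to be non-decreasing in p and clipped at 1.
    """
    obs = np.asarray(observed_p, dtype=float)
    order = np.argsort(obs)
    sorted_p = obs[order]
    n_perm = len(permuted_p)
    if n_perm == 0:
        raise ValueError("need at least one permutation")
    perm_all = np.sort(np.concatenate([np.asarray(p)[~np.isnan(p)] for p in permuted_p]))
    perm_counts = np.searchsorted(perm_all, sorted_p, side="right") / n_perm
    obs_counts = np.arange(1, len(sorted_p) + 1, dtype=float)
    ratio = perm_counts / obs_counts
    ratio = np.minimum.accumulate(ratio[::-1])[::-1]  # non-decreasing in p
    q = np.empty_like(obs)
    q[order] = np.minimum(ratio, 1.0)
    return q


def scan_eqtl(
    norm_expr: pd.DataFrame,
    markers: MarkerRegionSet,
    gene_chrom: pd.Series,
    min_per_class: int = 5,
    return_full: bool = False,
):
    """Rank-sum scan of every gene against every marker region.

    Returns the best-marker-per-chromosome table (one row per gene x
    chromosome with at least one testable marker), and optionally the full
    gene x marker p-value matrix needed by the hotspot analysis.
    """
    codes = encode_marker_genotypes(markers.genotypes.reindex(columns=norm_expr.columns))
    pmat = ranksum_scan_matrix(norm_expr.to_numpy(), codes, min_per_class)
    best = best_marker_per_chromosome(pmat, norm_expr.index, gene_chrom, markers)
    if return_full:
        return best, pmat
    return best


def map_eqtl(
    norm_expr: pd.DataFrame,
    markers: MarkerRegionSet,
    gene_chrom: pd.Series,
    n_permutations: int = 20,
    min_per_class: int = 5,
    rng: np.random.Generator | None = None,
    keep_full: bool = False,
    hotspot_threshold: float = 0.005,
):
    """Full eQTL analysis: scan, permutation FDR, cis/trans classification.

    Returns (results, perm_info) where results has one row per (gene, best
    marker on a chromosome) with q_value and classification.  With
    ``keep_full``, perm_info carries what the hotspot analysis needs: the
    observed gene x marker p-matrix and, per permutation, the per-marker
    counts of targets below ``hotspot_threshold``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    codes = encode_marker_genotypes(markers.genotypes.reindex(columns=norm_expr.columns))
    expr = norm_expr.to_numpy()
    pmat = ranksum_scan_matrix(expr, codes, min_per_class)
    best = best_marker_per_chromosome(pmat, norm_expr.index, gene_chrom, markers)
    perm_best = []
    null_counts = []
    for _ in range(n_permutations):
        perm_codes = permute_marker_codes(codes, rng)
        perm_pmat = ranksum_scan_matrix(expr, perm_codes, min_per_class)
        pb = best_marker_per_chromosome(perm_pmat, norm_expr.index, gene_chrom, markers)
        perm_best.append(pb["p_value"].to_numpy())
        if keep_full:
            null_counts.append(hotspot_counts(perm_pmat, hotspot_threshold))
    best["q_value"] = permutation_q_values(best["p_value"].to_numpy(), perm_best)
    perm_info = (
        {"pmat": pmat, "null_counts": null_counts, "hotspot_threshold": hotspot_threshold}
        if keep_full
        else None
    )
    return best, perm_info


def classify_cis_trans(results: pd.DataFrame, q_cutoffs=(0.01, 0.05, 0.1, 0.2)) -> pd.DataFrame:
    """cis / trans counts and trans fraction as a function of FDR cutoff."""
    rows = []
    for q in q_cutoffs:
        called = results[results["q_value"] < q]
        n_cis = int((called["classification"] == "cis").sum())
        n_trans = int((called["classification"] == "trans").sum())
        total = n_cis + n_trans
        rows.append(
            {
                "q_cutoff": q,
                "n_eqtl": total,
                "n_cis": n_cis,
                "n_trans": n_trans,
                "trans_fraction": n_trans / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows)


def hotspot_counts(pmat: np.ndarray, threshold: float = 0.005) -> np.ndarray:
    """Per-marker count of target genes with p below ``threshold``."""
    with np.errstate(invalid="ignore"):
        return np.nansum(pmat < threshold, axis=0).astype(float)


def test_hotspots(
    pmat: np.ndarray,
    null_counts: list[np.ndarray],
    threshold: float = 0.005,
    marker_mask: np.ndarray | None = None,
) -> dict:
    """Trans-hotspot test: are sub-threshold targets concentrated on markers?

    Counts target genes with p < ``threshold`` per marker region and compares
    the observed count distribution with the pooled permutation-null counts
    (per-marker counts from permuted scans) by a two-sample KS test.
    ``marker_mask`` restricts both distributions to a subset of markers
    (e.g. markers containing the strongest ASE genes).
    """
    obs = hotspot_counts(pmat, threshold)
    null = list(null_counts)
    if marker_mask is not None:
        obs = obs[marker_mask]
        null = [c[marker_mask] for c in null]
    pooled_null = np.concatenate(null)
    ks = stats.ks_2samp(obs, pooled_null, method="asymp")
    # The asymptotic KS p assumes independent counts, but adjacent markers
    # share genotypes, so it overstates significance.  A calibrated p treats
    # the observed scan and the permuted scans as exchangeable: each sample's
    # KS statistic is computed against the pool of all the others, and the
    # observed statistic is ranked among them.
    samples = [obs] + null
    ks_stats = []
    for i, s in enumerate(samples):
        rest = np.concatenate([x for j, x in enumerate(samples) if j != i])
        ks_stats.append(stats.ks_2samp(s, rest, method="asymp").statistic)
    calibrated_p = float(np.mean([k >= ks_stats[0] for k in ks_stats]))
    return {
        "counts": obs,
        "null_counts": pooled_null,
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "calibrated_p": calibrated_p,
    }


def markers_with_top_ase(
    markers: MarkerRegionSet, ase_effect: pd.Series, top_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask of marker regions containing a top-ASE gene.

    ``ase_effect`` is a per-gene effect size (|mean BAF - 0.5|); the top
    ``top_fraction`` of genes by effect define the marker subset.
    """
    effect = ase_effect.dropna()
    if effect.empty:
        return np.zeros(len(markers), dtype=bool)
    cutoff = effect.quantile(1.0 - top_fraction)
    top_genes = effect.index[effect >= cutoff]
    top_regions = set(markers.gene_to_region.reindex(top_genes).dropna())
    return markers.regions.index.isin(top_regions)


def ase_eqtl_concordance(
    expr_rpm: pd.DataFrame,
    genotypes: pd.DataFrame,
    votes: pd.DataFrame,
    min_per_class: int = 5,
    top_n: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Predict BAF from total expression by genotype class and compare to ASE.

    BAF_exp = mu_B6/B6 / (mu_B6/B6 + mu_B6/Cast) and BAF_pred =
    BAF_exp / (2 (1 - BAF_exp)) — the plug-in estimate of the B6 allele
    fraction under the two-genotype mean model; sampling noise in the means
    can push BAF_pred above 1.  Measured BAF pools votes over heterozygous
    embryos.  Returns per-gene records and Spearman correlations overall and
    for the ``top_n`` genes by allele-specific coverage.
    """
    geno = genotypes.reindex(columns=expr_rpm.columns)
    het = geno.to_numpy() == HET
    hom = geno.to_numpy() == HOM
    vals = expr_rpm.to_numpy()
    n_het = het.sum(axis=1)
    n_hom = hom.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mu_het = np.nanmean(np.where(het, vals, np.nan), axis=1)
        mu_hom = np.nanmean(np.where(hom, vals, np.nan), axis=1)

    v = votes.copy()
    gi = genotypes.index.get_indexer(v["gene"])
    ei = expr_rpm.columns.get_indexer(v["embryo"])
    valid = (gi >= 0) & (ei >= 0)
    v["het"] = False
    v.loc[valid, "het"] = het[gi[valid], ei[valid]]
    pooled = v[v["het"]].groupby("gene")[["b6_votes", "cast_votes"]].sum()
    informative = pooled["b6_votes"] + pooled["cast_votes"]
    baf_measured = (pooled["b6_votes"] / informative).reindex(expr_rpm.index)
    coverage = informative.reindex(expr_rpm.index).fillna(0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        baf_exp = mu_hom / (mu_hom + mu_het)
        baf_pred = np.where(baf_exp < 1.0, baf_exp / (2.0 * (1.0 - baf_exp)), np.nan)
    usable = (n_het >= min_per_class) & (n_hom >= min_per_class)
    records = pd.DataFrame(
        {
            "mu_hom": mu_hom,
            "mu_het": mu_het,
            "baf_exp": np.where(usable, baf_exp, np.nan),
            "baf_pred": np.where(usable, baf_pred, np.nan),
            "baf_measured": baf_measured,
            "allele_coverage": coverage,
        },
        index=expr_rpm.index,
    )
    ok = records["baf_pred"].notna() & records["baf_measured"].notna()
    stats_out = {"n": int(ok.sum()), "rho": np.nan, "rho_top": np.nan}
    if ok.sum() >= 3:
        stats_out["rho"] = float(
            stats.spearmanr(records.loc[ok, "baf_pred"], records.loc[ok, "baf_measured"])[0]
        )
        top = records[ok].nlargest(min(top_n, int(ok.sum())), "allele_coverage")
        if len(top) >= 3:
            stats_out["rho_top"] = float(stats.spearmanr(top["baf_pred"], top["baf_measured"])[0])
    return records, stats_out


def conservation_correlation(
    effect: pd.Series,
    scores: pd.Series,
    mean_expression: pd.Series,
    min_expression: float = 5.0,
    min_genes: int = 20,
) -> dict:
    """Spearman correlation of a per-gene constraint score with effect size.

    ``effect`` is -log10 eQTL p or |BAF - 0.5|; lowly expressed genes are
    removed first because their scores are systematically low.
    """
    keep = mean_expression.index[mean_expression >= min_expression]
    merged = pd.concat([effect, scores], axis=1, keys=["effect", "score"]).loc[
        effect.index.intersection(keep)
    ].dropna()
    if len(merged) < min_genes:
        raise ValueError(f"only {len(merged)} genes after filtering (need {min_genes})")
    rho, p = stats.spearmanr(merged["score"], merged["effect"])
    return {"rho": float(rho), "p": float(p), "n": int(len(merged))}
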