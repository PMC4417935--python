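"""Allele-specific expression, imprinting, and developmental-trend tests.

ASE is tested per gene on library-size-normalised paired allelic differences
across heterozygous embryos (F1 and N2 pooled).  Imprinting contrasts the two
reciprocal crosses: a parent-of-origin effect flips the biased allele between
the crosses, whereas a cis effect biases both crosses the same way.
Developmental trends correlate per-embryo BAF (or total expression) with
somite count, the morphological proxy for embryonic age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CAST_IS_MATERNAL, HET


def _het_votes(votes: pd.DataFrame, genotypes: pd.DataFrame | None) -> pd.DataFrame:
    """Restrict the vote table to embryos heterozygous at the gene.

    With ``genotypes`` None every row is kept (all-F1 input).  Vote rows for
    (gene, embryo) pairs missing from the genotype matrix are dropped.
    """
    if genotypes is None:
        return votes
    stacked = genotypes.stack()
    keep = stacked[stacked == HET]
    idx = pd.MultiIndex.from_frame(votes[["gene", "embryo"]])
    return votes[idx.isin(keep.index)]


def per_embryo_baf(votes: pd.DataFrame) -> pd.DataFrame:
    out = votes.copy()
    informative = out["b6_votes"] + out["cast_votes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["baf"] = np.where(informative > 0, out["b6_votes"] / informative, np.nan)
    out["informative_votes"] = informative
    return out


def test_ase(
    votes: pd.DataFrame,
    library_sizes: pd.Series,
    genotypes: pd.DataFrame | None = None,
    min_embryos: int = 3,
    alpha: float = 0.01,
    baf_window: tuple[float, float] = (0.45, 0.55),
) -> pd.DataFrame:
    """Paired t-test of library-normalised allelic differences against zero.

    Per heterozygous embryo, d = (cast_votes - b6_votes) / library_size x 1e6
    (the per-million scale used for expression).  Genes with fewer than
    ``min_embryos`` informative embryos are untested (NaN p, excluded from
    the Bonferroni denominator).  A significant gene needs Bonferroni
    p < ``alpha`` and a mean BAF outside the ``baf_window`` band — tiny but
    consistent imbalances inside the band are not called.
    """
    v = per_embryo_baf(_het_votes(votes, genotypes))
    v = v[v["informative_votes"] > 0].copy()
    v["d"] = (
        (v["cast_votes"] - v["b6_votes"]) / library_sizes.reindex(v["embryo"]).to_numpy() * 1e6
    )
    d_mat = v.pivot_table(index="gene", columns="embryo", values="d", aggfunc="first")
    baf_mat = v.pivot_table(index="gene", columns="embryo", values="baf", aggfunc="first")
    arr = d_mat.to_numpy()
    n = (~np.isnan(arr)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(arr, axis=1)
        sd = np.nanstd(arr, axis=1, ddof=1)
        t = mean / (sd / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1))
    p[np.isinf(t)] = 0.0
    p[np.isnan(t)] = np.nan
    untested = n < min_embryos
    t[untested] = np.nan
    p[untested] = np.nan
    res = pd.DataFrame(
        {
            "gene": d_mat.index,
            "mean_baf": baf_mat.reindex(d_mat.index).mean(axis=1).to_numpy(),
            "n_embryos": n,
            "t_statistic": t,
            "p_value": p,
        }
    )
    tested = res["p_value"].notna()
    n_tested = int(tested.sum())
    res["p_bonferroni"] = np.minimum(res["p_value"] * n_tested, 1.0)
    lo, hi = baf_window
    res["significant"] = (
        tested
        & (res["p_bonferroni"] < alpha)
        & ((res["mean_baf"] < lo) | (res["mean_baf"] > hi))
    )
    return res.set_index("gene")


def _binom_p(k: int, n: int, p0: float) -> float:
    """Two-sided binomial p; exact for small n, normal approximation above."""
    if n == 0:
        return np.nan
    if n <= 1000:
        return stats.binomtest(k, n, p0).pvalue
    sd = np.sqrt(n * p0 * (1 - p0))
    if sd == 0:
        return 1.0 if k == n * p0 else 0.0
    z = (abs(k - n * p0) - 0.5) / sd
    return float(2 * stats.norm.sf(max(z, 0.0)))


def test_imprinting(
    votes: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Reciprocal-cross binomial test for parent-of-origin expression.

    Votes are pooled within each cross direction (heterozygous embryos only).
    Each direction's pooled B6 vote count is tested against the gene's
    cross-pooled B6 fraction (which absorbs any cis effect); the reported p is
    the larger of the two per-direction p-values, so significance requires
    both crosses to deviate — and in opposite allele directions, the
    signature of imprinting.  cross_difference is BAF(B6-mother crosses)
    minus BAF(Cast- or F1-mother crosses): +1 for a fully maternally
    expressed gene, -1 for a fully paternally expressed one.
    """
    v = _het_votes(votes, genotypes).copy()
    cast_maternal = metadata["cross"].map(CAST_IS_MATERNAL)
    v["cast_maternal"] = cast_maternal.reindex(v["embryo"]).to_numpy()
    pooled = v.groupby(["gene", "cast_maternal"])[["b6_votes", "cast_votes"]].sum()
    rows = []
    for gene, sub in pooled.groupby(level="gene", sort=True):
        sub = sub.droplevel("gene")
        if set(sub.index) != {False, True}:
            continue  # untested: only one cross direction informative
        b6 = sub["b6_votes"]
        total = sub["b6_votes"] + sub["cast_votes"]
        if (total == 0).any():
            continue
        p0 = b6.sum() / total.sum()
        baf_b6_mother = b6[False] / total[False]  # B6 mother => Cast allele paternal
        baf_other = b6[True] / total[True]
        p_dir = [
            _binom_p(int(round(b6[d])), int(round(total[d])), p0) for d in (False, True)
        ]
        opposite = (baf_b6_mother - p0) * (baf_other - p0) < 0
        rows.append(
            (gene, baf_b6_mother, baf_other, baf_b6_mother - baf_other, max(p_dir), opposite)
        )
    res = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "baf_b6_mother",
            "baf_other_mother",
            "cross_difference",
            "p_value",
            "opposite_directions",
        ],
    )
    n_tested = len(res)
    res["p_bonferroni"] = np.minimum(res["p_value"] * max(n_tested, 1), 1.0)
    res["significant"] = (res["p_bonferroni"] < alpha) & res["opposite_directions"]
    return res.set_index("gene")


def _spearman_by_gene(values: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """Vectorised per-row Spearman correlation against one covariate.

    ``values`` is genes x embryos with NaN for missing; rho and the
    t-distribution p-value are computed per gene over its non-missing embryos.
    """
    rows = []
    cov = covariate
    for gene, row in values.iterrows():
        mask = row.notna() & cov.notna()
        n = int(mask.sum())
        x = row[mask]
        if n < 3 or x.nunique() < 2 or cov[mask].nunique() < 2:
            rows.append((gene, np.nan, np.nan, n))
            continue
        rho, p = stats.spearmanr(x, cov[mask])
        rows.append((gene, rho, p, n))
    return pd.DataFrame(rows, columns=["gene", "spearman_rho", "p_value", "n_embryos"]).set_index("gene")


def _add_q(res: pd.DataFrame, alpha: float) -> pd.DataFrame:
    tested = res["p_value"].notna()
    q = np.full(len(res), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(res.loc[tested, "p_value"], method="fdr_bh")[1]
    res["q_value"] = q
    res["significant"] = tested & (res["q_value"] < alpha)
    return res


def test_developmental_ase(
    votes: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    min_embryos: int = 10,
    min_distinct_somites: int = 5,
    alpha: float = 0.10,
) -> pd.DataFrame:
    """Spearman correlation of per-embryo BAF with somite count (BH q).

    Only genes with BAF defined in at least ``min_embryos`` heterozygous
    embryos spanning ``min_distinct_somites`` distinct somite counts are
    tested.
    """
    v = per_embryo_baf(_het_votes(votes, genotypes))
    v = v[v["informative_votes"] > 0]
    baf = v.pivot_table(index="gene", columns="embryo", values="baf", aggfunc="first")
    somites = metadata["somites"].reindex(baf.columns)
    enough = []
    for gene, row in baf.iterrows():
        m = row.notna() & somites.notna()
        enough.append(m.sum() >= min_embryos and somites[m].nunique() >= min_distinct_somites)
    res = _spearman_by_gene(baf[pd.Series(enough, index=baf.index)], somites)
    res.loc[~pd.Series(enough, index=baf.index), "p_value"] = np.nan
    return _add_q(res, alpha)


def test_developmental_expression(
    expr_rpm: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of total expression (RPM) with somite count.

    Caller is expected to pass only genes passing the expression filters.
    """
    somites = metadata["somites"].reindex(expr_rpm.columns)
    res = _spearman_by_gene(expr_rpm, somites)
    return _add_q(res, alpha)
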