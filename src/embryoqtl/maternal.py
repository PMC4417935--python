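"""Maternal genetic effects on embryonic expression.

The backcross gives N2 embryos genotypically distinct mothers (B6/B6 vs
B6/Cast F1) while every embryo carries B6 mitochondria, so a difference in
embryonic expression between maternal classes that survives the confound
battery reflects a genuine effect of the mother's nuclear genotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HET, HOM
from .report import summarize_change

CONFOUND_CHECKS = ("sex_restricted", "litter_averaged", "somite_stability", "imprinted_locus")


def _mwu(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) == 0 or len(b) == 0:
        return np.nan, np.nan
    if np.ptp(np.concatenate([a, b])) == 0:
        return len(a) * len(b) / 2.0, 1.0
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def test_maternal_effect(
    expr_rpm: pd.DataFrame,
    metadata: pd.DataFrame,
    min_per_class: int = 5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U on RPM between maternal genotype classes.

    Compares N2 embryos with B6/B6 mothers to those with F1 mothers,
    Bonferroni-corrected over the genes actually tested.  Effect sizes:
    fold_change = larger group mean / smaller group mean, percent_change =
    change from the F1-mother mean to the B6-mother mean.
    """
    n2 = metadata[metadata["generation"] == "N2"]
    b6_m = n2.index[n2["mother_class"] == "B6"]
    f1_m = n2.index[n2["mother_class"] == "F1"]
    b6_m = b6_m.intersection(expr_rpm.columns)
    f1_m = f1_m.intersection(expr_rpm.columns)
    if len(b6_m) < min_per_class or len(f1_m) < min_per_class:
        raise ValueError("a maternal class has too few embryos to test")
    a = expr_rpm[b6_m].to_numpy()
    b = expr_rpm[f1_m].to_numpy()
    rows = []
    for i, gene in enumerate(expr_rpm.index):
        u, p = _mwu(a[i], b[i])
        mean_b6, mean_f1 = a[i].mean(), b[i].mean()
        if mean_f1 > 0 and mean_b6 > 0:
            pct, fold = summarize_change(mean_f1, mean_b6)
        else:
            pct, fold = np.nan, np.nan
        rows.append((gene, mean_f1, mean_b6, fold, pct, u, p))
    res = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "mean_rpm_f1_mother",
            "mean_rpm_b6_mother",
            "fold_change",
            "percent_change",
            "U_statistic",
            "p_value",
        ],
    ).set_index("gene")
    tested = res["p_value"].notna()
    res["p_bonferroni"] = np.minimum(res["p_value"] * int(tested.sum()), 1.0)
    res["significant"] = tested & (res["p_bonferroni"] < alpha)
    return res


def _direction(expr_rpm_row: pd.Series, b6_m, f1_m) -> float:
    return np.sign(expr_rpm_row[b6_m].mean() - expr_rpm_row[f1_m].mean())


def check_confounds(
    results: pd.DataFrame,
    expr_rpm: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    imprinted_genes=(),
    min_per_class: int = 5,
    retest_alpha: float = 0.05,
) -> pd.DataFrame:
    """Confound battery for the significant maternal-effect genes.

    Four re-tests per gene; a flag is raised when the check *fails* (effect
    direction or significance is lost, or an alternative grouping explains the
    data better):

    - sex_restricted: Mann-Whitney repeated on female embryos only.
    - litter_averaged: litters replace embryos as the unit (litter-mean
      expression), removing litter-level pseudoreplication.
    - somite_stability: the effect direction must agree across somite
      tertiles (developmental-stage stability).
    - imprinted_locus: the maternal grouping must give a smaller
      Mann-Whitney p than grouping by embryonic genotype at each imprinted
      locus — otherwise the "maternal" effect is better explained as a trans
      effect downstream of an imprinted gene.

    Checks whose strata are too small come back NA (pd.NA).
    """
    n2 = metadata[metadata["generation"] == "N2"]
    n2 = n2.loc[n2.index.intersection(expr_rpm.columns)]
    b6_m = n2.index[n2["mother_class"] == "B6"]
    f1_m = n2.index[n2["mother_class"] == "F1"]
    sig_genes = results.index[results["significant"]]
    flags = pd.DataFrame(index=sig_genes, columns=list(CONFOUND_CHECKS), dtype=object)

    females = n2.index[n2["sex"] == "F"]
    litter_means = expr_rpm[n2.index].T.groupby(n2["litter"]).mean().T
    litter_class = n2.groupby("litter")["mother_class"].first()
    tertiles = pd.qcut(n2["somites"], 3, labels=False, duplicates="drop")

    for gene in sig_genes:
        row = expr_rpm.loc[gene]
        base_dir = _direction(row, b6_m, f1_m)

        fa = females.intersection(b6_m)
        fb = females.intersection(f1_m)
        if len(fa) < min_per_class or len(fb) < min_per_class:
            flags.loc[gene, "sex_restricted"] = pd.NA
        else:
            _, p = _mwu(row[fa].to_numpy(), row[fb].to_numpy())
            same_dir = _direction(row, fa, fb) == base_dir
            flags.loc[gene, "sex_restricted"] = not (same_dir and p < retest_alpha)

        la = litter_class.index[litter_class == "B6"]
        lb = litter_class.index[litter_class == "F1"]
        if len(la) < 3 or len(lb) < 3:
            flags.loc[gene, "litter_averaged"] = pd.NA
        else:
            lrow = litter_means.loc[gene]
            _, p = _mwu(lrow[la].to_numpy(), lrow[lb].to_numpy())
            same_dir = np.sign(lrow[la].mean() - lrow[lb].mean()) == base_dir
            flags.loc[gene, "litter_averaged"] = not (same_dir and p < retest_alpha)

        dirs = []
        for t in sorted(tertiles.dropna().unique()):
            stratum = n2.index[tertiles == t]
            sa, sb = stratum.intersection(b6_m), stratum.intersection(f1_m)
            if len(sa) >= min_per_class and len(sb) >= min_per_class:
                dirs.append(_direction(row, sa, sb))
        if not dirs:
            flags.loc[gene, "somite_stability"] = pd.NA
        else:
            flags.loc[gene, "somite_stability"] = any(d != base_dir for d in dirs)

        if genotypes is None or not len(imprinted_genes):
            flags.loc[gene, "imprinted_locus"] = pd.NA
        else:
            _, p_maternal = _mwu(row[b6_m].to_numpy(), row[f1_m].to_numpy())
            beaten = False
            for locus in imprinted_genes:
                if locus not in genotypes.index:
                    continue
                g = genotypes.loc[locus, n2.index]
                het = n2.index[(g == HET).to_numpy()]
                hom = n2.index[(g == HOM).to_numpy()]
                if len(het) < min_per_class or len(hom) < min_per_class:
                    continue
                _, p_locus = _mwu(row[het].to_numpy(), row[hom].to_numpy())
                if np.isfinite(p_locus) and p_locus < p_maternal:
                    beaten = True
                    break
            flags.loc[gene, "imprinted_locus"] = beaten
    return flags
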