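"""Normalization, rank-sum eQTL scan, permutation FDR, hotspots, concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryoqtl.datatypes import HET, HOM, MarkerRegionSet, SimulationTruth
from embryoqtl.eqtl import (
    ase_eqtl_concordance,
    best_marker_per_chromosome,
    classify_cis_trans,
    conservation_correlation,
    encode_marker_genotypes,
    hotspot_counts,
    map_eqtl,
    markers_with_top_ase,
    normalize_expression,
    permutation_q_values,
    ranksum_scan_matrix,
    scan_eqtl,
)
from embryoqtl.genotyping import build_marker_regions
from embryoqtl.simulate import SimulationConfig, make_annotation, simulate_dataset


def _markers(geno: pd.DataFrame, chroms) -> MarkerRegionSet:
    regions = pd.DataFrame(
        {
            "chrom": chroms,
            "start_gene": geno.index,
            "end_gene": geno.index,
            "n_genes": 1,
        },
        index=pd.Index(geno.index, name="region"),
    )
    return MarkerRegionSet(regions=regions, genotypes=geno, gene_to_region=pd.Series(geno.index, index=geno.index))


class TestNormalization:
    def _meta(self, n, seed=0, batches=1):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "generation": "N2",
                "cross": "B6xF1",
                "mother_class": "B6",
                "litter": "L0",
                "somites": rng.integers(42, 58, n),
                "batch": [f"lane{i % batches}" for i in range(n)],
                "sex": rng.choice(["F", "M"], n),
            },
            index=pd.Index([f"e{i}" for i in range(n)], name="embryo"),
        )

    def test_k0_no_covariates_reduces_to_centering(self):
        meta = self._meta(30)
        meta["sex"] = "F"
        meta["somites"] = 50
        rng = np.random.default_rng(1)
        rpm = pd.DataFrame(rng.lognormal(3, 1, (8, 30)), columns=meta.index)
        norm = normalize_expression(rpm, meta, k_hidden_factors=0)
        expected = np.log(rpm + 1).sub(np.log(rpm + 1).mean(axis=1), axis=0)
        assert np.allclose(norm, expected)

    def test_residuals_centered_and_orthogonal_to_covariates(self):
        meta = self._meta(60, batches=4)
        rng = np.random.default_rng(2)
        rpm = pd.DataFrame(rng.lognormal(3, 1, (20, 60)), columns=meta.index)
        norm = normalize_expression(rpm, meta, k_hidden_factors=2)
        assert np.allclose(norm.mean(axis=1), 0, atol=1e-10)
        som = meta["somites"] - meta["somites"].mean()
        assert np.allclose(norm @ som, 0, atol=1e-8)

    def test_batch_structure_removed(self):
        # multiplicative batch effects dominate raw expression; after
        # normalization the between-batch variance should nearly vanish
        cfg = SimulationConfig(
            n_autosomes=3, genes_per_chromosome=30, batch_sd=0.5, seed=21
        )
        d = simulate_dataset(cfg)
        meta = d.metadata
        n2 = meta.index[meta["generation"] == "N2"]
        logx = np.log(d.expression.rpm[n2] + 1)
        norm = normalize_expression(d.expression.rpm[n2], meta, k_hidden_factors=5)

        def between_batch_var(mat):
            grand = mat.mean(axis=1)
            out = 0.0
            for b, cols in meta.loc[n2].groupby("batch").groups.items():
                out += ((mat[cols].mean(axis=1) - grand) ** 2).mean()
            return out

        assert between_batch_var(norm) < 0.05 * between_batch_var(logx)

    def test_k_too_large_rejected(self):
        meta = self._meta(10)
        rpm = pd.DataFrame(np.ones((3, 10)), columns=meta.index)
        with pytest.raises(ValueError):
            normalize_expression(rpm, meta, k_hidden_factors=10)


class TestRanksumScan:
    def test_matches_scipy_mannwhitney(self):
        rng = np.random.default_rng(3)
        expr = rng.normal(size=(12, 40))
        codes = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        codes[0, :5] = -1  # an unknown-embryo pattern
        p = ranksum_scan_matrix(expr, codes, min_per_class=5)
        for r in range(codes.shape[0]):
            inc = codes[r] >= 0
            het = codes[r] == 1
            for g in range(expr.shape[0]):
                a, b = expr[g, het], expr[g, inc & (codes[r] == 0)]
                if min(len(a), len(b)) < 5:
                    assert np.isnan(p[g, r])
                    continue
                ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
                assert p[g, r] == pytest.approx(ref, rel=1e-9)

    def test_handles_ties_like_scipy(self):
        rng = np.random.default_rng(4)
        expr = rng.integers(0, 4, size=(5, 30)).astype(float)  # heavy ties
        codes = rng.integers(0, 2, size=(3, 30)).astype(np.int8)
        p = ranksum_scan_matrix(expr, codes, min_per_class=5)
        for r in range(3):
            for g in range(5):
                a, b = expr[g, codes[r] == 1], expr[g, codes[r] == 0]
                if min(len(a), len(b)) < 5 or np.ptp(expr[g]) == 0:
                    continue
                ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
                assert p[g, r] == pytest.approx(ref, rel=1e-9)

    def test_best_marker_is_minimum_over_chromosome(self):
        rng = np.random.default_rng(5)
        genes = pd.Index([f"g{i}" for i in range(6)], name="gene")
        geno = pd.DataFrame(
            rng.choice([HET, HOM], size=(8, 30)),
            index=pd.Index([f"m{i}" for i in range(8)], name="region"),
            columns=[f"e{i}" for i in range(30)],
        )
        markers = _markers(geno, ["chr1"] * 5 + ["chr2"] * 3)
        expr = pd.DataFrame(rng.normal(size=(6, 30)), index=genes, columns=geno.columns)
        gene_chrom = pd.Series("chr1", index=genes)
        best, pmat = scan_eqtl(expr, markers, gene_chrom, return_full=True)
        for _, row in best.iterrows():
            g = genes.get_loc(row["gene"])
            cols = np.nonzero(markers.regions["chrom"].to_numpy() == row["marker_chrom"])[0]
            assert row["p_value"] == pytest.approx(np.nanmin(pmat[g, cols]))

    def test_cis_trans_partition_exhaustive_and_exclusive(self):
        res = pd.DataFrame(
            {
                "gene_chrom": ["chr1", "chr2", "chr2"],
                "marker_chrom": ["chr1", "chr14", "chr2"],
                "q_value": [0.001, 0.001, 0.5],
                "classification": ["cis", "trans", "cis"],
            }
        )
        table = classify_cis_trans(res)
        at_01 = table[table["q_cutoff"] == 0.01].iloc[0]
        assert at_01["n_cis"] == 1 and at_01["n_trans"] == 1
        assert (table["n_cis"] + table["n_trans"] == table["n_eqtl"]).all()


class TestPermutationFdr:
    def test_q_monotone_in_p_and_order_invariant(self):
        rng = np.random.default_rng(6)
        obs = rng.uniform(size=300)
        perms = [rng.uniform(size=300) for _ in range(10)]
        q = permutation_q_values(obs, perms)
        order = np.argsort(obs)
        assert (np.diff(q[order]) >= -1e-12).all()
        shuffle = rng.permutation(300)
        q2 = permutation_q_values(obs[shuffle], perms)
        assert np.allclose(q2, q[shuffle])

    def test_null_yields_q_near_one(self):
        rng = np.random.default_rng(7)
        obs = rng.uniform(size=500)
        perms = [rng.uniform(size=500) for _ in range(20)]
        q = permutation_q_values(obs, perms)
        assert (q < 0.01).sum() == 0


class TestConcordance:
    def _toy(self, mu_hom, mu_het, baf_measured=0.5, n=20):
        embryos = [f"e{i}" for i in range(2 * n)]
        genes = pd.Index(["g1"], name="gene")
        geno = pd.DataFrame([[HOM] * n + [HET] * n], index=genes, columns=embryos)
        rpm = pd.DataFrame([[mu_hom] * n + [mu_het] * n], index=genes, columns=embryos)
        b6 = baf_measured * 100
        votes = pd.DataFrame(
            {
                "gene": ["g1"] * n,
                "embryo": embryos[n:],
                "b6_votes": [b6] * n,
                "cast_votes": [100 - b6] * n,
                "other_votes": [0.0] * n,
                "snp_read_count": [100] * n,
            }
        )
        return rpm, geno, votes

    @pytest.mark.parametrize(
        "mu_hom, mu_het, expected_pred",
        [
            (100.0, 100.0, 0.5),  # no cis effect
            (100.0, 50.0, 1.0),  # Cast allele silent
            (100.0, 40.0, 100 / 140 / (2 * (1 - 100 / 140))),  # baf_exp > 2/3 -> pred > 1
        ],
    )
    def test_baf_pred_formula(self, mu_hom, mu_het, expected_pred):
        rpm, geno, votes = self._toy(mu_hom, mu_het)
        records, _ = ase_eqtl_concordance(rpm, geno, votes)
        assert records.loc["g1", "baf_pred"] == pytest.approx(expected_pred)
        if mu_hom / (mu_hom + mu_het) > 2 / 3:
            assert records.loc["g1", "baf_pred"] > 1.0

    def test_baf_exp_one_gives_na(self):
        rpm, geno, votes = self._toy(100.0, 0.0)
        records, _ = ase_eqtl_concordance(rpm, geno, votes)
        assert np.isnan(records.loc["g1", "baf_pred"])

    def test_prediction_tracks_truth_on_simulation(self):
        cfg = SimulationConfig(
            n_autosomes=4, genes_per_chromosome=50, seed=31,
            snp_read_fraction=0.8, library_size_log_mean=14.5,
        )
        ann = make_annotation(cfg)
        rng = np.random.default_rng(8)
        folds = np.exp(rng.normal(0, 0.6, len(ann)))
        truth = SimulationTruth(cis_fold={g: float(f) for g, f in zip(ann.index, folds)})
        d = simulate_dataset(cfg, truth)
        n2 = d.metadata.index[d.metadata["generation"] == "N2"]
        records, out = ase_eqtl_concordance(
            d.expression.rpm[n2], d.genotypes[n2], d.votes[d.votes["embryo"].isin(n2)]
        )
        true_baf = pd.Series({g: 1 / (1 + f) for g, f in truth.cis_fold.items()})
        ok = records["baf_pred"].notna()
        rho_pred = stats.spearmanr(records.loc[ok, "baf_pred"], true_baf[ok])[0]
        rho_exp = stats.spearmanr(records.loc[ok, "baf_exp"], true_baf[ok])[0]
        assert out["rho"] > 0.8
        # the transformation is calibrated: predicting BAF is at least as good
        # as the untransformed expression ratio
        assert rho_pred >= rho_exp - 0.01


class TestConservation:
    def test_independent_scores_rho_near_zero(self):
        rng = np.random.default_rng(9)
        genes = pd.Index([f"g{i}" for i in range(2000)])
        effect = pd.Series(rng.uniform(0, 0.5, 2000), index=genes)
        scores = pd.Series(rng.normal(0, 1, 2000), index=genes)
        expr = pd.Series(100.0, index=genes)
        out = conservation_correlation(effect, scores, expr)
        assert abs(out["rho"]) < 0.06

    def test_recovers_simulated_negative_coupling(self):
        rng = np.random.default_rng(10)
        n = 2800
        genes = pd.Index([f"g{i}" for i in range(n)])
        z = rng.normal(size=n)
        target_rho = -0.15
        # build score negatively coupled to effect with the desired rank corr
        effect = pd.Series(stats.norm.cdf(z), index=genes)
        noise = rng.normal(size=n)
        lam = 0.152  # corr(z, -lam z + sqrt(1-lam^2) e) ~ -0.15 after ranks
        scores = pd.Series(-lam * z + np.sqrt(1 - lam**2) * noise, index=genes)
        expr = pd.Series(100.0, index=genes)
        out = conservation_correlation(effect, scores, expr)
        assert out["rho"] == pytest.approx(target_rho, abs=0.05)
        assert out["rho"] < 0

    def test_too_few_genes_rejected(self):
        genes = pd.Index([f"g{i}" for i in range(10)])
        with pytest.raises(ValueError):
            conservation_correlation(
                pd.Series(1.0, index=genes), pd.Series(1.0, index=genes), pd.Series(100.0, index=genes)
            )


class TestHotspots:
    def test_count_conservation(self):
        rng = np.random.default_rng(11)
        pmat = rng.uniform(size=(200, 40))
        pmat[rng.uniform(size=pmat.shape) < 0.05] = np.nan
        counts = hotspot_counts(pmat, 0.005)
        with np.errstate(invalid="ignore"):
            assert counts.sum() == np.nansum(pmat < 0.005)

    def test_marker_subset_by_ase_effect(self):
        geno = pd.DataFrame(
            [[HET, HOM]] * 4,
            index=pd.Index([f"m{i}" for i in range(4)], name="region"),
            columns=["e1", "e2"],
        )
        markers = _markers(geno, ["chr1"] * 4)
        markers.gene_to_region[:] = ["m0", "m1", "m2", "m3"]
        effect = pd.Series([0.4, 0.3, 0.01, 0.02], index=markers.gene_to_region.index)
        mask = markers_with_top_ase(markers, effect, top_fraction=0.5)
        assert list(mask) == [True, True, False, False]
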