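"""ASE paired test, imprinting contrast, developmental trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryoqtl.ase import test_ase as run_ase
from embryoqtl.ase import test_developmental_ase as run_dev_ase
from embryoqtl.ase import test_developmental_expression as run_dev_expr
from embryoqtl.ase import test_imprinting as run_imprinting
from embryoqtl.datatypes import HET


def _votes(rows):
    return pd.DataFrame(rows, columns=["gene", "embryo", "b6_votes", "cast_votes", "other_votes", "snp_read_count"])


def _lib(embryos, size=1_000_000):
    return pd.Series(size, index=pd.Index(embryos, name="embryo"), dtype=float)


class TestAse:
    def test_balanced_votes_not_significant(self):
        rows = [("g1", f"e{i}", 50.0, 50.0, 0.0, 100) for i in range(20)]
        res = run_ase(_votes(rows), _lib([f"e{i}" for i in range(20)]))
        assert res.loc["g1", "p_value"] == 1.0
        assert not res.loc["g1", "significant"]

    def test_baf_window_excludes_small_shifts(self):
        # consistent but tiny imbalance: p is small, mean BAF 0.52 inside the
        # window, so the gene must not be called
        rng = np.random.default_rng(0)
        rows = [("g1", f"e{i}", 520 + rng.integers(0, 3), 480.0, 0.0, 1000) for i in range(100)]
        res = run_ase(_votes(rows), _lib([f"e{i}" for i in range(100)]))
        assert res.loc["g1", "p_bonferroni"] < 0.01
        assert 0.45 < res.loc["g1", "mean_baf"] < 0.55
        assert not res.loc["g1", "significant"]

    def test_too_few_embryos_untested(self):
        rows = [("g1", "e1", 10.0, 0.0, 0.0, 10), ("g1", "e2", 10.0, 0.0, 0.0, 10)]
        res = run_ase(_votes(rows), _lib(["e1", "e2"]))
        assert np.isnan(res.loc["g1", "p_value"])

    def test_detects_simulated_cis_effect(self, effect_dataset, effect_truth):
        res = run_ase(
            effect_dataset.votes,
            effect_dataset.expression.library_size,
            genotypes=effect_dataset.genotypes,
        )
        cis = list(effect_truth.cis_fold)
        assert res.loc[cis, "significant"].mean() > 0.9
        # true BAF 1/3 at fold 2
        assert res.loc[cis, "mean_baf"].mean() == pytest.approx(1 / 3, abs=0.03)

    def test_null_pvalues_uniform(self, null_dataset):
        res = run_ase(
            null_dataset.votes,
            null_dataset.expression.library_size,
            genotypes=null_dataset.genotypes,
        )
        p = res["p_value"].dropna()
        assert len(p) > 50
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_t_pvalue_not_anticonservative_vs_sign_flip(self, null_dataset):
        # the paired t-test should be conservative or equal relative to a
        # sign-flip permutation reference on null data
        res = run_ase(
            null_dataset.votes,
            null_dataset.expression.library_size,
            genotypes=null_dataset.genotypes,
        )
        v = null_dataset.votes.copy()
        lib = null_dataset.expression.library_size
        het = null_dataset.genotypes.stack() == HET
        idx = pd.MultiIndex.from_frame(v[["gene", "embryo"]])
        v = v[idx.isin(het[het].index)]
        v["d"] = (v["cast_votes"] - v["b6_votes"]) / lib.reindex(v["embryo"]).to_numpy() * 1e6
        rng = np.random.default_rng(11)
        n_flips = 400
        pairs = []
        for gene, sub in v.groupby("gene"):
            if len(sub) < 10 or len(pairs) >= 40:
                continue
            d = sub["d"].to_numpy()
            t_obs = abs(d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))
            signs = rng.choice([-1.0, 1.0], size=(n_flips, len(d)))
            flipped = signs * d
            t_perm = np.abs(flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(len(d))))
            p_perm = (1 + (t_perm >= t_obs).sum()) / (n_flips + 1)
            pairs.append((res.loc[gene, "p_value"], p_perm))
        assert len(pairs) >= 10
        p_t, p_perm = np.array(pairs).T
        # the two p-values track each other closely ...
        assert stats.spearmanr(p_t, p_perm)[0] > 0.9
        # ... the t-test never claims significance the resampling denies ...
        assert not ((p_t < 0.01) & (p_perm > 0.05)).any()
        # ... and is not systematically anticonservative
        assert np.median(p_t - p_perm) > -0.05


class TestImprinting:
    def _meta(self, crosses):
        return pd.DataFrame(
            {"cross": crosses}, index=pd.Index([f"e{i}" for i in range(len(crosses))], name="embryo")
        )

    def test_balanced_in_both_crosses_not_significant(self):
        rows = [("g1", f"e{i}", 500.0, 500.0, 0.0, 1000) for i in range(10)]
        meta = self._meta(["B6xCast"] * 5 + ["CastxB6"] * 5)
        res = run_imprinting(_votes(rows), meta)
        assert not res.loc["g1", "significant"]

    def test_cis_effect_alone_not_imprinting(self):
        # BAF 0.3 in both cross directions: strong ASE, no parent-of-origin signal
        rows = [("g1", f"e{i}", 300.0, 700.0, 0.0, 1000) for i in range(10)]
        meta = self._meta(["B6xCast"] * 5 + ["CastxB6"] * 5)
        res = run_imprinting(_votes(rows), meta)
        assert not res.loc["g1", "significant"]
        assert res.loc["g1", "cross_difference"] == pytest.approx(0.0, abs=1e-9)

    def test_fully_maternal_gene_detected(self):
        # maternal expression: B6-mother embryos show only B6 reads, Cast-mother
        # embryos only Cast reads -> cross_difference +1
        rows = [("g1", f"e{i}", 500.0, 0.0, 0.0, 500) for i in range(5)]
        rows += [("g1", f"e{i+5}", 0.0, 500.0, 0.0, 500) for i in range(5)]
        meta = self._meta(["B6xCast"] * 5 + ["CastxB6"] * 5)
        res = run_imprinting(_votes(rows), meta)
        assert res.loc["g1", "significant"]
        assert res.loc["g1", "cross_difference"] == pytest.approx(1.0)

    def test_single_direction_untested(self):
        rows = [("g1", f"e{i}", 500.0, 0.0, 0.0, 500) for i in range(5)]
        meta = self._meta(["B6xCast"] * 5)
        res = run_imprinting(_votes(rows), meta)
        assert "g1" not in res.index

    def test_simulation_truth_recovered(self, effect_dataset, effect_truth):
        res = run_imprinting(
            effect_dataset.votes, effect_dataset.metadata, genotypes=effect_dataset.genotypes
        )
        imprinted = [g for g in effect_truth.imprinted if g in res.index]
        assert res.loc[imprinted, "significant"].all()
        # signs follow the silenced parent
        for g in imprinted:
            origin, _ = effect_truth.imprinted[g]
            expected_sign = 1.0 if origin == "paternal" else -1.0
            assert np.sign(res.loc[g, "cross_difference"]) == expected_sign
        # pure cis genes are never called imprinted
        cis_only = [g for g in effect_truth.cis_fold if g in res.index]
        assert not res.loc[cis_only, "significant"].any()

    def test_f1_n2_baf_estimates_correlate(self):
        # widespread cis variation of varying strength: the per-gene mean BAF
        # measured in deep F1 data must track the estimate from many shallow
        # N2 embryos
        from embryoqtl.ase import per_embryo_baf, _het_votes
        from embryoqtl.datatypes import SimulationTruth
        from embryoqtl.simulate import SimulationConfig, make_annotation, simulate_dataset

        cfg = SimulationConfig(n_autosomes=4, genes_per_chromosome=30, seed=71)
        ann = make_annotation(cfg)
        rng = np.random.default_rng(5)
        folds = np.exp(rng.normal(0.0, 0.5, len(ann)))
        truth = SimulationTruth(cis_fold={g: float(f) for g, f in zip(ann.index, folds)})
        d = simulate_dataset(cfg, truth)
        v = per_embryo_baf(_het_votes(d.votes, d.genotypes))
        v = v[v["informative_votes"] > 0]
        gen = d.metadata["generation"].reindex(v["embryo"]).to_numpy()
        f1 = v[gen == "F1"].groupby("gene")["baf"].mean()
        n2 = v[gen == "N2"].groupby("gene")["baf"].mean()
        joined = pd.concat([f1, n2], axis=1, keys=["f1", "n2"]).dropna()
        rho = stats.spearmanr(joined["f1"], joined["n2"])[0]
        assert rho > 0.7  # qualitative agreement between the two estimates


class TestDevelopmental:
    def _setup(self, slope=0.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        embryos = [f"e{i}" for i in range(n)]
        somites = rng.integers(42, 58, n)
        meta = pd.DataFrame({"somites": somites}, index=pd.Index(embryos, name="embryo"))
        baf = np.clip(0.5 + slope * (somites - 50) + rng.normal(0, 0.03, n), 0.01, 0.99)
        depth = 500
        rows = [
            ("g1", e, float(np.round(b * depth)), float(depth - np.round(b * depth)), 0.0, depth)
            for e, b in zip(embryos, baf)
        ]
        return _votes(rows), meta

    def test_monotone_baf_gives_rho_one(self):
        embryos = [f"e{i}" for i in range(12)]
        meta = pd.DataFrame({"somites": np.arange(42, 54)}, index=pd.Index(embryos, name="embryo"))
        rows = [
            ("g1", e, float(100 + 10 * i), float(100 - 5 * i), 0.0, 300)
            for i, e in enumerate(embryos)
        ]
        res = run_dev_ase(_votes(rows), meta)
        assert res.loc["g1", "spearman_rho"] == pytest.approx(1.0)

    def test_slope_detected(self):
        votes, meta = self._setup(slope=0.02)
        res = run_dev_ase(votes, meta)
        assert res.loc["g1", "significant"]

    def test_permuted_somites_rarely_called(self):
        # shuffling somite labels destroys the trend; across many genes the
        # BH-significant fraction stays at or below the nominal q level
        rng = np.random.default_rng(2)
        frames = []
        for g in range(40):
            votes, meta = self._setup(slope=0.02, seed=100 + g)
            votes["gene"] = f"g{g}"
            frames.append(votes)
        all_votes = pd.concat(frames, ignore_index=True)
        meta_perm = meta.copy()
        meta_perm["somites"] = rng.permutation(meta["somites"].to_numpy())
        res = run_dev_ase(all_votes, meta_perm)
        assert res["significant"].mean() <= 0.10

    def test_expression_trend_recovered(self, effect_dataset, effect_truth):
        res = run_dev_expr(
            effect_dataset.expression.rpm, effect_dataset.metadata
        )
        trend_genes = list(effect_truth.somite_slope_expr)
        assert res.loc[trend_genes, "significant"].all()
        flat = res.drop(index=trend_genes + list(effect_truth.somite_slope_allele))
        # BH at q<0.05 on mostly-null genes yields few calls
        assert flat["significant"].mean() < 0.02

    def test_allelic_trend_recovered(self, effect_dataset, effect_truth):
        res = run_dev_ase(
            effect_dataset.votes, effect_dataset.metadata, genotypes=effect_dataset.genotypes
        )
        trend = [g for g in effect_truth.somite_slope_allele if g in res.index]
        assert res.loc[trend, "significant"].mean() >= 0.75
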