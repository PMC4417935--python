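"""End-to-end orchestration of the synthetic backcross analysis.

Stages run in dependency order: simulate -> genotype -> ASE / imprinting /
developmental -> maternal -> eQTL -> report.  A run is fully specified by
(config, seed); identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import eqtl as eqtl_mod
from . import genotyping, maternal, simulate
from .datatypes import SimulationTruth
from .io import (
    write_bed12,
    write_expression,
    write_marker_regions,
    write_matrix,
    write_snp_vcf,
    write_truth,
    write_votes,
)
from .report import summarize_proportion

log = logging.getLogger("embryoqtl")


def run_pipeline(
    config: simulate.SimulationConfig,
    truth: SimulationTruth | None = None,
    out_dir: str | Path | None = None,
    n_permutations: int = 20,
    k_hidden_factors: int = 5,
    use_true_genotypes: bool = False,
    stages: tuple = ("simulate", "genotype", "ase", "maternal", "eqtl", "report"),
) -> dict:
    """Run the synthetic pipeline and return all stage results.

    ``use_true_genotypes`` skips HMM genotyping and builds marker regions
    from the simulator's true genotypes (useful for calibration studies that
    are not about genotyping accuracy).
    """
    t0 = time.time()
    results: dict = {"config": asdict(config)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**16 + 1]))

    log.info("simulate: seed=%s", config.seed)
    data = simulate.simulate_dataset(config, truth, with_snp_table=out_dir is not None)
    results["data"] = data
    meta = data.metadata
    rpm = data.expression.rpm

    if "genotype" in stages:
        n2 = meta.index[meta["generation"] == "N2"]
        if use_true_genotypes:
            genotype_matrix = data.genotypes[n2]
            markers = genotyping.build_marker_regions(genotype_matrix, data.annotation)
            breakpoints = pd.DataFrame(columns=["embryo", "chrom", "left_gene", "right_gene"])
        else:
            n2_votes = data.votes[data.votes["embryo"].isin(n2)]
            genotype_matrix, breakpoints, markers = genotyping.genotype_pipeline(
                n2_votes, data.annotation, n2
            )
        results["genotypes"] = genotype_matrix
        results["breakpoints"] = breakpoints
        results["markers"] = markers
        log.info("genotype: %d marker regions", len(markers))

    true_geno_all = data.genotypes  # het/hom status for vote selection

    if "ase" in stages:
        results["ase"] = ase_mod.test_ase(
            data.votes, data.expression.library_size, genotypes=true_geno_all
        )
        results["imprinting"] = ase_mod.test_imprinting(data.votes, meta, genotypes=true_geno_all)
        results["developmental_ase"] = ase_mod.test_developmental_ase(
            data.votes, meta, genotypes=true_geno_all
        )
        results["developmental_expression"] = ase_mod.test_developmental_expression(rpm, meta)
        log.info(
            "ase: %d significant of %d",
            int(results["ase"]["significant"].sum()),
            len(results["ase"]),
        )

    if "maternal" in stages:
        results["maternal"] = maternal.test_maternal_effect(rpm, meta)
        imprinted_genes = [
            g for g in results.get("imprinting", pd.DataFrame()).index
            if "imprinting" in results and results["imprinting"].loc[g, "significant"]
        ]
        results["maternal_confounds"] = maternal.check_confounds(
            results["maternal"], rpm, meta,
            genotypes=results.get("genotypes"), imprinted_genes=imprinted_genes,
        )

    if "eqtl" in stages:
        if "markers" not in results:
            raise RuntimeError("eqtl stage requires the genotype stage (marker regions missing)")
        n2 = meta.index[meta["generation"] == "N2"]
        norm = eqtl_mod.normalize_expression(rpm[n2], meta, k_hidden_factors=k_hidden_factors)
        best, perm_info = eqtl_mod.map_eqtl(
            norm,
            results["markers"],
            data.annotation["chrom"],
            n_permutations=n_permutations,
            rng=rng,
            keep_full=True,
        )
        results["eqtl"] = best
        results["eqtl_by_cutoff"] = eqtl_mod.classify_cis_trans(best)
        results["hotspots"] = eqtl_mod.test_hotspots(
            perm_info["pmat"], perm_info["null_counts"]
        )
        results["concordance_records"], results["concordance"] = eqtl_mod.ase_eqtl_concordance(
            rpm[n2], data.genotypes[n2], data.votes[data.votes["embryo"].isin(n2)]
        )

    if "report" in stages:
        results["report"] = build_report(results)
        results["report"]["runtime_s"] = round(time.time() - t0, 2)

    if out_dir is not None:
        write_outputs(results, Path(out_dir))
    return results


def build_report(results: dict) -> dict:
    """Per-stage counts and derived percentages."""
    rep: dict = {"seed": results["config"]["seed"]}
    if "ase" in results:
        ase = results["ase"]
        tested = int(ase["p_value"].notna().sum())
        sig = int(ase["significant"].sum())
        rep["ase"] = {
            "tested": tested,
            "significant": sig,
            "percent": summarize_proportion(sig, tested) if tested else None,
        }
        imp = results["imprinting"]
        rep["imprinting"] = {"tested": len(imp), "significant": int(imp["significant"].sum())}
    if "maternal" in results:
        mat = results["maternal"]
        rep["maternal"] = {
            "tested": int(mat["p_value"].notna().sum()),
            "significant": int(mat["significant"].sum()),
        }
    if "markers" in results:
        rep["marker_regions"] = len(results["markers"])
    if "eqtl" in results:
        called = results["eqtl"][results["eqtl"]["q_value"] < 0.01]
        n_cis = int((called["classification"] == "cis").sum())
        rep["eqtl"] = {
            "significant_q01": len(called),
            "cis": n_cis,
            "trans": len(called) - n_cis,
            "percent_cis": summarize_proportion(n_cis, len(called)) if len(called) else None,
        }
        rep["concordance_rho"] = results["concordance"]["rho"]
        rep["hotspot_ks_p"] = results["hotspots"]["ks_p"]
    return rep


def write_outputs(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    data = results["data"]
    if len(data.snp_table):
        write_snp_vcf(data.snp_table, out_dir / "snps.vcf")
    write_bed12(data.annotation, out_dir / "genes.bed")
    data.metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index_label="embryo")
    write_expression(data.expression, out_dir / "counts.tsv", out_dir / "library_sizes.tsv")
    write_votes(data.votes, out_dir / "votes.tsv")
    write_truth(data.truth, out_dir / "truth.json")
    simulate.truth_to_records(data.truth).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    if "genotypes" in results:
        write_matrix(results["genotypes"], out_dir / "genotypes.tsv")
        results["breakpoints"].to_csv(out_dir / "breakpoints.tsv", sep="\t", index=False)
        write_marker_regions(
            results["markers"], out_dir / "marker_regions.tsv", out_dir / "marker_genotypes.tsv"
        )
    for key, name in [
        ("ase", "ase_results.tsv"),
        ("imprinting", "imprinting_results.tsv"),
        ("developmental_ase", "developmental_ase.tsv"),
        ("developmental_expression", "developmental_expression.tsv"),
        ("maternal", "maternal_effects.tsv"),
        ("maternal_confounds", "maternal_confounds.tsv"),
        ("eqtl", "eqtl_results.tsv"),
        ("eqtl_by_cutoff", "eqtl_by_cutoff.tsv"),
        ("concordance_records", "concordance.tsv"),
    ]:
        if key in results:
            df = results[key]
            df.to_csv(out_dir / name, sep="\t", index=not isinstance(df.index, pd.RangeIndex))
    if "report" in results:
        (out_dir / "report.json").write_text(json.dumps(results["report"], indent=1, default=str))
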