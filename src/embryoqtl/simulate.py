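"""Synthetic two-strain backcross generator.

Emulates the study design the analysis assumes: reciprocal F1 crosses between
B6 and Cast plus N2 embryos from backcrossing (B6xCast) F1 mice to B6, profiled
with a 3'-biased RNA-seq protocol.  Produces gene-level counts with
library-size, batch and developmental-stage structure, binomially sampled
allele-specific read votes, and a ground-truth ledger of cis, maternal,
imprinting, somite-trend and hotspot effects for parameter-recovery tests.

The crossover model is Poisson: per F1 gamete and chromosome, the number of
crossovers is Poisson(map length in Morgans) with breakpoints placed uniformly
along the chromosome and no interference.  Counts are negative binomial
(gamma-Poisson) with a common dispersion; dispersion 0 degenerates to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CAST_IS_MATERNAL,
    HET,
    HOM,
    MOTHER_CLASS,
    ExpressionMatrix,
    SimulationTruth,
)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Sample sizes default to the real design: 8 F1 embryos per reciprocal
    direction, and 154 N2 embryos split 65 (F1 mother) / 89 (B6 mother).
    """

    n_f1_per_direction: int = 8
    n_n2_f1xb6: int = 65
    n_n2_b6xf1: int = 89
    n_autosomes: int = 19
    genes_per_chromosome: int = 400
    genetic_map_length_morgans_per_chrom: float = 0.5
    baseline_expression_log_mean: float = 3.4  # natural log of RPM, exp() ~ 30 RPM
    baseline_expression_log_sd: float = 1.0
    dispersion: float = 0.05
    snp_read_fraction: float = 0.3
    library_size_log_mean: float = 14.0  # exp() ~ 1.2e6 reads, N2 scale
    library_size_log_sd: float = 0.25
    f1_library_scale: float = 13.0  # F1 libraries were sequenced much deeper
    somite_range: tuple[int, int] = (42, 57)
    vote_error_rate: float = 0.002  # per-vote "other" call rate
    hom_error_rate: float = 0.002  # per-vote wrong-strain rate in homozygotes
    batch_sd: float = 0.1  # log-normal sd of per-(batch, gene) multipliers
    embryos_per_batch: int = 12  # one multiplexed sequencing lane
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_f1_per_direction,
            self.n_n2_f1xb6,
            self.n_n2_b6xf1,
            self.n_autosomes,
            self.genes_per_chromosome,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all design counts must be >= 1")
        if self.genetic_map_length_morgans_per_chrom < 0:
            raise ValueError("map length must be non-negative")
        for name in ("snp_read_fraction", "vote_error_rate", "hom_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        lo, hi = self.somite_range
        if hi < lo:
            raise ValueError("empty somite range")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticDataset:
    """Everything a full pipeline run consumes, plus the truth."""

    config: SimulationConfig
    annotation: pd.DataFrame
    snp_table: pd.DataFrame
    metadata: pd.DataFrame
    genotypes: pd.DataFrame  # true genotypes, genes x embryos
    expression: ExpressionMatrix
    votes: pd.DataFrame
    truth: SimulationTruth
    crossovers: dict = field(default_factory=dict)  # embryo -> [(chrom, fraction), ...]


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced single-exon genes on each autosome.

    Genetic position is the gene's fractional position along the chromosome;
    crossovers are placed in the same fraction space.
    """
    rows = []
    for c in range(1, config.n_autosomes + 1):
        for i in range(config.genes_per_chromosome):
            start = 100_000 * i + 10_000
            rows.append(
                {
                    "gene": f"g{c:02d}_{i:04d}",
                    "chrom": f"chr{c}",
                    "start": start,
                    "end": start + 3_000,
                    "strand": "+",
                    "genetic_pos": (i + 0.5) / config.genes_per_chromosome,
                }
            )
    ann = pd.DataFrame(rows).set_index("gene")
    return ann


def make_snp_table(annotation: pd.DataFrame, rng: np.random.Generator, snps_per_gene: int = 3) -> pd.DataFrame:
    """A few strain-distinguishing SNPs in each gene's 3' end."""
    bases = np.array(list("ACGT"))
    rows = []
    for gene, row in annotation.iterrows():
        offsets = np.sort(rng.choice(np.arange(2000, 3000), size=snps_per_gene, replace=False))
        for off in offsets:
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "chrom": row["chrom"],
                    "pos": int(row["start"]) + int(off),
                    "b6_allele": bases[ref],
                    "cast_allele": bases[alt],
                    "high_quality": True,
                    "indel_distance": 1000,
                    "gene": gene,
                }
            )
    return pd.DataFrame(rows)


def simulate_n2_genotypes(
    config: SimulationConfig,
    n_embryos: int,
    rng: np.random.Generator | None = None,
    annotation: pd.DataFrame | None = None,
    embryo_names: list[str] | None = None,
):
    """Simulate N2 genotypes as mosaics of B6/B6 and B6/Cast segments.

    The F1 gamete on each chromosome starts B6 or Cast with probability 1/2
    and switches at Poisson-many uniform breakpoints, so every gene is
    heterozygous in an expected 50% of embryos.

    Returns (genotypes genes x embryos, crossovers: embryo -> [(chrom, pos)]).
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    if annotation is None:
        annotation = make_annotation(config)
    if embryo_names is None:
        embryo_names = [f"N2_{i:03d}" for i in range(n_embryos)]
    if len(embryo_names) != n_embryos:
        raise ValueError("embryo_names length mismatch")

    L = config.genetic_map_length_morgans_per_chrom
    chroms = annotation["chrom"].to_numpy()
    pos = annotation["genetic_pos"].to_numpy()
    calls = np.empty((len(annotation), n_embryos), dtype=object)
    crossovers: dict[str, list] = {name: [] for name in embryo_names}
    for chrom in annotation["chrom"].unique():
        mask = chroms == chrom
        p = pos[mask]
        for j, name in enumerate(embryo_names):
            start_cast = rng.random() < 0.5
            k = rng.poisson(L)
            if k:
                breaks = np.sort(rng.random(k))
                crossovers[name].extend((chrom, b) for b in breaks)
                segment = np.searchsorted(breaks, p, side="right")
            else:
                segment = np.zeros(p.shape, dtype=int)
            is_cast = (segment % 2 == 0) == start_cast
            calls[mask, j] = np.where(is_cast, HET, HOM)
    genotypes = pd.DataFrame(calls, index=annotation.index, columns=embryo_names)
    return genotypes, crossovers


def make_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Embryo metadata: cross, maternal class, litter, somites, batch, sex."""
    lo, hi = config.somite_range
    rows = []
    specs = [
        ("F1", "B6xCast", config.n_f1_per_direction),
        ("F1", "CastxB6", config.n_f1_per_direction),
        ("N2", "F1xB6", config.n_n2_f1xb6),
        ("N2", "B6xF1", config.n_n2_b6xf1),
    ]
    for gen, cross, n in specs:
        litter_size = 6
        for i in range(n):
            rows.append(
                {
                    "embryo": f"{gen}_{cross}_{i:03d}",
                    "generation": gen,
                    "cross": cross,
                    "mother_class": MOTHER_CLASS[cross],
                    "litter": f"{cross}_L{i // litter_size:02d}",
                    "somites": int(rng.integers(lo, hi + 1)),
                    "sex": "F" if rng.random() < 0.5 else "M",
                }
            )
    meta = pd.DataFrame(rows).set_index("embryo")
    # multiplexed pooling: lane membership is randomized across embryos, so
    # lane effects are not confounded with cross direction or litter
    lane = np.array([f"lane{i // config.embryos_per_batch:02d}" for i in range(len(meta))])
    meta["batch"] = lane[rng.permutation(len(meta))]
    return meta


def _allele_levels(genes: pd.Index, metadata: pd.DataFrame, genotypes: pd.DataFrame, truth: SimulationTruth):
    """Relative expression of the B6 and Cast allele per (gene, embryo).

    Baseline is 1/2 per allele; the Cast allele is scaled by the cis fold
    (possibly somite-dependent) and imprinting silences whichever allele has
    the silenced parental origin, down to its residual fraction.
    Homozygous (B6/B6) embryos carry one maternal and one paternal B6 copy.
    Returns (b6_level, cast_level) arrays of shape (genes, embryos).
    """
    n_g, n_e = len(genes), len(metadata)
    fold = np.ones((n_g, 1))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, f in truth.cis_fold.items():
        fold[gene_pos[g], 0] = f
    fold = np.broadcast_to(fold, (n_g, n_e)).copy()
    somites = metadata["somites"].to_numpy()
    mid = somites.mean()
    for g, slope in truth.somite_slope_allele.items():
        fold[gene_pos[g], :] *= np.exp(slope * (somites - mid))

    het = (genotypes.to_numpy() == HET)
    cast_maternal = metadata["cross"].map(CAST_IS_MATERNAL).to_numpy()  # only meaningful where het

    b6 = np.full((n_g, n_e), 0.5)
    cast = 0.5 * fold
    cast[~het] = 0.0
    b6[~het] = 1.0  # two B6 copies
    for g, (origin, residual) in truth.imprinted.items():
        i = gene_pos[g]
        silence_cast = het[i] & (cast_maternal == (origin == "maternal"))
        cast[i, silence_cast] *= residual
        silence_b6 = het[i] & ~silence_cast
        b6[i, silence_b6] *= residual
        # homozygotes: one of the two B6 copies is silenced
        b6[i, ~het[i]] = 0.5 * (1.0 + residual)
    return b6, cast


def simulate_expression(
    truth: SimulationTruth,
    genotypes: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    baseline_rpm: pd.Series | None = None,
    library_size: pd.Series | None = None,
) -> ExpressionMatrix:
    """Draw per-(gene, embryo) counts from the multiplicative model.

    mean count = library_size x baseline RPM/1e6 x allelic level
    x maternal multiplier x somite trend x hotspot multiplier x batch
    multiplier, with negative-binomial noise at the configured dispersion.
    """
    genes = genotypes.index
    embryos = metadata.index
    truth.validate(genes)
    if not genotypes.columns.equals(embryos):
        genotypes = genotypes.reindex(columns=embryos)
        if genotypes.isna().any().any():
            raise ValueError("genotypes and metadata cover different embryos")
    n_g, n_e = len(genes), len(embryos)
    gene_pos = {g: i for i, g in enumerate(genes)}

    if baseline_rpm is None:
        baseline_rpm = pd.Series(
            np.exp(rng.normal(config.baseline_expression_log_mean, config.baseline_expression_log_sd, n_g)),
            index=genes,
        )
    if library_size is None:
        lib = np.exp(rng.normal(config.library_size_log_mean, config.library_size_log_sd, n_e))
        lib *= np.where(metadata["generation"].to_numpy() == "F1", config.f1_library_scale, 1.0)
        library_size = pd.Series(np.round(lib).astype(np.int64), index=embryos)

    b6_level, cast_level = _allele_levels(genes, metadata, genotypes, truth)
    mult = b6_level + cast_level

    is_b6_mother = (metadata["mother_class"] == "B6").to_numpy()
    for g, f in truth.maternal_fold.items():
        mult[gene_pos[g], is_b6_mother] *= f

    somites = metadata["somites"].to_numpy()
    mid = somites.mean()
    for g, slope in truth.somite_slope_expr.items():
        mult[gene_pos[g], :] *= np.exp(slope * (somites - mid))

    if truth.hotspot is not None:
        locus, targets = truth.hotspot
        het_at_locus = genotypes.loc[locus].to_numpy() == HET
        for g, f in targets.items():
            mult[gene_pos[g], het_at_locus] *= f

    batches = metadata["batch"].to_numpy()
    if config.batch_sd > 0:
        for b in pd.unique(batches):
            bmult = np.exp(rng.normal(0.0, config.batch_sd, n_g))
            mult[:, batches == b] *= bmult[:, None]

    mean = library_size.to_numpy()[None, :] * baseline_rpm.to_numpy()[:, None] / 1e6 * mult
    if config.dispersion > 1e-12:
        lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=embryos), library_size
    )


def simulate_allele_votes(
    truth: SimulationTruth,
    genotypes: pd.DataFrame,
    expression: ExpressionMatrix,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binomial allele-vote sampling at the gene's true B6 allele fraction.

    SNP-covering reads are Binomial(total reads, snp_read_fraction); each vote
    is "other" with the configured error rate, else B6 with probability equal
    to the gene's allelic ratio (1 - hom_error_rate in homozygotes).
    """
    genes = genotypes.index
    counts = expression.counts.to_numpy()
    n_g, n_e = counts.shape
    b6_level, cast_level = _allele_levels(genes, metadata, genotypes, truth)
    het = genotypes.to_numpy() == HET
    with np.errstate(invalid="ignore", divide="ignore"):
        true_baf = np.where(b6_level + cast_level > 0, b6_level / (b6_level + cast_level), 0.5)
    true_baf = np.where(het, true_baf, 1.0 - config.hom_error_rate)

    snp_reads = rng.binomial(counts, config.snp_read_fraction)
    other = rng.binomial(snp_reads, config.vote_error_rate)
    informative = snp_reads - other
    b6 = rng.binomial(informative, true_baf)
    cast = informative - b6

    gene_col = np.repeat(genes.to_numpy(), n_e)
    embryo_col = np.tile(expression.embryos.to_numpy(), n_g)
    votes = pd.DataFrame(
        {
            "gene": gene_col,
            "embryo": embryo_col,
            "b6_votes": b6.ravel().astype(float),
            "cast_votes": cast.ravel().astype(float),
            "other_votes": other.ravel().astype(float),
            "snp_read_count": snp_reads.ravel(),
        }
    )
    return votes[votes["snp_read_count"] > 0].reset_index(drop=True)


def simulate_dataset(
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
    with_snp_table: bool = False,
) -> SyntheticDataset:
    """Full synthetic dataset: 2x reciprocal F1 plus reciprocal N2 embryos."""
    config.validate()
    rng = config.rng()
    if truth is None:
        truth = SimulationTruth()
    annotation = make_annotation(config)
    snp_table = make_snp_table(annotation, rng) if with_snp_table else pd.DataFrame()
    metadata = make_metadata(config, rng)

    f1_names = metadata.index[metadata["generation"] == "F1"].tolist()
    n2_names = metadata.index[metadata["generation"] == "N2"].tolist()
    f1_geno = pd.DataFrame(HET, index=annotation.index, columns=f1_names)
    n2_geno, crossovers = simulate_n2_genotypes(
        config, len(n2_names), rng, annotation, embryo_names=n2_names
    )
    genotypes = pd.concat([f1_geno, n2_geno], axis=1).reindex(columns=metadata.index)

    expression = simulate_expression(truth, genotypes, metadata, config, rng)
    votes = simulate_allele_votes(truth, genotypes, expression, metadata, config, rng)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        snp_table=snp_table,
        metadata=metadata,
        genotypes=genotypes,
        expression=expression,
        votes=votes,
        truth=truth,
        crossovers=crossovers,
    )


def truth_to_records(truth: SimulationTruth) -> pd.DataFrame:
    """Flatten the truth ledger to a tidy table for TSV output."""
    rows = []
    for g, f in truth.cis_fold.items():
        rows.append({"gene": g, "effect": "cis_fold", "value": f, "detail": ""})
    for g, f in truth.maternal_fold.items():
        rows.append({"gene": g, "effect": "maternal_fold", "value": f, "detail": ""})
    for g, (origin, residual) in truth.imprinted.items():
        rows.append({"gene": g, "effect": "imprinted", "value": residual, "detail": origin})
    for g, s in truth.somite_slope_expr.items():
        rows.append({"gene": g, "effect": "somite_slope_expr", "value": s, "detail": ""})
    for g, s in truth.somite_slope_allele.items():
        rows.append({"gene": g, "effect": "somite_slope_allele", "value": s, "detail": ""})
    if truth.hotspot is not None:
        locus, targets = truth.hotspot
        for g, f in targets.items():
            rows.append({"gene": g, "effect": "hotspot_target", "value": f, "detail": locus})
    return pd.DataFrame(rows, columns=["gene", "effect", "value", "detail"])
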