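"""Shared containers and conventions for the backcross expression analysis.

Two inbred strains are crossed: C57BL/6 ("B6") and Cast/Ei ("Cast").  F1
hybrids carry one allele from each strain everywhere; N2 embryos (F1 backcrossed
to B6) are B6/B6 or B6/Cast at each autosomal locus.  Cross names list the
mother first, so ``B6xF1`` means a B6 mother mated to an F1 father.

All matrices are pandas DataFrames with genes as rows and embryos as columns.
Allele votes are held in long form, one row per (gene, embryo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# genotype calls (backcross design: Cast/Cast is impossible in N2 embryos)
HOM = "B6/B6"
HET = "B6/Cast"
UNKNOWN = "unknown"

#: cross direction -> does a heterozygous embryo's Cast allele come from the mother?
CAST_IS_MATERNAL = {
    "B6xCast": False,  # F1 embryo, B6 mother
    "CastxB6": True,   # F1 embryo, Cast mother
    "B6xF1": False,    # N2 embryo, B6 mother
    "F1xB6": True,     # N2 embryo, F1 mother
}

#: cross direction -> maternal genotype class used by the maternal-effect test
MOTHER_CLASS = {"B6xCast": "B6", "CastxB6": "Cast", "B6xF1": "B6", "F1xB6": "F1"}

VOTE_COLUMNS = ["gene", "embryo", "b6_votes", "cast_votes", "other_votes", "snp_read_count"]


def empty_vote_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": pd.Series(dtype=str),
            "embryo": pd.Series(dtype=str),
            "b6_votes": pd.Series(dtype=float),
            "cast_votes": pd.Series(dtype=float),
            "other_votes": pd.Series(dtype=float),
            "snp_read_count": pd.Series(dtype=int),
        }
    )


def validate_vote_table(votes: pd.DataFrame) -> None:
    """Check vote-mass conservation: each read contributes at most one vote."""
    missing = set(VOTE_COLUMNS) - set(votes.columns)
    if missing:
        raise ValueError(f"vote table missing columns: {sorted(missing)}")
    if (votes[["b6_votes", "cast_votes", "other_votes"]].to_numpy() < 0).any():
        raise ValueError("negative vote counts")
    total = votes["b6_votes"] + votes["cast_votes"] + votes["other_votes"]
    if (total > votes["snp_read_count"] + 1e-9).any():
        raise ValueError("vote mass exceeds SNP-covering read count")


def baf(votes: pd.DataFrame) -> pd.Series:
    """Per-row B6 allele fraction, b6/(b6+cast); NaN where no informative votes.

    "Other" votes (reads matching neither strain allele) are excluded from the
    denominator.
    """
    informative = votes["b6_votes"] + votes["cast_votes"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = votes["b6_votes"] / informative
    return out.where(informative > 0)


@dataclass
class ExpressionMatrix:
    """Raw gene-level counts plus library-size normalisation (RPM).

    Parameters
    ----------
    counts
        genes x embryos integer read counts (exon-overlapping reads only).
    library_size
        total mapped reads per embryo; defaults to the column sums of
        ``counts`` when not supplied (in real data, some reads fall outside
        annotated genes, so the supplied library size can exceed the sum).
    """

    counts: pd.DataFrame
    library_size: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if (self.library_size <= 0).any():
            bad = self.library_size.index[self.library_size <= 0].tolist()
            raise ValueError(f"non-positive library size for embryos: {bad[:5]}")

    @property
    def rpm(self) -> pd.DataFrame:
        """Reads per million mapped reads."""
        return self.counts / self.library_size * 1e6

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def embryos(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[genes], self.library_size)


def validate_metadata(metadata: pd.DataFrame) -> None:
    """Validate embryo metadata.

    Required columns: generation (F1/N2), cross, mother_class, litter,
    somites, batch, sex.  The mitochondrial confound of the maternal-effect
    analysis is excluded structurally: every N2 embryo must descend from a
    B6xCast F1 (B6 grand-dam), i.e. carry B6 mitochondria, which the two N2
    cross names guarantee.
    """
    required = {"generation", "cross", "mother_class", "litter", "somites", "batch", "sex"}
    missing = required - set(metadata.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_cross = set(metadata["cross"]) - set(CAST_IS_MATERNAL)
    if bad_cross:
        raise ValueError(f"unknown cross directions: {sorted(bad_cross)}")
    n2 = metadata[metadata["generation"] == "N2"]
    if not set(n2["cross"]) <= {"B6xF1", "F1xB6"}:
        raise ValueError("N2 embryos must come from B6xF1 or F1xB6 crosses (B6 mitochondria)")


@dataclass
class MarkerRegionSet:
    """Recombination-delimited marker regions: the unit of eQTL testing.

    ``regions`` has one row per region with columns: region (id), chrom,
    start_gene, end_gene, n_genes.  ``genotypes`` is regions x embryos with
    calls in {B6/B6, B6/Cast, unknown} (the per-embryo consensus).
    ``gene_to_region`` maps every member gene to its region id.
    """

    regions: pd.DataFrame
    genotypes: pd.DataFrame
    gene_to_region: pd.Series

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class SimulationTruth:
    """Ground-truth effect ledger for parameter-recovery tests.

    cis_fold: gene -> expression of the Cast allele relative to the B6 allele.
    maternal_fold: gene -> total-expression fold change under a B6 mother
    relative to an F1 mother.  imprinted: gene -> (silenced parental origin,
    residual expression fraction of the silenced allele).  somite_slope_expr:
    gene -> log-linear slope of total expression per somite.
    somite_slope_allele: gene -> log-linear slope of the Cast:B6 allelic ratio
    per somite.  hotspot: optional (locus gene, {target gene -> fold change
    when heterozygous at the locus}).
    """

    cis_fold: dict = field(default_factory=dict)
    maternal_fold: dict = field(default_factory=dict)
    imprinted: dict = field(default_factory=dict)
    somite_slope_expr: dict = field(default_factory=dict)
    somite_slope_allele: dict = field(default_factory=dict)
    hotspot: tuple | None = None

    def validate(self, genes) -> None:
        genes = set(genes)
        for name, table in [
            ("cis_fold", self.cis_fold),
            ("maternal_fold", self.maternal_fold),
            ("imprinted", self.imprinted),
            ("somite_slope_expr", self.somite_slope_expr),
            ("somite_slope_allele", self.somite_slope_allele),
        ]:
            unknown = set(table) - genes
            if unknown:
                raise ValueError(f"truth ledger {name} names genes absent from annotation: {sorted(unknown)[:5]}")
        for gene, fold in {**self.cis_fold, **self.maternal_fold}.items():
            if fold < 0:
                raise ValueError(f"negative fold change for {gene}")
        for gene, (origin, residual) in self.imprinted.items():
            if origin not in ("maternal", "paternal"):
                raise ValueError(f"silenced origin must be maternal/paternal, got {origin!r}")
            if not 0.0 <= residual <= 1.0:
                raise ValueError(f"residual fraction outside [0,1] for {gene}")
        if self.hotspot is not None:
            locus, targets = self.hotspot
            if locus not in genes:
                raise ValueError(f"hotspot locus {locus!r} not in annotation")
            unknown = set(targets) - genes
            if unknown:
                raise ValueError(f"hotspot targets absent from annotation: {sorted(unknown)[:5]}")
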