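"""Core data containers shared across the pipeline.

Summary statistics live in pandas DataFrames with the GWAS-summary column
dialect ``SNP CHR POS EA OA EAF BETA SE P N`` (effect allele EA, other allele
OA, effect-allele frequency EAF). Effects are additive per-allele effects on
the trait scale recorded in the dataset metadata (SD units for standardized
continuous traits, log-odds for binary traits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SUMMARY_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(ea: str, oa: str) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    return COMPLEMENT.get(ea) == oa


@dataclass
class VariantAssoc:
    """One variant's association with one trait."""

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise ValueError(f"alleles must be A/C/G/T, got {self.effect_allele}/{self.other_allele}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"eaf must be in (0,1), got {self.eaf}")
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"pval must be in (0,1], got {self.pval}")


@dataclass
class SummaryDataset:
    """A trait's summary statistics plus trait metadata.

    Parameters
    ----------
    trait
        Trait label (e.g. ``"hba1c"``, ``"expr_AMPK"``, ``"cad"``).
    df
        Table with columns ``SNP CHR POS EA OA EAF BETA SE P N``.
    trait_type
        ``"continuous"`` or ``"binary"`` (binary betas are log odds ratios).
    unit
        Human-readable unit of BETA.
    trait_sd
        Phenotypic SD on the BETA scale; 1.0 for standardized traits.
    """

    trait: str
    df: pd.DataFrame
    trait_type: str = "continuous"
    unit: str = "SD"
    trait_sd: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"summary table for {self.trait} lacks columns {missing}")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")
        if (self.df["SE"] <= 0).any():
            raise ValueError("all SE must be > 0")

    def lookup(self, snp: str) -> Optional[pd.Series]:
        hit = self.df.loc[self.df["SNP"] == snp]
        return None if hit.empty else hit.iloc[0]

    def subset(self, snps) -> "SummaryDataset":
        sub = self.df[self.df["SNP"].isin(set(snps))].reset_index(drop=True)
        return SummaryDataset(self.trait, sub, self.trait_type, self.unit, self.trait_sd)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, trait: str = "trait", **meta) -> "SummaryDataset":
        df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
        return cls(trait, df, **meta)


@dataclass
class LDReference:
    """Pairwise signed correlation r among variants (r² derivable).

    ``r[i, j]`` is the correlation between effect-allele dosages of variants
    ``snps[i]`` and ``snps[j]`` as oriented by ``ea``/``oa`` — the "phase" of
    the panel, used to orient proxy substitutions.
    """

    snps: list
    r: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray

    def __post_init__(self) -> None:
        self.snps = list(self.snps)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snps)
        if self.r.shape != (k, k):
            raise ValueError("r matrix shape does not match variant count")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("r matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("r diagonal must be 1")
        if np.abs(self.r).max() > 1 + 1e-8:
            raise ValueError("|r| must be <= 1")
        self._idx = {s: i for i, s in enumerate(self.snps)}

    def index(self, snp: str) -> int:
        try:
            return self._idx[snp]
        except KeyError:
            raise KeyError(f"variant {snp} absent from LD reference") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def to_files(self, matrix_path, index_path) -> None:
        pd.DataFrame(
            {"SNP": self.snps, "CHR": self.chrom, "POS": self.pos, "EA": self.ea, "OA": self.oa}
        ).to_csv(index_path, sep="\t", index=False)
        np.savetxt(matrix_path, self.r, fmt="%.8g", delimiter="\t")

    @classmethod
    def from_files(cls, matrix_path, index_path) -> "LDReference":
        idx = pd.read_csv(index_path, sep="\t", dtype={"SNP": str, "CHR": str, "EA": str, "OA": str})
        r = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        return cls(idx["SNP"].tolist(), r, idx["CHR"].to_numpy(), idx["POS"].to_numpy(), idx["EA"].to_numpy(), idx["OA"].to_numpy())


COVARIATE_NAMES = ["age", "sex", "array"] + [f"PC{i}" for i in range(1, 11)]


@dataclass
class CohortData:
    """Individual-level data for one-sample MR.

    ``dosages`` columns are variant ids; ``variant_info`` records the counted
    (effect) allele of each dosage column. Covariates are age, sex, genotyping
    array and the top 10 principal components (13 columns).
    """

    dosages: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    variant_info: pd.DataFrame  # SNP EA OA EAF

    def __post_init__(self) -> None:
        if list(self.covariates.columns) != COVARIATE_NAMES:
            raise ValueError(f"covariates must be exactly {COVARIATE_NAMES}")
        if self.dosages.isna().any().any():
            raise ValueError("dosages contain missing values")
        if len({len(self.dosages), len(self.covariates), len(self.phenotypes)}) != 1:
            raise ValueError("dosages, covariates and phenotypes must have equal row counts")

    @property
    def n(self) -> int:
        return len(self.dosages)

    def effect_allele(self, snp: str) -> str:
        row = self.variant_info.loc[self.variant_info["SNP"] == snp]
        if row.empty:
            raise KeyError(f"variant {snp} not in cohort")
        return str(row.iloc[0]["EA"])

    def to_tsv(self, pheno_path, dosage_path) -> None:
        pd.concat([self.covariates, self.phenotypes], axis=1).to_csv(pheno_path, sep="\t", index=False, float_format="%.8g")
        self.dosages.to_csv(dosage_path, sep="\t", index=False, float_format="%.6g")


@dataclass
class MREstimate:
    """One MR estimate in the tidy result convention.

    ``beta`` is the causal effect per 1 SD of HbA1c lowering (the 0.62%
    reduction scale) unless ``unit`` says otherwise; for binary outcomes the
    odds-ratio view is attached by ``scale_estimate``.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    q: float = float("nan")
    q_df: int = 0
    q_pval: float = float("nan")
    unit: str = "per 1 SD HbA1c lowering"
    outcome: str = ""
    exposure: str = ""
    outcome_type: str = "continuous"
    odds_ratio: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")
    percent_risk_change: float = float("nan")
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "nsnp": self.n_variants,
            "b": self.beta,
            "se": self.se,
            "lo95": self.ci_low,
            "up95": self.ci_high,
            "p": self.pval,
            "Q": self.q,
            "Q_p": self.q_pval,
            "unit": self.unit,
        }
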