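"""Selection of genetic instruments for drug targets and circulating HbA1c.

A variant instruments the perturbation of a metformin target when it (i)
associates with the target gene's expression in the cis region (±500 kb of
the lead cis-eQTL) and with HbA1c, (ii) lies in a region where expression and
HbA1c colocalize (PP.H4 above threshold), (iii) is independent of other
retained variants after greedy LD clumping, and (iv) is common (MAF ≥ 1%).
Retained instruments carry the HbA1c association as their exposure effect —
the therapeutic axis the targets are meant to move — annotated with
per-variant F and R² instrument-strength diagnostics.

Circulating-HbA1c benchmark instruments are selected differently: variants
genome-wide significant for both HbA1c and type 2 diabetes, clumped at a
looser r² threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .coloc import ColocPriors, ColocResult, colocalize
from .datatypes import LDReference, SummaryDataset

# Instrument registry: per-target instrument counts of the reference
# analysis. The seven-target configuration sums to 34; the originally named
# five-target subset (without FBP1 and ADCY1) sums to 32 — both are recorded.
TARGET_INSTRUMENT_COUNTS = {
    "MC1": 26,       # mitochondrial complex I
    "AMPK": 3,       # AMP-activated protein kinase
    "GDF15": 1,      # growth differentiation factor 15
    "MG3": 1,        # mitochondrial glycerol 3
    "GCG/GLP1": 1,   # glucagon / glucagon-like peptide 1
    "FBP1": 1,       # fructose bisphosphatase 1
    "ADCY1": 1,      # adenylyl cyclase 1
}
FIVE_TARGET_SET = ("MC1", "AMPK", "GDF15", "MG3", "GCG/GLP1")
HBA1C_BENCHMARK_N_INSTRUMENTS = 23
WEAK_INSTRUMENT_F = 10.0


def total_instruments(targets=None) -> int:
    targets = TARGET_INSTRUMENT_COUNTS if targets is None else targets
    return int(sum(TARGET_INSTRUMENT_COUNTS[t] for t in targets))


@dataclass
class SelectionCriteria:
    """Thresholds of the instrument-selection procedure (defaults as used
    throughout: cis window 500 kb, eQTL P < 0.01, HbA1c P < 0.05,
    colocalization probability > 0.7, clump r² < 0.001, MAF ≥ 1%; biomarker
    instruments P < 5e-8 on both traits, clump r² < 0.01)."""

    cis_window_bp: int = 500_000
    eqtl_p_max: float = 0.01
    hba1c_p_max: float = 0.05
    coloc_prob_min: float = 0.7
    clump_r2_max: float = 0.001
    maf_min: float = 0.01
    gwas_p_max: float = 5e-8
    biomarker_clump_r2_max: float = 0.01

    def __post_init__(self) -> None:
        for name in ("eqtl_p_max", "hba1c_p_max", "coloc_prob_min", "gwas_p_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0,1], got {v}")
        if not 0.0 <= self.clump_r2_max < 1.0 or not 0.0 <= self.biomarker_clump_r2_max < 1.0:
            raise ValueError("clump r2 thresholds must be in [0,1)")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0,0.5)")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "SelectionCriteria":
        """Read thresholds from the ``selection:`` block of a YAML config."""
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        block = doc.get("selection", {}) if isinstance(doc, dict) else {}
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in block.items() if k in known})


@dataclass
class InstrumentSet:
    """Retained instruments for one exposure, oriented to the exposure trait.

    ``table`` uses the summary dialect plus F and R2 columns. An empty table
    with ``empty_reason`` set is a valid outcome (e.g. failed colocalization).
    """

    target: str
    table: pd.DataFrame
    empty_reason: Optional[str] = None
    coloc: Optional[ColocResult] = None
    aggregate_f: float = float("nan")
    aggregate_r2: float = float("nan")
    weak: bool = False
    provenance: dict = field(default_factory=dict)

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    @property
    def snps(self) -> list:
        return self.table["SNP"].tolist()

    def to_tsv(self, path) -> None:
        out = self.table.rename(columns={"BETA": "BETA_expo", "SE": "SE_expo", "P": "P_expo"})
        out.insert(0, "target", self.target)
        cols = ["target", "SNP", "EA", "OA", "EAF", "BETA_expo", "SE_expo", "P_expo", "F", "R2"]
        out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def greedy_clump(df: pd.DataFrame, ld: LDReference, r2_max: float, rank_col: str = "P") -> pd.DataFrame:
    """Greedy LD clumping: rank ascending by ``rank_col`` (p-value ties —
    which happen when p underflows at extreme z — broken by |z| descending,
    then position, then allele order), keep a variant iff its r² with every
    already-kept variant is below ``r2_max``.

    Missing LD entries for a candidate pair are an error — silent
    independence assumptions are how correlated instruments sneak in.
    """
    ranked = df.assign(_negz=-(df["BETA"] / df["SE"]).abs()).sort_values(
        [rank_col, "_negz", "POS", "EA", "OA"], kind="mergesort")
    kept_idx: list = []
    for idx, row in ranked.iterrows():
        ok = True
        for kidx in kept_idx:
            r2 = ld.r2_between(row["SNP"], ranked.loc[kidx, "SNP"])  # KeyError if absent
            if r2 >= r2_max:
                ok = False
                break
        if ok:
            kept_idx.append(idx)
    return df.loc[sorted(kept_idx)].reset_index(drop=True)


def instrument_strength(iv: InstrumentSet | pd.DataFrame, n: int, trait_sd: float = 1.0):
    """Annotate per-variant F and R² and compute aggregate strength.

    Per variant: F = (beta/se)² (the squared z approximation) and
    R² = 2·EAF·(1−EAF)·beta² / trait variance. Aggregate R² sums per-variant
    R² (instruments are clumped to independence); aggregate
    F = R²(n−k−1)/((1−R²)k). Instruments with aggregate F < 10 are flagged
    weak.
    """
    table = iv.table if isinstance(iv, InstrumentSet) else iv
    if (table["SE"] <= 0).any():
        raise ValueError("se must be > 0 for instrument strength")
    f_per = (table["BETA"] / table["SE"]) ** 2
    r2_per = 2.0 * table["EAF"] * (1.0 - table["EAF"]) * table["BETA"] ** 2 / trait_sd**2
    table = table.copy()
    table["F"] = f_per.to_numpy()
    table["R2"] = r2_per.to_numpy()
    k = len(table)
    r2_agg = float(r2_per.sum())
    f_agg = r2_agg * (n - k - 1) / ((1.0 - r2_agg) * k) if k > 0 and r2_agg < 1 else float("nan")
    if isinstance(iv, InstrumentSet):
        iv.table = table
        iv.aggregate_f = f_agg
        iv.aggregate_r2 = r2_agg
        iv.weak = bool(f_agg < WEAK_INSTRUMENT_F) if np.isfinite(f_agg) else True
        return iv
    return table, f_agg, r2_agg


def _maf_col(df: pd.DataFrame) -> pd.Series:
    return np.minimum(df["EAF"], 1.0 - df["EAF"])


def select_target_instruments(eqtl: SummaryDataset, hba1c: SummaryDataset, ld: LDReference,
                              gene_region: tuple | None = None,
                              crit: SelectionCriteria | None = None,
                              target: str = "target",
                              priors: ColocPriors | None = None) -> InstrumentSet:
    """Select instruments for one drug target.

    ``gene_region`` is ``(chrom, start, end)``; when None, the cis window is
    the ±cis_window_bp interval centred on the lead (smallest-P) cis-eQTL
    variant. Exposure effects of the retained instruments are the HbA1c
    associations. An empty set with ``empty_reason`` is returned when the
    region fails colocalization or no variant passes the filters.
    """
    crit = crit or SelectionCriteria()
    edf = eqtl.df
    if gene_region is None:
        lead = edf.loc[edf["P"].idxmin()]
        chrom, lo, hi = str(lead["CHR"]), lead["POS"] - crit.cis_window_bp, lead["POS"] + crit.cis_window_bp
    else:
        chrom, lo, hi = str(gene_region[0]), gene_region[1], gene_region[2]
    in_cis = edf[(edf["CHR"].astype(str) == chrom) & edf["POS"].between(lo, hi)]
    if in_cis.empty:
        return InstrumentSet(target, in_cis.copy(), empty_reason="no_cis_variants")

    region_eqtl = SummaryDataset(eqtl.trait, in_cis.reset_index(drop=True), eqtl.trait_type, eqtl.unit, eqtl.trait_sd)
    cres = colocalize(region_eqtl, hba1c.subset(in_cis["SNP"]), priors)
    prov = {"cis_window": (chrom, int(lo), int(hi)), "pp_h4": cres.pp_h4}
    if cres.pp_h4 <= crit.coloc_prob_min:
        return InstrumentSet(target, in_cis.iloc[0:0].copy(), empty_reason="coloc", coloc=cres, provenance=prov)

    hdf = hba1c.df.set_index("SNP")
    cand = in_cis[in_cis["P"] < crit.eqtl_p_max]
    cand = cand[cand["SNP"].isin(hdf.index)]
    cand = cand[_maf_col(cand) >= crit.maf_min]
    # exposure-side rows: the HbA1c associations of the candidates
    hrows = hdf.loc[cand["SNP"]].reset_index()
    hrows = hrows[_maf_col(hrows) >= crit.maf_min]
    hrows = hrows[hrows["P"] < crit.hba1c_p_max].reset_index(drop=True)
    if hrows.empty:
        return InstrumentSet(target, hrows, empty_reason="no_candidates", coloc=cres, provenance=prov)

    clumped = greedy_clump(hrows, ld, crit.clump_r2_max, rank_col="P")
    iv = InstrumentSet(target, clumped, coloc=cres, provenance=prov)
    n = int(np.median(clumped["N"])) if len(clumped) else 0
    return instrument_strength(iv, n=n, trait_sd=hba1c.trait_sd)


def select_biomarker_instruments(hba1c: SummaryDataset, t2d: SummaryDataset, ld: LDReference,
                                 crit: SelectionCriteria | None = None,
                                 target: str = "HBA1C") -> InstrumentSet:
    """Benchmark instruments for circulating HbA1c: genome-wide significant
    for both HbA1c and type 2 diabetes, clumped at the biomarker r²."""
    crit = crit or SelectionCriteria()
    tdf = t2d.df.set_index("SNP")
    cand = hba1c.df[hba1c.df["P"] < crit.gwas_p_max]
    cand = cand[cand["SNP"].isin(tdf.index)]
    cand = cand[_maf_col(cand) >= crit.maf_min]
    cand = cand[tdf.loc[cand["SNP"], "P"].to_numpy() < crit.gwas_p_max].reset_index(drop=True)
    if cand.empty:
        return InstrumentSet(target, cand, empty_reason="no_candidates")
    clumped = greedy_clump(cand, ld, crit.biomarker_clump_r2_max, rank_col="P")
    iv = InstrumentSet(target, clumped)
    return instrument_strength(iv, n=int(np.median(clumped["N"])), trait_sd=hba1c.trait_sd)
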