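"""Synthetic GWAS summary statistics, LD references and an individual-level
cohort with a known causal chain, for exercising the whole pipeline.

The generator emulates the statistical structure of a drug-target MR study of
metformin: seven drug targets, each with a cis region in which some variants
perturb the target gene's expression; expression perturbation moves HbA1c;
HbA1c moves cardiometabolic outcomes (BMI, SBP, DBP continuous; CAD, T2D
binary on the log-odds scale). Regional LD is block-exchangeable: within a
block every pair of variants has correlation ``ld_block_rho``; across blocks
variants are independent. Summary statistics are produced from the
closed-form expectation of the marginal (LD-contaminated) per-allele effect
plus correlated sampling noise at the study sample sizes — equivalent in
distribution to regressing one variant at a time in a simulated GWAS sample,
at a fraction of the cost. A set of independent "glycemic biomarker" variants
with strong direct HbA1c and T2D effects feeds the circulating-HbA1c
benchmark instrument selection.

The default effect sizes are the study conditions recovered downstream:
per 1 SD HbA1c *increase*, +0.22 kg/m² BMI, +0.19 mmHg SBP, +0.29 mmHg DBP,
+log(1/0.62) log-odds CAD, +log(1/0.57) log-odds T2D — so the reported
per-SD-lowering estimates are the familiar negative/protective values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import COMPLEMENT, CohortData, COVARIATE_NAMES, LDReference, SummaryDataset
from .harmonize import HarmonizedTable, HARMONIZED_COLUMNS
from .instrument_selection import TARGET_INSTRUMENT_COUNTS

OUTCOME_SPECS = {
    # name: (trait_type, unit, phenotypic sd on the beta scale, case fraction)
    "bmi": ("continuous", "kg/m2", 4.7, None),
    "sbp": ("continuous", "mmHg", 19.0, None),
    "dbp": ("continuous", "mmHg", 10.0, None),
    "cad": ("binary", "log odds", 1.0, 0.10),
    "t2d": ("binary", "log odds", 1.0, 0.10),
}

DEFAULT_OUTCOME_EFFECTS = {
    "bmi": 0.22,
    "sbp": 0.19,
    "dbp": 0.29,
    "cad": math.log(1.0 / 0.62),
    "t2d": math.log(1.0 / 0.57),
}

_NONPALINDROMIC_PARTNERS = {"A": ("C", "G"), "T": ("C", "G"), "C": ("A", "T"), "G": ("A", "T")}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Sample sizes default to the source study scale: exposure (eQTL) GWAS
    31,684; HbA1c GWAS 344,182; outcome GWAS 466,947; one-sample cohort
    338,425. ``causal_effect_hba1c_to_outcome`` is either a scalar applied to
    every outcome or a per-outcome mapping, on the per-1-SD-HbA1c-increase
    scale. ``pleiotropy_sd`` is the SD of direct variant→outcome effects on
    the standardized-genotype scale (0 = valid instruments).
    """

    n_exposure_gwas: int = 31_684
    n_outcome_gwas: int = 466_947
    n_hba1c_gwas: int = 344_182
    n_cohort: int = 338_425
    maf_range: tuple = (0.05, 0.5)
    ld_block_rho: float = 0.9
    block_size: int = 5
    causal_effect_expr_to_hba1c: float = 0.15
    causal_effect_hba1c_to_outcome: float | dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS))
    pleiotropy_sd: float = 0.0
    frac_palindromic: float = 0.1
    frac_swapped_alleles: float = 0.1
    frac_missing_outcome: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_exposure_gwas", "n_outcome_gwas", "n_hba1c_gwas", "n_cohort"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range frequencies must be in (0, 0.5]")
        if not 0.0 <= self.ld_block_rho < 1.0 or self.ld_block_rho**2 >= 1.0:
            raise ValueError("ld_block_rho must be in [0,1)")
        for name in ("frac_palindromic", "frac_swapped_alleles", "frac_missing_outcome"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    def outcome_effect(self, outcome: str) -> float:
        eff = self.causal_effect_hba1c_to_outcome
        if isinstance(eff, dict):
            return float(eff.get(outcome, 0.0))
        return float(eff)


@dataclass
class Region:
    """One target's cis region: variants, block LD, true causal structure."""

    target: str
    chrom: str
    snps: list
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    eaf: np.ndarray
    r: np.ndarray
    causal_idx: np.ndarray
    # per-variant true effect on expression, standardized-genotype scale
    expr_beta_std: np.ndarray

    @property
    def n_variants(self) -> int:
        return len(self.snps)

    def ld_reference(self) -> LDReference:
        return LDReference(self.snps, self.r, np.repeat(self.chrom, self.n_variants),
                           self.pos, self.ea, self.oa)


@dataclass
class StudySummaryData:
    """Everything the summary-level pipeline consumes, plus the truth."""

    eqtl: dict
    hba1c: SummaryDataset
    outcomes: dict
    ld: dict
    regions: dict
    truth: dict


def combine_ld_references(refs: list[LDReference]) -> LDReference:
    """Block-diagonal union of disjoint LD references (cross-reference r = 0)."""
    snps = [s for ref in refs for s in ref.snps]
    if len(set(snps)) != len(snps):
        raise ValueError("LD references overlap; cannot combine")
    k = len(snps)
    r = np.zeros((k, k))
    off = 0
    for ref in refs:
        w = len(ref.snps)
        r[off:off + w, off:off + w] = ref.r
        off += w
    return LDReference(
        snps, r,
        np.concatenate([np.asarray(ref.chrom, dtype=object) for ref in refs]),
        np.concatenate([ref.pos for ref in refs]),
        np.concatenate([ref.ea for ref in refs]),
        np.concatenate([ref.oa for ref in refs]),
    )


def _block_corr(n: int, block_size: int, rho: float) -> np.ndarray:
    r = np.zeros((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r[start:stop, start:stop] = rho
    np.fill_diagonal(r, 1.0)
    return r


def _assign_alleles(rng: np.random.Generator, k: int, frac_palindromic: float):
    ea = np.empty(k, dtype="U1")
    oa = np.empty(k, dtype="U1")
    pal = rng.random(k) < frac_palindromic
    bases = np.array(list("ACGT"))
    for i in range(k):
        a = bases[rng.integers(4)]
        ea[i] = a
        oa[i] = COMPLEMENT[a] if pal[i] else _NONPALINDROMIC_PARTNERS[a][rng.integers(2)]
    return ea, oa, pal


def _draw_eafs(rng: np.random.Generator, pal: np.ndarray, maf_range: tuple) -> np.ndarray:
    """EAFs in the configured MAF range; palindromic variants split between
    near-0.5 (ambiguous, dropped by harmonization) and clearly-polar
    frequencies so both branches of the MAF-0.4 rule are exercised."""
    k = len(pal)
    eaf = rng.uniform(maf_range[0], maf_range[1], size=k)
    pal_idx = np.flatnonzero(pal)
    half = len(pal_idx) // 2
    eaf[pal_idx[:half]] = rng.uniform(0.41, 0.49, size=half)
    eaf[pal_idx[half:]] = rng.uniform(0.10, 0.35, size=len(pal_idx) - half)
    return eaf


def _chol(r: np.ndarray) -> np.ndarray:
    return np.linalg.cholesky(r + 1e-10 * np.eye(len(r)))


def _summary_frame(region_like: dict, beta: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
    z = np.abs(beta / se)
    p = np.clip(2.0 * stats.norm.sf(z), 5e-324, 1.0)
    return pd.DataFrame({
        "SNP": region_like["snps"], "CHR": region_like["chrom"], "POS": region_like["pos"],
        "EA": region_like["ea"], "OA": region_like["oa"], "EAF": region_like["eaf"],
        "BETA": beta, "SE": se, "P": p, "N": n,
    })


def _draw_marginal_summary(r: np.ndarray, beta_std_true: np.ndarray, eaf: np.ndarray,
                           n: int, sd_trait: float, rng: np.random.Generator,
                           eff_var: float = 1.0, chol: np.ndarray | None = None):
    """Marginal per-allele effect estimates and SEs under block LD.

    On the standardized-genotype scale the marginal expectation is R @ b and
    the sampling covariance of the estimates is ~ R/(n·eff_var); per-allele
    quantities divide by sqrt(2p(1-p)) and scale by the trait SD.
    """
    ms = r @ beta_std_true
    L = chol if chol is not None else _chol(r)
    noise = (L @ rng.standard_normal(len(ms))) / math.sqrt(n * eff_var)
    bhat_std = ms + noise
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf))
    beta = bhat_std * sd_trait / denom
    se = np.full(len(ms), sd_trait) / (np.sqrt(n * eff_var) * denom)
    return beta, se


def _swap_alleles(df: pd.DataFrame, rng: np.random.Generator, frac: float) -> pd.DataFrame:
    """Emit a random subset of rows with EA/OA swapped and betas negated —
    same content, different representation, to exercise harmonization."""
    if frac <= 0:
        return df
    df = df.copy()
    m = rng.random(len(df)) < frac
    ea = df.loc[m, "EA"].copy()
    df.loc[m, "EA"] = df.loc[m, "OA"].to_numpy()
    df.loc[m, "OA"] = ea.to_numpy()
    df.loc[m, "BETA"] = -df.loc[m, "BETA"]
    df.loc[m, "EAF"] = 1.0 - df.loc[m, "EAF"]
    return df


def build_regions(cfg: SimConfig) -> dict:
    """One cis region per target; the number of (independent) causal eQTL
    variants per target follows the instrument registry, one causal variant
    per LD block so clumping at r² < 0.001 retains exactly the causal set."""
    rng = np.random.default_rng(cfg.seed)
    regions = {}
    for t_i, (target, n_causal) in enumerate(sorted(TARGET_INSTRUMENT_COUNTS.items())):
        n_blocks = n_causal + 2
        k = n_blocks * cfg.block_size
        ea, oa, pal = _assign_alleles(rng, k, cfg.frac_palindromic)
        eaf = _draw_eafs(rng, pal, cfg.maf_range)
        chrom = f"chr{t_i + 1}"
        # 3 kb spacing keeps even the widest region inside a ±500 kb cis
        # window anchored anywhere in the region
        pos = (1_000_000 + 3_000 * np.arange(k)).astype(int)
        snps = [f"rs{t_i + 1}_{j:04d}" for j in range(k)]
        r = _block_corr(k, cfg.block_size, cfg.ld_block_rho)
        causal_idx = np.array([b * cfg.block_size + cfg.block_size // 2 for b in range(n_causal)])
        expr_beta_std = np.zeros(k)
        # one dominant lead cis-eQTL per region (shared with HbA1c), with
        # weaker secondary signals: single-causal colocalization then finds
        # the shared lead robustly even in multi-signal regions
        mags = rng.uniform(0.15, 0.30, size=n_causal)
        mags[0] = rng.uniform(0.45, 0.55)
        signs = rng.choice([-1.0, 1.0], size=n_causal)
        expr_beta_std[causal_idx] = mags * signs
        regions[target] = Region(target, chrom, snps, pos, ea, oa, eaf, r,
                                 causal_idx, expr_beta_std)
    return regions


def _biomarker_panel(cfg: SimConfig, rng: np.random.Generator, k: int = 23) -> dict:
    """Independent glycemic loci with strong direct HbA1c and T2D effects
    (glycemic biomarker variants are typically strong diabetes loci), feeding
    the circulating-HbA1c benchmark selection."""
    ea, oa, pal = _assign_alleles(rng, k, 0.0)
    eaf = rng.uniform(0.1, 0.5, size=k)
    mag = rng.uniform(0.04, 0.08, size=k) * rng.choice([-1.0, 1.0], size=k)
    return {
        "snps": [f"rsbm_{j:03d}" for j in range(k)],
        "chrom": "chr9", "pos": (2_000_000 + 10_000 * np.arange(k)).astype(int),
        "ea": ea, "oa": oa, "eaf": eaf,
        "hba1c_beta_std": mag,          # per SD genotype, SD HbA1c
        "t2d_beta_std": 1.2 * mag,      # log-odds per SD genotype
    }


def simulate_summary_stats(cfg: SimConfig) -> StudySummaryData:
    """Generate the full multi-trait summary-statistics bundle.

    Returns per-target eQTL datasets, an HbA1c dataset covering every target
    region plus the biomarker panel, outcome datasets (BMI/SBP/DBP/CAD/T2D)
    covering the same variants, per-region LD references, and the generating
    truth (per-variant HbA1c allele effects, per-outcome causal effects).
    """
    regions = build_regions(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    gamma = cfg.causal_effect_expr_to_hba1c

    eqtl, ld = {}, {}
    hba1c_frames, outcome_frames = [], {o: [] for o in OUTCOME_SPECS}
    truth_w_allele = {}
    pleio: dict = {o: {} for o in OUTCOME_SPECS}

    for target, reg in regions.items():
        rd = {"snps": reg.snps, "chrom": reg.chrom, "pos": reg.pos,
              "ea": reg.ea, "oa": reg.oa, "eaf": reg.eaf}
        L = _chol(reg.r)
        beta, se = _draw_marginal_summary(reg.r, reg.expr_beta_std, reg.eaf,
                                          cfg.n_exposure_gwas, 1.0, rng, chol=L)
        eqtl[target] = SummaryDataset(f"expr_{target}", _summary_frame(rd, beta, se, cfg.n_exposure_gwas),
                                      "continuous", "SD expression")
        ld[target] = reg.ld_reference()

        hba1c_beta_std = gamma * reg.expr_beta_std
        denom = np.sqrt(2.0 * reg.eaf * (1.0 - reg.eaf))
        for i in reg.causal_idx:
            truth_w_allele[reg.snps[i]] = float(hba1c_beta_std[i] / denom[i])
        beta, se = _draw_marginal_summary(reg.r, hba1c_beta_std, reg.eaf,
                                          cfg.n_hba1c_gwas, 1.0, rng, chol=L)
        hba1c_frames.append(_summary_frame(rd, beta, se, cfg.n_hba1c_gwas))

        for oname, (otype, _unit, osd, cf) in OUTCOME_SPECS.items():
            delta = cfg.outcome_effect(oname)
            out_beta_std = delta * hba1c_beta_std / (osd if otype == "continuous" else 1.0)
            if cfg.pleiotropy_sd > 0:
                direct = np.zeros(reg.n_variants)
                direct[reg.causal_idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=len(reg.causal_idx))
                for i in reg.causal_idx:
                    pleio[oname][reg.snps[i]] = float(direct[i])
                out_beta_std = out_beta_std + direct / (osd if otype == "continuous" else 1.0)
            eff_var = cf * (1.0 - cf) if otype == "binary" else 1.0
            beta, se = _draw_marginal_summary(reg.r, out_beta_std, reg.eaf,
                                              cfg.n_outcome_gwas, osd, rng,
                                              eff_var=eff_var, chol=L)
            outcome_frames[oname].append(_summary_frame(rd, beta, se, cfg.n_outcome_gwas))

    bm = _biomarker_panel(cfg, rng)
    denom = np.sqrt(2.0 * bm["eaf"] * (1.0 - bm["eaf"]))
    eye = np.eye(len(bm["snps"]))
    beta, se = _draw_marginal_summary(eye, bm["hba1c_beta_std"], bm["eaf"],
                                      cfg.n_hba1c_gwas, 1.0, rng)
    hba1c_frames.append(_summary_frame(bm, beta, se, cfg.n_hba1c_gwas))
    for oname, (otype, _unit, osd, cf) in OUTCOME_SPECS.items():
        if oname == "t2d":
            bstd = bm["t2d_beta_std"]
        else:
            delta = cfg.outcome_effect(oname)
            bstd = delta * bm["hba1c_beta_std"] / (osd if otype == "continuous" else 1.0)
        eff_var = cf * (1.0 - cf) if otype == "binary" else 1.0
        beta, se = _draw_marginal_summary(eye, bstd, bm["eaf"], cfg.n_outcome_gwas,
                                          osd, rng, eff_var=eff_var)
        outcome_frames[oname].append(_summary_frame(bm, beta, se, cfg.n_outcome_gwas))

    bm_ld = LDReference(bm["snps"], eye, np.repeat(bm["chrom"], len(bm["snps"])),
                        bm["pos"], bm["ea"], bm["oa"])
    ld["biomarker"] = bm_ld
    ld["all"] = combine_ld_references([ld[t] for t in sorted(regions)] + [bm_ld])

    hba1c = SummaryDataset("hba1c", pd.concat(hba1c_frames, ignore_index=True),
                           "continuous", "SD (0.62%) HbA1c")
    outcomes = {}
    for oname, (otype, unit, osd, _cf) in OUTCOME_SPECS.items():
        df = pd.concat(outcome_frames[oname], ignore_index=True)
        df = _swap_alleles(df, rng, cfg.frac_swapped_alleles)
        if cfg.frac_missing_outcome > 0:
            df = df[rng.random(len(df)) >= cfg.frac_missing_outcome].reset_index(drop=True)
        outcomes[oname] = SummaryDataset(oname, df, otype, unit, osd)

    truth = {
        "hba1c_allele_effects": truth_w_allele,
        "outcome_effects_per_sd_increase": {o: cfg.outcome_effect(o) for o in OUTCOME_SPECS},
        "causal_snps": {t: [r.snps[i] for i in r.causal_idx] for t, r in regions.items()},
        "pleiotropy": pleio,
        "gamma": gamma,
    }
    return StudySummaryData(eqtl=eqtl, hba1c=hba1c, outcomes=outcomes, ld=ld,
                            regions=regions, truth=truth)


# covariate effects on phenotypes: fixed, small and nonzero so that covariate
# adjustment in one-sample MR is observable
_COV_EFFECTS_HBA1C = np.array([0.010, 0.05, 0.02] + [0.01] * 10)       # per covariate unit
_COV_EFFECTS_OUT = {"bmi": 0.03, "sbp": 0.35, "dbp": 0.12}             # age coefficient
_CONFOUNDER_ON_HBA1C = 0.3
_CONFOUNDER_ON_OUT = {"bmi": 0.8, "sbp": 3.0, "dbp": 1.6}              # outcome units per SD U


def sample_dosages(eaf: np.ndarray, n: int, rng: np.random.Generator,
                   r_latent: np.ndarray | None = None) -> np.ndarray:
    """Dosages in {0,1,2} via latent-Gaussian thresholding of two haplotypes.

    With ``r_latent`` given, haplotype indicators are produced by
    thresholding correlated standard normals, yielding block LD at the
    dosage level (attenuated relative to the latent correlation — documented
    behaviour, not a bug). Without it, variants are independent binomials.
    """
    k = len(eaf)
    if r_latent is None:
        return rng.binomial(2, eaf[None, :].repeat(n, axis=0)).astype(float)
    L = _chol(r_latent)
    thr = stats.norm.ppf(eaf)
    g = np.zeros((n, k))
    for _hap in range(2):
        z = rng.standard_normal((n, k)) @ L.T
        g += (z < thr[None, :]).astype(float)
    return g


def simulate_cohort(cfg: SimConfig, study: StudySummaryData | None = None,
                    seed: int | None = None) -> CohortData:
    """Individual-level cohort for one-sample MR, consistent with the
    summary-level truth of ``study`` (regenerated from cfg.seed when absent).

    HbA1c (SD units, total variance 1) is the score-weighted genotype effect
    plus covariate effects, an unobserved confounder U and noise; continuous
    outcomes are causal_effect × HbA1c plus direct (pleiotropic) variant
    effects, covariate effects, the same confounder and noise, scaled to the
    outcome's phenotypic SD. ``seed`` overrides cfg.seed for the cohort draw
    only (replicate cohorts against one fixed summary-level truth).
    """
    if study is None:
        study = simulate_summary_stats(cfg)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed if seed is None else seed, 2)))
    n = cfg.n_cohort

    # dosages for every region variant (instruments may be LD neighbours of
    # the causal variants), generated block by block to bound memory
    snps, eafs, info_rows, blocks = [], [], [], []
    for reg in study.regions.values():
        for start in range(0, reg.n_variants, cfg.block_size):
            stop = min(start + cfg.block_size, reg.n_variants)
            blocks.append((reg, start, stop))
        snps.extend(reg.snps)
        eafs.extend(reg.eaf)
        for j, s in enumerate(reg.snps):
            info_rows.append({"SNP": s, "EA": reg.ea[j], "OA": reg.oa[j], "EAF": reg.eaf[j]})
    eafs = np.asarray(eafs)

    g = np.empty((n, len(snps)), dtype=np.float32)
    col = 0
    for reg, start, stop in blocks:
        width = stop - start
        r_latent = _block_corr(width, width, cfg.ld_block_rho)
        g[:, col:col + width] = sample_dosages(reg.eaf[start:stop], n, rng,
                                               r_latent=r_latent if width > 1 else None)
        col += width

    w_allele = study.truth["hba1c_allele_effects"]
    causal_cols = np.array([i for i, s in enumerate(snps) if s in w_allele])
    w = np.array([w_allele[snps[i]] for i in causal_cols])
    causal_eaf = eafs[causal_cols]
    # centred causal dosages (small slice; the full matrix stays float32)
    gc = np.asarray(g[:, causal_cols], dtype=float) - 2.0 * causal_eaf[None, :]

    age = rng.normal(57.0, 8.0, n)
    sex = rng.binomial(1, 0.54, n).astype(float)
    array = rng.binomial(1, 0.9, n).astype(float)
    pcs = rng.standard_normal((n, 10))
    cov = pd.DataFrame(np.column_stack([age, sex, array, pcs]), columns=COVARIATE_NAMES)
    cov_centred = np.column_stack([age - 57.0, sex - 0.54, array - 0.9, pcs])

    u = rng.standard_normal(n)
    genetic = gc @ w
    var_g = float(np.sum(w**2 * 2 * causal_eaf * (1 - causal_eaf)))
    cov_part = cov_centred @ _COV_EFFECTS_HBA1C
    var_cov = float(_COV_EFFECTS_HBA1C @ np.diag([64.0, 0.2484, 0.09] + [1.0] * 10) @ _COV_EFFECTS_HBA1C)
    resid_var = 1.0 - var_g - var_cov - _CONFOUNDER_ON_HBA1C**2
    if resid_var <= 0:
        raise ValueError("genetic + covariate + confounder variance exceeds the HbA1c variance")
    hba1c = genetic + cov_part + _CONFOUNDER_ON_HBA1C * u + math.sqrt(resid_var) * rng.standard_normal(n)

    pheno = {"hba1c": hba1c}
    for oname in ("bmi", "sbp", "dbp"):
        osd = OUTCOME_SPECS[oname][2]
        delta = cfg.outcome_effect(oname)
        direct = np.zeros(n)
        if cfg.pleiotropy_sd > 0:
            d = rng.normal(0.0, cfg.pleiotropy_sd, size=len(w)) / np.sqrt(2 * causal_eaf * (1 - causal_eaf))
            direct = gc @ d
        age_eff = _COV_EFFECTS_OUT[oname]
        conf = _CONFOUNDER_ON_OUT[oname]
        explained = delta**2 + (age_eff**2) * 64.0 + conf**2
        resid = osd**2 - explained
        if resid <= 0:
            raise ValueError(f"outcome {oname}: structural variance exceeds phenotypic variance")
        pheno[oname] = (delta * hba1c + direct + age_eff * (age - 57.0) + conf * u
                        + math.sqrt(resid) * rng.standard_normal(n))

    return CohortData(
        dosages=pd.DataFrame(g, columns=snps),
        covariates=cov,
        phenotypes=pd.DataFrame(pheno),
        variant_info=pd.DataFrame(info_rows),
    )


def simulate_coloc_region(shared: bool, n_variants: int, cfg: SimConfig,
                          z_causal: float = 10.0):
    """A two-trait region with a shared or distinct causal variant.

    Trait 1 is expression-like (sample size ``n_exposure_gwas``), trait 2
    HbA1c-like (``n_hba1c_gwas``). The causal z-score is ``z_causal`` in
    expectation (0 gives a null region). Distinct causal variants are placed
    in different LD blocks, hence r² ≈ 0 between them.
    """
    if n_variants < 2:
        raise ValueError("a colocalization region needs at least 2 variants")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 3)))
    k = n_variants
    ea, oa, pal = _assign_alleles(rng, k, 0.0)
    eaf = rng.uniform(max(cfg.maf_range[0], 0.1), cfg.maf_range[1], size=k)
    r = _block_corr(k, cfg.block_size, cfg.ld_block_rho)
    rd = {"snps": [f"rsc_{j:04d}" for j in range(k)], "chrom": "chr20",
          "pos": (3_000_000 + 5_000 * np.arange(k)).astype(int),
          "ea": ea, "oa": oa, "eaf": eaf}

    c1 = k // 2
    if shared:
        c2 = c1
    else:
        c2 = (c1 + 2 * cfg.block_size) % k
        if c2 // cfg.block_size == c1 // cfg.block_size:
            c2 = (c1 + cfg.block_size) % k

    b1 = np.zeros(k)
    b2 = np.zeros(k)
    b1[c1] = z_causal / math.sqrt(cfg.n_exposure_gwas)
    b2[c2] = z_causal / math.sqrt(cfg.n_hba1c_gwas)
    L = _chol(r)
    beta1, se1 = _draw_marginal_summary(r, b1, eaf, cfg.n_exposure_gwas, 1.0, rng, chol=L)
    beta2, se2 = _draw_marginal_summary(r, b2, eaf, cfg.n_hba1c_gwas, 1.0, rng, chol=L)
    sd1 = SummaryDataset("trait1", _summary_frame(rd, beta1, se1, cfg.n_exposure_gwas))
    sd2 = SummaryDataset("trait2", _summary_frame(rd, beta2, se2, cfg.n_hba1c_gwas))
    ldref = LDReference(rd["snps"], r, np.repeat("chr20", k), rd["pos"], ea, oa)
    return sd1, sd2, ldref


def simulate_harmonized_table(k: int = 34, true_effect: float = -0.22,
                              beta_exp_range: tuple = (0.02, 0.05),
                              se_exp: float = 0.0035, se_out: float = 0.004,
                              n_invalid: int = 0, invalid_shift: float = 0.0,
                              seed: int = 0, outcome: str = "outcome",
                              outcome_type: str = "continuous") -> HarmonizedTable:
    """Directly generate an oriented HarmonizedTable from known ratios — the
    light-weight generator behind estimator calibration and robustness
    suites. ``true_effect`` is the causal effect per 1 SD lowering; the last
    ``n_invalid`` instruments get their outcome effect shifted by
    ``invalid_shift × beta_exposure`` (directional pleiotropy).
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*beta_exp_range, size=k)  # SD lowered per allele
    by_true = true_effect * bx_true
    if n_invalid > 0:
        by_true[-n_invalid:] += invalid_shift * bx_true[-n_invalid:]
    bx = bx_true + se_exp * rng.standard_normal(k)
    by = by_true + se_out * rng.standard_normal(k)
    df = pd.DataFrame({
        "SNP": [f"rs_{j:04d}" for j in range(k)], "proxy_snp": "",
        "EA": "A", "OA": "G",
        "beta_exposure": bx, "se_exposure": se_exp, "eaf_exposure": 0.3,
        "beta_outcome": by, "se_outcome": se_out, "eaf_outcome": 0.3,
        "action": "kept",
    }, columns=HARMONIZED_COLUMNS)
    return HarmonizedTable("exposure", outcome, df, outcome_type=outcome_type, oriented=True)


def simulate_mvmr_table(k: int = 40, direct_effect_1: float = -0.3,
                        direct_effect_2: float = 0.0, exposure_corr: float = 0.6,
                        se_out: float = 0.01, seed: int = 0) -> pd.DataFrame:
    """Variant-level table for multivariable MR with two exposures whose
    genetic effects are correlated across variants; the outcome effect is
    direct_effect_1 · beta_exp1 + direct_effect_2 · beta_exp2 + noise."""
    rng = np.random.default_rng(seed)
    b1 = rng.uniform(0.05, 0.2, size=k) * rng.choice([-1.0, 1.0], size=k)
    b2 = exposure_corr * b1 + math.sqrt(max(0.0, 1 - exposure_corr**2)) * rng.uniform(0.05, 0.2, size=k) * rng.choice([-1.0, 1.0], size=k)
    by = direct_effect_1 * b1 + direct_effect_2 * b2 + se_out * rng.standard_normal(k)
    return pd.DataFrame({
        "SNP": [f"rs_{j:04d}" for j in range(k)],
        "BETA_exp1": b1 + 0.005 * rng.standard_normal(k), "SE_exp1": 0.005,
        "BETA_exp2": b2 + 0.005 * rng.standard_normal(k), "SE_exp2": 0.005,
        "BETA_out": by, "SE_out": se_out,
    })
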