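"""One-sample Mendelian randomization in an individual-level cohort.

Builds weighted allele scores from externally derived instruments, runs
two-stage least squares (2SLS) with covariate adjustment (age, sex,
genotyping array, top 10 PCs), and the "two-sample estimators within a
single cohort" workflow in which instrument weights come from an external
dataset (avoiding winner's curse) while the HbA1c and outcome associations
are estimated within the cohort by covariate-adjusted per-variant
regressions.

Sign convention: scores are oriented so that a higher score means more
genetically proxied HbA1c *lowering*, and all estimates are reported per
1 SD of HbA1c lowering — negative means the outcome falls when HbA1c falls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CohortData, COVARIATE_NAMES, MREstimate, SummaryDataset
from .harmonize import HarmonizedTable, HARMONIZED_COLUMNS, harmonize, orient_to_lowering
from .instrument_selection import InstrumentSet, WEAK_INSTRUMENT_F
from .mr2s import _normal_ci_p, estimator_battery


@dataclass
class GeneticScore:
    """Per-individual weighted allele score for one target.

    Weights are the instruments' HbA1c-lowering effects (positive, SD per
    allele) applied to the dosage of the lowering allele, so higher score =
    more HbA1c lowering.
    """

    target: str
    snps: list
    weights: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.var(self.values) <= 0:
            raise ValueError("score has zero variance")


def build_score(cohort: CohortData, iv: InstrumentSet, weighted: bool = True) -> GeneticScore:
    """Score = sum of weight_j x dosage_j of the HbA1c-lowering allele.

    Instruments absent from the cohort's dosage panel are an error (proxy
    substitution happens upstream at instrument level). ``weighted=False``
    uses unit weights (allele count score).
    """
    missing = [s for s in iv.snps if s not in cohort.dosages.columns]
    if missing:
        raise KeyError(f"instruments missing from cohort dosages: {missing}")
    parts = []
    weights = []
    for _, row in iv.table.iterrows():
        snp = row["SNP"]
        d = cohort.dosages[snp].to_numpy(float)
        cohort_ea = cohort.effect_allele(snp)
        beta = float(row["BETA"])  # exposure (HbA1c) effect of row EA
        # lowering allele: the allele whose effect on HbA1c is negative
        low_allele = row["EA"] if beta < 0 else row["OA"]
        if cohort_ea != low_allele:
            d = 2.0 - d
        w = abs(beta) if weighted else 1.0
        parts.append(w * d)
        weights.append(w)
    values = np.sum(parts, axis=0)
    return GeneticScore(iv.target, list(iv.snps), np.asarray(weights), values)


def _design(cohort: CohortData, covariates) -> np.ndarray:
    c = cohort.covariates[list(covariates)].to_numpy(float) if covariates else np.empty((cohort.n, 0))
    return np.column_stack([np.ones(cohort.n), c])


def _ols(x: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = x.shape[0] - x.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return beta, cov, resid


def tsls(cohort: CohortData, score: GeneticScore, outcome_name: str,
         covariates=COVARIATE_NAMES, exposure_name: str = "hba1c",
         robust: bool = False) -> MREstimate:
    """Two-stage least squares of an outcome on score-instrumented HbA1c.

    Stage 1 regresses HbA1c on score + covariates; stage 2 regresses the
    outcome on the stage-1 fitted values + covariates. Standard errors use
    the conventional IV variance with residuals computed from the *observed*
    exposure (``robust=True`` switches to the heteroskedasticity-robust
    sandwich). The estimate is reported per 1 SD HbA1c lowering.
    """
    if outcome_name not in cohort.phenotypes.columns:
        raise KeyError(f"outcome {outcome_name} not in cohort phenotypes")
    y = cohort.phenotypes[outcome_name].to_numpy(float)
    x_expo = cohort.phenotypes[exposure_name].to_numpy(float)
    c = _design(cohort, covariates)

    z1 = np.column_stack([score.values, c])
    beta1, cov1, _ = _ols(z1, x_expo)
    if abs(beta1[0]) < 1e-12:
        raise ValueError("zero first-stage coefficient; score does not predict the exposure")
    stage1_f = float(beta1[0] ** 2 / cov1[0, 0])
    fitted = z1 @ beta1

    x2 = np.column_stack([fitted, c])
    beta2, *_ = np.linalg.lstsq(x2, y, rcond=None)
    # IV variance: residuals from the observed exposure, not the fitted one
    x_struct = np.column_stack([x_expo, c])
    resid = y - x_struct @ beta2
    xtx_inv = np.linalg.inv(x2.T @ x2)
    if robust:
        meat = x2.T @ (x2 * (resid**2)[:, None])
        cov2 = xtx_inv @ meat @ xtx_inv
    else:
        sigma2 = float(resid @ resid) / (len(y) - x2.shape[1])
        cov2 = sigma2 * xtx_inv

    # per 1 SD lowering: negate the per-unit-increase coefficient
    b = -float(beta2[0])
    se = float(np.sqrt(cov2[0, 0]))
    lo, hi, p = _normal_ci_p(b, se)
    return MREstimate(method="Two stage least squares", beta=b, se=se, ci_low=lo,
                      ci_high=hi, pval=p, n_variants=len(score.snps),
                      exposure=score.target, outcome=outcome_name,
                      extras={"stage1_f": stage1_f, "design": "one_sample"})


def _adjusted_assoc(cohort: CohortData, values: np.ndarray, covariates) -> tuple[np.ndarray, np.ndarray]:
    """Covariate-adjusted per-variant regression of `values` on each dosage."""
    c = _design(cohort, covariates)
    betas, ses = [], []
    for snp in cohort.dosages.columns:
        x = np.column_stack([cohort.dosages[snp].to_numpy(float), c])
        beta, cov, _ = _ols(x, values)
        betas.append(beta[0])
        ses.append(np.sqrt(cov[0, 0]))
    return np.asarray(betas), np.asarray(ses)


def within_cohort_two_sample(cohort: CohortData, iv: InstrumentSet, outcome_name: str,
                             covariates=COVARIATE_NAMES, exposure_name: str = "hba1c",
                             n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """Two-sample MR estimators inside one cohort.

    Exposure effects come from the external instrument set (winner's-curse
    protection); outcome effects are the covariate-adjusted within-cohort
    per-variant regressions. A single-variant exposure routes to the Wald
    ratio. Results carry ``design = within_cohort_two_sample``.
    """
    snps = [s for s in iv.snps if s in cohort.dosages.columns]
    if not snps:
        raise KeyError("no instrument variants present in the cohort")
    sub = cohort.dosages[snps]
    y = cohort.phenotypes[outcome_name].to_numpy(float)
    c = _design(cohort, covariates)
    by, sy = [], []
    for snp in snps:
        x = np.column_stack([sub[snp].to_numpy(float), c])
        beta, cov, _ = _ols(x, y)
        by.append(beta[0])
        sy.append(np.sqrt(cov[0, 0]))

    itab = iv.table.set_index("SNP").loc[snps]
    rows = []
    for i, snp in enumerate(snps):
        e = itab.loc[snp]
        cohort_ea = cohort.effect_allele(snp)
        sign = 1.0 if cohort_ea == e["EA"] else -1.0
        rows.append({
            "SNP": snp, "proxy_snp": "", "EA": e["EA"], "OA": e["OA"],
            "beta_exposure": float(e["BETA"]), "se_exposure": float(e["SE"]),
            "eaf_exposure": float(e["EAF"]),
            "beta_outcome": sign * by[i], "se_outcome": sy[i],
            "eaf_outcome": float(e["EAF"]), "action": "kept",
        })
    tbl = HarmonizedTable(iv.target, outcome_name,
                          pd.DataFrame(rows, columns=HARMONIZED_COLUMNS))
    oriented = orient_to_lowering(tbl)
    ests = estimator_battery(oriented, n_boot=n_boot, seed=seed)
    for e in ests:
        e.extras["design"] = "within_cohort_two_sample"
    return ests


def one_sample_grid(cohort: CohortData, instrument_sets: dict, outcomes=("bmi", "sbp", "dbp"),
                    f_min: float = WEAK_INSTRUMENT_F, include_all_targets: bool = True,
                    n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """The one-sample result grid: all-targets plus per-target 2SLS and
    within-cohort two-sample estimates for each outcome.

    Targets whose score-exposure F falls below ``f_min`` are dropped from the
    target-specific runs (weak-instrument exclusion, as for the GCG
    instrument in the reference analysis) but still contribute to the
    combined all-targets exposure.
    """
    rows = []

    def add(est: MREstimate, exposure_set: str) -> None:
        row = est.to_row()
        row["exposure_set"] = exposure_set
        row["design"] = est.extras.get("design", "one_sample")
        row["stage1_f"] = est.extras.get("stage1_f", np.nan)
        rows.append(row)

    sets: list[tuple[str, InstrumentSet]] = []
    if include_all_targets:
        combined = pd.concat([iv.table for iv in instrument_sets.values()], ignore_index=True)
        sets.append(("all_targets", InstrumentSet("all_targets", combined)))
    sets += [("per_target", iv) for iv in instrument_sets.values()]

    for exposure_set, iv in sets:
        present = [s for s in iv.snps if s in cohort.dosages.columns]
        if not present:
            continue
        iv_here = InstrumentSet(iv.target, iv.table[iv.table["SNP"].isin(present)].reset_index(drop=True))
        score = build_score(cohort, iv_here)
        # first-stage strength of the score on the observed exposure
        z1 = np.column_stack([score.values, _design(cohort, COVARIATE_NAMES)])
        b1, cov1, _ = _ols(z1, cohort.phenotypes["hba1c"].to_numpy(float))
        score_f = float(b1[0] ** 2 / cov1[0, 0])
        if exposure_set == "per_target" and score_f < f_min:
            continue  # weak-instrument exclusion from target-specific runs
        for outcome in outcomes:
            est = tsls(cohort, score, outcome)
            add(est, exposure_set)
            for e in within_cohort_two_sample(cohort, iv_here, outcome,
                                              n_boot=n_boot, seed=seed):
                add(e, exposure_set)
    return pd.DataFrame(rows)
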