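"""Two-sample Mendelian randomization estimators and sensitivity statistics.

All estimators consume a :class:`~targetmr.harmonize.HarmonizedTable` in the
HbA1c-lowering orientation, so a negative estimate means the outcome is
lowered by genetically proxied HbA1c lowering (the metformin direction).
Per-variant Wald ratios (outcome effect over exposure effect, delta-method
standard errors) are combined by fixed- or multiplicative-random-effects
inverse-variance weighting; the pleiotropy-robust weighted median and
simple/weighted mode estimators and Cochran's Q heterogeneity statistic
follow the conventions of the standard two-sample MR toolchain. P-values are
two-sided normal throughout (large-sample GWAS convention).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import MREstimate
from .harmonize import HarmonizedTable

Z95 = 1.959963984540054  # Phi^{-1}(0.975)


def _normal_ci_p(beta: float, se: float) -> tuple[float, float, float]:
    if se <= 0 or not np.isfinite(se):
        return np.nan, np.nan, np.nan
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta - Z95 * se, beta + Z95 * se, max(p, 5e-324)


def _extract(tbl: HarmonizedTable):
    """Per-variant effect arrays from the kept rows of an oriented table."""
    if not tbl.oriented:
        raise ValueError("table must be oriented to the HbA1c-lowering allele first "
                         "(see harmonize.orient_to_lowering)")
    k = tbl.kept()
    bx = k["beta_exposure"].to_numpy(float)
    sx = k["se_exposure"].to_numpy(float)
    by = k["beta_outcome"].to_numpy(float)
    sy = k["se_outcome"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments; Wald ratios undefined")
    return bx, sx, by, sy, k["SNP"].tolist()


def _ratios(bx, sx, by, sy, first_order: bool = True):
    r = by / bx
    if first_order:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / np.abs(bx)
    return r, se


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float,
               first_order: bool = True, **meta) -> MREstimate:
    """Single-variant causal estimate beta_out/beta_exp.

    The default delta-method SE is the full first-order two-term form
    sqrt(se_out²/beta_exp² + beta_out²·se_exp²/beta_exp⁴); ``first_order=
    False`` gives the simpler se_out/|beta_exp|.
    """
    if beta_exp == 0:
        raise ValueError("beta_exp must be nonzero for a Wald ratio")
    r, se = _ratios(np.array([beta_exp]), np.array([se_exp]),
                    np.array([beta_out]), np.array([se_out]), first_order)
    lo, hi, p = _normal_ci_p(float(r[0]), float(se[0]))
    return MREstimate(method="Wald ratio", beta=float(r[0]), se=float(se[0]),
                      ci_low=lo, ci_high=hi, pval=p, n_variants=1, **meta)


def _q_statistic(r, w, beta):
    return float(np.sum(w * (r - beta) ** 2))


def ivw(tbl: HarmonizedTable, effects_model: str = "multiplicative_random", **meta) -> MREstimate:
    """Inverse-variance weighted meta-analysis of per-variant Wald ratios.

    ``effects_model``: ``fixed``, ``multiplicative_random`` (the default; SE
    inflated by sqrt(Q/(k−1)), floored at 1) or ``additive_random``
    (DerSimonian–Laird). A single-variant table routes to the Wald ratio,
    labelled accordingly.
    """
    bx, sx, by, sy, _ = _extract(tbl)
    meta = {"exposure": tbl.exposure, "outcome": tbl.outcome, "outcome_type": tbl.outcome_type, **meta}
    if len(bx) == 1:
        return wald_ratio(bx[0], sx[0], by[0], sy[0], **meta)
    if effects_model not in ("fixed", "multiplicative_random", "additive_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")

    r, se_r = _ratios(bx, sx, by, sy)
    w = 1.0 / se_r**2
    if not np.all(np.isfinite(w)) or np.sum(w) <= 0:
        raise ValueError("invalid inverse-variance weights")
    beta = float(np.sum(w * r) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    k = len(r)
    q = _q_statistic(r, w, beta)
    q_p = float(stats.chi2.sf(q, k - 1))

    if effects_model == "fixed":
        se, label = se_fixed, "IVW (fixed effects)"
    elif effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
        label = "Inverse variance weighted"
    else:  # additive DerSimonian-Laird
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (se_r**2 + tau2)
        beta = float(np.sum(w_star * r) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))
        label = "IVW (additive random effects)"
    lo, hi, p = _normal_ci_p(beta, se)
    return MREstimate(method=label, beta=beta, se=float(se), ci_low=lo, ci_high=hi,
                      pval=p, n_variants=k, q=q, q_df=k - 1, q_pval=q_p, **meta)


def cochran_q(tbl: HarmonizedTable) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test of the Wald ratios around the
    fixed-effects IVW estimate; returns (Q, df, p)."""
    bx, sx, by, sy, _ = _extract(tbl)
    if len(bx) < 2:
        raise ValueError("Cochran's Q needs >= 2 variants")
    r, se_r = _ratios(bx, sx, by, sy)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * r) / np.sum(w))
    q = _q_statistic(r, w, beta)
    df = len(r) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median at cumulative weight 0.5 (weights
    normalized to sum 1, midpoint cumulative convention)."""
    order = np.argsort(r, kind="mergesort")
    r, w = r[order], w[order] / np.sum(w)
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, r))


def weighted_median(tbl: HarmonizedTable, n_boot: int = 1000, seed: int = 0, **meta) -> MREstimate:
    """Weighted-median MR estimate: consistent when valid instruments carry
    more than half the inverse-variance weight. SE by seeded parametric
    bootstrap (per-variant betas resampled from their normals)."""
    bx, sx, by, sy, _ = _extract(tbl)
    if len(bx) < 3:
        raise ValueError("weighted median needs >= 3 variants")
    meta = {"exposure": tbl.exposure, "outcome": tbl.outcome, "outcome_type": tbl.outcome_type, **meta}
    r, se_r = _ratios(bx, sx, by, sy)
    w = 1.0 / se_r**2
    est = _weighted_median(r, w)
    se = _bootstrap_se(_weighted_median, bx, sx, by, sy, weighted=True, n_boot=n_boot, seed=seed)
    lo, hi, p = _normal_ci_p(est, se)
    return MREstimate(method="Weighted median", beta=est, se=se, ci_low=lo, ci_high=hi,
                      pval=p, n_variants=len(bx), **meta)


def _mode_point(r: np.ndarray, w: np.ndarray, bandwidth_factor: float = 1.0) -> float:
    """Argmax of the normal-kernel weighted density of the ratios, with the
    Silverman-type bandwidth phi * 0.9 * min(sd, iqr/1.34) * k^(-1/5)."""
    k = len(r)
    sd = np.std(r, ddof=1) if k > 1 else 0.0
    iqr = np.subtract(*np.percentile(r, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = bandwidth_factor * 0.9 * spread * k ** (-0.2)
    if h <= 0 or not np.isfinite(h):
        return float(r[0])  # all ratios identical
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 2048)
    wn = w / np.sum(w)
    dens = np.sum(wn[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2), axis=0)
    return float(grid[np.argmax(dens)])


def mode_estimator(tbl: HarmonizedTable, weighted: bool = True, bandwidth_factor: float = 1.0,
                   n_boot: int = 1000, seed: int = 0, **meta) -> MREstimate:
    """Simple or weighted mode MR estimate (ZEMPA: consistent when the most
    common ratio among instruments is the causal one). SE by seeded
    parametric bootstrap."""
    bx, sx, by, sy, _ = _extract(tbl)
    if len(bx) < 3:
        raise ValueError("mode estimator needs >= 3 variants")
    meta = {"exposure": tbl.exposure, "outcome": tbl.outcome, "outcome_type": tbl.outcome_type, **meta}
    r, se_r = _ratios(bx, sx, by, sy)
    w = 1.0 / se_r**2 if weighted else np.ones_like(r)

    def point(rr, ww):
        return _mode_point(rr, ww, bandwidth_factor)

    est = point(r, w)
    se = _bootstrap_se(point, bx, sx, by, sy, weighted=weighted, n_boot=n_boot, seed=seed,
                       bandwidth_factor=bandwidth_factor)
    lo, hi, p = _normal_ci_p(est, se)
    return MREstimate(method="Weighted mode" if weighted else "Simple mode",
                      beta=est, se=se, ci_low=lo, ci_high=hi, pval=p, n_variants=len(bx), **meta)


def _bootstrap_se(point_fn, bx, sx, by, sy, weighted: bool, n_boot: int, seed: int,
                  **kw) -> float:
    if n_boot < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    k = len(bx)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sx * rng.standard_normal(k)
        byb = by + sy * rng.standard_normal(k)
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        rb, se_rb = _ratios(bxb, sx, byb, sy)
        wb = 1.0 / se_rb**2 if weighted else np.ones(k)
        if "bandwidth_factor" in kw:
            ests[b] = point_fn(rb, wb)
        else:
            ests[b] = point_fn(rb, wb)
    return float(np.std(ests, ddof=1))


def leave_one_out(tbl: HarmonizedTable, effects_model: str = "multiplicative_random"):
    """Leave-one-variant-out IVW re-estimates plus the single-variant Wald
    forest, for spotting single influential variants.

    Returns a (loo_table, single_variant_table) pair of DataFrames.
    """
    import pandas as pd

    bx, sx, by, sy, snps = _extract(tbl)
    if len(bx) < 3:
        raise ValueError("leave-one-out needs >= 3 variants")
    loo_rows, single_rows = [], []
    for i, snp in enumerate(snps):
        mask = np.ones(len(bx), bool)
        mask[i] = False
        sub = tbl.kept().loc[mask].reset_index(drop=True)
        sub_tbl = HarmonizedTable(tbl.exposure, tbl.outcome, sub, tbl.outcome_type, oriented=True)
        est = ivw(sub_tbl, effects_model=effects_model)
        loo_rows.append({"omitted": snp, "b": est.beta, "se": est.se,
                         "lo95": est.ci_low, "up95": est.ci_high, "p": est.pval})
        w = wald_ratio(bx[i], sx[i], by[i], sy[i])
        single_rows.append({"SNP": snp, "b": w.beta, "se": w.se,
                            "lo95": w.ci_low, "up95": w.ci_high, "p": w.pval})
    return pd.DataFrame(loo_rows), pd.DataFrame(single_rows)


def scale_estimate(est: MREstimate, sd_in_trait_units: float = 0.62,
                   outcome_type: str | None = None) -> MREstimate:
    """Annotate the SD-lowering scale (1 SD of HbA1c ≈ a 0.62% absolute
    reduction) and, for binary outcomes, attach the odds-ratio view:
    OR = exp(beta), CI bounds mapped monotonically, percent change in odds
    = 100·(1−OR). Betas are already per SD, so no renormalization occurs.
    """
    if sd_in_trait_units <= 0:
        raise ValueError("sd_in_trait_units must be positive")
    otype = outcome_type or est.outcome_type
    out = MREstimate(**{**est.__dict__})
    out.unit = f"per 1 SD ({sd_in_trait_units:g}% absolute) HbA1c lowering"
    if otype == "binary":
        out.outcome_type = "binary"
        out.odds_ratio = float(np.exp(est.beta))
        out.or_ci_low = float(np.exp(est.ci_low))
        out.or_ci_high = float(np.exp(est.ci_high))
        out.percent_risk_change = 100.0 * (1.0 - out.odds_ratio)
    return out


def estimator_battery(tbl: HarmonizedTable, n_boot: int = 1000, seed: int = 0,
                      include_modes: bool = True) -> list[MREstimate]:
    """The reference battery: IVW (random), IVW (fixed), weighted median and
    weighted mode for multi-variant exposures; Wald ratio for single-variant
    ones. Median/mode need >= 3 variants and are skipped below that."""
    bx = _extract(tbl)[0]
    k = len(bx)
    out = [ivw(tbl, "multiplicative_random")]
    if k >= 2:
        out.append(ivw(tbl, "fixed"))
    if include_modes and k >= 3:
        out.append(weighted_median(tbl, n_boot=n_boot, seed=seed))
        out.append(mode_estimator(tbl, weighted=True, n_boot=n_boot, seed=seed + 1))
    return out
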