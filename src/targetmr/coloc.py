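"""Approximate-Bayes-factor colocalization of two regional association sets.

Tests whether two traits share a single causal variant in a genomic region,
under the classic single-causal-variant-per-trait model. For each variant a
Wakefield approximate Bayes factor compares "this variant is causal" against
the null, and configuration sums over variants give posterior probabilities
for five hypotheses:

H0 no association with either trait; H1/H2 association with trait 1/2 only;
H3 both traits associated, distinct causal variants; H4 both traits
associated, one shared causal variant. The "colocalization probability" used
for instrument selection is PP(H4); PP(H3)+PP(H4) is also reported.

All sums are done in log space so regions with |z| up to ~100 are handled
without overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import COMPLEMENT, SummaryDataset

HYPOTHESES = ["pp_h0", "pp_h1", "pp_h2", "pp_h3", "pp_h4"]


@dataclass
class ColocPriors:
    """Per-variant prior probabilities and effect-size prior scales.

    p1/p2: prior that a variant is causal for trait 1 / trait 2.
    p12: prior that a variant is causal for both.
    prior_sd_quant / prior_sd_binary: SD of the causal effect prior on the
    standardized (continuous) and log-odds (binary) scales.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    prior_sd_quant: float = 0.15
    prior_sd_binary: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.p12 <= min(self.p1, self.p2) < 1.0):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")

    def prior_sd_for(self, ds: SummaryDataset) -> float:
        return self.prior_sd_binary if ds.trait_type == "binary" else self.prior_sd_quant


@dataclass
class ColocResult:
    pp: np.ndarray  # [pp_h0..pp_h4]
    n_variants: int
    labf1: np.ndarray
    labf2: np.ndarray
    snps: list

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.pp)) - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")

    @property
    def pp_h4(self) -> float:
        return float(self.pp[4])

    @property
    def pp_h3_plus_h4(self) -> float:
        return float(self.pp[3] + self.pp[4])

    def as_dict(self) -> dict:
        out = {h: float(v) for h, v in zip(HYPOTHESES, self.pp)}
        out["n_variants"] = self.n_variants
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame([self.as_dict()]).to_csv(path, sep="\t", index=False, float_format="%.8g")


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one association.

    With z = beta/se and shrinkage r = prior_sd^2 / (se^2 + prior_sd^2):
    log ABF = 0.5 log(1 - r) + 0.5 z^2 r, the log marginal-likelihood ratio
    of "causal with N(0, prior_sd^2) effect" against "no effect".
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    z = beta / se
    r = prior_sd**2 / (se**2 + prior_sd**2)
    return 0.5 * np.log1p(-r) + 0.5 * z * z * r


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, clamped at -inf when they coincide."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def _intersect_regions(region1: SummaryDataset, region2: SummaryDataset) -> pd.DataFrame:
    d1 = region1.df.set_index("SNP")
    d2 = region2.df.set_index("SNP")
    common = d1.index.intersection(d2.index)
    rows = []
    for snp in common:
        a, b = d1.loc[snp], d2.loc[snp]
        pair1 = (a["EA"], a["OA"])
        pair2 = (b["EA"], b["OA"])
        flip2 = (COMPLEMENT[b["EA"]], COMPLEMENT[b["OA"]])
        if set(pair1) == set(pair2) or set(pair1) == set(flip2):
            rows.append({"SNP": snp, "BETA1": a["BETA"], "SE1": a["SE"], "BETA2": b["BETA"], "SE2": b["SE"]})
        else:
            warnings.warn(f"variant {snp} has incompatible alleles across traits; excluded from coloc")
    return pd.DataFrame(rows)


def colocalize(region1: SummaryDataset, region2: SummaryDataset, priors: ColocPriors | None = None) -> ColocResult:
    """Colocalize two traits' regional summary statistics.

    Variants are intersected on id (alleles must match up to swap and/or
    strand complement; ABFs depend on z^2 only, so orientation is moot).
    Requires at least 2 shared variants.
    """
    priors = priors or ColocPriors()
    merged = _intersect_regions(region1, region2)
    if len(merged) < 2:
        raise ValueError("colocalization needs >= 2 variants shared between the regions")

    labf1 = log_abf(merged["BETA1"].to_numpy(), merged["SE1"].to_numpy(), priors.prior_sd_for(region1))
    labf2 = log_abf(merged["BETA2"].to_numpy(), merged["SE2"].to_numpy(), priors.prior_sd_for(region2))

    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l12 = logsumexp(labf1 + labf2)  # sum over shared-variant configurations

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(priors.p1) + l1
    lh[2] = np.log(priors.p2) + l2
    # H3 sums over ordered pairs i != j: (sum_i)(sum_j) - sum_{i=j}
    lh[3] = np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(l1 + l2, l12)
    lh[4] = np.log(priors.p12) + l12

    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(pp=pp, n_variants=len(merged), labf1=labf1, labf2=labf2, snps=merged["SNP"].tolist())
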