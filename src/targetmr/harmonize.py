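"""Align exposure and outcome summary statistics to a shared effect allele.

Exposure instruments and outcome records may be reported on different alleles
or strands. This module brings every instrument/outcome pair onto one effect
allele, drops strand-ambiguous (palindromic) variants whose minor allele
frequency makes orientation unreliable, substitutes high-LD proxies for
instruments missing from the outcome dataset, and finally re-signs the table
so that the effect allele is always the HbA1c-lowering allele (the metformin
direction): a negative outcome beta then means the outcome is lowered by
genetically proxied HbA1c lowering.

Reason codes in the ``action`` column:

- ``kept`` — alleles matched directly (possibly after strand complement)
- ``flipped`` — outcome alleles were swapped; beta negated, EAF complemented
- ``proxied`` — instrument missing from outcome, replaced by an LD proxy
- ``dropped_palindromic`` — A/T or C/G variant with MAF > threshold
- ``dropped_missing`` — absent from outcome and no adequate proxy
- ``allele_mismatch`` — alleles irreconcilable even after strand complement
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import COMPLEMENT, LDReference, SummaryDataset, is_palindromic

KEPT_ACTIONS = ("kept", "flipped", "proxied")

HARMONIZED_COLUMNS = [
    "SNP", "proxy_snp", "EA", "OA",
    "beta_exposure", "se_exposure", "eaf_exposure",
    "beta_outcome", "se_outcome", "eaf_outcome",
    "action",
]


@dataclass
class HarmonizedTable:
    """Instrument-wise aligned exposure/outcome effect pairs ready for MR.

    ``oriented`` marks the HbA1c-lowering normal form: ``beta_exposure`` is
    then a positive number of exposure SDs *lowered* per effect allele, and
    ``beta_outcome`` is the outcome effect of that same (lowering) allele.
    """

    exposure: str
    outcome: str
    df: pd.DataFrame
    outcome_type: str = "continuous"
    oriented: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"harmonized table lacks columns {missing}")

    def kept(self) -> pd.DataFrame:
        return self.df[self.df["action"].isin(KEPT_ACTIONS)].reset_index(drop=True)

    @property
    def n_kept(self) -> int:
        return int(self.df["action"].isin(KEPT_ACTIONS).sum())

    def to_tsv(self, path) -> None:
        # orientation state travels with the table
        self.df.assign(oriented=self.oriented).to_csv(path, sep="\t", index=False,
                                                      float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, exposure="exposure", outcome="outcome", **kw) -> "HarmonizedTable":
        df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "proxy_snp": str, "EA": str, "OA": str})
        df["proxy_snp"] = df["proxy_snp"].fillna("")
        if "oriented" in df.columns:
            kw.setdefault("oriented", bool(df["oriented"].iloc[0]))
            df = df.drop(columns=["oriented"])
        return cls(exposure, outcome, df, **kw)


def _maf(eaf: float) -> float:
    return min(eaf, 1.0 - eaf)


def _strand_complement(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def _align_outcome(exp_ea, exp_oa, out_ea, out_oa, beta_out, eaf_out, exp_eaf,
                   palindrome_maf_max, infer_palindromic_strand=True):
    """Return (beta, eaf, action) for the outcome record expressed on the
    exposure's effect allele, or (None, None, reason) when the row drops."""
    if is_palindromic(exp_ea, exp_oa):
        if _maf(exp_eaf) > palindrome_maf_max or _maf(eaf_out) > palindrome_maf_max:
            return None, None, "dropped_palindromic"
        # letters alone cannot resolve strand; align by letter, then check
        # allele-frequency agreement to detect a strand flip
        if out_ea == exp_ea:
            beta, eaf, action = beta_out, eaf_out, "kept"
        elif out_ea == exp_oa:
            beta, eaf, action = -beta_out, 1.0 - eaf_out, "flipped"
        else:
            return None, None, "allele_mismatch"
        if infer_palindromic_strand and (exp_eaf - 0.5) * (eaf - 0.5) < 0:
            beta, eaf = -beta, 1.0 - eaf
            action = "flipped"
        return beta, eaf, action

    # non-palindromic: try direct, swapped, then strand-complemented forms
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return beta_out, eaf_out, "kept"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return -beta_out, 1.0 - eaf_out, "flipped"
    c_ea, c_oa = _strand_complement(out_ea, out_oa)
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return beta_out, eaf_out, "kept"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return -beta_out, 1.0 - eaf_out, "flipped"
    return None, None, "allele_mismatch"


def _find_proxy(snp, ld: LDReference, outcome_snps: set, proxy_r2_min: float, window_bp: float):
    """Best available proxy for `snp` in the outcome set: highest r², ties
    broken by distance then id."""
    try:
        i = ld.index(snp)
    except KeyError:
        return None
    pos_i, chrom_i = ld.pos[i], ld.chrom[i]
    best = None
    for j, cand in enumerate(ld.snps):
        if cand == snp or cand not in outcome_snps:
            continue
        if str(ld.chrom[j]) != str(chrom_i) or abs(int(ld.pos[j]) - int(pos_i)) > window_bp:
            continue
        r = float(ld.r[i, j])
        if r * r <= proxy_r2_min:
            continue
        key = (-r * r, abs(int(ld.pos[j]) - int(pos_i)), str(cand))
        if best is None or key < best[0]:
            best = (key, cand, r)
    if best is None:
        return None
    return best[1], best[2]


def harmonize(exposure, outcome: SummaryDataset, ld: LDReference | None = None,
              palindrome_maf_max: float = 0.4, proxy_r2_min: float = 0.8,
              proxy_window_bp: float = 500_000,
              infer_palindromic_strand: bool = True) -> HarmonizedTable:
    """Build a HarmonizedTable from an instrument set and an outcome dataset.

    Parameters
    ----------
    exposure
        An ``InstrumentSet`` or a DataFrame in the summary-column dialect,
        holding the exposure-side associations of the instruments.
    outcome
        Outcome-trait summary statistics.
    ld
        Signed-r LD reference; enables proxy substitution for instruments
        missing from the outcome dataset. The proxy substitutes on the
        outcome side only — the original instrument's exposure effect is
        retained.
    palindrome_maf_max
        Palindromic variants with MAF above this on either side are dropped.
    proxy_r2_min
        Minimum r² (strict) for a proxy; search window ±``proxy_window_bp``.
    """
    exp_df = exposure.table if hasattr(exposure, "table") else exposure
    exp_name = getattr(exposure, "target", "exposure")
    out_by_snp = outcome.df.set_index("SNP")
    outcome_snps = set(outcome.df["SNP"])

    rows = []
    for _, e in exp_df.iterrows():
        snp = e["SNP"]
        row = {
            "SNP": snp, "proxy_snp": "", "EA": e["EA"], "OA": e["OA"],
            "beta_exposure": float(e["BETA"]), "se_exposure": float(e["SE"]),
            "eaf_exposure": float(e["EAF"]),
            "beta_outcome": np.nan, "se_outcome": np.nan, "eaf_outcome": np.nan,
        }
        if snp in outcome_snps:
            o = out_by_snp.loc[snp]
            beta, eaf, action = _align_outcome(
                e["EA"], e["OA"], o["EA"], o["OA"], float(o["BETA"]), float(o["EAF"]),
                float(e["EAF"]), palindrome_maf_max, infer_palindromic_strand)
            if beta is None:
                if action == "allele_mismatch":
                    warnings.warn(f"variant {snp}: irreconcilable alleles between exposure and outcome")
            else:
                row.update(beta_outcome=beta, se_outcome=float(o["SE"]), eaf_outcome=eaf)
            row["action"] = action
        elif ld is not None:
            hit = _find_proxy(snp, ld, outcome_snps, proxy_r2_min, proxy_window_bp)
            if hit is None:
                row["action"] = "dropped_missing"
            else:
                proxy, r_sign = hit
                o = out_by_snp.loc[proxy]
                j = ld.index(proxy)
                # orient the proxy's outcome record to the LD panel's phase
                beta, eaf, act = _align_outcome(
                    ld.ea[j], ld.oa[j], o["EA"], o["OA"], float(o["BETA"]), float(o["EAF"]),
                    float(e["EAF"]), palindrome_maf_max, infer_palindromic_strand)
                if beta is None:
                    row["action"] = "dropped_missing"
                else:
                    # transfer through signed LD onto the instrument's panel
                    # allele, then onto the instrument's exposure EA
                    i = ld.index(snp)
                    sign = np.sign(r_sign) if r_sign != 0 else 1.0
                    if (e["EA"], e["OA"]) == (ld.oa[i], ld.ea[i]):
                        sign = -sign
                    row.update(beta_outcome=sign * beta, se_outcome=float(o["SE"]),
                               eaf_outcome=eaf if sign > 0 else 1.0 - eaf,
                               proxy_snp=proxy)
                    row["action"] = "proxied"
        else:
            row["action"] = "dropped_missing"
        rows.append(row)

    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedTable(exposure=exp_name, outcome=outcome.trait, df=df,
                           outcome_type=outcome.trait_type)


def orient_to_lowering(tbl: HarmonizedTable) -> HarmonizedTable:
    """Re-sign every row so the effect allele is the HbA1c-lowering allele.

    After orientation ``beta_exposure`` holds the (positive) number of
    exposure SDs lowered per effect allele and ``beta_outcome`` the effect of
    that allele on the outcome, so Wald ratios read as outcome change per
    1 SD of HbA1c lowering. Idempotent: an oriented table is returned as-is.
    """
    if tbl.oriented:
        return tbl
    df = tbl.df.copy()
    kept = df["action"].isin(KEPT_ACTIONS)
    raising = kept & (df["beta_exposure"] > 0)
    for col_a, col_b in (("EA", "OA"),):
        ea = df.loc[raising, col_a].copy()
        df.loc[raising, col_a] = df.loc[raising, col_b]
        df.loc[raising, col_b] = ea
    df.loc[raising, "eaf_exposure"] = 1.0 - df.loc[raising, "eaf_exposure"]
    df.loc[raising, "eaf_outcome"] = 1.0 - df.loc[raising, "eaf_outcome"]
    df.loc[raising, "beta_exposure"] *= -1.0
    df.loc[raising, "beta_outcome"] *= -1.0
    # express exposure column as SD *lowered* per effect allele (positive)
    df.loc[kept, "beta_exposure"] = -df.loc[kept, "beta_exposure"]
    return replace(tbl, df=df, oriented=True)
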