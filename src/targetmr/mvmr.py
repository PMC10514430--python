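"""Multivariable Mendelian randomization (MVMR-IVW).

Univariable MR estimates a *total* causal effect; when instruments also act
through a secondary exposure (here: red-blood-cell traits on the
HbA1c-to-outcome path), the *direct* effect of the exposure of interest is
estimated by regressing variant-outcome effects jointly on all exposures'
variant-exposure effects — weighted least squares without intercept, weights
1/se_out², with a multiplicative overdispersion factor floored at 1 (the
same convention as the univariable random-effects IVW).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .datatypes import MREstimate
from .mr2s import _normal_ci_p


def exposure_names(tbl: pd.DataFrame) -> list[str]:
    """Exposure suffixes from BETA_<name>/SE_<name> column pairs (the
    outcome columns BETA_out/SE_out excluded)."""
    names = []
    for c in tbl.columns:
        m = re.fullmatch(r"BETA_(.+)", c)
        if m and m.group(1) != "out":
            if f"SE_{m.group(1)}" not in tbl.columns:
                raise ValueError(f"missing SE column for exposure {m.group(1)}")
            names.append(m.group(1))
    return names


def mvmr_ivw(tbl: pd.DataFrame, outcome: str = "outcome",
             outcome_type: str = "continuous") -> list[MREstimate]:
    """Direct effects of each exposure, adjusted for the others.

    ``tbl`` holds one row per variant with columns BETA_<exposure>,
    SE_<exposure> for each of m >= 2 exposures and BETA_out, SE_out, all
    aligned to one effect allele. Requires more variants than exposures and a
    full-rank design.
    """
    names = exposure_names(tbl)
    m = len(names)
    if m < 2:
        raise ValueError("multivariable MR needs >= 2 exposures")
    clean = tbl.dropna(subset=[f"BETA_{n}" for n in names] + ["BETA_out", "SE_out"])
    k = len(clean)
    if k <= m:
        raise ValueError(f"need more variants ({k}) than exposures ({m})")

    x_full = clean[[f"BETA_{n}" for n in names]].to_numpy(float)
    y = clean["BETA_out"].to_numpy(float)
    w = 1.0 / clean["SE_out"].to_numpy(float) ** 2

    # an all-zero exposure column carries no signal: it is reported with a
    # zero direct effect and the fit reduces to the remaining exposures
    # (with a single remaining exposure, exactly the univariable IVW)
    active = [j for j in range(m) if np.any(x_full[:, j] != 0)]
    x = x_full[:, active]
    if np.linalg.matrix_rank(x) < len(active):
        raise np.linalg.LinAlgError("rank-deficient exposure design")

    sw = np.sqrt(w)
    xw = x * sw[:, None]
    yw = y * sw
    xtx = xw.T @ xw
    beta_active = np.linalg.solve(xtx, xw.T @ yw)
    resid = yw - xw @ beta_active
    # multiplicative overdispersion, floored at 1
    phi = max(1.0, float(resid @ resid) / (k - len(active)))
    cov = phi * np.linalg.inv(xtx)
    ses_active = np.sqrt(np.diag(cov))

    beta = np.zeros(m)
    ses = np.full(m, np.nan)
    for pos, j in enumerate(active):
        beta[j] = beta_active[pos]
        ses[j] = ses_active[pos]

    out = []
    for j, name in enumerate(names):
        lo, hi, p = _normal_ci_p(float(beta[j]), float(ses[j]))
        out.append(MREstimate(
            method="Multivariable IVW", beta=float(beta[j]), se=float(ses[j]),
            ci_low=lo, ci_high=hi, pval=p, n_variants=k,
            exposure=name, outcome=outcome, outcome_type=outcome_type,
            extras={"adjusted_for": [n for n in names if n != name],
                    "overdispersion": phi},
        ))
    return out


def mvmr_results_frame(estimates: list[MREstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        row = e.to_row()
        row["adjusted_for"] = ",".join(e.extras.get("adjusted_for", []))
        rows.append(row)
    return pd.DataFrame(rows)
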