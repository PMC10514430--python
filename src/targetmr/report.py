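"""Result assembly: Bonferroni flags, long-format grids, forest plots, and
trial-vs-MR triangulation rescaling.

MR estimates are expressed per 1 SD (0.62 percentage-point) HbA1c lowering;
a clinical trial reports its own mean HbA1c reduction, so the two evidence
sources are made comparable by linear rescaling of the MR effect (point and
CI bounds identically) to the trial's HbA1c dose. Concordance is declared
when the rescaled CIs overlap and the point estimates share a sign.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MREstimate

HBA1C_SD_PCT = 0.62  # 1 SD of HbA1c expressed in absolute percentage points


def bonferroni_threshold(n_tests: int = 8, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bonferroni_flag(results: pd.DataFrame, n_tests: int = 8, alpha: float = 0.05,
                    p_col: str = "p") -> pd.DataFrame:
    """Flag rows passing the multiplicity-corrected threshold alpha/n_tests
    (strict inequality: p exactly at the threshold does not pass)."""
    thr = bonferroni_threshold(n_tests, alpha)
    out = results.copy()
    out["bonferroni_threshold"] = thr
    out["pass_bonferroni"] = out[p_col] < thr
    return out


@dataclass
class TriangulationEntry:
    """One outcome's trial-vs-MR comparison on a common HbA1c-dose scale."""

    outcome: str
    trial_effect: float
    trial_ci: tuple
    trial_hba1c_reduction_pct: float
    mr_effect_per_sd: float
    mr_ci_per_sd: tuple
    rescaled_mr_effect: float
    rescaled_mr_ci: tuple
    concordant: bool | None

    def as_dict(self) -> dict:
        trial_ci = self.trial_ci if self.trial_ci is not None else (float("nan"),) * 2
        return {
            "outcome": self.outcome,
            "trial_effect": self.trial_effect,
            "trial_lo95": trial_ci[0], "trial_up95": trial_ci[1],
            "trial_hba1c_reduction_pct": self.trial_hba1c_reduction_pct,
            "mr_effect_per_sd": self.mr_effect_per_sd,
            "mr_rescaled": self.rescaled_mr_effect,
            "mr_rescaled_lo95": self.rescaled_mr_ci[0],
            "mr_rescaled_up95": self.rescaled_mr_ci[1],
            "concordant": self.concordant,
        }


def rescale_to_trial(mr: MREstimate, trial_hba1c_reduction_pct: float,
                     sd_pct: float = HBA1C_SD_PCT,
                     trial_effect: float | None = None,
                     trial_ci: tuple | None = None) -> TriangulationEntry:
    """Rescale an MR estimate (per 1 SD = ``sd_pct``% lowering) to a trial's
    mean HbA1c reduction; the scaling is linear and applied identically to
    the point estimate and both CI bounds."""
    if sd_pct <= 0:
        raise ValueError("sd_pct must be positive")
    f = trial_hba1c_reduction_pct / sd_pct
    rescaled = mr.beta * f
    ci = (mr.ci_low * f, mr.ci_high * f) if f >= 0 else (mr.ci_high * f, mr.ci_low * f)
    concordant = None
    if trial_effect is not None and trial_ci is not None:
        overlap = (ci[0] <= trial_ci[1]) and (trial_ci[0] <= ci[1])
        same_sign = np.sign(rescaled) == np.sign(trial_effect)
        concordant = bool(overlap and same_sign)
    return TriangulationEntry(
        outcome=mr.outcome, trial_effect=trial_effect, trial_ci=trial_ci,
        trial_hba1c_reduction_pct=trial_hba1c_reduction_pct,
        mr_effect_per_sd=mr.beta, mr_ci_per_sd=(mr.ci_low, mr.ci_high),
        rescaled_mr_effect=rescaled, rescaled_mr_ci=ci, concordant=concordant)


def make_provenance(seed: int, config: dict | None = None, inputs: dict | None = None) -> dict:
    """Provenance record: seed plus stable hashes of the config and inputs."""
    def _hash(obj) -> str:
        return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]

    return {"seed": seed,
            "config_hash": _hash(config or {}),
            "inputs_hash": _hash(inputs or {})}


GRID_SORT = ["exposure_set", "outcome", "exposure", "method"]


def result_grid(estimates, provenance: dict | None = None) -> pd.DataFrame:
    """Long-format grid keyed by exposure-set x outcome x method.

    ``estimates`` is an iterable of (exposure_set, MREstimate) pairs or a
    dict mapping exposure-set label to a list of estimates. Ordering is
    deterministic so identical inputs reproduce byte-identical tables.
    """
    if isinstance(estimates, dict):
        pairs = [(k, e) for k, lst in estimates.items() for e in lst]
    else:
        pairs = list(estimates)
    rows = []
    for exposure_set, est in pairs:
        row = est.to_row()
        row["exposure_set"] = exposure_set
        if est.outcome_type == "binary" and np.isfinite(est.odds_ratio):
            row["OR"] = est.odds_ratio
            row["OR_lo95"] = est.or_ci_low
            row["OR_up95"] = est.or_ci_high
        for key, val in (provenance or {}).items():
            row[key] = val
        rows.append(row)
    grid = pd.DataFrame(rows)
    return grid.sort_values(GRID_SORT, kind="mergesort").reset_index(drop=True)


def forest_plot(grid: pd.DataFrame, path, title: str = "") -> None:
    """Minimal forest-style figure of the grid, written as vector SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = grid.reset_index(drop=True)
    labels = [f"{r['exposure_set']}:{r['outcome']}:{r['method']}" for _, r in g.iterrows()]
    y = np.arange(len(g))[::-1]
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.3 * len(g) + 1)))
    ax.errorbar(g["b"], y, xerr=[g["b"] - g["lo95"], g["up95"] - g["b"]],
                fmt="o", color="black", ecolor="gray", capsize=2, markersize=3)
    ax.axvline(0.0, color="steelblue", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("effect per 1 SD HbA1c lowering")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def triangulation_table(entries) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in entries])
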