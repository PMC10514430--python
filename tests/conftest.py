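import numpy as np
import pandas as pd
import pytest

import targetmr as tm


@pytest.fixture(scope="session")
def cfg():
    """Study conditions with a small cohort (summary-level generation cost
    does not depend on sample size, so GWAS sizes stay at study scale)."""
    return tm.SimConfig(seed=11, n_cohort=2500)


@pytest.fixture(scope="session")
def study(cfg):
    return tm.simulate_summary_stats(cfg)


@pytest.fixture(scope="session")
def instrument_sets(cfg, study):
    ivs = {}
    for target in study.eqtl:
        iv = tm.select_target_instruments(study.eqtl[target], study.hba1c,
                                          study.ld[target], target=target)
        if iv.n_instruments:
            ivs[target] = iv
    return ivs


@pytest.fixture(scope="session")
def all_targets_iv(instrument_sets):
    combined = pd.concat([iv.table for iv in instrument_sets.values()], ignore_index=True)
    return tm.InstrumentSet("all_targets", combined)


@pytest.fixture(scope="session")
def cohort(cfg, study):
    return tm.simulate_cohort(cfg, study)


@pytest.fixture(scope="session")
def oriented_bmi(all_targets_iv, study):
    tbl = tm.harmonize(all_targets_iv, study.outcomes["bmi"])
    return tm.orient_to_lowering(tbl)


def make_summary(df_rows, trait="trait", **meta) -> tm.SummaryDataset:
    """Small summary dataset from a list of row dicts; fills defaults."""
    defaults = {"CHR": "chr1", "POS": 1000, "EA": "A", "OA": "G", "EAF": 0.3,
                "BETA": 0.05, "SE": 0.01, "P": 1e-4, "N": 10000}
    rows = []
    for i, r in enumerate(df_rows):
        row = {"SNP": f"rs{i}", **defaults, **r}
        rows.append(row)
    return tm.SummaryDataset(trait, pd.DataFrame(rows), **meta)


def make_ld(snps, r, pos=None, ea=None, oa=None, chrom="chr1") -> tm.LDReference:
    k = len(snps)
    pos = pos if pos is not None else 1000 + 1000 * np.arange(k)
    ea = ea if ea is not None else np.repeat("A", k)
    oa = oa if oa is not None else np.repeat("G", k)
    return tm.LDReference(snps, np.asarray(r, float), np.repeat(chrom, k), np.asarray(pos), np.asarray(ea), np.asarray(oa))
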