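import numpy as np
import pandas as pd
import pytest

from mrbattery.sumstats import SumstatTable


def make_table(
    trait_name="trait",
    snps=("rs1", "rs2", "rs3", "rs4", "rs5"),
    a1="AAGCT",
    a2="GCATC",
    betas=None,
    ses=None,
    infos=None,
    trait_type="quantitative",
    prevalence=None,
    **extra_columns,
):
    """Hand-built small summary-statistic table with consistent p-values."""
    from scipy import stats

    m = len(snps)
    betas = np.asarray(betas if betas is not None else np.linspace(0.05, 0.25, m))
    ses = np.asarray(ses if ses is not None else np.full(m, 0.01))
    df = pd.DataFrame(
        {
            "SNP": list(snps),
            "CHR": "1",
            "BP": np.arange(1, m + 1) * 100_000,
            "A1": list(a1[:m]),
            "A2": list(a2[:m]),
            "BETA": betas,
            "SE": ses,
            "P": 2 * stats.norm.sf(np.abs(betas / ses)),
            "INFO": infos if infos is not None else np.ones(m),
            "N": 100_000,
            **extra_columns,
        }
    )
    return SumstatTable(trait_name, trait_type, df, prevalence=prevalence)


@pytest.fixture
def small_table():
    return make_table()
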