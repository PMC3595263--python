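import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import mirpair as mp
from mirpair.qpcr import METASTATIC, PRIMARY, CtMatrix, PairedCohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


SMALL_PLANTED = (("miR-sim-001", 2.0), ("miR-sim-002", -1.5), ("miR-sim-003", 3.0))


@pytest.fixture
def small_params():
    """A small but fully featured cohort: 4 patients, 20 assays, 3 planted."""
    return mp.SimParams(
        n_patients=4,
        n_mirnas=20,
        planted_mirnas=SMALL_PLANTED,
        n_genes=400,
        targets_per_mirna=20,
        seed=7,
    )


@pytest.fixture
def zero_noise_params():
    return mp.SimParams(
        n_patients=4,
        n_mirnas=20,
        planted_mirnas=SMALL_PLANTED,
        pair_noise_sd=0.0,
        mrna_noise_sd=0.0,
        baseline_dct_sd=2.0,
        baseline_dct_mean=10.0,
        dropout_ct_cutoff=40.0,
        n_genes=400,
        targets_per_mirna=20,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_params):
    return mp.generate_paired_cohort(small_params)


def make_ct(values, samples=None, undetected=None, max_cycle=40.0):
    """Build a CtMatrix from a dict assay -> list of Ct (None = undetected)."""
    samples = samples or [f"S{i}" for i in range(1, len(next(iter(values.values()))) + 1)]
    ct = pd.DataFrame(
        {s: [np.nan if v is None else float(v) for v in col]
         for s, col in zip(samples, zip(*values.values()))},
        index=list(values),
    )
    undet = ct.isna()
    if undetected is not None:
        undet = pd.DataFrame(undetected, index=ct.index, columns=ct.columns)
    return CtMatrix(ct=ct, undetected=undet, max_cycle=max_cycle)


def make_cohort(n_patients, prefix="P"):
    rows = []
    for i in range(1, n_patients + 1):
        rows.append((f"{prefix}{i}-pri", f"{prefix}{i}", PRIMARY))
        rows.append((f"{prefix}{i}-met", f"{prefix}{i}", METASTATIC))
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "site"])
    return PairedCohort(df.set_index("sample_id"))
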