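"""Shared fixtures: a published-margin-faithful clinical cohort and synthetic data.

The published clinical table reports only per-covariate margins (counts per
subtype for sex, laterality, age bins, N/C stage, RB1 status) plus age
medians and ranges; the 21-patient annotation list below is constructed to
match every one of those margins exactly.  Each covariate test depends only
on its own cross-tab, so the (unknown) joint distribution is irrelevant.
"""

import numpy as np
import pytest

from rbdge.rcc import SampleAnnotation
from rbdge.simulate import SimulationConfig, simulate_dataset


def _patients(subtype, sexes, lateralities, ages, n_stages, c_stages, rb1s, start):
    return [
        SampleAnnotation(
            sample_id=f"P{start + i:02d}",
            subtype=subtype,
            sex=sexes[i],
            laterality=lateralities[i],
            age_months=ages[i],
            n_stage=n_stages[i],
            c_stage=c_stages[i],
            rb1_germline=rb1s[i],
        )
        for i in range(len(ages))
    ]


@pytest.fixture(scope="session")
def table1_annotations():
    """21 patients matching the published per-covariate margins.

    URB (n=11): 2 female / 9 male; 5 unilateral / 6 bilateral; ages with
    median 14, range 4-50, bins 8/1/2; N stage 3/6/2; C stage 7/2/2;
    RB1 yes 6 / no 5.  DRB (n=10): 6 female / 4 male; 6 unilateral /
    4 bilateral; ages median 10.5, range 2-45, bins 6/2/2; N stage 4/6/0;
    C stage 7/2/1; RB1 yes 2 / no 8.
    """
    urb = _patients(
        "URB",
        sexes=["female"] * 2 + ["male"] * 9,
        lateralities=["unilateral"] * 5 + ["bilateral"] * 6,
        ages=[4, 6, 8, 10, 14, 14, 15, 16, 20, 40, 50],
        n_stages=["N0"] * 3 + ["N1"] * 6 + ["N2"] * 2,
        c_stages=["C0"] * 7 + ["C1"] * 2 + ["C2"] * 2,
        rb1s=[True] * 6 + [False] * 5,
        start=1,
    )
    drb = _patients(
        "DRB",
        sexes=["female"] * 6 + ["male"] * 4,
        lateralities=["unilateral"] * 6 + ["bilateral"] * 4,
        ages=[2, 5, 7, 9, 10, 11, 20, 30, 40, 45],
        n_stages=["N0"] * 4 + ["N1"] * 6,
        c_stages=["C0"] * 7 + ["C1"] * 2 + ["C2"] * 1,
        rb1s=[True] * 2 + [False] * 8,
        start=12,
    )
    return urb + drb


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-simulate cohort: fewer genes, same sample layout."""
    return SimulationConfig(
        n_endogenous=120, n_reference=10, de_fraction=0.2, seed=11
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size cohort (770 genes, 11+10+2 samples)."""
    return simulate_dataset(SimulationConfig(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
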