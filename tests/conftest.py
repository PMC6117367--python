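import numpy as np
import pandas as pd
import pytest

from predscan import (
    ArchitectureSpec,
    simulate_biomarker,
    simulate_covariates,
    simulate_genotypes,
)
from predscan.phewas import AssociationResult
from predscan.simulate import random_snp_panel


@pytest.fixture(scope="session")
def small_panel():
    return random_snp_panel(50, seed=101)


@pytest.fixture(scope="session")
def small_genotypes(small_panel):
    return simulate_genotypes(400, small_panel, seed=102)


@pytest.fixture(scope="session")
def small_covariates(small_genotypes):
    return simulate_covariates(small_genotypes.samples, seed=103)


@pytest.fixture(scope="session")
def sparse_trait(small_genotypes):
    arch = ArchitectureSpec(pve=0.5, pge=0.8, n_large=3, n_poly=20, seed=104)
    return simulate_biomarker(small_genotypes, arch)


def make_result(
    phecode="008",
    beta=0.1,
    p=0.05,
    biomarker="bm",
    n_cases=500,
    converged=True,
    **kw,
):
    res = AssociationResult(
        biomarker=biomarker,
        phecode=phecode,
        label="",
        beta=beta,
        se=abs(beta) / 2 + 0.01,
        p=p,
        n_cases=n_cases,
        n_controls=4 * n_cases,
        converged=converged,
    )
    for k, v in kw.items():
        setattr(res, k, v)
    return res
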