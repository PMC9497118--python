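"""Shared fixtures: small simulated cohorts and a toy drug library."""

import numpy as np
import pandas as pd
import pytest

from comboscreen.cohort_io import CohortBundle, DrugEntry, DrugTargetLibrary
from comboscreen.simulate import SimulationConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_sim():
    """Deterministic two-cohort simulation, null effects, modest size."""
    cfg = SimulationConfig(
        seed=42, n_patients={"t": 120, "m": 60}, n_genes=100,
        drug_library_spec={"dsigdb": 8, "hdac_panel": 2, "checkpoint": 1},
    )
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def bundles(small_sim):
    bt, bm, _, _ = small_sim
    return bt, bm


@pytest.fixture(scope="session")
def library(small_sim):
    return small_sim[2]


def make_bundle(name="t", n=30, genes=("A", "B", "C", "D"), seed=0,
                mutations=None, expression=None, clinical=None):
    """Hand-rolled tiny bundle for targeted unit tests."""
    rng = np.random.default_rng(seed)
    pids = [f"{name}_p{i}" for i in range(n)]
    genes = list(genes)
    if clinical is None:
        clinical = pd.DataFrame({
            "age": rng.uniform(40, 80, n),
            "sex": rng.choice(["female", "male"], n),
            "os_time": rng.exponential(500, n) + 1,
            "os_event": rng.integers(0, 2, n),
            "braf_tx": rng.integers(0, 2, n),
            "ipi_nivo_tx": rng.integers(0, 2, n),
            "genotype_group": rng.choice(["BRAF", "NRAS", "TripleWT"], n),
        }, index=pd.Index(pids, name="patient_id"))
    if mutations is None:
        mutations = pd.DataFrame(
            rng.integers(0, 2, (len(genes), n)).astype(np.int8),
            index=genes, columns=pids)
    if expression is None:
        expression = pd.DataFrame(
            rng.normal(5, 1, (len(genes), n)), index=genes, columns=pids)
    return CohortBundle(name=name, clinical=clinical,
                        mutations=mutations, expression=expression).validate()


@pytest.fixture
def tiny_bundle():
    return make_bundle()


def make_library(mapping, source="user"):
    return DrugTargetLibrary({
        name: DrugEntry(frozenset(g.upper() for g in genes), source)
        for name, genes in mapping.items()})
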