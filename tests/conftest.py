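"""Shared fixtures: tiny hand-checkable proteins and a small simulated cohort."""

from __future__ import annotations

import numpy as np
import pytest

from pcproteo.io import ProteinEntry
from pcproteo.simulate import DEFAULT_EFFECT, PanelSpec, SimConfig, simulate_cohort

# K/R after positions 2 (K), 5 (R), 11 (K); length 15
DEMO_SEQ = "MKLVRAGDSTKNNFW"


@pytest.fixture
def demo_protein() -> ProteinEntry:
    return ProteinEntry(accession="P0TEST", gene="DEMO", sequence=DEMO_SEQ)


def small_config(**overrides) -> SimConfig:
    """A reduced cohort that keeps every structural feature of the default."""
    kwargs = dict(
        n_patients=6,
        n_nat=5,
        n_pc=7,
        n_tumor=8,
        n_metachronous_patients=2,
        n_proteins=40,
        protein_len_range=(150, 400),
        max_peptides_per_protein=6,
        semi_events_per_protein=2,
        panels={
            "pc_up": PanelSpec(
                ("COL1A1", "COL6A1", "FN1", "BGN"), (0.0, DEFAULT_EFFECT, 0.0)
            ),
            "tumor_up": PanelSpec(("HK1", "PKM"), (0.0, 0.0, DEFAULT_EFFECT)),
            "tumor_down": PanelSpec(("SDHA", "CS"), (0.0, 0.0, -DEFAULT_EFFECT)),
        },
        slope_pos_genes=("CASP1",),
        slope_neg_genes=("ETFA",),
        marker_panel=("MCM2", "MCM3"),
        semi_family_bias_genes=("COL1A1", "COL6A1"),
        semi_family_other_genes=(),
        semi_family_total_share=0.3,
        pc_restricted_semi_genes=("COL6A1",),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(), seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
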