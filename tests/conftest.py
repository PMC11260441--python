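"""Shared fixtures: hand-built pedigrees, random-pedigree generation, and a
study-shaped simulated dataset reused by the slower model tests."""

import numpy as np
import pandas as pd
import pytest

from pedvar.pedigree import Pedigree, validate_pedigree
from pedvar.simulate import (DesignConfig, VarianceComponents,
                             generate_pedigree, simulate_phenotypes)


def random_pedigree(seed: int, n_founders: int = 6, n_generations: int = 3,
                    per_generation: int = 5) -> Pedigree:
    """Random multi-generation pedigree; matings may be between relatives,
    so inbreeding (and diagonal entries above 1) can arise."""
    rng = np.random.default_rng(seed)
    records = [(f"F{k}", "", "") for k in range(n_founders)]
    pool = [r[0] for r in records]
    counter = 0
    for _ in range(n_generations):
        new = []
        for _ in range(per_generation):
            sire, dam = rng.choice(pool, size=2, replace=False)
            if rng.random() < 0.1:  # occasional single-known-parent record
                dam = ""
            name = f"X{counter}"
            counter += 1
            records.append((name, sire, dam))
            new.append(name)
        pool = pool + new
    return validate_pedigree(records)


@pytest.fixture
def trio() -> Pedigree:
    """Two unrelated founders and two full-sib offspring."""
    return validate_pedigree([
        ("S", "", ""), ("D", "", ""),
        ("C1", "S", "D"), ("C2", "S", "D"),
    ])


@pytest.fixture(scope="session")
def study():
    """Study-shaped design: pedigree, assignments, and an additive-dominant
    simulated phenotype table (h2 = 0.5 truth)."""
    ped, asg = generate_pedigree(DesignConfig(seed=101))
    vc = VarianceComponents()
    table = simulate_phenotypes(ped, asg, vc, seed=202)
    return ped, asg, table, vc


@pytest.fixture(scope="session")
def study_additive_only():
    """Study-shaped design with purely additive variance (V_dam = V_brood =
    0, h2 = 0.7): the ground truth for identifiability checks."""
    ped, asg = generate_pedigree(DesignConfig(seed=303))
    vc = VarianceComponents(V_a=0.00063, V_dam=0.0, V_brood=0.0, V_e=0.00027)
    table = simulate_phenotypes(ped, asg, vc, seed=404)
    return ped, asg, table, vc


def offspring_rows(table: pd.DataFrame) -> pd.DataFrame:
    mask = (table["dam"].astype(str) != "") & (table["sire"].astype(str) != "")
    return table[mask].reset_index(drop=True)
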