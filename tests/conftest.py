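"""Shared fixtures: small synthetic genomes with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from retrobench.genome_model import Assembly
from retrobench.synthetic_genome import (
    InsertionPlan,
    copia_family,
    gypsy_family,
    plant_insertions,
    simulate_background,
)


@pytest.fixture(scope="session")
def small_family():
    return copia_family(name="fam_small", ltr_len=500, total_len=5000)


@pytest.fixture(scope="session")
def detection_sim(small_family):
    """800 kb genome with 20 identical-LTR (age 0) planted elements."""
    rng = np.random.default_rng(101)
    bg = simulate_background(800_000, 0.44, rng)
    plans = [InsertionPlan(small_family, 0.0) for _ in range(20)]
    genome, truth = plant_insertions(bg, plans, rng, min_spacing=28_000)
    return Assembly([genome]), truth


@pytest.fixture(scope="session")
def aged_sim(small_family):
    """500 kb genome with 8 aged elements (0.3-1.5 Myr) plus 5 genes."""
    from retrobench.synthetic_genome import plant_genes

    rng = np.random.default_rng(202)
    bg = simulate_background(500_000, 0.44, rng)
    fam2 = gypsy_family(name="fam_small_g", ltr_len=500, total_len=5500)
    plans = [
        InsertionPlan(small_family if i % 2 == 0 else fam2,
                      float(rng.uniform(0.3e6, 1.5e6)))
        for i in range(8)
    ]
    genome, truth = plant_insertions(bg, plans, rng, min_spacing=30_000)
    genome, truth = plant_genes(genome, truth, 5, gene_len=1200, seed=rng)
    return genome, truth


@pytest.fixture(scope="session")
def aged_assembly(aged_sim):
    genome, _ = aged_sim
    return Assembly([genome])
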