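import numpy as np
import pandas as pd
import pytest

from polyat.io import AccessionPanel, GenotypeMatrix, site_table
from polyat.simulate import SimulationConfig, simulate_dataset, simulate_population


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """Reduced-scale study conditions for fast unit tests."""
    base = dict(
        seed=seed,
        chromosomes={"1A": 400_000, "2A": 400_000, "1B": 400_000,
                     "2B": 400_000, "1D": 400_000, "2D": 400_000},
        group_sizes={"wild_emmer": 8, "durum": 5, "ae_tauschii": 8,
                     "landrace_east": 5, "landrace_west": 5, "variety": 8},
        standing_per_subgenome=600,
        branch_new_per_subgenome=300,
        sweeps_per_subgenome=1,
        sweep_extra_snps=40,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_small():
    return simulate_population(small_config(seed=7))


@pytest.fixture(scope="session")
def sim_with_genes():
    return simulate_dataset(small_config(seed=11), with_genes=True)


@pytest.fixture
def toy_geno():
    """Four accessions x three sites with known hand-computable composition."""
    sites = site_table(
        chrom=["1A", "1A", "1A"], pos=[10, 20, 30],
        ref=["A", "C", "G"], alt=["G", "T", "T"],
    )
    dosage = np.array([
        [0.0, 0.5, 1.0],   # hom-ref A, het C/T, hom-alt T
        [0.0, 0.0, 0.0],
        [1.0, 1.0, 1.0],
        [np.nan, 0.5, 0.0],
    ])
    return GenotypeMatrix(["a1", "a2", "a3", "a4"], sites, dosage)


@pytest.fixture
def toy_panel():
    return AccessionPanel(
        {"a1": "variety", "a2": "variety", "a3": "wild_emmer", "a4": "wild_emmer"})


def random_genotypes(rng, n_acc=12, n_sites=80, missing=0.1, chrom="1A"):
    """Random dosage matrix for oracle comparisons."""
    dosage = rng.choice([0.0, 0.5, 1.0], size=(n_acc, n_sites), p=[0.45, 0.1, 0.45])
    mask = rng.random((n_acc, n_sites)) < missing
    dosage[mask] = np.nan
    pos = np.sort(rng.choice(np.arange(10, 500_000), size=n_sites, replace=False))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_sites)]
    alt = np.array([bases[(list("ACGT").index(r) + rng.integers(1, 4)) % 4] for r in ref])
    sites = site_table([chrom] * n_sites, pos, ref, alt)
    accs = [f"s{i}" for i in range(n_acc)]
    return GenotypeMatrix(accs, sites, dosage)
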