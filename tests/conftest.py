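import numpy as np
import pytest

import cgvscreen as cgv


@pytest.fixture(scope="session")
def tame_screen():
    """A small screen with moderate effects and no separated cells."""
    cfg = cgv.SimulationConfig(
        n_strains=10,
        n_genes=3,
        wells_per_cell=6,
        offspring_per_well=100,
        n_snps=30,
        seed=6,
        n_resistant_strains=0,
        per_gene_modifier_loci=2,
        modifier_effect_sd=0.5,
        informational_effect_sd=0.3,
        overdispersion_rho=0.1,
        baseline_lethality_per_gene=(0.3, 0.45, 0.6),
    )
    genotypes = cgv.simulate_genotypes(cfg)
    wells, truth = cgv.simulate_screen(cfg, genotypes)
    return cfg, genotypes, wells, truth


@pytest.fixture(scope="session")
def family_kinship():
    """Block-family kinship: K = 0.5 I + 0.5 within-family, 10 families of 5."""
    n, fams = 50, 10
    fam = np.repeat(np.arange(fams), n // fams)
    K = 0.5 * np.eye(n) + 0.5 * (fam[:, None] == fam[None, :])
    return K, np.linalg.cholesky(K)
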