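import numpy as np
import pytest

from twinvol.simulate import small_spec, simulate_cohort


@pytest.fixture(scope="session")
def ae_cohort():
    """Single-dataset AE world: a2=0.8, 500+500 pairs, no covariate effects."""
    spec = small_spec(n_mz_pairs=500, n_dz_pairs=500, a2=0.8, seed=101)
    cohort, truth = simulate_cohort(spec)
    return cohort, truth


@pytest.fixture(scope="session")
def mixed_cohort():
    """Two-region cohort with genetic correlation, DZOS pairs, unpaired
    twins, siblings and covariate effects — exercises every block shape."""
    R_A = np.array([[1.0, 0.9], [0.9, 1.0]])
    R_E = np.array([[1.0, 0.2], [0.2, 1.0]])
    spec = small_spec(
        n_mz_pairs=300, n_dz_pairs=300, a2=0.8, n_regions=2,
        R_A=R_A, R_E=R_E, n_dzos_pairs=50, n_unpaired=30,
        n_sib_families=20, beta_age=0.02, beta_sex=0.1, beta_icv=2e-6,
        seed=202)
    cohort, truth = simulate_cohort(spec)
    return cohort, truth
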