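import numpy as np
import pytest

from admixkit import simulate as sim

# Reduced genome for unit tests: 6 chromosomes x 1 Morgan x 1000 SNPs each.
# Acceptance-level checks use the full default geometry instead.
SMALL = dict(n_snps=6000, n_chromosomes=6)


@pytest.fixture(scope="session")
def small_pools():
    pool_a, pool_b, snps = sim.generate_ancestral_pools(seed=11, **SMALL)
    return pool_a, pool_b, snps


@pytest.fixture(scope="session")
def pulse_cohort(small_pools):
    """theta=0.2, lam=50 pulse cohort with independent reference panels."""
    pool_a, pool_b, snps = small_pools
    rng = np.random.default_rng(12)
    cohort = sim.simulate_pulse(pool_a, pool_b, 0.2, 50.0, 10, rng)
    fa, _ = sim.reference_frequencies(pool_a, 100, rng)
    fb, _ = sim.reference_frequencies(pool_b, 100, rng)
    return cohort, fa, fb, snps
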