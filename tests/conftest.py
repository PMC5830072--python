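import numpy as np
import pytest
from hypothesis import settings

import sirescan as ss

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_halfsib():
    """A 10-family × 5-offspring panel (n=50, m=120) with moderate h²."""
    cfg = ss.SimulationConfig(
        n_sires=10, offspring_per_sire=5, n_snps=120, sigma_u2=3.0, sigma_e2=7.0, seed=42
    )
    gm, y, truth = ss.simulate_dataset(cfg)
    return cfg, gm, y, truth


@pytest.fixture(scope="session")
def small_nullfit(small_halfsib):
    """Null REML fit on the small panel (QC'd, GRM, intercept-only X)."""
    _, gm, y, _ = small_halfsib
    gm_qc, _ = ss.qc_filter(gm)
    grm = ss.compute_grm(gm_qc)
    nf = ss.fit_null(y, None, grm)
    return gm_qc, y, grm, nf


def random_genotype_matrix(rng, n=12, m=8, missing_rate=0.0):
    """A random unrelated GenotypeMatrix for round-trip / property tests."""
    p = rng.uniform(0.1, 0.5, size=m)
    d = (rng.random((n, m)) < p).astype(float) + (rng.random((n, m)) < p)
    if missing_rate:
        d[rng.random((n, m)) < missing_rate] = np.nan
    markers = [
        ss.MarkerInfo(
            snp_id=f"m{j}",
            chromosome=str(rng.integers(1, 30)),
            position=int(rng.integers(1, 10**6)),
            allele_a="A",
            allele_b="G",
        )
        for j in range(m)
    ]
    ids = [f"ind{i}" for i in range(n)]
    return ss.GenotypeMatrix(dosages=d, individual_ids=ids, markers=markers)
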