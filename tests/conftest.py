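import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from urbanscape.containers import GenotypeTable
from urbanscape.synthetic import simulate_colonies

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_genotype_table(dosages, depths=None, colony_of=None, chrom="chr1"):
    """Build a GenotypeTable from a plain dosage array (nan = missing)."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    if depths is None:
        depths = np.full_like(dosages, 20.0)
        depths[np.isnan(dosages)] = 0.0
    loci = pd.DataFrame(
        {
            "chrom": [chrom] * L,
            "pos": np.arange(1, L + 1) * 100,
            "ref": ["A"] * L,
            "alt": ["G"] * L,
            "locus_id": [f"L{i:04d}" for i in range(L)],
        }
    )
    if colony_of is None:
        colony_of = ["c0"] * n
    individuals = pd.DataFrame({"id": [f"i{i}" for i in range(n)], "colony_id": colony_of})
    return GenotypeTable(dosages, np.asarray(depths, dtype=float), loci, individuals)


@pytest.fixture
def gt_factory():
    return make_genotype_table


@pytest.fixture(scope="session")
def colonies10():
    return simulate_colonies(n_urban=5, n_rural=5, seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small on-disk fixture set shared across IO tests."""
    from urbanscape.synthetic import write_fixture_set

    out = tmp_path_factory.mktemp("fixtures")
    manifest = write_fixture_set(out, seed=7, n_loci=300, n_adaptive=5, overwrite=True)
    return out, manifest
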