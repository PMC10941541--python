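import numpy as np
import pandas as pd
import pytest

from cogex import synthetic
from cogex.atlas import DonorProfiles


def region_index(n_per_hemisphere: int) -> pd.Index:
    return pd.Index(
        [f"lh_region{j + 1:02d}" for j in range(n_per_hemisphere)]
        + [f"rh_region{j + 1:02d}" for j in range(n_per_hemisphere)]
    )


@pytest.fixture(scope="session")
def small_expression():
    """Median matrix + truth for a small planted-structure dataset."""
    profiles, median, truth = synthetic.generate_expression(
        n_regions=24, n_genes=300, n_donors=4, seed=11
    )
    return profiles, median, truth


@pytest.fixture(scope="session")
def parcellation68():
    return synthetic.generate_sphere_parcellation(34, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_profiles(donor_values: dict, region_ids, gene_ids) -> DonorProfiles:
    """Build DonorProfiles from {donor: 2-D array} with shared axes."""
    donors = {
        name: pd.DataFrame(vals, index=region_ids, columns=gene_ids)
        for name, vals in donor_values.items()
    }
    return DonorProfiles(donors=donors)
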