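import numpy as np
import pytest

from copebuoy import CTDProfile, GroupSpec, MorphometricRecord, default_archetypes


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def droplet_record():
    """Prosome (1.0, 0.5) mm with one 0.2 mm droplet: 8.0 % lipid area."""
    return MorphometricRecord(
        species_label="M. clausi",
        stage_label="C5",
        site="red_sea",
        date_label="Jun-09",
        depth_layer_m=5.0,
        prosome_length=1.0,
        prosome_width=0.5,
        droplet_diameters=(0.2,),
    )


@pytest.fixture
def arctic_spec():
    """A sampling-table-shaped group: n=33, PL 3.18 +- 0.185 mm at 8 m."""
    return GroupSpec(
        species_label="C. glacialis C5",
        stage_label="C5",
        site="arctic",
        date_label="18.7.11",
        depth_layer_m=8.0,
        n=33,
        prosome_length_mean=3.18,
        prosome_length_sd=0.185,
        width_to_length_ratio=0.36,
        lipid_pct_mean=18.0,
        lipid_pct_sd=6.0,
        lipid_geometry="sac_contour",
    )


@pytest.fixture
def two_point_profile():
    return CTDProfile(depth=(0.0, 40.0), temperature=(26.0, 24.0), salinity=(40.0, 41.0))


@pytest.fixture
def archetypes():
    return default_archetypes()
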