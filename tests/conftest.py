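import numpy as np
import pytest

from aggrekey import AggregateProfile, RunConfig, StudyDesign, reference


@pytest.fixture(scope="session")
def design():
    """The study layout: seven treatments, three replicates."""
    return StudyDesign.balanced(reference.TREATMENTS, 3)


@pytest.fixture(scope="session")
def mean_profiles():
    """One profile per treatment built from the published treatment means:
    masses proportional to the mean mass proportions, concentrations equal
    to the mean per-fraction SOC."""
    profiles = []
    for t in reference.TREATMENTS:
        profiles.append(AggregateProfile(
            sample_id=t,
            masses=reference.MASS_PROPORTION_MEAN.loc[t].to_numpy() * 0.6,
            soc_conc=reference.SOC_CONCENTRATION_MEAN.loc[t].to_numpy(),
            soc_bulk=float(reference.TOTAL_SOC_MEAN.loc[t])))
    return profiles


@pytest.fixture
def fast_config():
    """Scaled-down ensemble/permutation sizes for quick pipeline runs."""
    return RunConfig(rf_trees=60, rf_permutations=40,
                     permanova_permutations=99, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
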