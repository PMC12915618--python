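import numpy as np
import pandas as pd
import pytest

from foodwebts.nichemodel import FeedingKernel
from foodwebts.synth import generate_interaction_records, generate_species_pool


@pytest.fixture(scope="session")
def kernel():
    return FeedingKernel(mu=1.5, sigma=0.3)


@pytest.fixture(scope="session")
def wide_pool():
    """Predator and prey sub-pools far from the size floor, so kernel draws
    are essentially untruncated."""
    pred = generate_species_pool(
        300, size_log10_mean=2.0, size_log10_sd=0.3, piscivore_fraction=1.0, seed=101
    )
    prey = generate_species_pool(
        600, size_log10_mean=0.5, size_log10_sd=0.6, piscivore_fraction=0.0, seed=102
    )
    prey = prey.assign(species_id="prey_" + prey["species_id"])
    return pd.concat([pred, prey], ignore_index=True)


@pytest.fixture(scope="session")
def calibration_records(wide_pool, kernel):
    return generate_interaction_records(wide_pool, kernel, 4000, seed=103)


def make_survey(rows):
    """Build a survey table from (study, unit, year, season, sample, species,
    abundance) tuples; coordinates keep units spatially distinct."""
    recs = []
    for study, unit, year, season, sample, species, abundance in rows:
        lat = 10.0 + 2.0 * (sum(map(ord, unit)) % 7)
        recs.append(
            {
                "study_id": study,
                "unit_id": unit,
                "year": year,
                "season": season,
                "sample_id": sample,
                "species_id": species,
                "abundance": abundance,
                "latitude": lat,
                "longitude": 5.0,
                "realm": "marine",
            }
        )
    return pd.DataFrame(recs)
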