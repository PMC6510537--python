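"""Shared fixtures: small synthetic studies and handmade tables."""

import pandas as pd
import pytest

from tifquant import synthetic
from tifquant.io import PeakTable, SampleSheet


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 16 metabolites, 3 pools, two small groups."""
    return synthetic.GroundTruthConfig(
        n_metabolites=16,
        fraction_isotope_dilution=0.5,
        n_pools=3,
        groups=(
            synthetic.GroupSpec("tif", 4, matrix_type="tif"),
            synthetic.GroupSpec("plasma", 5, matrix_type="plasma"),
        ),
        n_normalizers=2,
        seed=20260921,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthetic.SyntheticStudy(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """No instrument noise, unit matrix factors, no biological variation."""
    return synthetic.GroundTruthConfig(
        n_metabolites=16,
        fraction_isotope_dilution=0.5,
        n_pools=3,
        groups=(synthetic.GroupSpec("tif", 4, matrix_type="tif"),),
        matrix_factors={
            "water": synthetic.MatrixFactorSpec(kind="fixed", value=1.0),
            "standard_dilution": synthetic.MatrixFactorSpec(kind="fixed", value=1.0),
            "tif": synthetic.MatrixFactorSpec(kind="fixed", value=1.0),
            "plasma": synthetic.MatrixFactorSpec(kind="fixed", value=1.0),
        },
        instrument_noise_cv=0.0,
        biological_gsd=1.0,
        n_normalizers=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return synthetic.SyntheticStudy(noiseless_config)


def make_peak_table(rows):
    """rows: iterable of (sample_id, species_id, peak_area)."""
    return PeakTable(pd.DataFrame(rows, columns=["sample_id", "species_id", "peak_area"]))


def make_dilution_sheet(pool_id, levels):
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"std_{pool_id}_{lv}" for lv in levels],
                "matrix_type": "standard_dilution",
                "dilution_level": list(levels),
                "pool_id": pool_id,
            }
        )
    )
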