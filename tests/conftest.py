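import numpy as np
import pandas as pd
import pytest

from cfamf import amf as amf_mod
from cfamf.simulate import SimulationConfig, simulate_cohort


def build_matrix(cohort, min_cpgs=5, max_null_fraction=0.10):
    """Assemble the AMF matrix of a simulated cohort (no masking)."""
    scheme = amf_mod.BinScheme(chrom_sizes=cohort.chrom_sizes,
                               bin_width=cohort.config.bin_width,
                               min_cpgs=min_cpgs)
    bins = amf_mod.eligible_bins(cohort.cpg_positions, scheme)
    vectors = {sid: amf_mod.compute_amf(cs, scheme, bins)
               for sid, cs in cohort.calls.items()}
    matrix, report = amf_mod.assemble_matrix(
        vectors, bins, qc=None, max_null_fraction=max_null_fraction)
    return matrix, report


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted-effect cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(
        n_good=40, n_poor=15, n_bins=600, n_dmr=20, seed=11))


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    matrix, _ = build_matrix(small_cohort)
    return matrix


@pytest.fixture()
def toy_matrix():
    """Tiny handcrafted AMF matrix: 4 bins x 4 samples, one missing cell."""
    bins = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "start": [0, 100, 200, 300],
        "end": [100, 200, 300, 400],
        "n_cpgs": [5, 6, 7, 5],
    })
    values = np.array([
        [0.9, 0.8, 0.85, 0.95],
        [0.1, 0.2, np.nan, 0.15],
        [0.5, 0.5, 0.5, 0.5],
        [0.99, 1.0, 0.98, 0.97],
    ])
    return amf_mod.AMFMatrix(bins=bins, samples=["s1", "s2", "s3", "s4"],
                             values=values)
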