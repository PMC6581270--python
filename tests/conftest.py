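import numpy as np
import pytest

from ntakit import AcquisitionMeta, SampleNameSchema, WideExperimentTable

SCHEMA = SampleNameSchema(
    field_names=("group", "sample", "dilution", "injection", "tech_rep"),
    separator="_",
    dilution_field="dilution",
)


def make_wide(rng, n_bins=10, n_meas=4, bin_width=1.0, size_min=0.0,
              dilutions=(125, 250, 500)):
    """A random valid wide table with schema-parseable measurement names."""
    meta = AcquisitionMeta(
        software_version="3.2",
        bin_width=bin_width,
        size_min=size_min,
        size_max=size_min + n_bins * bin_width,
    )
    names = tuple(
        f"G{j % 3}_S{j}_{dilutions[j % len(dilutions)]}_a_1" for j in range(n_meas)
    )
    counts = rng.uniform(0.0, 1e8, size=(n_bins, n_meas))
    return WideExperimentTable(
        meta=meta, bin_centers=meta.bin_centers(),
        measurement_names=names, counts=counts,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def schema():
    return SCHEMA


@pytest.fixture
def small_wide(rng):
    return make_wide(rng)
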