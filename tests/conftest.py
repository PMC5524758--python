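import numpy as np
import pandas as pd
import pytest

from lipidlens.preprocess import FeatureTable
from lipidlens.simulate import CohortSpec, FeaturePanelSpec, generate_cohort, generate_feature_table


@pytest.fixture(scope="session")
def cohort126():
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_panel(cohort126):
    """Compact panel: 300 ions, 5 IS, light missingness — fast to preprocess."""
    spec = FeaturePanelSpec(
        n_ions=300, n_internal_standards=5, missing_fraction_high=0.1,
        rmd_in_range_fraction=0.8, seed=7,
    )
    return generate_feature_table(spec, cohort126)


@pytest.fixture(scope="session")
def processed_small(small_panel):
    from lipidlens.preprocess import preprocess

    table, report = preprocess(small_panel)
    return table, report


def make_table(values, rt=None, mz=None, is_flags=None, injection_order=None, is_qc=None):
    """Hand-built FeatureTable from a 2-D array; helper for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ions = [f"ion{j}" for j in range(m)]
    samples = [f"s{i}" for i in range(n)]
    ion_meta = pd.DataFrame(
        {
            "retention_time": rt if rt is not None else np.ones(m),
            "mz": mz if mz is not None else np.linspace(400.2, 800.5, m),
            "is_internal_standard": is_flags if is_flags is not None else [False] * m,
        },
        index=pd.Index(ions, name="ion"),
    )
    sample_meta = pd.DataFrame(
        {
            "injection_order": injection_order if injection_order is not None else np.arange(n),
            "is_qc": is_qc if is_qc is not None else [False] * n,
        },
        index=pd.Index(samples, name="sample"),
    )
    return FeatureTable(pd.DataFrame(values, index=sample_meta.index, columns=ion_meta.index),
                        ion_meta, sample_meta)
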