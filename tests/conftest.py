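import numpy as np
import pandas as pd
import pytest

import hdquant as hq


@pytest.fixture(scope="session")
def sc_reference():
    """Synthetic single-cell reference with planted markers and 50% depletion."""
    return hq.simulate_sc(hq.SCSimConfig(seed=11))


@pytest.fixture(scope="session")
def pseudobulk(sc_reference):
    merge = {t: t for t in sc_reference.obs["cell_type"].unique()}
    return hq.build_pseudobulk(sc_reference, merge)


@pytest.fixture(scope="session")
def marker_panel(pseudobulk):
    spec = hq.compute_specificity(pseudobulk["reference"])
    return hq.select_markers(spec, min_tpm=50, min_specificity=0.40, top_k=20)


def mixture_proportions(depletion: float, types) -> np.ndarray:
    """Proportions with the first type at ``depletion`` times its uniform
    reference share; the deficit is spread over the remaining types."""
    n = len(types)
    p0 = depletion / n
    return np.array([p0] + [(1.0 - p0) / (n - 1)] * (n - 1))


@pytest.fixture(scope="session")
def bulk_mixture(pseudobulk):
    """Six bulk libraries: 3 reference, 3 with the first type at half abundance."""
    profiles = pseudobulk["reference"]
    types = profiles.columns
    props = pd.DataFrame(
        [mixture_proportions(1.0, types)] * 3 + [mixture_proportions(0.5, types)] * 3,
        columns=types, index=[f"s{i}" for i in range(6)],
    )
    return hq.simulate_bulk(props, profiles, noise_cv=0.1, seed=13)
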