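import numpy as np
import pandas as pd
import pytest

from metaconcord.data_model import IntegratedDataset, MethodInfo
from metaconcord.nomenclature import CompoundRecord, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def build_dataset(cells, compounds=None, methods=None, max_replicates=3):
    """Construct an in-memory dataset from {(category, method, metabolite):
    {sample: [intensities]}} cells; None entries become missing."""
    rows = []
    for (category, method_id, metabolite), samples in cells.items():
        for sample, values in samples.items():
            for rep, value in enumerate(values, start=1):
                rows.append(
                    (
                        method_id,
                        category,
                        metabolite,
                        sample,
                        rep,
                        np.nan if value is None else float(value),
                    )
                )
    measurements = pd.DataFrame(
        rows,
        columns=["method_id", "category", "metabolite", "sample", "replicate", "intensity"],
    )
    if methods is None:
        methods = [
            MethodInfo(method_id=m, lab_id=f"L_{c}_{m}", category=c)
            for c, m in sorted({(c, m) for (c, m, _met) in cells})
        ]
    if compounds is None:
        compounds = [
            CompoundRecord(canonical_id=met, display_name=met, category=c)
            for c, met in sorted({(c, met) for (c, _m, met) in cells})
        ]
    return IntegratedDataset(
        methods=methods,
        measurements=measurements,
        compounds=compounds,
        max_replicates=max_replicates,
    )


@pytest.fixture
def make_dataset():
    return build_dataset
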