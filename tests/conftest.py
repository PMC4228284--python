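import numpy as np
import pytest

from endotree.cohort_model import (
    CovariateTable,
    ExpressionMatrix,
    IndicatorSet,
)


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    values = rng.uniform(100, 5000, size=(6, 5))
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(6)],
        [f"s{i}" for i in range(5)],
        scale_tag="intensity",
    )


@pytest.fixture
def small_cov() -> CovariateTable:
    rng = np.random.default_rng(7)
    values = rng.standard_normal((5, 4))
    values[1, 2] = np.nan
    values[3, 0] = np.nan
    ids = ["age", "height", "phadiatop", "serum_cat"]
    cats = {
        "age": "clinic",
        "height": "clinic",
        "phadiatop": "allergen_screen",
        "serum_cat": "serum_allergen",
    }
    return CovariateTable(values, [f"s{i}" for i in range(5)], ids, cats, {})


@pytest.fixture
def small_ind() -> IndicatorSet:
    return IndicatorSet(
        [f"s{i}" for i in range(5)],
        ["asthmatic", "non_asthmatic", "asthmatic", "unknown", "non_asthmatic"],
        ["yes", "no", "yes", "unknown", "no"],
        ["yes", "no", "no", "unknown", "no"],
        ["4", "0", "3", "unknown", "1"],
        ["2", "0", "4", "unknown", "0"],
    )
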