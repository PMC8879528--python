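"""Shared fixtures: the printed reference code matrices and default setups.

The three reference matrices are the codes physically printed on the
tablets: the minimal 3x3 code (2x2 data + 5 parity cells), the 5x5 code
(4x4 data + 9 parity cells), and the maximal 5x9 code (4x8 data + 13
parity cells).
"""

from __future__ import annotations

import numpy as np
import pytest

from layermark import codec
from layermark.geometry import TabletGeometry, WatermarkParams, plan_patch

MIN_CODE_3X3 = """
0 1 1
1 1 0
1 0 1
"""

CODE_5X5 = """
1 1 0 0 0
0 1 1 0 0
1 1 0 1 1
1 1 0 0 0
1 0 1 1 1
"""

MAX_CODE_5X9 = """
0 0 1 0 0 1 1 1 0
0 0 0 1 1 1 0 0 1
1 1 1 1 1 1 1 0 1
1 0 0 1 0 0 1 0 1
0 1 0 1 0 1 1 1 1
"""


@pytest.fixture(scope="session")
def min_code() -> codec.BitMatrix:
    return codec.matrix_from_text(MIN_CODE_3X3)


@pytest.fixture(scope="session")
def mid_code() -> codec.BitMatrix:
    return codec.matrix_from_text(CODE_5X5)


@pytest.fixture(scope="session")
def max_code() -> codec.BitMatrix:
    return codec.matrix_from_text(MAX_CODE_5X9)


@pytest.fixture(scope="session")
def small_tablet() -> TabletGeometry:
    """Smallest watermarkable oblong: 12 x 4 x 4 mm, 2 mm corner radius."""
    return TabletGeometry(12.0, 4.0, 4.0, 2.0)


@pytest.fixture(scope="session")
def large_tablet() -> TabletGeometry:
    """Largest swallowable oblong: 23 x 8 x 6 mm, 4 mm corner radius."""
    return TabletGeometry(23.0, 8.0, 6.0, 4.0)


@pytest.fixture(scope="session")
def default_params() -> WatermarkParams:
    return WatermarkParams()


@pytest.fixture(scope="session")
def small_plan(small_tablet, default_params):
    return plan_patch(small_tablet, default_params, 3, 3)


@pytest.fixture(scope="session")
def large_plan(large_tablet, default_params):
    return plan_patch(large_tablet, default_params, 5, 5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
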