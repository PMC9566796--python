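"""Shared fixtures: the bundled worked-example study (a published
SWOT-AHP analysis of new-media-enabled public-health promotion) and
helpers for building matrices programmatically."""

import numpy as np
import pytest

from swotahp import ComparisonMatrix, load_example_study, run_pipeline

# Printed reference values of the worked example (4-decimal display).
EXPECTED_WEIGHTS = {
    "S": (0.0672, 0.0942, 0.2429, 0.5956),
    # WW1 is printed as 0.9782 in the source table but is a misprint for
    # 0.0978 (confirmed by AW_W1 = 0.2935 and the strength -0.1956 = -2 x 0.0978).
    "W": (0.0978, 0.7151, 0.1871),
    "O": (0.2840, 0.1715, 0.4708, 0.0736),
    # WT3 printed 0.6521 is a misprint for 0.6479 (confirmed by the
    # strength -3.8874 = -6 x 0.6479).
    "T": (0.2298, 0.1221, 0.6479),
}
EXPECTED_LAMBDA = {"S": 4.2301, "W": 3.00198, "O": 4.05136, "T": 3.00369}
EXPECTED_CI = {"S": 0.0766, "W": 0.0009, "O": 0.0171, "T": 0.0018}
INTENSITIES = {"S": (1, 2, 4, 6), "W": (-2, -5, -1), "O": (4, 3, 6, 2), "T": (-3, -2, -6)}
EXPECTED_STRENGTHS = {
    "S": (0.0671, 0.1884, 0.9716, 3.5736),
    "W": (-0.1956, -3.5750, -0.1871),
    "O": (1.1360, 0.5145, 2.8254, 0.1472),
    "T": (-0.6897, -0.2444, -3.8874),
}
EXPECTED_TOTALS = {"S": 4.8007, "W": -3.9577, "O": 4.6231, "T": -4.8215}
EXPECTED_CENTROID = (0.21075, -0.0496)
EXPECTED_THETA = -13.243
EXPECTED_RHO = 0.53699

MATRIX_ROWS = {
    "S": [[1, "1/2", "1/3", "1/7"], [2, 1, "1/5", "1/6"], [3, 5, 1, "1/4"], [7, 6, 4, 1]],
    "W": [[1, "1/7", "1/2"], [7, 1, 4], [2, "1/4", 1]],
    "O": [[1, 2, "1/2", 4], ["1/2", 1, "1/3", 3], [2, 3, 1, 5], ["1/4", "1/3", "1/5", 1]],
    "T": [[1, 2, "1/3"], ["1/2", 1, "1/5"], [3, 5, 1]],
}
FACTOR_IDS = {
    "S": ("S1", "S2", "S3", "S4"),
    "W": ("W1", "W2", "W3"),
    "O": ("O1", "O2", "O3", "O4"),
    "T": ("T1", "T2", "T3"),
}


@pytest.fixture(scope="session")
def example_matrices() -> dict[str, ComparisonMatrix]:
    return {
        g: ComparisonMatrix.from_rows(MATRIX_ROWS[g], FACTOR_IDS[g], group_id=g)
        for g in "SWOT"
    }


@pytest.fixture(scope="session")
def example_report():
    """Full pipeline run of the bundled worked example."""
    return run_pipeline(load_example_study())


def consistent_matrix(weights, ids=None) -> ComparisonMatrix:
    w = np.asarray(weights, dtype=float)
    ids = ids or tuple(f"F{i+1}" for i in range(len(w)))
    return ComparisonMatrix(group_id="X", factor_ids=ids, values=np.outer(w, 1 / w))
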