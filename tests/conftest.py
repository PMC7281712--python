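"""Shared fixtures: published ground-truth parameter sets and curve builders.

All data used by the tests is generated programmatically; the four
multi-driver and one mono-driver parameter sets below are the published
biphasic fits that serve as simulation ground truths throughout.
"""

from __future__ import annotations

import numpy as np
import pytest

from biphasic import (
    BiphasicParams,
    CENSOR_BOUND_NM,
    DoseResponseCurve,
    simulate_monotherapy,
)

# Published biphasic fits used as generative ground truths:
# (cell line, drug) -> (F1, Kd1 nM, Kd2 nM or None, censored)
MULTIDRIVER_TRUTHS = {
    ("MDA-MB-231", "dasatinib"): BiphasicParams(f1=0.49, kd1_nm=29.9, kd2_nm=9300.0),
    ("MDA-MB-468", "lapatinib"): BiphasicParams(f1=0.53, kd1_nm=17.0, kd2_nm=3050.0),
    ("MDA-MB-468", "GSK690693"): BiphasicParams(f1=0.37, kd1_nm=67.0, kd2_nm=15600.0),
    ("MDA-MB-231", "AZD-6244"): BiphasicParams(
        f1=0.36, kd1_nm=91.0, kd2_nm=CENSOR_BOUND_NM, kd2_censored=True
    ),
}

MONODRIVER_TRUTH = ("CTV-1", "dasatinib"), BiphasicParams(f1=1.0, kd1_nm=9.1, kd2_nm=None)


@pytest.fixture
def dasatinib_truth() -> BiphasicParams:
    return MULTIDRIVER_TRUTHS[("MDA-MB-231", "dasatinib")]


@pytest.fixture
def mono_truth() -> BiphasicParams:
    return MONODRIVER_TRUTH[1]


@pytest.fixture
def noiseless_dasatinib_curve(dasatinib_truth) -> DoseResponseCurve:
    return simulate_monotherapy(
        dasatinib_truth, cell_line="MDA-MB-231", treatment="dasatinib", noise_sd=0.0
    )


def grid_oracle_biphasic(curve: DoseResponseCurve, n_grid: int = 40) -> float:
    """Independent dense grid-search oracle for the biphasic RMSE minimum.

    Enumerates an n x n x n grid: F1 linear in [0, 1], Kd1 and Kd2
    log-spaced in [0.1 nM, 100 uM] with Kd2 >= Kd1, and returns the best
    RMSE against the per-concentration mean inhibition.
    """
    d = curve.concentrations_nm
    y = curve.mean_inhibition
    f1s = np.linspace(0.0, 1.0, n_grid)
    kds = np.geomspace(0.1, 1e5, n_grid)
    site = d[None, :] / (d[None, :] + kds[:, None])  # (n_grid, n_conc)
    best = np.inf
    for f1 in f1s:
        # pred[j, k, :] for kd1 index j, kd2 index k
        pred = f1 * site[:, None, :] + (1.0 - f1) * site[None, :, :]
        rmse = np.sqrt(np.mean((pred - y[None, None, :]) ** 2, axis=-1))
        j, k = np.triu_indices(n_grid)  # kd2 >= kd1
        best = min(best, float(rmse[j, k].min()))
    return best


def grid_oracle_hill(curve: DoseResponseCurve, n_grid: int = 40) -> float:
    """Dense grid-search oracle for the Hill RMSE minimum."""
    d = curve.concentrations_nm
    y = curve.mean_inhibition
    best = np.inf
    ic50s = np.geomspace(0.1, 1e5, n_grid)
    ns = np.linspace(0.1, 5.0, n_grid)
    for i_max in np.linspace(0.0, 1.0, n_grid):
        dn = d[None, None, :] ** ns[None, :, None]
        icn = ic50s[:, None, None] ** ns[None, :, None]
        pred = i_max * dn / (icn + dn)
        rmse = np.sqrt(np.mean((pred - y) ** 2, axis=-1))
        best = min(best, float(rmse.min()))
    return best
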