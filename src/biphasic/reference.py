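"""Bundled example panel of published joint Hill + biphasic fit parameters.

Seven cancer cell lines (colorectal: HT-29, SK-CO-1, NCI-H747; triple
negative breast: MDA-MB-231, MDA-MB-468; lung: HCC-827; leukemia: CTV-1)
plus the TNBC line DU-4475 screened against kinase inhibitors, each row a
(cell line, drug) response fitted jointly with the Hill equation and the
biphasic two-site model.  These are fitted-parameter constants for
demonstrating driver classification and combination ranking; the underlying
raw screening wells are not bundled, so the parameters are inputs here, not
recomputation targets.

Notes on individual entries:

* ``kd2_um`` is ``None`` where no second phase was reported and ``inf``
  where it was censored at the ">100 uM" bound.
* The HCC-827 F1/F2 ratios were garbled in the published table (spreadsheet
  date-mangling); the values used here (92/8, 93/7, 98/2) are the only
  orientation consistent with the rows' own mono-driver pattern (n > 1.7,
  Kd1 ~ IC50*, I_max ~ 90%).
* Two empirical IC50 constants are carried with both of their published
  readings, which differ between the summary table and the curve graphs;
  both provenances are kept distinct rather than reconciled.
"""

from __future__ import annotations

from math import inf

from .models import BiphasicParams, HillParams

__all__ = [
    "REFERENCE_PANEL",
    "REFERENCE_TARGETS",
    "EMPIRICAL_IC_NM",
    "reference_fit_pairs",
]

# cell, drug, Hill (rmse, i_max, ic50*_nM, n), biphasic (rmse, f1, kd1_nM, kd2_uM)
_ROWS = [
    ("HT-29", "AZD-6244", 0.027, 0.73, 248, 0.52, 0.029, 0.55, 92, 54.1),
    ("HT-29", "BMS-754807", 0.023, 1.00, 585, 0.34, 0.047, 0.44, 12, 8.4),
    ("HT-29", "Dasatinib", 0.032, 0.67, 147, 0.62, 0.026, 0.51, 59, 33.3),
    ("HT-29", "HG6-64-1", 0.024, 0.51, 16, 0.84, 0.026, 0.50, 14, inf),
    ("SK-CO-1", "AZD-6244", 0.025, 0.83, 543, 0.69, 0.025, 0.55, 169, 13.6),
    ("SK-CO-1", "BMS-754807", 0.034, 0.68, 200, 0.50, 0.048, 0.44, 32, 29.3),
    ("NCI-H747", "AZD-6244", 0.019, 0.75, 71, 0.62, 0.029, 0.61, 34, 25.6),
    ("NCI-H747", "BMS-754807", 0.028, 0.75, 231, 0.60, 0.031, 0.54, 75, 22.4),
    ("MDA-MB-231", "AZD-6244", 0.021, 0.46, 210, 0.68, 0.023, 0.36, 91, inf),
    ("MDA-MB-231", "Dasatinib", 0.05, 0.88, 300, 0.49, 0.018, 0.49, 30, 9.3),
    ("MDA-MB-468", "GSK690693", 0.08, 1.00, 2940, 0.42, 0.06, 0.37, 67, 15.6),
    ("MDA-MB-468", "Lapatinib", 0.026, 1.00, 190, 0.45, 0.038, 0.53, 17, 3.1),
    ("HCC-827", "Gefitinib", 0.027, 0.89, 10, 1.73, 0.056, 0.92, 11, inf),
    ("HCC-827", "Erlotinib", 0.029, 0.90, 14, 1.87, 0.062, 0.93, 16, inf),
    ("HCC-827", "Dasatinib", 0.049, 0.93, 149, 1.88, 0.075, 0.98, 157, inf),
    ("CTV-1", "Bosutinib", 0.033, 0.96, 51, 2.71, 0.10, 1.00, 56, None),
    ("CTV-1", "Dasatinib", 0.043, 0.97, 9.1, 2.72, 0.11, 1.00, 9.1, None),
    ("CTV-1", "WH-4-023", 0.043, 0.98, 712, 2.49, 0.096, 1.00, 716, None),
    ("DU-4475", "AZ628", 0.011, 0.91, 27, 1.81, 0.055, 0.95, 26, 3469),
    ("DU-4475", "PLX4720", 0.035, 0.90, 378, 1.41, 0.052, 0.98, 472, 32448),
    ("DU-4475", "SB590885", 0.081, 0.75, 353, 1.47, 0.088, 0.86, 524, 60),
    ("DU-4475", "RDEA119", 0.030, 0.86, 37, 1.62, 0.055, 0.90, 37, 75644),
    ("DU-4475", "CI-1040", 0.024, 0.88, 116, 1.63, 0.054, 0.93, 131, 50525),
    ("DU-4475", "PD-0325901", 0.044, 0.81, 2.4, 2.30, 0.094, 0.87, 2.6, 2169),
    ("DU-4475", "VX-11e", 0.029, 0.98, 80, 1.36, 0.049, 1.00, 80, None),
]

#: Known verdict of each panel cell line: the leukemia and lung lines are
#: driven by a single mutated kinase; the colorectal and TNBC lines depend
#: on several independent drivers.
REFERENCE_CELL_VERDICTS = {
    "HT-29": "multi",
    "SK-CO-1": "multi",
    "NCI-H747": "multi",
    "MDA-MB-231": "multi",
    "MDA-MB-468": "multi",
    "HCC-827": "mono",
    "CTV-1": "mono",
    "DU-4475": "mono",
}

#: Primary declared target of each panel drug (from external binding data).
REFERENCE_TARGETS = {
    "AZD-6244": "Mek",
    "BMS-754807": "IGF-1R/IR",
    "Dasatinib": "Src-family",
    "HG6-64-1": "BRAF",
    "GSK690693": "Akt",
    "Lapatinib": "EGFR/ErbB2",
    "Gefitinib": "EGFR",
    "Erlotinib": "EGFR",
    "Bosutinib": "Src-family",
    "WH-4-023": "Src-family",
    "AZ628": "BRAF",
    "PLX4720": "BRAF",
    "SB590885": "BRAF",
    "RDEA119": "Mek",
    "CI-1040": "Mek",
    "PD-0325901": "Mek",
    "VX-11e": "Erk",
}

#: Empirical (graph-read) IC_x constants, nM, tagged by provenance: "table"
#: values come from the published summary table, "curve" values from the
#: dose-response graphs; the two readings were never reconciled at source.
EMPIRICAL_IC_NM = {
    ("MDA-MB-231", "Dasatinib", 0.5): {"table": 578.0, "curve": 697.0},
    ("MDA-MB-231", "Dasatinib", 0.7): {"curve": 7413.0},
    ("MDA-MB-231", "Dasatinib+AZD-6244", 0.5): {"curve": 73.0},
    ("MDA-MB-231", "Dasatinib+AZD-6244", 0.7): {"curve": 158.0},
    ("MDA-MB-468", "Lapatinib", 0.5): {"table": 300.0, "curve": 231.0},
    ("MDA-MB-468", "Lapatinib+GSK690693", 0.5): {"curve": 22.0},
    ("MDA-MB-468", "Lapatinib+GSK690693", 0.7): {"curve": 64.0},
    ("MDA-MB-468", "GSK690693", 0.5): {"table": 9280.0},
    ("MDA-MB-468", "Dasatinib+AZD-6244", 0.5): {"curve": 15000.0},
}


def _biphasic(f1: float, kd1_nm: float, kd2_um) -> BiphasicParams:
    if kd2_um is None:
        return BiphasicParams(f1=f1, kd1_nm=kd1_nm, kd2_nm=None)
    if kd2_um == inf:
        from .models import CENSOR_BOUND_NM

        return BiphasicParams(f1=f1, kd1_nm=kd1_nm, kd2_nm=CENSOR_BOUND_NM, kd2_censored=True)
    return BiphasicParams(f1=f1, kd1_nm=kd1_nm, kd2_nm=kd2_um * 1e3)


REFERENCE_PANEL = [
    {
        "cell_line": cell,
        "drug": drug,
        "hill_rmse": h_rmse,
        "hill": HillParams(i_max=i_max, ic50_star_nm=ic50, n=n),
        "biphasic_rmse": b_rmse,
        "biphasic": _biphasic(f1, kd1, kd2),
    }
    for cell, drug, h_rmse, i_max, ic50, n, b_rmse, f1, kd1, kd2 in _ROWS
]


def reference_fit_pairs():
    """The panel as (hill FitResult, biphasic FitResult) pairs, ready for
    :func:`biphasic.classify.classify_response`."""
    from .fitting import FitResult

    pairs = []
    for row in REFERENCE_PANEL:
        common = dict(cell_line=row["cell_line"], treatment=row["drug"], n_points=16, converged=True, starts_tried=0)
        pairs.append(
            (
                FitResult(params=row["hill"], rmse=row["hill_rmse"], **common),
                FitResult(params=row["biphasic"], rmse=row["biphasic_rmse"], **common),
            )
        )
    return pairs
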