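"""Domain types, plate ingestion, and viability/inhibition normalization.

The canonical internal concentration unit is nanomolar and the canonical
response is the inhibited fraction of viability in [0, 1]; inhibition I and
relative viability V satisfy I = 1 - V for every well.  Replicate inhibition
values are *not* clamped to [0, 1] here — small negative or supra-1 values
are replicate noise and are informative for fitting; clamping happens only
at the IC_x-interpolation and plotting boundary.

Plate data follow the MTT-assay convention: corrected absorbance
(A490 - A750) of a treated well, divided by the mean corrected absorbance of
the control (vehicle-only) wells, gives relative viability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Concentration",
    "WellRecord",
    "DoseResponseCurve",
    "to_nanomolar",
    "normalize_plate",
    "normalize_gdsc",
    "read_curve_csv",
    "write_curve_csv",
    "write_fit_table",
]

_UNIT_TO_NM = {
    "pm": 1e-3,
    "nm": 1.0,
    "um": 1e3,
    "μm": 1e3,  # μM
    "µm": 1e3,  # µM
    "mm": 1e6,
}

ACCEPTED_UNITS = ("pM", "nM", "uM", "μM", "mM")
ACCEPTED_VALUE_TYPES = ("absorbance_pair", "viability", "inhibition")

CURVE_CSV_COLUMNS = [
    "cell_line",
    "drug",
    "concentration",
    "unit",
    "replicate",
    "value",
    "value_type",
]


def to_nanomolar(value: float, unit: str) -> float:
    """Convert a concentration to nM.  Accepted units: pM, nM, uM/μM, mM."""
    factor = _UNIT_TO_NM.get(str(unit).strip().lower())
    if factor is None:
        raise ValueError(
            f"unknown concentration unit {unit!r}; accepted units: "
            + ", ".join(ACCEPTED_UNITS)
        )
    return float(value) * factor


@dataclass(frozen=True, order=True)
class Concentration:
    """A drug concentration, stored in nM.

    Zero is permitted only for control (vehicle) wells; dosed wells must be
    strictly positive.
    """

    nm: float

    def __post_init__(self) -> None:
        if self.nm < 0:
            raise ValueError(f"concentration must be nonnegative, got {self.nm} nM")

    @classmethod
    def of(cls, value: float, unit: str = "nM") -> "Concentration":
        return cls(to_nanomolar(value, unit))

    @property
    def um(self) -> float:
        return self.nm / 1e3


@dataclass
class WellRecord:
    """One well of a viability plate (raw absorbance pair)."""

    cell_line: str
    treatment: str
    concentration_nm: float
    replicate: int
    a490: float
    a750: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.a490 < 0 or self.a750 < 0:
            raise ValueError("absorbances must be nonnegative")
        if self.is_control and self.concentration_nm != 0:
            raise ValueError("control wells must have concentration 0")
        if not self.is_control and self.concentration_nm <= 0:
            raise ValueError("dosed wells must have concentration > 0")

    @property
    def corrected(self) -> float:
        """Background-corrected absorbance A490 - A750 (viability proxy)."""
        return self.a490 - self.a750


@dataclass
class DoseResponseCurve:
    """Replicate inhibition measurements for one (cell line, treatment).

    ``inhibition`` is a (replicates x concentrations) matrix of inhibited
    fractions; entries may be NaN where a replicate is missing and may
    slightly exceed [0, 1] (replicate noise, deliberately unclamped).
    """

    cell_line: str
    treatment: str
    concentrations_nm: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_nm = np.asarray(self.concentrations_nm, dtype=float)
        self.inhibition = np.atleast_2d(np.asarray(self.inhibition, dtype=float))
        if self.concentrations_nm.ndim != 1:
            raise ValueError("concentrations_nm must be one-dimensional")
        if np.any(self.concentrations_nm <= 0):
            raise ValueError("curve concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations_nm) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if self.inhibition.shape[1] != self.concentrations_nm.size:
            raise ValueError(
                "inhibition matrix has "
                f"{self.inhibition.shape[1]} columns for "
                f"{self.concentrations_nm.size} concentrations"
            )

    @property
    def n_replicates(self) -> int:
        return self.inhibition.shape[0]

    @property
    def n_concentrations(self) -> int:
        return self.concentrations_nm.size

    @property
    def mean_inhibition(self) -> np.ndarray:
        """Per-concentration mean over replicates (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.inhibition, axis=0)

    @property
    def sem(self) -> np.ndarray:
        """Per-concentration standard error of the mean (ddof=1)."""
        counts = np.sum(np.isfinite(self.inhibition), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(self.inhibition, axis=0, ddof=1)
        out = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), 0.0)
        return out

    def clamped_mean(self) -> np.ndarray:
        """Mean inhibition clamped to [0, 1], for interpolation and plotting."""
        return np.clip(self.mean_inhibition, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def _assemble_curve(
    cell_line: str,
    treatment: str,
    conc: Sequence[float],
    repl: Sequence[int],
    inhib: Sequence[float],
) -> DoseResponseCurve:
    """Pivot long-format (concentration, replicate, inhibition) triples into
    a replicate-by-concentration matrix with an ascending dose grid."""
    df = pd.DataFrame({"conc": conc, "replicate": repl, "inhibition": inhib})
    wide = df.pivot_table(
        index="replicate", columns="conc", values="inhibition", aggfunc="mean"
    ).sort_index(axis=1)
    return DoseResponseCurve(
        cell_line=cell_line,
        treatment=treatment,
        concentrations_nm=wide.columns.to_numpy(dtype=float),
        inhibition=wide.to_numpy(dtype=float),
    )


def normalize_plate(wells: Iterable[WellRecord]) -> list[DoseResponseCurve]:
    """Normalize raw plate wells to inhibition curves.

    Relative viability of a treated well is its corrected absorbance
    (A490 - A750) divided by the mean corrected absorbance of the control
    wells of the same cell line; inhibition is ``1 - V``.  Control wells are
    pooled per cell line (vehicle controls are shared across the drugs on a
    plate).  A group with no controls raises ``ValueError``; a negative
    corrected absorbance triggers a warning but the value is retained.
    """
    wells = list(wells)
    for w in wells:
        if w.corrected < 0:
            warnings.warn(
                f"negative corrected absorbance ({w.corrected:.4g}) for "
                f"{w.cell_line}/{w.treatment} at {w.concentration_nm} nM; retained",
                stacklevel=2,
            )
    control_mean: dict[str, float] = {}
    for cell in {w.cell_line for w in wells}:
        ctrl = [w.corrected for w in wells if w.cell_line == cell and w.is_control]
        if ctrl:
            control_mean[cell] = float(np.mean(ctrl))

    curves = []
    groups = sorted({(w.cell_line, w.treatment) for w in wells if not w.is_control})
    for cell, treatment in groups:
        if cell not in control_mean:
            raise ValueError(f"no control wells for group {cell}/{treatment}")
        members = [w for w in wells if (w.cell_line, w.treatment) == (cell, treatment) and not w.is_control]
        inhib = [1.0 - w.corrected / control_mean[cell] for w in members]
        curves.append(
            _assemble_curve(
                cell,
                treatment,
                [w.concentration_nm for w in members],
                [w.replicate for w in members],
                inhib,
            )
        )
    return curves


def normalize_gdsc(raw: pd.DataFrame) -> list[DoseResponseCurve]:
    """Normalize a raw screening-intensity table to inhibition curves.

    Expects long-format columns ``conc`` (nM unless a ``unit`` column is
    present), ``intensity`` and ``tag`` (``control`` or ``treated``), plus
    optional ``cell_line``, ``drug`` and ``replicate``.  Relative viability
    is raw intensity over the mean control intensity of the same cell line;
    inhibition is ``1 - V``.
    """
    required = {"conc", "intensity", "tag"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw viability table is missing columns: {sorted(missing)}")
    df = raw.copy()
    if "cell_line" not in df:
        df["cell_line"] = "unknown"
    if "drug" not in df:
        df["drug"] = "unknown"
    if "replicate" not in df:
        df["replicate"] = 1
    if "unit" in df:
        df["conc_nm"] = [to_nanomolar(v, u) for v, u in zip(df["conc"], df["unit"])]
    else:
        df["conc_nm"] = df["conc"].astype(float)

    tags = set(df["tag"].unique())
    if not tags <= {"control", "treated"}:
        raise ValueError(
            f"unknown tag values {sorted(tags - {'control', 'treated'})}; "
            "accepted: control, treated"
        )
    curves = []
    for cell, cell_df in df.groupby("cell_line", sort=True):
        controls = cell_df.loc[cell_df["tag"] == "control", "intensity"]
        if controls.empty:
            raise ValueError(f"no control wells designated for cell line {cell}")
        ctrl_mean = float(controls.mean())
        treated = cell_df[cell_df["tag"] == "treated"]
        for drug, g in treated.groupby("drug", sort=True):
            inhib = 1.0 - g["intensity"].astype(float) / ctrl_mean
            curves.append(
                _assemble_curve(
                    str(cell), str(drug), g["conc_nm"].tolist(), g["replicate"].tolist(), inhib.tolist()
                )
            )
    return curves


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------


def read_curve_csv(path) -> list[DoseResponseCurve]:
    """Read dose-response curves from long-format CSV.

    Header: ``cell_line, drug, concentration, unit, replicate, value,
    value_type`` with ``value_type`` one of ``absorbance_pair`` (``value`` is
    A490 and an extra ``value2`` column holds A750; rows at concentration 0
    are controls), ``viability`` or ``inhibition``.  Malformed rows raise
    ``ValueError`` naming the offending line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CURVE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve CSV is missing columns: {missing}")

    wells: list[WellRecord] = []
    rows: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        vt = row.value_type
        if vt not in ACCEPTED_VALUE_TYPES:
            raise ValueError(
                f"line {lineno}: unknown value_type {vt!r}; accepted: "
                + ", ".join(ACCEPTED_VALUE_TYPES)
            )
        try:
            conc_nm = to_nanomolar(float(row.concentration), row.unit)
            replicate = int(row.replicate)
            value = float(row.value)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        if vt == "absorbance_pair":
            if "value2" not in df.columns:
                raise ValueError(
                    f"line {lineno}: value_type absorbance_pair requires a "
                    "'value2' column holding A750"
                )
            try:
                a750 = float(getattr(row, "value2"))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            wells.append(
                WellRecord(
                    cell_line=row.cell_line,
                    treatment=row.drug,
                    concentration_nm=conc_nm,
                    replicate=replicate,
                    a490=value,
                    a750=a750,
                    is_control=conc_nm == 0,
                )
            )
        else:
            inhib = 1.0 - value if vt == "viability" else value
            rows.append(
                {
                    "cell_line": row.cell_line,
                    "drug": row.drug,
                    "conc": conc_nm,
                    "replicate": replicate,
                    "inhibition": inhib,
                }
            )

    curves = normalize_plate(wells) if wells else []
    if rows:
        tidy = pd.DataFrame(rows)
        for (cell, drug), g in tidy.groupby(["cell_line", "drug"], sort=True):
            curves.append(
                _assemble_curve(cell, drug, g["conc"].tolist(), g["replicate"].tolist(), g["inhibition"].tolist())
            )
    return curves


def write_curve_csv(curves: Iterable[DoseResponseCurve], path) -> None:
    """Write curves in the long-format schema of :func:`read_curve_csv`
    (value_type ``inhibition``, unit nM); round-trip stable."""
    rows = []
    for c in curves:
        for r in range(c.n_replicates):
            for j, conc in enumerate(c.concentrations_nm):
                v = c.inhibition[r, j]
                if not np.isfinite(v):
                    continue
                rows.append(
                    {
                        "cell_line": c.cell_line,
                        "drug": c.treatment,
                        "concentration": repr(float(conc)),
                        "unit": "nM",
                        "replicate": r + 1,
                        "value": repr(float(v)),
                        "value_type": "inhibition",
                    }
                )
    pd.DataFrame(rows, columns=CURVE_CSV_COLUMNS).to_csv(path, index=False)


def write_fit_table(fit_rows, path) -> None:
    """Write joint Hill + biphasic fit results as a tidy CSV.

    ``fit_rows`` is an iterable of ``(hill_fit, biphasic_fit)`` pairs (see
    :mod:`biphasic.fitting`).  Column layout mirrors the conventional
    published fit tables: Hill RMSE, I_max (%), IC50* (nM), n, then biphasic
    RMSE, F1/F2 (%), Kd1 (nM), Kd2 (uM) with censored Kd2 printed ">100" and
    an absent second phase printed "None".  Floats carry 6 significant
    digits.
    """
    rows = []
    for hill, bi in fit_rows:
        hp, bp = hill.params, bi.params
        if bp.second_phase_absent:
            kd2 = "None"
        elif bp.kd2_censored:
            kd2 = ">100"
        else:
            kd2 = f"{bp.kd2_nm / 1e3:.6g}"
        rows.append(
            {
                "cell_line": hill.cell_line,
                "drug": hill.treatment,
                "hill_rmse": f"{hill.rmse:.6g}",
                "i_max_pct": f"{hp.i_max * 100:.6g}",
                "ic50_star_nm": f"{hp.ic50_star_nm:.6g}",
                "hill_n": f"{hp.n:.6g}",
                "biphasic_rmse": f"{bi.rmse:.6g}",
                "f1_f2_pct": f"{bp.f1 * 100:.0f}/{bp.f2 * 100:.0f}",
                "kd1_nm": f"{bp.kd1_nm:.6g}",
                "kd2_um": kd2,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
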