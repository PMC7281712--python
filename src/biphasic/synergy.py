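"""Empirical IC_x extraction, dose-reduction index, isobolograms, and
combination ranking.

IC_x values are read off the empirical curve by linear interpolation of the
clamped mean inhibition against log10(dose) — a reproducible stand-in for
reading concentrations "off the graph" — with model-based inversion
available as a cross-check.  For a 1:1 (equal-molar) two-drug mixture at
per-drug dose D, the Chou-Talalay combination index at inhibition level x is

    CI = D / ICx_1 + D / ICx_2

and the pooled dose-reduction index is its reciprocal,

    DRI = ICx_1 * ICx_2 / (ICx_combo * (ICx_1 + ICx_2)),

with CI < 1 (DRI > 1) indicating synergy.  Per-drug dose reductions
ICx_i / ICx_combo are reported alongside the pooled value.  When any
required IC_x is unattainable (the curve tops out below the level) the DRI
is reported absent with a reason rather than extrapolated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .core_io import DoseResponseCurve
from .models import BiphasicParams, HillParams, inverse_dose

__all__ = [
    "ICxEstimate",
    "IsobologramRecord",
    "SynergyLevelRecord",
    "SynergyReport",
    "SpecificityFold",
    "ic_x",
    "ic_x_model",
    "dose_reduction_index",
    "combination_index",
    "isobologram_points",
    "rank_combinations",
    "specificity_fold",
    "build_synergy_report",
]

DEFAULT_LEVELS = (0.5, 0.7, 0.9)


@dataclass
class ICxEstimate:
    """Dose producing a target inhibition level on one curve.

    ``dose_nm`` is per drug for 1:1 combinations and is ``None`` when the
    level is unattainable (the curve never reaches it).
    """

    level: float
    dose_nm: float | None
    attainable: bool
    method: str  # "interpolated" or "model_based"


def ic_x(curve: DoseResponseCurve, level: float) -> ICxEstimate:
    """Interpolate the dose at which mean inhibition crosses ``level``.

    Linear interpolation on log10(dose) between the first bracketing pair
    of the clamped per-concentration means.  If the curve tops out below
    the level the estimate is flagged unattainable; if the mean crosses the
    level more than once (non-monotone noise) the first crossing is used
    and a warning emitted.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"inhibition level must be in (0, 1), got {level}")
    if curve.n_concentrations < 2:
        raise ValueError("need at least two concentrations to interpolate")
    y = curve.clamped_mean()
    x = np.log10(curve.concentrations_nm)
    if np.nanmax(y) < level:
        return ICxEstimate(level=level, dose_nm=None, attainable=False, method="interpolated")
    if y[0] >= level:
        warnings.warn(
            f"mean inhibition already at or above {level:.0%} at the lowest dose; "
            "reporting the lowest dose as an upper-bound IC estimate",
            stacklevel=2,
        )
        return ICxEstimate(
            level=level,
            dose_nm=float(curve.concentrations_nm[0]),
            attainable=True,
            method="interpolated",
        )
    below = y < level
    crossings = np.nonzero(below[:-1] & ~below[1:])[0]
    if crossings.size > 1:
        warnings.warn(
            f"mean inhibition crosses the {level:.0%} level {crossings.size} times; "
            "using the first crossing",
            stacklevel=2,
        )
    i = int(crossings[0])
    frac = (level - y[i]) / (y[i + 1] - y[i])
    dose = 10.0 ** (x[i] + frac * (x[i + 1] - x[i]))
    return ICxEstimate(level=level, dose_nm=float(dose), attainable=True, method="interpolated")


def ic_x_model(params: HillParams | BiphasicParams, level: float) -> ICxEstimate:
    """Model-based IC_x via the fitted curve's inverse (cross-check mode)."""
    try:
        dose = inverse_dose(level, params)
    except ValueError:
        return ICxEstimate(level=level, dose_nm=None, attainable=False, method="model_based")
    return ICxEstimate(level=level, dose_nm=dose, attainable=True, method="model_based")


def dose_reduction_index(ic1_nm: float, ic2_nm: float, ic_combo_nm: float) -> float:
    """Pooled dose-reduction index of a 1:1 mixture at one inhibition level.

    ``ic_combo_nm`` is the per-drug dose of the mixture.  Equals the
    reciprocal of the combination index; > 1 indicates synergy-driven dose
    reduction.
    """
    for name, v in (("ic1_nm", ic1_nm), ("ic2_nm", ic2_nm), ("ic_combo_nm", ic_combo_nm)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (ic1_nm * ic2_nm) / (ic_combo_nm * (ic1_nm + ic2_nm))


def combination_index(ic1_nm: float, ic2_nm: float, ic_combo_nm: float) -> float:
    """Chou-Talalay combination index for a 1:1 mixture (1/DRI)."""
    return 1.0 / dose_reduction_index(ic1_nm, ic2_nm, ic_combo_nm)


@dataclass
class IsobologramRecord:
    """Plot-ready isobologram data at one inhibition level."""

    level: float
    intercept_drug1: tuple[float, float]  # (ic1, 0)
    intercept_drug2: tuple[float, float]  # (0, ic2)
    additivity_line: tuple[tuple[float, float], tuple[float, float]]
    combination_point: tuple[float, float]
    interaction_index: float  # d1/ic1 + d2/ic2: <1 synergy, 1 additive, >1 antagonism


def isobologram_points(
    ic1_nm: float, ic2_nm: float, combo_point_nm: tuple[float, float], *, level: float = 0.5
) -> IsobologramRecord:
    """Isobologram coordinates for one inhibition level.

    Raises ``ValueError`` if either single-agent IC is missing (the
    additivity line is undefined at that level).
    """
    if ic1_nm is None or ic2_nm is None or ic1_nm <= 0 or ic2_nm <= 0:
        raise ValueError("isobologram undefined at this level: single-agent IC_x unattainable")
    d1, d2 = combo_point_nm
    if d1 < 0 or d2 < 0:
        raise ValueError("combination doses must be nonnegative")
    return IsobologramRecord(
        level=level,
        intercept_drug1=(float(ic1_nm), 0.0),
        intercept_drug2=(0.0, float(ic2_nm)),
        additivity_line=((float(ic1_nm), 0.0), (0.0, float(ic2_nm))),
        combination_point=(float(d1), float(d2)),
        interaction_index=float(d1 / ic1_nm + d2 / ic2_nm),
    )


@dataclass
class RankedPair:
    drug1: str
    drug2: str
    target1: str
    target2: str
    coverage: float  # min(F1_a + F1_b, 1): combined target-specific amplitude
    max_kd1_nm: float  # potency bottleneck of the pair


def rank_combinations(
    fits: Mapping[str, BiphasicParams], targets: Mapping[str, str]
) -> list[RankedPair]:
    """Rank candidate 1:1 combinations by combined target-specific coverage.

    Pairs of drugs with distinct target labels are scored by
    ``min(F1_a + F1_b, 1)`` (how much of viability the two target-specific
    phases can jointly remove; descending) and tie-broken by the larger of
    the two Kd1 values (the potency bottleneck; ascending).  Pairs sharing
    a target label are excluded — hitting the same driver twice adds no
    coverage.  Fewer than two eligible drugs yields an empty list.
    """
    drugs = sorted(set(fits) & set(targets))
    pairs = []
    for a, b in itertools.combinations(drugs, 2):
        if targets[a] == targets[b]:
            continue
        coverage = min(fits[a].f1 + fits[b].f1, 1.0)
        pairs.append(
            RankedPair(
                drug1=a,
                drug2=b,
                target1=targets[a],
                target2=targets[b],
                coverage=coverage,
                max_kd1_nm=max(fits[a].kd1_nm, fits[b].kd1_nm),
            )
        )
    pairs.sort(key=lambda p: (-p.coverage, p.max_kd1_nm, p.drug1, p.drug2))
    return pairs


@dataclass
class SpecificityFold:
    """IC_x fold-difference between two cell lines for the same treatment."""

    level: float
    fold: float
    lower_bound: bool  # True when the less sensitive line never reaches the level

    def __str__(self) -> str:
        prefix = ">= " if self.lower_bound else ""
        return f"{prefix}{self.fold:.3g}-fold at {self.level:.0%} inhibition"


def specificity_fold(
    curve_sensitive: DoseResponseCurve,
    curve_resistant: DoseResponseCurve,
    level: float,
) -> SpecificityFold:
    """Fold difference IC_x(resistant) / IC_x(sensitive) at one level.

    If the resistant curve never reaches the level the fold is reported as
    a lower bound using its top dose; the level being unattainable on the
    sensitive curve is an error.
    """
    icx_s = ic_x(curve_sensitive, level)
    if not icx_s.attainable:
        raise ValueError(
            f"{level:.0%} inhibition unattainable on the sensitive curve "
            f"({curve_sensitive.cell_line}/{curve_sensitive.treatment})"
        )
    icx_r = ic_x(curve_resistant, level)
    if icx_r.attainable:
        return SpecificityFold(level=level, fold=icx_r.dose_nm / icx_s.dose_nm, lower_bound=False)
    top = float(curve_resistant.concentrations_nm[-1])
    return SpecificityFold(level=level, fold=top / icx_s.dose_nm, lower_bound=True)


@dataclass
class SynergyLevelRecord:
    level: float
    ic_drug1_nm: float | None
    ic_drug2_nm: float | None
    ic_combo_nm: float | None
    dri: float | None
    ci: float | None
    dri_drug1: float | None
    dri_drug2: float | None
    note: str | None = None


@dataclass
class SynergyReport:
    """Per-level synergy quantification for one 1:1 drug combination."""

    cell_line: str
    drug1: str
    drug2: str
    levels: list[SynergyLevelRecord]
    isobolograms: list[IsobologramRecord]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def build_synergy_report(
    curve1: DoseResponseCurve,
    curve2: DoseResponseCurve,
    curve_combo: DoseResponseCurve,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> SynergyReport:
    """Assemble the full synergy report for two drugs and their 1:1 mixture.

    At each inhibition level: single-agent and combination IC_x by
    log-linear interpolation, pooled DRI and CI (only when all three IC_x
    are attainable), per-drug dose reductions, and isobologram coordinates
    with the combination plotted at (D, D) per-drug dose.
    """
    report = SynergyReport(
        cell_line=curve_combo.cell_line,
        drug1=curve1.treatment,
        drug2=curve2.treatment,
        levels=[],
        isobolograms=[],
    )
    for level in levels:
        e1, e2, ec = (ic_x(c, level) for c in (curve1, curve2, curve_combo))
        note = None
        if not (e1.attainable and e2.attainable and ec.attainable):
            missing = [
                name
                for name, e in ((curve1.treatment, e1), (curve2.treatment, e2), ("combination", ec))
                if not e.attainable
            ]
            note = (
                f"DRI not calculable at {level:.0%}: level unattainable for "
                + ", ".join(missing)
            )
            report.notes.append(note)
            dri = ci = dri1 = dri2 = None
        else:
            dri = dose_reduction_index(e1.dose_nm, e2.dose_nm, ec.dose_nm)
            ci = 1.0 / dri
            dri1 = e1.dose_nm / ec.dose_nm
            dri2 = e2.dose_nm / ec.dose_nm
            report.isobolograms.append(
                isobologram_points(
                    e1.dose_nm, e2.dose_nm, (ec.dose_nm, ec.dose_nm), level=level
                )
            )
        report.levels.append(
            SynergyLevelRecord(
                level=level,
                ic_drug1_nm=e1.dose_nm,
                ic_drug2_nm=e2.dose_nm,
                ic_combo_nm=ec.dose_nm,
                dri=dri,
                ci=ci,
                dri_drug1=dri1,
                dri_drug2=dri2,
                note=note,
            )
        )
    return report
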