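"""Synthetic plate-data generator.

Emulates the screening design the analysis assumes: 16-point two-fold
dilution series from 0.6 nM (top dose 0.6 x 2^15 ~ 19.66 uM, i.e. the
conventional "0.6 nM to 20 uM" window), three replicates per concentration,
and additive i.i.d. Gaussian replicate noise on the inhibition scale with a
default standard deviation of 0.02, bracketing the residual magnitude of
well-fit published curves (RMSE ~ 0.02-0.11).

Ground-truth scenarios:

* mono-driver: a single saturating phase (F1 = 1);
* multi-driver: a biphasic response (partial F1 at low-nM Kd1 plus an
  off-target phase at uM Kd2);
* combination, independent action: viability is the product of independent
  survival terms, one per driver-specific phase and one per off-target
  phase — a simulation assumption for a 1:1 mixture whose drivers act
  through distinct pathways;
* combination, Loewe additive: the dose-equivalence null (the mixture dose
  splits between the two single-agent dose scales), used as the additivity
  reference for isobologram tests.

Combination doses are per drug (equal-molar 1:1 mixtures); totals are never
summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core_io import DoseResponseCurve, WellRecord
from .models import BiphasicParams, biphasic_inhibition, inverse_dose

__all__ = [
    "STANDARD_GRID_NM",
    "DEFAULT_NOISE_SD",
    "DEFAULT_REPLICATES",
    "SimulationConfig",
    "standard_grid",
    "simulate_monotherapy",
    "simulate_combination",
    "simulate_combination_additive",
    "simulate_plate",
]

#: 16 two-fold dilutions from 0.6 nM up to ~19.66 uM.
STANDARD_GRID_NM = 0.6 * 2.0 ** np.arange(16)

DEFAULT_NOISE_SD = 0.02
DEFAULT_REPLICATES = 3

SCENARIOS = (
    "mono_driver",
    "multi_driver",
    "combination_additive",
    "combination_multi_driver",
)


def standard_grid() -> np.ndarray:
    """A fresh copy of the standard 16-point dose grid (nM)."""
    return STANDARD_GRID_NM.copy()


@dataclass
class SimulationConfig:
    """Ground truth and noise structure for one simulated experiment."""

    scenario: str
    truth: dict[str, BiphasicParams]
    grid_nm: np.ndarray = field(default_factory=standard_grid)
    replicates: int = DEFAULT_REPLICATES
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; accepted: {SCENARIOS}")
        self.grid_nm = np.asarray(self.grid_nm, dtype=float)
        if self.grid_nm.ndim != 1 or np.any(np.diff(self.grid_nm) <= 0) or np.any(self.grid_nm <= 0):
            raise ValueError("grid must be a strictly increasing positive dose series")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _noisy_curve(mean, cfg: SimulationConfig, cell_line: str, treatment: str, rng=None) -> DoseResponseCurve:
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.replicates, cfg.grid_nm.size))
    return DoseResponseCurve(
        cell_line=cell_line,
        treatment=treatment,
        concentrations_nm=cfg.grid_nm.copy(),
        inhibition=mean[None, :] + noise,
    )


def simulate_monotherapy(
    truth: BiphasicParams,
    *,
    cell_line: str = "SIM",
    treatment: str = "drug",
    grid_nm: Sequence[float] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> DoseResponseCurve:
    """Simulate a single-drug triplicate curve from a biphasic ground truth.

    The replicate mean equals the model exactly; each replicate adds
    Gaussian noise on the inhibition scale.  Deterministic under a fixed
    seed.
    """
    scenario = "mono_driver" if truth.second_phase_absent else "multi_driver"
    cfg = SimulationConfig(
        scenario=scenario,
        truth={treatment: truth},
        grid_nm=standard_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float),
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )
    mean = biphasic_inhibition(cfg.grid_nm, truth)
    return _noisy_curve(np.asarray(mean), cfg, cell_line, treatment)


def simulate_combination(
    drivers: Sequence[tuple[float, float]],
    off_targets: Sequence[tuple[float, float]] = (),
    *,
    cell_line: str = "SIM",
    treatment: str = "combo",
    grid_nm: Sequence[float] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> DoseResponseCurve:
    """Simulate a 1:1 combination under independent action across drivers.

    ``drivers`` and ``off_targets`` are (fraction, Kd nM) pairs, one per
    driver-specific phase of each drug and one per off-target phase;
    viability at per-drug dose D is the product of the survival terms
    ``1 - f * D / (D + K)``.  Fractions must each lie in [0, 1] and the
    driver fractions may sum to at most 1 (they partition viability).
    """
    if not drivers:
        raise ValueError("at least one driver term is required")
    for f, k in list(drivers) + list(off_targets):
        if not 0.0 <= f <= 1.0 or k <= 0:
            raise ValueError(f"invalid (fraction, Kd) term ({f}, {k})")
    if sum(f for f, _ in drivers) > 1.0 + 1e-9:
        raise ValueError("driver fractions must sum to at most 1")
    grid = standard_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    viability = np.ones_like(grid)
    for f, k in list(drivers) + list(off_targets):
        viability *= 1.0 - f * grid / (grid + k)
    cfg = SimulationConfig(
        scenario="combination_multi_driver",
        truth={},
        grid_nm=grid,
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )
    return _noisy_curve(1.0 - viability, cfg, cell_line, treatment)


def _loewe_inhibition(d: float, a: BiphasicParams, b: BiphasicParams) -> float:
    """Inhibition of the Loewe-additive 1:1 mixture at per-drug dose ``d``.

    Solves d/D_A(I) + d/D_B(I) = 1 for I, where D_X(I) is the single-agent
    dose of drug X producing inhibition I (dose equivalence).
    """
    asym = min(
        a.f1 if a.second_phase_absent else 1.0,
        b.f1 if b.second_phase_absent else 1.0,
    )

    def excess(i):
        return d / inverse_dose(i, a) + d / inverse_dose(i, b) - 1.0

    lo, hi = 1e-9, asym - 1e-9
    if excess(lo) < 0:  # dose too small to produce measurable inhibition
        return 0.0
    return float(brentq(excess, lo, hi, rtol=1e-12))


def simulate_combination_additive(
    truth_a: BiphasicParams,
    truth_b: BiphasicParams,
    *,
    cell_line: str = "SIM",
    treatment: str = "combo_additive",
    grid_nm: Sequence[float] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
) -> DoseResponseCurve:
    """Simulate the Loewe-additive null for a 1:1 mixture of two drugs.

    By construction the resulting curve sits exactly on the isobologram
    additivity line at every attainable inhibition level, so it serves as
    the zero-interaction reference.
    """
    grid = standard_grid() if grid_nm is None else np.asarray(grid_nm, dtype=float)
    mean = np.array([_loewe_inhibition(float(d), truth_a, truth_b) for d in grid])
    cfg = SimulationConfig(
        scenario="combination_additive",
        truth={"A": truth_a, "B": truth_b},
        grid_nm=grid,
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )
    return _noisy_curve(mean, cfg, cell_line, treatment)


def simulate_plate(
    truth: BiphasicParams,
    *,
    cell_line: str = "SIM",
    treatment: str = "drug",
    grid_nm: Sequence[float] | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    baseline_a490: float = 1.05,
    background_a750: float = 0.05,
    n_controls: int = 6,
) -> list[WellRecord]:
    """Emit raw A490/A750 wells whose normalization reproduces the simulated
    inhibition exactly.

    The same seed produces the same underlying inhibition draws as
    :func:`simulate_monotherapy`, so ``normalize_plate(simulate_plate(...))``
    recovers that curve identically.  Control wells carry the clean baseline
    absorbance.
    """
    curve = simulate_monotherapy(
        truth,
        cell_line=cell_line,
        treatment=treatment,
        grid_nm=grid_nm,
        replicates=replicates,
        noise_sd=noise_sd,
        seed=seed,
    )
    control_corrected = baseline_a490 - background_a750
    wells = [
        WellRecord(
            cell_line=cell_line,
            treatment="control",
            concentration_nm=0.0,
            replicate=i + 1,
            a490=baseline_a490,
            a750=background_a750,
            is_control=True,
        )
        for i in range(n_controls)
    ]
    for r in range(curve.n_replicates):
        for j, conc in enumerate(curve.concentrations_nm):
            viability = 1.0 - curve.inhibition[r, j]
            wells.append(
                WellRecord(
                    cell_line=cell_line,
                    treatment=treatment,
                    concentration_nm=float(conc),
                    replicate=r + 1,
                    a490=background_a750 + viability * control_corrected,
                    a750=background_a750,
                    is_control=False,
                )
            )
    return wells
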