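"""Closed-form inhibition models and their inverses.

Two models of the inhibition ``I`` of cell viability by a drug at
concentration ``D`` (nM):

* the three-parameter Hill equation

  .. math:: I = I_{max} \\frac{D^n}{IC_{50}^{*n} + D^n}

  where ``I_max`` is the maximal inhibition, ``IC50*`` the half-effect
  concentration of the drug-sensitive viability fraction, and ``n`` the
  Hill coefficient (slope);

* the biphasic two-site model

  .. math:: I = F_1 \\frac{D}{D + K_{d1}} + F_2 \\frac{D}{D + K_{d2}}

  which decomposes the response into a high-affinity target-specific phase
  (amplitude ``F1``, apparent dissociation constant ``Kd1``) and a
  low-affinity off-target phase (``F2 = 1 - F1``, ``Kd2``).

Inhibition is an inhibited fraction of viability in [0, 1] (percent only at
reporting boundaries); concentrations are nanomolar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "CENSOR_BOUND_NM",
    "HillParams",
    "BiphasicParams",
    "hill_inhibition",
    "biphasic_inhibition",
    "inverse_dose",
]

#: Upper reporting bound for Kd2 (100 uM).  Fitted values at this bound are
#: flagged censored and printed as ">100" (uM); forward evaluation uses the
#: bound itself.
CENSOR_BOUND_NM = 1.0e5

#: F1 at or above this value means the second phase is absent (printed
#: "None"): the model degenerates to single-site binding.
SECOND_PHASE_ABSENT_F1 = 0.995


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters: maximal inhibition, half-effect dose, slope."""

    i_max: float
    ic50_star_nm: float
    n: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.i_max <= 1.0:
            raise ValueError(f"i_max must be a fraction in [0, 1], got {self.i_max}")
        if self.ic50_star_nm <= 0:
            raise ValueError(f"ic50_star_nm must be positive, got {self.ic50_star_nm}")
        if self.n <= 0:
            raise ValueError(f"Hill coefficient n must be positive, got {self.n}")


@dataclass(frozen=True)
class BiphasicParams:
    """Two-site parameters.

    ``f2`` is always derived as ``1 - f1`` and never stored.  ``kd2_nm`` may
    be ``None`` only when the second phase is absent (``f1`` ~ 1), matching
    the "None" reporting convention; ``kd2_censored`` marks fits pinned at
    the 100 uM bound (printed ">100").
    """

    f1: float
    kd1_nm: float
    kd2_nm: float | None = None
    kd2_censored: bool = False
    second_phase_absent: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.f1 <= 1.0:
            raise ValueError(f"f1 must be a fraction in [0, 1], got {self.f1}")
        if self.kd1_nm <= 0:
            raise ValueError(f"kd1_nm must be positive, got {self.kd1_nm}")
        if self.kd2_nm is None:
            # No second phase: force the flag so downstream reporting is
            # consistent regardless of how the instance was built.
            object.__setattr__(self, "second_phase_absent", True)
        else:
            if self.kd2_nm <= 0:
                raise ValueError(f"kd2_nm must be positive, got {self.kd2_nm}")
            if not self.second_phase_absent and self.kd2_nm < self.kd1_nm:
                raise ValueError(
                    "kd2_nm must be >= kd1_nm (phase 1 is the high-affinity phase): "
                    f"kd1={self.kd1_nm}, kd2={self.kd2_nm}"
                )

    @property
    def f2(self) -> float:
        """Off-target amplitude, always ``1 - f1``."""
        return 1.0 - self.f1


def hill_inhibition(d, p: HillParams):
    """Hill-equation inhibition at dose ``d`` (nM, scalar or array)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    dn = np.power(d, p.n)
    with np.errstate(invalid="ignore"):
        out = p.i_max * dn / (p.ic50_star_nm**p.n + dn)
    out = np.where(d == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def biphasic_inhibition(d, p: BiphasicParams):
    """Two-site inhibition at dose ``d`` (nM, scalar or array).

    With the second phase absent this is the single-site curve
    ``f1 * d / (d + kd1)``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    out = p.f1 * d / (d + p.kd1_nm)
    if not p.second_phase_absent and p.kd2_nm is not None:
        out = out + p.f2 * d / (d + p.kd2_nm)
    return float(out) if out.ndim == 0 else out


def _asymptote(p: HillParams | BiphasicParams) -> float:
    if isinstance(p, HillParams):
        return p.i_max
    if p.second_phase_absent or p.kd2_nm is None:
        return p.f1
    return 1.0


def inverse_dose(target: float, p: HillParams | BiphasicParams) -> float:
    """Dose (nM) at which the model reaches ``target`` inhibition.

    The Hill inverse is closed form; the biphasic inverse is found by
    bracketed root-finding to 1e-12 relative tolerance.  Raises
    ``ValueError`` for targets at or above the model's asymptote, which no
    finite dose can reach.
    """
    asym = _asymptote(p)
    if not 0.0 < target < asym:
        raise ValueError(
            f"unreachable inhibition level {target}: model asymptote is {asym}"
        )
    if isinstance(p, HillParams):
        return p.ic50_star_nm * (target / (p.i_max - target)) ** (1.0 / p.n)
    lo, hi = 1e-9, p.kd1_nm
    while biphasic_inhibition(hi, p) < target:
        hi *= 10.0
        if hi > 1e15:  # pragma: no cover - guarded by the asymptote check
            raise RuntimeError("failed to bracket inverse dose")
    return float(brentq(lambda x: biphasic_inhibition(x, p) - target, lo, hi, rtol=1e-12))
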