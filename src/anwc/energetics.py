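"""Indirect-calorimetry conversions and efficiency definitions.

Metabolic rate (MR) is derived from oxygen uptake and the respiratory
exchange ratio (RER = VCO2/VO2) with the Weir equation, expressed in watts:

    MR [W] = 4184 * VO2 [L min^-1] * (1.1 * RER + 3.9) / 60

Gross efficiency is external power divided by total MR; net efficiency
subtracts the seated resting baseline MR from the denominator; delta
efficiency (reciprocal slope of the PO-MR regression) lives with the
regression model in :mod:`anwc.anwc_models`.

All functions are pure and accept scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WEIR_KCAL_J",
    "RER_INPUT_RANGE",
    "BaselineResult",
    "weir_mr",
    "vo2_for_mr",
    "gross_efficiency",
    "net_efficiency",
    "aerobic_mr_series",
]

#: Energy constant, J per kcal, fixed exactly as used in the Weir conversion.
WEIR_KCAL_J = 4184.0

#: Physiological sanity range accepted for measured RER inputs.
RER_INPUT_RANGE = (0.6, 1.3)

#: Plausibility bounds for gross efficiency during exercise (warn, not error).
GE_PLAUSIBLE = (0.0, 0.35)


@dataclass(frozen=True)
class BaselineResult:
    """Seated resting baseline, averaged over the 3-min baseline window.

    ``mr_bl`` is in absolute watts; ``rer_bl`` is left uncapped (resting RER
    above 1.00 does not occur in practice).
    """

    mr_bl: float
    vo2_bl: float  # L min^-1
    rer_bl: float

    def __post_init__(self) -> None:
        if not self.mr_bl > 0:
            raise ValueError(f"baseline MR must be positive, got {self.mr_bl}")


def _check_rer(rer) -> None:
    lo, hi = RER_INPUT_RANGE
    r = np.asarray(rer, dtype=float)
    if np.any(r < lo) or np.any(r > hi):
        raise ValueError(
            f"RER outside plausible input range [{lo}, {hi}]: "
            f"min={r.min()}, max={r.max()}"
        )


def weir_mr(vo2, rer, rer_cap: float | None = None):
    """Metabolic rate in watts from VO2 (L min^-1) and RER.

    Parameters
    ----------
    vo2 : float or array
        Oxygen uptake in L min^-1, must be >= 0.
    rer : float or array
        Respiratory exchange ratio; validated against ``RER_INPUT_RANGE``.
    rer_cap : float, optional
        If given, the RER actually used in the formula is ``min(rer, cap)``
        (submaximal MR uses RER <= 1.00; the raw value is kept for
        reporting by the caller).
    """
    v = np.asarray(vo2, dtype=float)
    if np.any(v < 0):
        raise ValueError("vo2 must be non-negative")
    _check_rer(rer)
    r = np.asarray(rer, dtype=float)
    if rer_cap is not None:
        r = np.minimum(r, rer_cap)
    out = WEIR_KCAL_J * v * (1.1 * r + 3.9) / 60.0
    return out if out.ndim else float(out)


def vo2_for_mr(mr, rer):
    """Invert :func:`weir_mr`: the VO2 (L min^-1) producing ``mr`` watts at ``rer``."""
    _check_rer(rer)
    m = np.asarray(mr, dtype=float)
    r = np.asarray(rer, dtype=float)
    out = m * 60.0 / (WEIR_KCAL_J * (1.1 * r + 3.9))
    return out if out.ndim else float(out)


def gross_efficiency(po, mr):
    """GE = PO / MR (both watts). ``mr`` must be positive."""
    m = np.asarray(mr, dtype=float)
    if np.any(m <= 0):
        raise ValueError("metabolic rate must be positive for gross efficiency")
    out = np.asarray(po, dtype=float) / m
    return out if out.ndim else float(out)


def net_efficiency(po, mr, mr_bl):
    """Net efficiency = PO / (MR - MR_baseline). Requires ``mr > mr_bl``."""
    m = np.asarray(mr, dtype=float)
    b = np.asarray(mr_bl, dtype=float)
    if np.any(m <= b):
        raise ValueError("metabolic rate must exceed baseline MR for net efficiency")
    out = np.asarray(po, dtype=float) / (m - b)
    return out if out.ndim else float(out)


def aerobic_mr_series(vo2_1s, tt_rer: float = 1.00):
    """Per-second aerobic MR (watts) over the all-out time trial.

    The TT assumes pure carbohydrate oxidation, so the Weir equation is
    applied pointwise with a fixed RER (default 1.00) regardless of the
    measured exchange ratio.
    """
    return weir_mr(np.asarray(vo2_1s, dtype=float), tt_rer)
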