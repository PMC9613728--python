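"""The four anaerobic work capacity / anaerobic capacity models.

Given the submaximal stage table, the seated baseline and the 1-s time-trial
series, four estimates of the anaerobically attributable work are computed:

* ``7+Y_LIN`` — OLS regression of stage metabolic rate (MR, W) on power
  output (PO, W) with the resting baseline included as the point (0, MR_BL);
* ``7-Y_LIN`` — the same regression on the seven stages only;
* ``GE_LAST`` — the gross efficiency of the last submaximal stage assumed
  constant during the TT (equivalently a zero-intercept line with slope
  1/GE_LAST);
* ``CP_3AO`` — critical power as the mean PO of the final 30 s of the 3-min
  all-out TT, with W' (work above CP) standing in for AnWC.

For the first three models the required MR at each TT second is predicted
from the model, the anaerobic MR is the excess over the measured aerobic MR
(MR_AN = MR_req - MR_AE), and the anaerobically attributable power is
PO_AN = PO - MR_AE * GE_inst with the model's instantaneous gross
efficiency. AnC integrates MR_AN over the 180 s; AnWC integrates PO_AN.
Integration uses the rectangular rule on the 1-s grid, matching the data
resolution. With a constant GE the identity AnWC = GE * AnC is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .energetics import BaselineResult

__all__ = [
    "MODEL_7PY",
    "MODEL_7MY",
    "MODEL_GE_LAST",
    "MODEL_CP",
    "ALL_MODELS",
    "PoMrRegression",
    "TTDecomposition",
    "fit_po_mr_regression",
    "required_mr_regression",
    "required_mr_ge_last",
    "instantaneous_ge",
    "anaerobic_mr",
    "anaerobic_po",
    "critical_power_3ao",
    "w_prime",
    "estimate_all_models",
]

MODEL_7PY = "7+Y_LIN"
MODEL_7MY = "7-Y_LIN"
MODEL_GE_LAST = "GE_LAST"
MODEL_CP = "CP_3AO"
ALL_MODELS = (MODEL_7PY, MODEL_7MY, MODEL_GE_LAST, MODEL_CP)


@dataclass(frozen=True)
class PoMrRegression:
    """Fitted linear PO -> MR model (absolute watts).

    ``slope`` is dimensionless (MR watts per PO watt), ``intercept`` in
    watts. ``see`` is the standard error of the estimate with an n-2
    denominator; delta efficiency is the reciprocal of the slope.
    """

    slope: float
    intercept: float
    include_baseline: bool
    r2: float
    see: float
    po: np.ndarray = field(repr=False)
    mr: np.ndarray = field(repr=False)

    @property
    def n_points(self) -> int:
        return int(self.po.size)

    @property
    def delta_efficiency(self) -> float:
        return 1.0 / self.slope

    def predict(self, po):
        """Required MR at power ``po``; supramaximal extrapolation is the
        intended use."""
        out = self.slope * np.asarray(po, dtype=float) + self.intercept
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class TTDecomposition:
    """Per-second decomposition of the TT under one model, plus the scalars.

    Arrays are aligned on the 1-s grid; energies are rectangular sums in
    absolute joules (per-kg scaling happens at the reporting layer). The CP
    model carries no MR decomposition: its ``po_an`` is the signed excess
    over CP and ``anwc`` is W'.
    """

    model: str
    t: np.ndarray = field(repr=False)
    po_tt: np.ndarray = field(repr=False)
    mr_ae: np.ndarray = field(repr=False)
    anwc: float
    mr_req: np.ndarray | None = field(default=None, repr=False)
    ge_inst: np.ndarray | None = field(default=None, repr=False)
    mr_an: np.ndarray | None = field(default=None, repr=False)
    po_an: np.ndarray | None = field(default=None, repr=False)
    anc: float | None = None
    cp: float | None = None
    ge_tt_avg: float | None = None


def fit_po_mr_regression(
    po, mr, baseline: BaselineResult | None = None
) -> PoMrRegression:
    """Ordinary least squares of stage MR on stage PO (both watts).

    If ``baseline`` is given it contributes the point (PO=0, MR=MR_BL) —
    the 7+Y variant; otherwise the seven stages stand alone (7-Y).
    """
    p = np.asarray(po, dtype=float)
    m = np.asarray(mr, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValueError("po and mr must be 1-D arrays of equal length")
    if baseline is not None:
        p = np.concatenate(([0.0], p))
        m = np.concatenate(([baseline.mr_bl], m))
    if p.size < 2:
        raise ValueError("regression needs at least two points")
    if np.ptp(p) == 0:
        raise ValueError("singular design: all PO values identical")
    fit = stats.linregress(p, m)
    resid = m - (fit.slope * p + fit.intercept)
    dof = p.size - 2
    see = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    return PoMrRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        include_baseline=baseline is not None,
        r2=float(fit.rvalue**2),
        see=see,
        po=p,
        mr=m,
    )


def required_mr_regression(reg: PoMrRegression, po_t) -> np.ndarray:
    """Required instantaneous MR during the TT from the regression equation."""
    return np.asarray(reg.predict(po_t), dtype=float)


def required_mr_ge_last(ge_last: float, po_t) -> np.ndarray:
    """Required MR assuming the constant GE of the last submaximal stage.

    Equivalent to a regression line with slope 1/GE_LAST and zero intercept.
    """
    if ge_last <= 0:
        raise ValueError("GE_LAST must be positive")
    return np.asarray(po_t, dtype=float) / ge_last


def instantaneous_ge(po_t, mr_req_t) -> np.ndarray:
    """Per-second GE during the TT: instantaneous PO over required MR."""
    p = np.asarray(po_t, dtype=float)
    m = np.asarray(mr_req_t, dtype=float)
    if p.shape != m.shape:
        raise ValueError("length mismatch between po and required MR")
    if np.any((p > 0) & (m == 0)):
        raise ValueError("required MR is zero where PO is positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        ge = np.where(m != 0, p / m, 0.0)
    return ge


def anaerobic_mr(mr_req_t, mr_ae_t, clamp_negative: bool = False):
    """Eq.-style anaerobic MR series and its integral AnC (J).

    MR_AN = MR_req - MR_AE pointwise; signed by default (small negative
    excursions late in the TT are retained unless ``clamp_negative``).
    """
    req = np.asarray(mr_req_t, dtype=float)
    ae = np.asarray(mr_ae_t, dtype=float)
    if req.shape != ae.shape:
        raise ValueError("length mismatch between required and aerobic MR")
    mr_an = req - ae
    if clamp_negative:
        mr_an = np.maximum(mr_an, 0.0)
    anc = float(np.sum(mr_an))  # 1-s rectangles
    return mr_an, anc


def anaerobic_po(po_t, mr_ae_t, ge_inst_t, clamp_negative: bool = False):
    """Anaerobically attributable power series and its integral AnWC (J).

    PO_AN = PO - MR_AE * GE_inst pointwise; with a constant GE this makes
    AnWC = GE * AnC an exact identity.
    """
    p = np.asarray(po_t, dtype=float)
    ae = np.asarray(mr_ae_t, dtype=float)
    g = np.asarray(ge_inst_t, dtype=float)
    if not (p.shape == ae.shape == g.shape):
        raise ValueError("length mismatch in anaerobic power inputs")
    po_an = p - ae * g
    if clamp_negative:
        po_an = np.maximum(po_an, 0.0)
    anwc = float(np.sum(po_an))
    return po_an, anwc


def critical_power_3ao(po_t, tail_s: int = 30) -> float:
    """CP as the mean PO of the final 30 s of the 3-min all-out TT."""
    p = np.asarray(po_t, dtype=float)
    if p.size < 180:
        raise ValueError(f"TT series of {p.size} s is shorter than 180 s")
    return float(np.mean(p[-tail_s:]))


def w_prime(po_t, cp: float, clamp_below_cp: bool = False) -> float:
    """W': power above CP integrated over the full TT (J).

    Signed by default, so W' = (mean PO - CP) * duration exactly; with
    ``clamp_below_cp`` the integrand is max(PO - CP, 0).
    """
    p = np.asarray(po_t, dtype=float)
    excess = p - cp
    if clamp_below_cp:
        excess = np.maximum(excess, 0.0)
    return float(np.sum(excess))


def _ge_tt_avg(po_t, mr_req_t, ge_inst_t, ratio_of_integrals: bool) -> float:
    if ratio_of_integrals:
        return float(np.sum(po_t) / np.sum(mr_req_t))
    return float(np.mean(ge_inst_t))


def _decompose(model, t, po_tt, mr_ae, mr_req, ge_inst, config) -> TTDecomposition:
    clamp = getattr(config, "clamp_negative_mr_an", False)
    mr_an, anc = anaerobic_mr(mr_req, mr_ae, clamp_negative=clamp)
    po_an, anwc = anaerobic_po(po_tt, mr_ae, ge_inst, clamp_negative=clamp)
    ge_avg = _ge_tt_avg(
        po_tt, mr_req, ge_inst, getattr(config, "ge_tt_avg_ratio_of_integrals", False)
    )
    return TTDecomposition(
        model=model,
        t=t,
        po_tt=po_tt,
        mr_ae=mr_ae,
        mr_req=mr_req,
        ge_inst=ge_inst,
        mr_an=mr_an,
        po_an=po_an,
        anc=anc,
        anwc=anwc,
        ge_tt_avg=ge_avg,
    )


def estimate_all_models(
    t,
    po_tt,
    mr_ae,
    config,
    reg_with_baseline: PoMrRegression | None = None,
    reg_without_baseline: PoMrRegression | None = None,
    ge_last: float | None = None,
) -> tuple[dict[str, TTDecomposition], dict[str, str]]:
    """Run every requested model on the shared TT series.

    Models whose inputs are absent (e.g. no submaximal data for the
    regressions when only the TT was recorded) are skipped and reported in
    the returned error mapping rather than aborting the remaining models —
    the CP model needs nothing beyond the TT power profile.
    """
    t = np.asarray(t, dtype=float)
    po_tt = np.asarray(po_tt, dtype=float)
    mr_ae = np.asarray(mr_ae, dtype=float)
    out: dict[str, TTDecomposition] = {}
    errors: dict[str, str] = {}
    for model in getattr(config, "models", ALL_MODELS):
        try:
            if model == MODEL_7PY or model == MODEL_7MY:
                reg = reg_with_baseline if model == MODEL_7PY else reg_without_baseline
                if reg is None:
                    raise ValueError(f"{model}: no fitted PO-MR regression available")
                mr_req = required_mr_regression(reg, po_tt)
                ge = instantaneous_ge(po_tt, mr_req)
                out[model] = _decompose(model, t, po_tt, mr_ae, mr_req, ge, config)
            elif model == MODEL_GE_LAST:
                if ge_last is None:
                    raise ValueError(
                        "GE_LAST: no last-stage gross efficiency available"
                    )
                mr_req = required_mr_ge_last(ge_last, po_tt)
                ge = np.full_like(po_tt, ge_last)
                out[model] = _decompose(model, t, po_tt, mr_ae, mr_req, ge, config)
            elif model == MODEL_CP:
                cp = critical_power_3ao(po_tt)
                wp = w_prime(po_tt, cp, getattr(config, "clamp_below_cp", False))
                out[model] = TTDecomposition(
                    model=model,
                    t=t,
                    po_tt=po_tt,
                    mr_ae=mr_ae,
                    po_an=po_tt - cp,
                    anwc=wp,
                    cp=cp,
                )
            else:
                raise ValueError(f"unknown model {model!r}")
        except ValueError as exc:
            errors[model] = str(exc)
    return out, errors
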