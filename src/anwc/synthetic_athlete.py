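"""Synthetic cycle-ergometry sessions with exact ground truth.

The generator emulates the statistical structure the four AnWC/AnC models
assume: a linear submaximal PO-MR relationship (true slope ~4.15 W per W,
positive intercept ~1.9 W kg^-1), seven steady-state 4-min stages spanning
roughly 40-74% of the peak aerobic MR, a seated baseline lying on the true
line, and a 3-min all-out TT with an exponentially decaying power profile
(peak ~9.3 -> end ~4.5 W kg^-1) and mono-exponential aerobic kinetics
(tau ~25 s) saturating at VO2peak. Respiratory output is 10-s box averages
of the true per-second VO2 with multiplicative log-normal noise (RER is
noiseless); power is exported second-by-second.

Submaximal stages are generated at their exact steady state — the stage
VO2 solves the Weir equation against the true line for the stated RER — so
with zero noise the regression models recover the truth to machine
precision. The truth record defines AnWC/AnC through the regression-model
equations with the true GE(t) = PO/(slope*PO + intercept); truth is
model-relative by construction and the record says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import energetics
from .core_data_io import (
    AthleteSession,
    BreathSeries,
    PowerSeries,
    SessionProtocol,
)

__all__ = [
    "SyntheticAthleteParams",
    "CohortDistributions",
    "SyntheticTruth",
    "default_protocol",
    "simulate_submaximal_session",
    "simulate_tt_allout",
    "simulate_full_session",
    "simulate_cohort",
]

# Session timeline (seconds): 3-min baseline, 6-min warm-up, 7 x 4-min
# stages, 6-min passive rest, 3-min all-out TT.
BASELINE_WINDOW = (0.0, 180.0)
WARMUP_WINDOW = (180.0, 540.0)
STAGE_START = 540.0
STAGE_LEN = 240.0
N_STAGES = 7
REST_WINDOW = (2220.0, 2580.0)
TT_WINDOW = (2580.0, 2760.0)
TT_LEN = 180


@dataclass(frozen=True)
class SyntheticAthleteParams:
    """Ground-truth physiology of one synthetic cyclist.

    Per-kg parameters follow the group means of highly trained male
    cyclists; absolute quantities are derived via ``body_mass``.
    """

    body_mass: float = 78.5                 # kg
    true_slope: float = 4.15                # MR watts per PO watt
    true_intercept: float = 1.9             # W kg^-1
    vo2peak: float = 64.0                   # ml kg^-1 min^-1
    baseline_vo2: float | None = None       # L min^-1; default: on-line baseline
    baseline_rer: float = 0.85
    tau_vo2: float = 25.0                   # s, aerobic kinetics time constant
    stage_po: tuple[float, ...] = (1.62, 1.93, 2.24, 2.54, 2.85, 3.16, 3.47)  # W/kg
    stage_rer: tuple[float, ...] = (0.87, 0.86, 0.87, 0.88, 0.89, 0.90, 0.91)
    tt_peak_po: float = 9.3                 # W kg^-1
    tt_end_po: float = 4.5                  # W kg^-1
    tau_po: float = 35.0                    # s, all-out power decay
    tt_rer_end: float = 1.10                # RER approached during the TT
    noise_cv_vo2: float = 0.02              # CV of 10-s VO2 samples

    def __post_init__(self) -> None:
        if self.true_slope <= 0:
            raise ValueError("true slope must be positive")
        if self.tt_peak_po <= self.tt_end_po:
            raise ValueError("TT peak power must exceed end power")
        if self.noise_cv_vo2 < 0:
            raise ValueError("noise CV must be non-negative")
        if len(self.stage_po) != len(self.stage_rer):
            raise ValueError("stage PO and RER lists must match")

    # -- derived absolute quantities -------------------------------------
    @property
    def intercept_w(self) -> float:
        return self.true_intercept * self.body_mass

    @property
    def vo2peak_l_min(self) -> float:
        return self.vo2peak * self.body_mass / 1000.0

    @property
    def mr_ae_peak_w(self) -> float:
        return energetics.weir_mr(self.vo2peak_l_min, 1.00)

    @property
    def baseline_vo2_l_min(self) -> float:
        if self.baseline_vo2 is not None:
            return self.baseline_vo2
        if self.intercept_w <= 0:
            return 0.30  # typical seated rest; an on-line baseline is impossible
        # baseline point placed exactly on the true line: MR_BL = intercept
        return energetics.vo2_for_mr(self.intercept_w, self.baseline_rer)

    @property
    def mr_bl_w(self) -> float:
        return energetics.weir_mr(self.baseline_vo2_l_min, self.baseline_rer)

    def stage_mr_w(self, i: int) -> float:
        return self.true_slope * self.stage_po[i] * self.body_mass + self.intercept_w

    def stage_vo2_l_min(self, i: int) -> float:
        vo2 = energetics.vo2_for_mr(self.stage_mr_w(i), self.stage_rer[i])
        if vo2 <= 0:
            raise ValueError(f"infeasible parameters: stage {i + 1} implies VO2 <= 0")
        return vo2


@dataclass(frozen=True)
class SyntheticTruth:
    """Exact per-second truth for the TT and the scalar targets.

    All arrays/energies are absolute (W, J); ``ge_true`` is the
    regression-model GE with the true slope/intercept, so the truth is
    defined relative to the regression model's equations.
    """

    po: np.ndarray = field(repr=False)        # W, 1-s grid over the TT
    mr_req: np.ndarray = field(repr=False)    # slope*po + intercept
    mr_ae: np.ndarray = field(repr=False)     # kinetic aerobic MR
    ge_true: np.ndarray = field(repr=False)   # po / mr_req
    anwc_true: float                          # J
    anc_true: float                           # J
    cp_implied: float                         # W, mean of last 30 s
    params: SyntheticAthleteParams = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------


def _tt_truth(params: SyntheticAthleteParams) -> SyntheticTruth:
    t = np.arange(TT_LEN, dtype=float)
    mass = params.body_mass
    po = (
        params.tt_end_po
        + (params.tt_peak_po - params.tt_end_po) * np.exp(-t / params.tau_po)
    ) * mass
    mr_req = params.true_slope * po + params.intercept_w
    target = np.minimum(mr_req, params.mr_ae_peak_w)
    # exact first-order step response for a piecewise-constant target
    decay = np.exp(-1.0 / params.tau_vo2)
    mr_ae = np.empty(TT_LEN)
    prev = params.mr_bl_w
    for i in range(TT_LEN):
        prev = target[i] + (prev - target[i]) * decay
        mr_ae[i] = prev
    ge_true = po / mr_req
    anc = float(np.sum(mr_req - mr_ae))
    anwc = float(np.sum(po - mr_ae * ge_true))
    return SyntheticTruth(
        po=po,
        mr_req=mr_req,
        mr_ae=mr_ae,
        ge_true=ge_true,
        anwc_true=anwc,
        anc_true=anc,
        cp_implied=float(np.mean(po[-30:])),
        params=params,
    )


def _sample_breath(
    vo2_1s: np.ndarray,
    rer_1s: np.ndarray,
    t0: float,
    rng: np.random.Generator,
    cv: float,
    spacing: int = 10,
) -> BreathSeries:
    """Box-average per-second truth to the native grid and add noise.

    VO2 samples carry multiplicative log-normal noise with unit mean; VCO2
    is the (noisy) VO2 times the block-mean true RER, so the sampled RER is
    noiseless.
    """
    n = vo2_1s.size // spacing
    vo2_b = vo2_1s[: n * spacing].reshape(n, spacing).mean(axis=1)
    vco2_b = (vo2_1s * rer_1s)[: n * spacing].reshape(n, spacing).mean(axis=1)
    rer_b = vco2_b / vo2_b
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        factors = np.ones(n)
    vo2_s = vo2_b * factors
    return BreathSeries(
        t=t0 + spacing / 2.0 + spacing * np.arange(n, dtype=float),
        vo2=vo2_s,
        vco2=vo2_s * rer_b,
        ve=25.0 * vo2_s,  # plausible ventilatory equivalent; descriptive only
        hr=None,
        spacing_s=spacing,
    )


def default_protocol(
    params: SyntheticAthleteParams,
    include_submaximal: bool = True,
    include_tt: bool = True,
) -> SessionProtocol:
    """Protocol matching the generator timeline (windows in session seconds)."""
    mass = params.body_mass
    stages = tuple(
        (STAGE_START + i * STAGE_LEN, STAGE_START + (i + 1) * STAGE_LEN)
        for i in range(len(params.stage_po))
    )
    return SessionProtocol(
        body_mass=mass,
        baseline_window=BASELINE_WINDOW if include_submaximal else None,
        stage_windows=stages if include_submaximal else (),
        stage_target_po=tuple(p * mass for p in params.stage_po)
        if include_submaximal
        else (),
        tt_window=TT_WINDOW if include_tt else None,
    )


def _submax_truth(params: SyntheticAthleteParams):
    """Per-second true VO2/RER/PO over [0, REST end): steady-state segments."""
    mass = params.body_mass
    end = int(REST_WINDOW[1])
    vo2 = np.empty(end)
    rer = np.empty(end)
    po = np.zeros(end)

    bl_vo2 = params.baseline_vo2_l_min
    vo2[: int(BASELINE_WINDOW[1])] = bl_vo2
    rer[: int(BASELINE_WINDOW[1])] = params.baseline_rer

    # warm-up at the first stage intensity (~40% of VO2peak)
    w0, w1 = int(WARMUP_WINDOW[0]), int(WARMUP_WINDOW[1])
    vo2[w0:w1] = params.stage_vo2_l_min(0)
    rer[w0:w1] = params.stage_rer[0]
    po[w0:w1] = params.stage_po[0] * mass

    for i in range(len(params.stage_po)):
        s = int(STAGE_START + i * STAGE_LEN)
        e = s + int(STAGE_LEN)
        vo2[s:e] = params.stage_vo2_l_min(i)
        rer[s:e] = params.stage_rer[i]
        po[s:e] = params.stage_po[i] * mass

    r0, r1 = int(REST_WINDOW[0]), int(REST_WINDOW[1])
    vo2[r0:r1] = bl_vo2
    rer[r0:r1] = params.baseline_rer
    return vo2, rer, po


def simulate_submaximal_session(
    params: SyntheticAthleteParams = SyntheticAthleteParams(),
    seed: int = 0,
    athlete_id: str = "synthetic",
) -> AthleteSession:
    """Baseline + warm-up + seven steady-state stages (no TT)."""
    rng = np.random.default_rng(seed)
    vo2, rer, po = _submax_truth(params)
    breath = _sample_breath(vo2, rer, 0.0, rng, params.noise_cv_vo2)
    n = po.size
    cadence = np.where(po > 0, 68.0 + 16.0 * po / (po.max() + 1e-12), 0.0)
    power = PowerSeries(t=np.arange(n, dtype=float), po=po, cadence=cadence)
    return AthleteSession(
        id=athlete_id,
        protocol=default_protocol(params, include_tt=False),
        breath=breath,
        power=power,
    )


def simulate_tt_allout(
    params: SyntheticAthleteParams = SyntheticAthleteParams(),
    seed: int = 0,
    athlete_id: str = "synthetic-tt",
) -> tuple[AthleteSession, SyntheticTruth]:
    """A stand-alone 3-min all-out TT (windowed at [0, 180))."""
    rng = np.random.default_rng(seed)
    truth = _tt_truth(params)
    vo2_1s = energetics.vo2_for_mr(truth.mr_ae, 1.00)
    rer_1s = 1.0 + (params.tt_rer_end - 1.0) * (
        1.0 - np.exp(-np.arange(TT_LEN) / 60.0)
    )
    breath = _sample_breath(vo2_1s, rer_1s, 0.0, rng, params.noise_cv_vo2)
    cadence = 90.0 + 37.0 * np.exp(-np.arange(TT_LEN) / params.tau_po)
    power = PowerSeries(
        t=np.arange(TT_LEN, dtype=float), po=truth.po, cadence=cadence
    )
    proto = SessionProtocol(
        body_mass=params.body_mass, tt_window=(0.0, float(TT_LEN))
    )
    session = AthleteSession(
        id=athlete_id, protocol=proto, breath=breath, power=power
    )
    return session, truth


def simulate_full_session(
    params: SyntheticAthleteParams = SyntheticAthleteParams(),
    seed: int = 0,
    athlete_id: str = "synthetic",
) -> tuple[AthleteSession, SyntheticTruth]:
    """The complete protocol: baseline through all-out TT, one athlete."""
    rng = np.random.default_rng(seed)
    vo2_sub, rer_sub, po_sub = _submax_truth(params)
    truth = _tt_truth(params)
    vo2_tt = energetics.vo2_for_mr(truth.mr_ae, 1.00)
    rer_tt = 1.0 + (params.tt_rer_end - 1.0) * (
        1.0 - np.exp(-np.arange(TT_LEN) / 60.0)
    )
    vo2 = np.concatenate([vo2_sub, vo2_tt])
    rer = np.concatenate([rer_sub, rer_tt])
    po = np.concatenate([po_sub, truth.po])
    breath = _sample_breath(vo2, rer, 0.0, rng, params.noise_cv_vo2)
    n = po.size
    cadence = np.where(po > 0, 68.0 + 16.0 * po / (params.stage_po[-1] * params.body_mass), 0.0)
    tt0 = int(TT_WINDOW[0])
    cadence[tt0:] = 90.0 + 37.0 * np.exp(-np.arange(TT_LEN) / params.tau_po)
    power = PowerSeries(t=np.arange(n, dtype=float), po=po, cadence=cadence)
    session = AthleteSession(
        id=athlete_id,
        protocol=default_protocol(params),
        breath=breath,
        power=power,
    )
    return session, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortDistributions:
    """Between-athlete normal distributions (mean, SD), truncated to the
    stated bounds; SDs follow the cohort spread of highly trained cyclists."""

    body_mass: tuple[float, float] = (78.5, 7.7)
    true_slope: tuple[float, float] = (4.15, 0.28)
    true_intercept: tuple[float, float] = (1.9, 0.5)
    vo2peak: tuple[float, float] = (64.0, 6.0)
    tau_vo2: tuple[float, float] = (25.0, 3.0)
    tt_peak_po: tuple[float, float] = (9.3, 1.2)
    tt_end_po: tuple[float, float] = (4.5, 0.23)
    noise_cv_vo2: float = 0.02

    _BOUNDS = {
        "body_mass": (55.0, 105.0),
        "true_slope": (3.2, 5.2),
        "true_intercept": (0.3, 3.5),
        "vo2peak": (50.0, 80.0),
        "tau_vo2": (15.0, 40.0),
        "tt_peak_po": (6.5, 13.0),
        "tt_end_po": (3.5, 5.5),
    }

    def draw(self, rng: np.random.Generator) -> SyntheticAthleteParams:
        vals = {}
        for name in self._BOUNDS:
            mean, sd = getattr(self, name)
            lo, hi = self._BOUNDS[name]
            vals[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
        # keep the all-out profile genuinely decaying
        vals["tt_peak_po"] = max(vals["tt_peak_po"], vals["tt_end_po"] + 1.0)
        return SyntheticAthleteParams(noise_cv_vo2=self.noise_cv_vo2, **vals)


def simulate_cohort(
    n: int = 15,
    seed: int = 0,
    distributions: CohortDistributions = CohortDistributions(),
) -> list[tuple[AthleteSession, SyntheticTruth]]:
    """Independent synthetic athletes with parameters drawn per athlete."""
    if n < 3:
        raise ValueError("a cohort needs at least 3 athletes")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        params = distributions.draw(rng)
        athlete_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_full_session(params, seed=athlete_seed, athlete_id=f"ath{i + 1:02d}")
        )
    return out
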