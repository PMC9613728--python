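"""Domain containers, delimited-text I/O, protocol configuration, and the
per-athlete pipeline.

Conventions
-----------
* Time is seconds from session start, 0-based; all windows half-open
  ``[start, end)``.
* Power/metabolic quantities are stored internally in absolute watts;
  per-kilogram values are computed only at the reporting layer.
* CSV dialects (column names, gas units) are declared in configuration,
  never sniffed — mixing-chamber exports vary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anwc_models, energetics, gas_exchange
from .anwc_models import ALL_MODELS, MODEL_CP, TTDecomposition, fit_po_mr_regression
from .energetics import BaselineResult

logger = logging.getLogger("anwc")

__all__ = [
    "BreathSeries",
    "PowerSeries",
    "SessionProtocol",
    "AthleteSession",
    "ModelConfig",
    "PowerDialect",
    "BreathDialect",
    "PipelineResult",
    "read_power_series",
    "read_breath_series",
    "write_power_series",
    "write_breath_series",
    "read_protocol",
    "write_protocol",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Analysis parameters, with defaults matching the standard protocol."""

    models: tuple[str, ...] = ALL_MODELS
    rer_cap: float = 1.00          # cap on RER used for submaximal MR
    tt_rer: float = 1.00           # fixed RER during the all-out TT
    clamp_negative_mr_an: bool = False
    clamp_below_cp: bool = False
    smooth_half_width: int = 4     # +/- seconds, 9-s counterbalanced window
    smooth_passes: int = 2
    smooth_submaximal: bool = False  # stage averages use raw 10-s samples
    ge_tt_avg_ratio_of_integrals: bool = False
    rer_peak_ratio_of_means: bool = False
    breath_spacing_s: int = 10
    max_power_gap_s: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


@dataclass(frozen=True)
class PowerDialect:
    sep: str = ","
    time_col: str = "t"
    po_col: str = "po"
    cadence_col: str | None = "cadence"


@dataclass(frozen=True)
class BreathDialect:
    sep: str = ","
    time_col: str = "t"
    vo2_col: str = "vo2"
    vco2_col: str = "vco2"
    ve_col: str = "ve"
    hr_col: str | None = "hr"
    gas_units: str = "L/min"  # or "ml/min"


# ---------------------------------------------------------------------------
# series containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BreathSeries:
    """Native-resolution respiratory samples (default 10-s mixing chamber).

    ``t`` holds the centre of each averaging interval, in seconds from
    session start; gas rates are L min^-1. A sample centred at ``c`` covers
    the half-open span ``[c - spacing/2, c + spacing/2)``.
    """

    t: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    hr: np.ndarray | None = None
    spacing_s: int = 10

    def __post_init__(self) -> None:
        for name in ("t", "vo2", "vco2", "ve"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.hr is not None:
            object.__setattr__(self, "hr", np.asarray(self.hr, dtype=float))
        n = self.t.size
        if any(getattr(self, c).size != n for c in ("vo2", "vco2", "ve")):
            raise ValueError("breath channels must share one time axis")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("non-monotone time in breath series")
            if not np.allclose(dt, self.spacing_s):
                raise ValueError(
                    f"breath spacing differs from native {self.spacing_s} s"
                )
        for c in ("vo2", "vco2", "ve"):
            if np.any(getattr(self, c) < 0):
                raise ValueError(f"negative {c} value in breath series")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def rer(self) -> np.ndarray:
        return self.vco2 / self.vo2

    @property
    def span(self) -> tuple[float, float]:
        h = self.spacing_s / 2.0
        return float(self.t[0] - h), float(self.t[-1] + h)

    def slice(self, window) -> "BreathSeries":
        """Samples whose centres fall inside ``[start, end)``."""
        start, end = window
        m = (self.t >= start) & (self.t < end)
        if not m.any():
            raise ValueError(f"no breath samples in window [{start}, {end})")
        return BreathSeries(
            t=self.t[m],
            vo2=self.vo2[m],
            vco2=self.vco2[m],
            ve=self.ve[m],
            hr=self.hr[m] if self.hr is not None else None,
            spacing_s=self.spacing_s,
        )

    def covers(self, window) -> bool:
        start, end = window
        lo, hi = self.span
        return lo <= start and hi >= end

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "vo2": self.vo2, "vco2": self.vco2, "ve": self.ve}
        if self.hr is not None:
            d["hr"] = self.hr
        return pd.DataFrame(d)


@dataclass(frozen=True)
class PowerSeries:
    """1-s ergometer samples: ``t`` integer seconds, ``po`` watts >= 0."""

    t: np.ndarray
    po: np.ndarray
    cadence: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "po", np.asarray(self.po, dtype=float))
        if self.cadence is not None:
            object.__setattr__(self, "cadence", np.asarray(self.cadence, dtype=float))
        if self.po.size != self.t.size:
            raise ValueError("po and t must have equal length")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("non-monotone time in power series")
            if not np.allclose(dt, 1.0):
                raise ValueError("power series must be on a 1-s grid")
        if np.any(self.po < 0):
            raise ValueError("negative power value")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t[0]), float(self.t[-1] + 1.0)

    def slice(self, window) -> "PowerSeries":
        start, end = window
        m = (self.t >= start) & (self.t < end)
        if not m.any():
            raise ValueError(f"no power samples in window [{start}, {end})")
        return PowerSeries(
            t=self.t[m],
            po=self.po[m],
            cadence=self.cadence[m] if self.cadence is not None else None,
        )

    def covers(self, window) -> bool:
        start, end = window
        lo, hi = self.span
        return lo <= start and hi >= end

    def to_frame(self) -> pd.DataFrame:
        d = {"t": self.t, "po": self.po}
        if self.cadence is not None:
            d["cadence"] = self.cadence
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# protocol / session
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionProtocol:
    """Timing of the session segments and per-stage power targets.

    Windows are half-open ``[start, end)`` seconds from session start. The
    standard protocol has a 3-min seated baseline, seven 4-min submaximal
    stages and a 180-s all-out TT; fragments (e.g. a TT recorded alone) may
    omit segments.
    """

    body_mass: float
    baseline_window: tuple[float, float] | None = None
    stage_windows: tuple[tuple[float, float], ...] = ()
    stage_target_po: tuple[float, ...] = ()  # absolute watts
    tt_window: tuple[float, float] | None = None
    final_minute_s: float = 60.0

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")
        object.__setattr__(
            self, "stage_windows", tuple(tuple(w) for w in self.stage_windows)
        )
        object.__setattr__(self, "stage_target_po", tuple(self.stage_target_po))
        if self.stage_target_po and len(self.stage_target_po) != len(self.stage_windows):
            raise ValueError("one target PO per stage window required")
        wins = []
        if self.baseline_window is not None:
            object.__setattr__(self, "baseline_window", tuple(self.baseline_window))
            wins.append(self.baseline_window)
        wins.extend(self.stage_windows)
        if self.tt_window is not None:
            object.__setattr__(self, "tt_window", tuple(self.tt_window))
            wins.append(self.tt_window)
        for s, e in wins:
            if e <= s:
                raise ValueError(f"empty window [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(wins, wins[1:]):
            if s2 < e1:
                raise ValueError("protocol windows must be ordered, non-overlapping")

    @property
    def n_stages(self) -> int:
        return len(self.stage_windows)

    @property
    def tt_duration_s(self) -> float:
        if self.tt_window is None:
            raise ValueError("protocol has no TT window")
        return self.tt_window[1] - self.tt_window[0]

    def to_dict(self) -> dict:
        return {
            "body_mass": self.body_mass,
            "baseline_window": list(self.baseline_window)
            if self.baseline_window
            else None,
            "stage_windows": [list(w) for w in self.stage_windows],
            "stage_target_po": list(self.stage_target_po),
            "tt_window": list(self.tt_window) if self.tt_window else None,
            "final_minute_s": self.final_minute_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionProtocol":
        return cls(
            body_mass=float(d["body_mass"]),
            baseline_window=tuple(d["baseline_window"])
            if d.get("baseline_window")
            else None,
            stage_windows=tuple(tuple(w) for w in d.get("stage_windows", [])),
            stage_target_po=tuple(d.get("stage_target_po", [])),
            tt_window=tuple(d["tt_window"]) if d.get("tt_window") else None,
            final_minute_s=float(d.get("final_minute_s", 60.0)),
        )


@dataclass(frozen=True)
class AthleteSession:
    """One athlete's recorded session: protocol + power + breath + metadata.

    ``metadata`` carries descriptive extras (blood lactate, RPE) that take
    no part in any calculation.
    """

    id: str
    protocol: SessionProtocol
    breath: BreathSeries
    power: PowerSeries
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.protocol
        wins = list(p.stage_windows)
        if p.baseline_window is not None:
            wins.append(p.baseline_window)
        if p.tt_window is not None:
            wins.append(p.tt_window)
        for w in wins:
            if not self.breath.covers(w):
                raise ValueError(f"breath series does not cover window {w}")
        pw = list(p.stage_windows)
        if p.tt_window is not None:
            pw.append(p.tt_window)
        for w in pw:
            if not self.power.covers(w):
                raise ValueError(f"power series does not cover window {w}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_power_series(
    path, dialect: PowerDialect = PowerDialect(), max_gap_s: int = 2
) -> PowerSeries:
    """Read a 1-s power/cadence CSV.

    Gaps of up to ``max_gap_s`` missing seconds are filled by linear
    interpolation (and logged); longer gaps are errors.
    """
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    for col in (dialect.time_col, dialect.po_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    t = df[dialect.time_col].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time")
    gaps = np.diff(t) - 1.0
    if np.any(gaps > max_gap_s):
        worst = float(gaps.max())
        raise ValueError(f"gap of {worst:.0f} s exceeds maximum {max_gap_s} s")
    full_t = np.arange(t[0], t[-1] + 1.0)

    def _fill(col: np.ndarray) -> np.ndarray:
        if full_t.size == t.size:
            return col  # contiguous: keep read values bit-exact
        out = np.interp(full_t, t, col)
        present = np.isin(full_t, t)
        out[present] = col  # anchors stay bit-exact; only gaps interpolated
        return out

    if full_t.size != t.size:
        logger.info(
            "power file %s: interpolating %d missing second(s)",
            path,
            full_t.size - t.size,
        )
    po = _fill(df[dialect.po_col].to_numpy(dtype=float))
    cad = None
    if dialect.cadence_col and dialect.cadence_col in df.columns:
        cad = _fill(df[dialect.cadence_col].to_numpy(dtype=float))
    return PowerSeries(t=full_t, po=po, cadence=cad)


def read_breath_series(
    path, dialect: BreathDialect = BreathDialect(), spacing_s: int = 10
) -> BreathSeries:
    """Read a native-resolution respiratory CSV (10-s rows by default).

    Gas columns are coerced from ml min^-1 when the dialect says so;
    validation (spacing, non-negativity) happens in ``BreathSeries``.
    """
    df = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    needed = (dialect.time_col, dialect.vo2_col, dialect.vco2_col, dialect.ve_col)
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    scale = 1e-3 if dialect.gas_units == "ml/min" else 1.0
    hr = None
    if dialect.hr_col and dialect.hr_col in df.columns:
        hr = df[dialect.hr_col].to_numpy(dtype=float)
    return BreathSeries(
        t=df[dialect.time_col].to_numpy(dtype=float),
        vo2=df[dialect.vo2_col].to_numpy(dtype=float) * scale,
        vco2=df[dialect.vco2_col].to_numpy(dtype=float) * scale,
        ve=df[dialect.ve_col].to_numpy(dtype=float) * scale
        if dialect.gas_units == "ml/min"
        else df[dialect.ve_col].to_numpy(dtype=float),
        hr=hr,
        spacing_s=spacing_s,
    )


def write_power_series(series: PowerSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_breath_series(series: BreathSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def write_protocol(protocol: SessionProtocol, path) -> None:
    Path(path).write_text(yaml.safe_dump(protocol.to_dict(), sort_keys=False))


def read_protocol(path) -> SessionProtocol:
    with open(path) as fh:
        return SessionProtocol.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineResult:
    """Everything computed for one athlete.

    ``summary`` is a tidy long table (athlete, model, quantity, value,
    units); models that could not run are listed in ``errors``.
    """

    athlete_id: str
    body_mass: float
    baseline: BaselineResult | None
    stage_table: pd.DataFrame | None
    regressions: dict[str, anwc_models.PoMrRegression]
    peaks: gas_exchange.PeakSet
    decompositions: dict[str, TTDecomposition]
    summary: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-ready nested summary (athlete -> model -> quantity)."""
        out: dict = {
            "athlete": self.athlete_id,
            "body_mass_kg": self.body_mass,
            "models": {},
            "errors": self.errors,
        }
        for _, row in self.summary.iterrows():
            model = row["model"]
            if model == "session":
                out.setdefault("session", {})[row["quantity"]] = {
                    "value": row["value"],
                    "units": row["units"],
                }
            else:
                out["models"].setdefault(model, {})[row["quantity"]] = {
                    "value": row["value"],
                    "units": row["units"],
                }
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(outdir / "results.csv", index=False)
        if self.stage_table is not None:
            self.stage_table.to_csv(outdir / "stages.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True)
        )


def _stage_table(session: AthleteSession, config: ModelConfig) -> pd.DataFrame:
    """Final-minute averages per submaximal stage, from raw 10-s samples."""
    rows = []
    proto = session.protocol
    for i, (s, e) in enumerate(proto.stage_windows):
        fm = (e - proto.final_minute_s, e)
        br = session.breath
        if config.smooth_submaximal:
            seg = br.slice((s, e))
            vo2_1s = gas_exchange.counterbalanced_smooth(
                gas_exchange.expand_to_1s(seg.vo2, br.spacing_s),
                config.smooth_half_width,
                config.smooth_passes,
            )
            vco2_1s = gas_exchange.counterbalanced_smooth(
                gas_exchange.expand_to_1s(seg.vco2, br.spacing_s),
                config.smooth_half_width,
                config.smooth_passes,
            )
            t1 = np.arange(seg.t[0] - br.spacing_s / 2.0, seg.t[-1] + br.spacing_s / 2.0)
            vo2 = gas_exchange.window_mean(t1, vo2_1s, fm)
            rer = gas_exchange.window_mean(t1, vco2_1s / vo2_1s, fm)
        else:
            vo2 = gas_exchange.window_mean(br.t, br.vo2, fm)
            rer = gas_exchange.window_mean(br.t, br.rer, fm)
        mr = energetics.weir_mr(vo2, rer, rer_cap=config.rer_cap)
        po = gas_exchange.window_mean(session.power.t, session.power.po, fm)
        cad = (
            gas_exchange.window_mean(session.power.t, session.power.cadence, fm)
            if session.power.cadence is not None
            else np.nan
        )
        rows.append(
            {
                "stage": i + 1,
                "po_w": po,
                "target_po_w": proto.stage_target_po[i]
                if proto.stage_target_po
                else np.nan,
                "cadence_rpm": cad,
                "vo2_l_min": vo2,
                "rer": rer,
                "mr_w": mr,
                "ge": energetics.gross_efficiency(po, mr),
            }
        )
    return pd.DataFrame(rows)


def _tt_series(session: AthleteSession, config: ModelConfig):
    """Per-second TT arrays: power, smoothed gases, aerobic MR."""
    proto = session.protocol
    tt = proto.tt_window
    pw = session.power.slice(tt)
    br = session.breath.slice(tt)
    vo2_1s = gas_exchange.expand_to_1s(br.vo2, br.spacing_s)
    vco2_1s = gas_exchange.expand_to_1s(br.vco2, br.spacing_s)
    vo2_s = gas_exchange.counterbalanced_smooth(
        vo2_1s, config.smooth_half_width, config.smooth_passes
    )
    vco2_s = gas_exchange.counterbalanced_smooth(
        vco2_1s, config.smooth_half_width, config.smooth_passes
    )
    n = min(len(pw), vo2_s.size)
    t = pw.t[:n]
    mr_ae = energetics.aerobic_mr_series(vo2_s[:n], config.tt_rer)
    return t, pw, vo2_s[:n], vco2_s[:n], mr_ae


def _peaks(
    session: AthleteSession, config: ModelConfig, vo2_s, vco2_s, pw: PowerSeries
) -> gas_exchange.PeakSet:
    vo2peak, w0 = gas_exchange.moving_peak(vo2_s, 20)
    if config.rer_peak_ratio_of_means:
        rer_peak = float(np.mean(vco2_s[w0 : w0 + 20]) / np.mean(vo2_s[w0 : w0 + 20]))
    else:
        rer_peak = float(np.mean(vco2_s[w0 : w0 + 20] / vo2_s[w0 : w0 + 20]))
    po_peak, _ = gas_exchange.moving_peak(pw.po, 5)
    cad_peak = (
        gas_exchange.moving_peak(pw.cadence, 5)[0] if pw.cadence is not None else None
    )
    hr_peak = None
    if session.breath.hr is not None:
        tt_br = session.breath.slice(session.protocol.tt_window)
        if tt_br.hr is not None:
            hr_peak = float(np.max(tt_br.hr))  # native 10-s values
    return gas_exchange.PeakSet(
        vo2peak=vo2peak,
        vo2peak_window_start=w0,
        rer_peak=rer_peak,
        po_peak=po_peak,
        cadence_peak=cad_peak,
        hr_peak=hr_peak,
    )


def run_pipeline(
    session: AthleteSession, config: ModelConfig = ModelConfig()
) -> PipelineResult:
    """Run the full per-athlete analysis; deterministic for fixed inputs.

    Submaximal products (baseline MR, stage table, regressions) are computed
    when the protocol defines them; the CP model needs only the TT, so a
    TT-only session still yields W' while the other models are reported in
    ``errors``.
    """
    proto = session.protocol
    mass = proto.body_mass
    errors: dict[str, str] = {}

    baseline = None
    if proto.baseline_window is not None:
        br = session.breath
        vo2_bl = gas_exchange.window_mean(br.t, br.vo2, proto.baseline_window)
        rer_bl = gas_exchange.window_mean(br.t, br.rer, proto.baseline_window)
        baseline = BaselineResult(
            mr_bl=energetics.weir_mr(vo2_bl, rer_bl), vo2_bl=vo2_bl, rer_bl=rer_bl
        )

    stage_table = None
    regs: dict[str, anwc_models.PoMrRegression] = {}
    ge_last = None
    if proto.n_stages >= 2:
        stage_table = _stage_table(session, config)
        if baseline is not None:
            stage_table["ne"] = energetics.net_efficiency(
                stage_table["po_w"], stage_table["mr_w"], baseline.mr_bl
            )
        po = stage_table["po_w"].to_numpy()
        mr = stage_table["mr_w"].to_numpy()
        if baseline is not None:
            regs[anwc_models.MODEL_7PY] = fit_po_mr_regression(po, mr, baseline)
        regs[anwc_models.MODEL_7MY] = fit_po_mr_regression(po, mr)
        ge_last = float(stage_table["ge"].iloc[-1])

    if proto.tt_window is None:
        raise ValueError("session has no TT window; nothing to decompose")
    t, pw, vo2_s, vco2_s, mr_ae = _tt_series(session, config)
    peaks = _peaks(session, config, vo2_s, vco2_s, pw)

    decomps, model_errors = anwc_models.estimate_all_models(
        t,
        pw.po[: t.size],
        mr_ae,
        config,
        reg_with_baseline=regs.get(anwc_models.MODEL_7PY),
        reg_without_baseline=regs.get(anwc_models.MODEL_7MY),
        ge_last=ge_last,
    )
    errors.update(model_errors)

    summary = _summary_table(
        session, config, baseline, stage_table, regs, peaks, decomps, vo2_s
    )
    return PipelineResult(
        athlete_id=session.id,
        body_mass=mass,
        baseline=baseline,
        stage_table=stage_table,
        regressions=regs,
        peaks=peaks,
        decompositions=decomps,
        summary=summary,
        errors=errors,
    )


def _summary_table(
    session, config, baseline, stage_table, regs, peaks, decomps, vo2_s
) -> pd.DataFrame:
    mass = session.protocol.body_mass
    rows: list[tuple[str, str, float, str]] = []

    def add(model, quantity, value, units):
        rows.append((model, quantity, float(value), units))

    tt_mean_vo2 = float(np.mean(vo2_s))
    mr_ae_peak = energetics.weir_mr(peaks.vo2peak, 1.00)
    add("session", "tt_mean_po", np.mean(decomps[next(iter(decomps))].po_tt) / mass,
        "W/kg") if decomps else None
    add("session", "tt_peak_po", peaks.po_peak / mass, "W/kg")
    add("session", "vo2peak", 1000.0 * peaks.vo2peak / mass, "ml/kg/min")
    add("session", "rer_peak", peaks.rer_peak, "ratio")
    add("session", "tt_mean_vo2", 1000.0 * tt_mean_vo2 / mass, "ml/kg/min")
    add(
        "session",
        "fractional_utilization",
        gas_exchange.fractional_utilization(tt_mean_vo2, peaks.vo2peak),
        "%",
    )
    add("session", "mr_ae_peak", mr_ae_peak / mass, "W/kg")
    if peaks.cadence_peak is not None:
        add("session", "tt_peak_cadence", peaks.cadence_peak, "rpm")
    if peaks.hr_peak is not None:
        add("session", "hr_peak", peaks.hr_peak, "beats/min")
    if baseline is not None:
        add("session", "mr_baseline", baseline.mr_bl / mass, "W/kg")
    if stage_table is not None:
        add("session", "ge_last_stage", 100.0 * stage_table["ge"].iloc[-1], "%")

    for name, reg in regs.items():
        add(name, "slope", reg.slope, "W/W")
        add(name, "intercept", reg.intercept / mass, "W/kg")
        add(name, "delta_efficiency", 100.0 * reg.delta_efficiency, "%")
        add(name, "r2", reg.r2, "fraction")
        add(name, "see", reg.see / mass, "W/kg")

    for name, dec in decomps.items():
        add(name, "anwc", dec.anwc / mass, "J/kg")
        if dec.anc is not None:
            add(name, "anc", dec.anc / mass / 1000.0, "kJ/kg")
        if dec.ge_tt_avg is not None:
            add(name, "ge_tt_avg", 100.0 * dec.ge_tt_avg, "%")
        if dec.mr_req is not None:
            add(name, "mr_tt_req", float(np.mean(dec.mr_req)) / mass, "W/kg")
            add(
                name,
                "mr_tt_req_pct_mr_ae_peak",
                100.0 * float(np.mean(dec.mr_req)) / mr_ae_peak,
                "%",
            )
            # MR required at CP under this model, as % of peak aerobic MR
            cp_dec = decomps.get(MODEL_CP)
            if cp_dec is not None and cp_dec.cp is not None:
                if dec.model == anwc_models.MODEL_GE_LAST:
                    mr_at_cp = cp_dec.cp / (dec.ge_inst[0])
                else:
                    mr_at_cp = regs[dec.model].predict(cp_dec.cp)
                add(name, "cp_pct_mr_ae_peak", 100.0 * mr_at_cp / mr_ae_peak, "%")
        if dec.cp is not None:
            add(name, "cp", dec.cp / mass, "W/kg")

    return pd.DataFrame(rows, columns=["model", "quantity", "value", "units"]).assign(
        athlete=session.id
    )[["athlete", "model", "quantity", "value", "units"]]
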