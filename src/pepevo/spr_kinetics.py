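"""Single-cycle SPR 1:1 binding kinetics: simulation and global fitting.

A 1:1 Langmuir interaction A + B <-> AB on a sensor surface follows

    dR/dt = ka * C * (Rmax - R) - kd * R

with response R in resonance units (RU), analyte concentration C in M,
association rate ka (M^-1 s^-1), dissociation rate kd (s^-1), and Kd =
kd / ka.  Within a segment of constant C the solution is mono-exponential:
R relaxes towards Req = ka*C*Rmax / (ka*C + kd) with observed rate
kobs = ka*C + kd.  Single-cycle kinetics injects an increasing
concentration series without regeneration, so R is carried continuously
across segment boundaries; the final segment is buffer-only dissociation
(C = 0, pure exponential decay).

The default injection schedule mirrors a five-point series of 2 nM,
20 nM, 200 nM, 2 uM and 20 uM with 120 s association per injection and
1800 s dissociation.

Fitting is global nonlinear least squares over (ka, kd, Rmax) in log
space against the piecewise closed form, multi-started from log-spaced
initial guesses.  Mass transport, drift and bulk refractive-index jumps
are not modelled: the fit expects reference/blank-subtracted data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

DEFAULT_CONCENTRATIONS = (2e-9, 2e-8, 2e-7, 2e-6, 2e-5)  # M
DEFAULT_ASSOCIATION_S = 120.0
DEFAULT_DISSOCIATION_S = 1800.0

KA_BOUNDS = (1e2, 1e9)  # M^-1 s^-1
KD_BOUNDS = (1e-6, 1.0)  # s^-1
RMAX_BOUNDS = (1e-6, 1e4)  # RU


@dataclass(frozen=True)
class KineticParams:
    """1:1 model parameters; Kd is derived as kd/ka."""

    ka: float  # M^-1 s^-1
    kd: float  # s^-1
    rmax: float  # RU

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.kd < 0:
            raise ValueError("kd must be non-negative")
        if self.rmax <= 0:
            raise ValueError("Rmax must be positive")

    @property
    def Kd(self) -> float:
        return kd_from_rates(self.ka, self.kd)


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant Kd = kd / ka, in M."""
    if ka <= 0:
        raise ValueError("ka must be positive")
    return kd / ka


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered (concentration, duration) segments plus final dissociation."""

    segments: tuple  # of (concentration M, duration s)
    dissociation_s: float = DEFAULT_DISSOCIATION_S
    sampling_interval_s: float = 1.0

    def __post_init__(self) -> None:
        segs = tuple((float(c), float(d)) for c, d in self.segments)
        object.__setattr__(self, "segments", segs)
        if any(c < 0 for c, _ in segs):
            raise ValueError("concentrations must be >= 0")
        if any(d <= 0 for _, d in segs) or self.dissociation_s <= 0:
            raise ValueError("durations must be > 0")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be > 0")

    @classmethod
    def single_cycle_default(cls, sampling_interval_s: float = 1.0) -> "InjectionSchedule":
        return cls(
            tuple((c, DEFAULT_ASSOCIATION_S) for c in DEFAULT_CONCENTRATIONS),
            DEFAULT_DISSOCIATION_S,
            sampling_interval_s,
        )

    def all_segments(self) -> list:
        """Association segments followed by the buffer dissociation segment."""
        return list(self.segments) + [(0.0, self.dissociation_s)]

    def to_dict(self) -> dict:
        return {
            "segments": [[c, d] for c, d in self.segments],
            "dissociation_s": self.dissociation_s,
            "sampling_interval_s": self.sampling_interval_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InjectionSchedule":
        return cls(
            tuple((c, t) for c, t in d["segments"]),
            d.get("dissociation_s", DEFAULT_DISSOCIATION_S),
            d.get("sampling_interval_s", 1.0),
        )


@dataclass
class Sensorgram:
    """SPR time series with its injection schedule."""

    time_s: np.ndarray
    response_ru: np.ndarray
    schedule: InjectionSchedule

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.response_ru = np.asarray(self.response_ru, dtype=float)
        if len(self.time_s) != len(self.response_ru):
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response_ru)):
            raise ValueError("response must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time_s, "response_RU": self.response_ru}).to_csv(
            path, index=False
        )
        Path(str(path)).with_suffix(".schedule.json").write_text(
            json.dumps(self.schedule.to_dict(), indent=1)
        )

    @classmethod
    def from_csv(cls, path, schedule: Optional[InjectionSchedule] = None) -> "Sensorgram":
        df = pd.read_csv(path)
        if schedule is None:
            sidecar = Path(str(path)).with_suffix(".schedule.json")
            if not sidecar.exists():
                raise FileNotFoundError(f"no schedule given and no sidecar {sidecar}")
            schedule = InjectionSchedule.from_dict(json.loads(sidecar.read_text()))
        return cls(df["time_s"].to_numpy(), df["response_RU"].to_numpy(), schedule)


def model_response(
    time_s: np.ndarray, schedule: InjectionSchedule, params: KineticParams, r0: float = 0.0
) -> np.ndarray:
    """Piecewise closed-form response at arbitrary times, carrying R across segments."""
    t = np.asarray(time_s, dtype=float)
    out = np.empty_like(t)
    seg_start = 0.0
    r_start = r0
    for conc, dur in schedule.all_segments():
        kobs = params.ka * conc + params.kd
        req = params.ka * conc * params.rmax / kobs if kobs > 0 else r_start
        mask = (t >= seg_start) & (t < seg_start + dur)
        if kobs > 0:
            out[mask] = req + (r_start - req) * np.exp(-kobs * (t[mask] - seg_start))
            r_start = req + (r_start - req) * math.exp(-kobs * dur)
        else:  # C = 0 and kd = 0: nothing moves
            out[mask] = r_start
        seg_start += dur
    # times at/after the end of the cycle hold the final value
    out[t >= seg_start] = r_start
    return out


def simulate_single_cycle(
    params: KineticParams,
    schedule: InjectionSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sensorgram:
    """Simulate a single-cycle sensorgram, optionally with additive Gaussian noise."""
    if schedule is None:
        schedule = InjectionSchedule.single_cycle_default()
    total = sum(d for _, d in schedule.all_segments())
    dt = schedule.sampling_interval_s
    time = np.arange(0.0, total + dt / 2, dt)
    resp = model_response(time, schedule, params)
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, size=resp.shape)
    return Sensorgram(time, resp, schedule)


@dataclass
class KineticFit:
    """Result of a global single-cycle fit."""

    params: Optional[KineticParams]
    residual_norm: float = math.nan
    converged: bool = False
    identifiable: bool = True
    n_starts: int = 0
    message: str = ""

    @property
    def Kd(self) -> float:
        if self.params is None:
            return math.nan
        return self.params.Kd


def _noise_floor(response: np.ndarray) -> float:
    # robust sd of first differences; /sqrt(2) maps diff noise to point noise
    diffs = np.abs(np.diff(response))
    return max(1.4826 * float(np.median(diffs)) / math.sqrt(2.0), 1e-9)


def fit_single_cycle(
    sensorgram: Sensorgram, initial_guess: Optional[KineticParams] = None
) -> KineticFit:
    """Global least-squares fit of (ka, kd, Rmax) to a single-cycle trace.

    Rates are fitted in log10 space (they span decades); when no initial
    guess is supplied the fit is multi-started from 5 log-spaced ka
    guesses and the best residual wins.  A flat trace (response range
    below 10x the estimated noise floor) is flagged non-identifiable.
    """
    resp = sensorgram.response_ru
    span = float(resp.max() - resp.min())
    if span < 10.0 * _noise_floor(resp) or span <= 0.0:
        return KineticFit(None, identifiable=False, message="flat or degenerate trace")

    def residual(p):
        kp = KineticParams(10 ** p["log_ka"].value, 10 ** p["log_kd"].value, p["rmax"].value)
        return model_response(sensorgram.time_s, sensorgram.schedule, kp) - resp

    if initial_guess is not None:
        starts = [initial_guess]
    else:
        rmax0 = max(span * 1.2, 1e-3)
        starts = [
            KineticParams(ka0, 1e-2, rmax0) for ka0 in np.logspace(3, 7, 5)
        ]

    best = None
    for guess in starts:
        p = lmfit.Parameters()
        p.add("log_ka", value=math.log10(guess.ka),
              min=math.log10(KA_BOUNDS[0]), max=math.log10(KA_BOUNDS[1]))
        p.add("log_kd", value=math.log10(max(guess.kd, KD_BOUNDS[0])),
              min=math.log10(KD_BOUNDS[0]), max=math.log10(KD_BOUNDS[1]))
        p.add("rmax", value=guess.rmax, min=RMAX_BOUNDS[0], max=RMAX_BOUNDS[1])
        try:
            res = lmfit.minimize(residual, p, method="least_squares")
        except Exception:
            continue
        norm = float(np.linalg.norm(res.residual))
        if best is None or norm < best[0]:
            best = (norm, res)

    if best is None:
        return KineticFit(None, converged=False, n_starts=len(starts), message="all starts failed")
    norm, res = best
    fitted = KineticParams(
        10 ** res.params["log_ka"].value,
        10 ** res.params["log_kd"].value,
        res.params["rmax"].value,
    )
    return KineticFit(
        fitted,
        residual_norm=norm,
        converged=bool(res.success),
        n_starts=len(starts),
        message=str(res.message),
    )
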