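"""Fluorescence recovery after photobleaching (FRAP) of phage tactoids.

A circular region of a labelled tactoid is bleached after a few imaging
frames and the fluorescence recovery is followed over time.  Traces are
normalised so that the pre-bleach mean maps to 100% and the first
post-bleach frame to 0%, several traces are averaged, and the recovery is
fitted with the single-exponential model

    I(t) = A * (1 - exp(-t / T))

with ``A`` the mobile fraction (on the 0-1 scale of the normalised signal)
and ``T`` the recovery time constant.  The half-life is T*ln 2 and the
immobile fraction is 1 - A: the share of fluorophores that never exchanges
back into the bleached region on the experiment's timescale.

The fit is exposed statsmodels-style: ``RecoveryModel(trace).fit()`` returns
a :class:`RecoveryResults` with estimates, standard errors and ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FrapTrace",
    "FrapFit",
    "RecoveryModel",
    "RecoveryResults",
    "DegenerateNormalizationError",
    "normalize_trace",
    "fit_recovery",
    "average_traces",
]

DEFAULT_PREBLEACH_FRAMES = 5  # bleach applied after 5 imaging frames


class DegenerateNormalizationError(ValueError):
    """Pre-bleach mean equals the first post-bleach value: no bleach depth."""


@dataclass(frozen=True)
class FrapTrace:
    """One time-intensity trace with its bleach bookkeeping.

    ``bleach_index`` is the index of the first post-bleach frame; frames
    before it are pre-bleach.  For normalised traces, times are re-zeroed to
    the first post-bleach frame and intensities are in percent.
    """

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach_frames: int = DEFAULT_PREBLEACH_FRAMES
    normalized: bool = False
    intensity_sd: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if t.shape != i.shape or t.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach_frames < 0 or self.n_prebleach_frames >= t.size:
            raise ValueError("n_prebleach_frames out of range")
        if t.size - self.bleach_index < 3:
            raise ValueError("need >= 3 post-bleach points")

    @property
    def bleach_index(self) -> int:
        return self.n_prebleach_frames

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.bleach_index :]

    @property
    def post_intensities(self) -> np.ndarray:
        return self.intensities[self.bleach_index :]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_prebleach_frames: int = DEFAULT_PREBLEACH_FRAMES
    ) -> "FrapTrace":
        return cls(
            times=df["time_s"].to_numpy(float),
            intensities=df["intensity"].to_numpy(float),
            n_prebleach_frames=n_prebleach_frames,
        )


def normalize_trace(raw: FrapTrace) -> FrapTrace:
    """Affine-normalise a trace: pre-bleach mean -> 100, first post-bleach -> 0.

    Times are re-zeroed to the first post-bleach frame (pre-bleach times
    become negative).  Idempotent on already-normalised traces.  Raises
    :class:`DegenerateNormalizationError` when the trace has no bleach depth.
    """
    if raw.n_prebleach_frames < 1:
        raise ValueError("normalisation needs >= 1 pre-bleach frame")
    pre_mean = float(np.mean(raw.intensities[: raw.bleach_index]))
    floor = float(raw.intensities[raw.bleach_index])
    if math.isclose(pre_mean, floor, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(pre_mean))):
        raise DegenerateNormalizationError(
            f"pre-bleach mean ({pre_mean}) equals first post-bleach value; "
            "cannot normalise a flat trace"
        )
    scaled = 100.0 * (raw.intensities - floor) / (pre_mean - floor)
    return FrapTrace(
        times=raw.times - raw.times[raw.bleach_index],
        intensities=scaled,
        n_prebleach_frames=raw.n_prebleach_frames,
        normalized=True,
    )


@dataclass(frozen=True)
class FrapFit:
    """Fitted exponential-recovery parameters.

    ``amplitude`` (A, the mobile fraction) is on the 0-1 scale of the
    normalised signal (100% == 1); ``time_constant`` T in seconds.
    ``valid`` is False for physically meaningless fits (non-positive T or
    A outside [0, 1], which the immobile-fraction reading assumes).
    """

    amplitude: float
    time_constant: float
    amplitude_se: float
    time_constant_se: float
    rss: float
    n_points: int

    @property
    def half_life(self) -> float:
        return self.time_constant * math.log(2)

    @property
    def mobile_fraction(self) -> float:
        return self.amplitude

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.amplitude

    @property
    def valid(self) -> bool:
        # small tolerance: optimiser round-off on exact full-recovery data
        return self.time_constant > 0 and 0.0 <= self.amplitude <= 1.0 + 1e-6


class RecoveryModel:
    """Single-exponential recovery model for one normalised FRAP trace."""

    def __init__(self, trace: FrapTrace):
        if not trace.normalized:
            trace = normalize_trace(trace)
        self.trace = trace

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_prebleach_frames: int = DEFAULT_PREBLEACH_FRAMES
    ) -> "RecoveryModel":
        return cls(FrapTrace.from_dataframe(df, n_prebleach_frames))

    def fit(self, xtol: float = 1e-10) -> "RecoveryResults":
        """Nonlinear least squares of I(t) = A(1 - exp(-t/T)) on the
        post-bleach points (intensities rescaled from percent to 0-1).

        Initialisation is deterministic: A0 from the final plateau, T0 the
        time at which the trace first reaches half the plateau.  A is bounded
        in (0, 1.5] — a fitted A slightly above 1 is reported but flagged
        invalid rather than silently clipped.
        """
        from scipy.optimize import curve_fit

        t = self.trace.post_times
        y = self.trace.post_intensities / 100.0

        plateau = max(float(np.mean(y[max(1, y.size - 5) :])), 1e-6)
        a0 = min(plateau, 1.5)
        above = np.nonzero(y >= plateau / 2.0)[0]
        t0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 4.0
        t0 = max(t0, 1e-3)

        def model(tt: np.ndarray, a: float, tau: float) -> np.ndarray:
            return a * (1.0 - np.exp(-tt / tau))

        try:
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=(a0, t0),
                bounds=([1e-9, 1e-9], [1.5, np.inf]),
                xtol=xtol,
                maxfev=10000,
            )
        except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
            raise RuntimeError(
                f"recovery fit did not converge (p0=({a0:.3g}, {t0:.3g})): {exc}"
            ) from exc
        a_hat, tau_hat = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        resid = y - model(t, a_hat, tau_hat)
        fit = FrapFit(
            amplitude=a_hat,
            time_constant=tau_hat,
            amplitude_se=float(se[0]),
            time_constant_se=float(se[1]),
            rss=float(np.sum(resid**2)),
            n_points=t.size,
        )
        return RecoveryResults(model=self, fit=fit)


@dataclass(frozen=True)
class RecoveryResults:
    model: RecoveryModel
    fit: FrapFit

    def __getattr__(self, name: str):
        # Delegate parameter access (amplitude, half_life, ...) to the fit
        return getattr(self.fit, name)

    def summary(self) -> str:
        f = self.fit
        lines = [
            "FRAP exponential-recovery fit: I(t) = A (1 - exp(-t/T))",
            f"  n post-bleach points = {f.n_points}",
            f"  A (mobile fraction)  = {f.amplitude:.4f} +/- {f.amplitude_se:.4f}",
            f"  T (time constant)    = {f.time_constant:.3f} s +/- {f.time_constant_se:.3f} s",
            f"  half-life            = {f.half_life:.3f} s",
            f"  immobile fraction    = {100 * f.immobile_fraction:.1f} %",
            f"  RSS = {f.rss:.4g}" + ("" if f.valid else "   [flagged: outside 0-1]"),
        ]
        return "\n".join(lines)


def fit_recovery(trace: FrapTrace) -> FrapFit:
    """Fit the exponential recovery model to a normalised trace."""
    return RecoveryModel(trace).fit().fit


def average_traces(traces: list[FrapTrace], time_tol: float = 1e-6) -> FrapTrace:
    """Pointwise mean of normalised traces on a common time grid.

    The per-point standard deviation across traces is attached as
    ``intensity_sd``.  Grids must agree within ``time_tol`` seconds.
    """
    if not traces:
        raise ValueError("need >= 1 trace")
    base = traces[0]
    for tr in traces[1:]:
        if tr.times.shape != base.times.shape or np.any(
            np.abs(tr.times - base.times) > time_tol
        ):
            raise ValueError("traces are not on a common time grid")
        if tr.bleach_index != base.bleach_index:
            raise ValueError("traces disagree on the bleach frame")
    stack = np.vstack([tr.intensities for tr in traces])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    return replace(base, intensities=mean, intensity_sd=sd)
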