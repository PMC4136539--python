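"""Half-clearance (t50) estimation from dust-removal time courses.

Dust fraction on a body part decays over grooming time; the time at which
the fitted curve crosses half of its fitted initial value, t50, summarizes
how fast a body part is cleaned.  Two curve families are supported:

* ``exponential``: f(t) = f0 * exp(-k t), with the closed form
  t50 = ln(2) / k;
* ``sigmoidal``: the 4-parameter logistic
  f(t) = floor + (ceiling - floor) / (1 + (t / midpoint)**slope),
  whose value at t = 0 is the ceiling, so t50 solves
  f(t50) = f(0) / 2 in closed form (t50 = midpoint when floor = 0).

When the nonlinear fit fails or the fitted curve never reaches half of its
initial value, a model-free fallback interpolates the raw data linearly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = ["DecayFit", "DustDecayModel", "fit_t50", "exponential_decay", "logistic4"]

LN2 = float(np.log(2.0))


def exponential_decay(t: np.ndarray, f0: float, k: float) -> np.ndarray:
    return f0 * np.exp(-k * np.asarray(t, dtype=float))


def logistic4(t: np.ndarray, floor: float, ceiling: float, midpoint: float, slope: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (t / midpoint) ** slope)


@dataclass
class DecayFit:
    """Results of a dust-decay fit.

    ``params`` holds the fitted parameter vector by name; ``t50`` is the
    half-clearance time on the fitted curve relative to its own value at
    t = 0 (not the raw first sample).  ``fallback`` flags that the
    least-squares fit failed and t50 came from linear interpolation of the
    raw data instead; ``message`` carries any diagnostic.
    """

    model: str
    params: Dict[str, float]
    t50: float
    fallback: bool = False
    message: str = ""

    def predict(self, t: Sequence[float]) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.fallback:
            raise ValueError("fallback fit has no parametric curve to evaluate")
        if self.model == "exponential":
            return exponential_decay(t, self.params["f0"], self.params["k"])
        return logistic4(t, self.params["floor"], self.params["ceiling"],
                         self.params["midpoint"], self.params["slope"])

    def summary(self) -> str:
        lines = [
            f"Dust decay fit ({self.model}{', fallback' if self.fallback else ''})",
            "-" * 48,
        ]
        for name, value in self.params.items():
            lines.append(f"{name:>10s}: {value:.6g}")
        lines.append(f"{'t50':>10s}: {self.t50:.6g}")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


def _fallback_t50(times: np.ndarray, fractions: np.ndarray, message: str) -> DecayFit:
    """Model-free t50: first linear-interpolated crossing of half the first sample."""
    target = fractions[0] / 2.0
    below = np.flatnonzero(fractions <= target)
    if fractions[0] <= 0 or below.size == 0:
        raise ValueError(f"cannot estimate t50: {message}; data never reach half the initial value")
    j = below[0]
    if j == 0:
        t50 = float(times[0])
    else:
        t0, t1 = times[j - 1], times[j]
        y0, y1 = fractions[j - 1], fractions[j]
        t50 = float(t0) if y0 == y1 else float(t0 + (y0 - target) * (t1 - t0) / (y0 - y1))
    return DecayFit(model="interpolation", params={}, t50=t50, fallback=True, message=message)


class DustDecayModel:
    """Least-squares dust-decay model for one body part's time course.

    Parameters
    ----------
    times
        Strictly increasing sample times (minutes in the experimental
        convention, but any unit works; t50 is returned in the same unit).
    fractions
        Dust fractions in [0, 1] at those times.
    kind
        ``"exponential"`` or ``"sigmoidal"``.
    """

    def __init__(self, times: Sequence[float], fractions: Sequence[float], kind: str = "exponential"):
        times = np.asarray(times, dtype=float)
        fractions = np.asarray(fractions, dtype=float)
        if kind not in ("exponential", "sigmoidal"):
            raise ValueError("kind must be 'exponential' or 'sigmoidal'")
        if times.size != fractions.size:
            raise ValueError("times and fractions must have equal length")
        if times.size < 4:
            raise ValueError("need at least 4 time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(fractions < 0) or np.any(fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")
        self.times = times
        self.fractions = fractions
        self.kind = kind
        self.message = ""
        if fractions[-1] > fractions[0]:
            self.message = "data trend upward; decay fit may be unreliable"
            warnings.warn(self.message, stacklevel=3)

    def fit(self) -> DecayFit:
        t, y = self.times, self.fractions
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                if self.kind == "exponential":
                    k0 = self._initial_rate_guess()
                    popt, _ = curve_fit(
                        exponential_decay, t, y, p0=[max(y[0], 1e-6), k0], maxfev=10000
                    )
                    f0, k = popt
                    if f0 <= 0 or k <= 0:
                        raise RuntimeError("non-decaying exponential fit")
                    return DecayFit(
                        model="exponential",
                        params={"f0": float(f0), "k": float(k)},
                        t50=LN2 / float(k),
                        message=self.message,
                    )
                mid0 = max(float(np.median(t[t > 0])) if np.any(t > 0) else 1.0, 1e-6)
                popt, _ = curve_fit(
                    logistic4, t, y,
                    p0=[float(y.min()), max(float(y[0]), 1e-6), mid0, 2.0],
                    bounds=([0.0, 1e-9, 1e-9, 0.05], [1.0, 2.0, np.inf, 50.0]),
                    maxfev=20000,
                )
                floor, ceiling, midpoint, slope = (float(v) for v in popt)
                half = ceiling / 2.0  # f(0) = ceiling for slope > 0
                if half <= floor:
                    raise RuntimeError("fitted curve never reaches half its initial value")
                # solve floor + (ceiling - floor)/(1 + x) = half for x = (t/mid)^slope
                x = (ceiling - floor) / (half - floor) - 1.0
                t50 = midpoint * x ** (1.0 / slope)
                return DecayFit(
                    model="sigmoidal",
                    params={"floor": floor, "ceiling": ceiling, "midpoint": midpoint, "slope": slope},
                    t50=float(t50),
                    message=self.message,
                )
        except (RuntimeError, ValueError) as exc:
            return _fallback_t50(t, y, f"{self.kind} fit failed ({exc})")

    def _initial_rate_guess(self) -> float:
        t, y = self.times, self.fractions
        target = y[0] / 2.0
        below = np.flatnonzero(y <= target)
        if y[0] > 0 and below.size:
            t_half = max(float(t[below[0]]), 1e-6)
            return LN2 / t_half
        span = float(t[-1] - t[0]) or 1.0
        return 1.0 / span


def fit_t50(
    times: Sequence[float], dust_fractions: Sequence[float], model: str = "exponential"
) -> DecayFit:
    """Fit a decay curve and return its half-clearance time.

    Convenience wrapper over :class:`DustDecayModel`.
    """
    return DustDecayModel(times, dust_fractions, kind=model).fit()
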