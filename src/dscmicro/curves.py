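"""Concentration and signal time series, and the gamma-variate bolus shape."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dscmicro.protocol import AcquisitionProtocol


def gamma_variate(t, amplitude: float, t0: float, r: float, b: float) -> np.ndarray:
    """Gamma-variate bolus curve A*(t-t0)^r * exp(-(t-t0)/b), zero before t0.

    The standard parametric shape of a first-pass contrast bolus; its mode
    sits at ``t0 + r*b`` and its area is ``A * b**(r+1) * Gamma(r+1)``.
    """
    if r <= 0 or b <= 0:
        raise ValueError("gamma-variate shape r and scale b must be positive")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    # evaluate in log space to avoid overflow for large r
    out[pos] = amplitude * np.exp(r * np.log(dt[pos]) - dt[pos] / b)
    return out


@dataclass
class SignalTimeSeries:
    """Raw MR signal magnitude per dynamic frame (arbitrary units)."""

    values: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.protocol.n_dynamics,):
            raise ValueError("signal length must equal protocol n_dynamics")


@dataclass
class ConcentrationCurve:
    """Relaxation-rate change time series (delta-R2* or delta-R2, in 1/s).

    DSC analysis works in relaxation-rate units throughout; no conversion
    to molar concentration is attempted because the contrast-agent
    relaxivity is not calibrated.
    """

    values: np.ndarray
    times: np.ndarray
    echo: str = "GRE"  # "GRE" | "SE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same length")
        if self.values.ndim != 1:
            raise ValueError("curve must be one-dimensional")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def peak(self) -> float:
        return float(np.max(self.values))

    @property
    def peak_time(self) -> float:
        return float(self.times[int(np.argmax(self.values))])

    def area(self) -> float:
        """Rectangle-rule area dt * sum(values); the convention used by the
        discrete convolution model, so area ratios are exactly conserved."""
        return float(self.dt * np.sum(self.values))

    def first_moment_width(self) -> float:
        """Normalized first-moment spread around the centroid (seconds)."""
        v = np.clip(self.values, 0.0, None)
        s = v.sum()
        if s <= 0:
            return float("inf")
        centroid = float((self.times * v).sum() / s)
        return float(np.sqrt(((self.times - centroid) ** 2 * v).sum() / s))

    def same_timebase(self, other: "ConcentrationCurve") -> bool:
        return self.times.shape == other.times.shape and np.allclose(
            self.times, other.times
        )
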