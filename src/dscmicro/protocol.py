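"""Acquisition protocol for a dynamic susceptibility contrast series."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing and geometry of a (dual-echo) DSC acquisition.

    Parameters
    ----------
    tr : float
        Repetition time, i.e. seconds per dynamic frame.
    te_gre : float
        Gradient-echo echo time in seconds.
    te_se : float or None
        Spin-echo echo time in seconds; ``None`` for a single-echo protocol.
    n_dynamics : int
        Number of dynamic frames acquired before, during and after the bolus.
    baseline_frames : int
        Number of pre-bolus frames used to estimate the baseline signal S0.
    voxel_volume : float
        Voxel volume in mm^3 (used for lesion volumetry).
    """

    tr: float
    te_gre: float
    te_se: float | None = None
    n_dynamics: int = 80
    baseline_frames: int = 10
    voxel_volume: float = 8.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.te_gre <= 0:
            raise ValueError("te_gre must be positive")
        if self.te_se is not None and self.te_se <= self.te_gre:
            raise ValueError("te_se must exceed te_gre in a dual-echo protocol")
        if self.n_dynamics < self.baseline_frames + 10:
            raise ValueError("n_dynamics must be at least baseline_frames + 10")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    @property
    def dual_echo(self) -> bool:
        return self.te_se is not None

    @property
    def duration(self) -> float:
        """Total sampled duration in seconds."""
        return self.tr * self.n_dynamics

    @property
    def times(self) -> np.ndarray:
        """Uniform time grid in seconds, t = 0 at the first frame."""
        return np.arange(self.n_dynamics) * self.tr

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)
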