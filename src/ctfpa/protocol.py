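"""Acquisition protocol and bolus-timing arithmetic.

The dynamic protocol modelled throughout the package is a single-location
abdominal CT perfusion acquisition: a contrast bolus (default 80 ml at
5.0 ml/s) is injected at t = 0, and after a fixed start delay (default 13 s)
a train of volume scans is acquired at a constant cycle time (default
34 frames every 1.5 s).  All curve times in the package are absolute seconds
on this axis (t = 0 at injection start).

The two-scan first-pass protocol places its first scan at the frame where
the aortic attenuation first exceeds a bolus-tracking threshold (default
120 HU) and its second scan ``t_p`` seconds later, where ``t_p`` is the
temporal centre of the bolus::

    t_p = t_i / 2 + d

with ``t_i`` the injection duration (volume / rate) and ``d`` an
organ-dependent dispersion delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionProtocol", "injection_duration", "compute_tp"]


def injection_duration(volume: float, rate: float) -> float:
    """Duration of the contrast injection in seconds.

    Parameters
    ----------
    volume : float
        Injected contrast volume in ml.
    rate : float
        Injection rate in ml/s; must be positive.
    """
    if rate <= 0:
        raise ValueError(f"injection rate must be positive, got {rate}")
    if volume < 0:
        raise ValueError(f"injection volume must be non-negative, got {volume}")
    return volume / rate


def compute_tp(t_i: float, d: float) -> float:
    """Temporal centre of the contrast bolus: ``t_p = t_i/2 + d``.

    ``t_i`` is the injection duration in seconds, ``d`` the dispersion delay
    in seconds.  The result is the delay of the second first-pass scan after
    the bolus-tracking trigger.
    """
    if t_i <= 0:
        raise ValueError(f"injection duration must be positive, got {t_i}")
    if d < 0:
        raise ValueError(f"dispersion delay must be non-negative, got {d}")
    return t_i / 2.0 + d


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Dynamic CT acquisition parameters.

    Attributes
    ----------
    n_frames : int
        Number of dynamic volume scans (>= 2).
    frame_spacing : float
        Cycle time between consecutive scans, seconds.
    start_delay : float
        Delay between injection start and the first scan, seconds.
    injection_volume : float
        Contrast volume, ml.
    injection_rate : float
        Injection rate, ml/s.
    trigger_threshold : float
        Bolus-tracking threshold on the aortic attenuation, absolute HU.
    acquisition_time : float
        Exposure time of a single volume scan, seconds; only used for
        scan-time accounting.
    """

    n_frames: int = 34
    frame_spacing: float = 1.5
    start_delay: float = 13.0
    injection_volume: float = 80.0
    injection_rate: float = 5.0
    trigger_threshold: float = 120.0
    acquisition_time: float = 0.5

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if self.frame_spacing <= 0:
            raise ValueError(f"frame_spacing must be positive, got {self.frame_spacing}")
        if self.injection_rate <= 0:
            raise ValueError(f"injection_rate must be positive, got {self.injection_rate}")
        if self.injection_volume < 0:
            raise ValueError("injection_volume must be non-negative")
        if self.start_delay < 0:
            raise ValueError("start_delay must be non-negative")

    @property
    def t_i(self) -> float:
        """Injection duration in seconds (volume / rate)."""
        return injection_duration(self.injection_volume, self.injection_rate)

    @property
    def frame_times(self) -> np.ndarray:
        """Absolute acquisition times of all frames, seconds after injection start."""
        return self.start_delay + self.frame_spacing * np.arange(self.n_frames, dtype=float)
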