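"""Radiation-dose and acquisition-time accounting.

Effective dose is estimated as dose-length product (DLP) times the
abdominal conversion factor (default 0.0153 mSv/(mGy.cm)).  Scan times are
derived from the protocol: a full dynamic acquisition spans all frame
cycles plus the final exposure, while a two-scan first-pass acquisition
spans the bolus-monitoring lead, the delay to the second scan and its
exposure.  Per-volume DLP for synthetic protocols is a configuration input;
no CT physics is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .protocol import AcquisitionProtocol

#: Abdominal CT effective-dose conversion factor, mSv per mGy.cm.
ABDOMEN_K = 0.0153

__all__ = [
    "ABDOMEN_K",
    "DoseRecord",
    "effective_dose",
    "percent_reduction",
    "protocol_scan_time",
    "dose_report",
]


def effective_dose(dlp: float, k: float = ABDOMEN_K) -> float:
    """Effective dose in mSv from DLP (mGy.cm) and conversion factor."""
    if dlp < 0:
        raise ValueError(f"DLP must be non-negative, got {dlp}")
    if k < 0:
        raise ValueError(f"conversion factor must be non-negative, got {k}")
    return dlp * k


def percent_reduction(new: float, reference: float) -> float:
    """Percent reduction of ``new`` relative to ``reference``: 100*(1 - new/ref)."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return 100.0 * (1.0 - new / reference)


@dataclass(frozen=True)
class DoseRecord:
    """Dose bookkeeping for one protocol variant."""

    label: str
    dlp: float
    n_volumes: int
    conversion_k: float = ABDOMEN_K

    def __post_init__(self) -> None:
        if self.dlp < 0 or self.conversion_k < 0 or self.n_volumes < 0:
            raise ValueError("dose quantities must be non-negative")

    @property
    def effective_dose(self) -> float:
        return effective_dose(self.dlp, self.conversion_k)


def protocol_scan_time(
    protocol: AcquisitionProtocol,
    variant: Literal["dynamic", "fpa"],
    fpa_last_delay: float = 0.0,
    monitoring_lead: float = 0.0,
) -> float:
    """Total acquisition time of a protocol variant, seconds.

    ``dynamic``: (n_frames - 1) cycles plus the final exposure.
    ``fpa``: bolus-monitoring lead up to the trigger plus the delay of the
    last first-pass scan after the trigger (``fpa_last_delay``) plus its
    exposure.
    """
    if variant == "dynamic":
        return (protocol.n_frames - 1) * protocol.frame_spacing + protocol.acquisition_time
    if variant == "fpa":
        if fpa_last_delay < 0 or monitoring_lead < 0:
            raise ValueError("delays must be non-negative")
        return monitoring_lead + fpa_last_delay + protocol.acquisition_time
    raise ValueError(f"unknown variant {variant!r}")


def dose_report(
    protocol: AcquisitionProtocol,
    dynamic_dlp: float,
    fpa_last_delay: float,
    k: float = ABDOMEN_K,
    fpa_n_volumes: int = 2,
    monitoring_lead: float = 0.0,
) -> dict:
    """Compare dynamic and two-scan first-pass protocols.

    The first-pass DLP is modelled as the per-volume share of the dynamic
    DLP (``fpa_n_volumes / n_frames``), consistent with dose scaling with
    the number of acquisitions.
    """
    dynamic = DoseRecord("dynamic", dynamic_dlp, protocol.n_frames, k)
    fpa = DoseRecord("fpa", dynamic_dlp * fpa_n_volumes / protocol.n_frames, fpa_n_volumes, k)
    t_dyn = protocol_scan_time(protocol, "dynamic")
    t_fpa = protocol_scan_time(protocol, "fpa", fpa_last_delay, monitoring_lead)
    return {
        "dynamic": {
            "dlp_mgycm": dynamic.dlp,
            "effective_dose_msv": dynamic.effective_dose,
            "n_volumes": dynamic.n_volumes,
            "scan_time_s": t_dyn,
        },
        "fpa": {
            "dlp_mgycm": fpa.dlp,
            "effective_dose_msv": fpa.effective_dose,
            "n_volumes": fpa.n_volumes,
            "scan_time_s": t_fpa,
        },
        "dose_reduction_percent": percent_reduction(fpa.effective_dose, dynamic.effective_dose),
        "scan_time_reduction_percent": percent_reduction(t_fpa, t_dyn),
    }
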