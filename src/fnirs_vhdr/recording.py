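"""In-memory containers for optical-density and hemoglobin recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventSchedule
from .montage import MontageLayout

CHROMOPHORES = ("OHb", "DHb", "THb")

#: sample-wise tolerance for the THb = OHb + DHb identity, molar
THB_TOL = 1e-12


@dataclass
class ODRecording:
    """Per-channel optical-density change series at two wavelengths.

    ``od`` has shape (n_channels, 2, n_samples); the wavelength axis follows
    ``montage.wavelengths``.
    """

    sampling_rate: float
    od: np.ndarray
    montage: MontageLayout
    schedule: EventSchedule

    def __post_init__(self):
        self.od = np.asarray(self.od, dtype=float)
        if self.od.ndim != 3 or self.od.shape[1] != 2:
            raise ValueError("od must have shape (n_channels, 2, n_samples)")
        if self.od.shape[0] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical-density series contain non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class HbRecording:
    """Per-channel OHb/DHb/THb concentration-change series (molar).

    THb is stored explicitly but must equal OHb + DHb sample-wise.  Channels
    flagged unusable (e.g. dead channels found during preprocessing) stay in
    the arrays but are excluded from downstream averaging.
    """

    sampling_rate: float
    ohb: np.ndarray
    dhb: np.ndarray
    thb: np.ndarray
    montage: MontageLayout
    schedule: EventSchedule
    usable: np.ndarray | None = None

    def __post_init__(self):
        self.ohb = np.atleast_2d(np.asarray(self.ohb, dtype=float))
        self.dhb = np.atleast_2d(np.asarray(self.dhb, dtype=float))
        self.thb = np.atleast_2d(np.asarray(self.thb, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not (self.ohb.shape == self.dhb.shape == self.thb.shape):
            raise ValueError("chromophore arrays must share a shape")
        if self.ohb.shape[0] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        for name, arr in (("OHb", self.ohb), ("DHb", self.dhb), ("THb", self.thb)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} series contain non-finite samples")
        if np.max(np.abs(self.thb - (self.ohb + self.dhb)), initial=0.0) >= THB_TOL:
            raise ValueError("THb must equal OHb + DHb sample-wise")
        if self.usable is None:
            self.usable = np.ones(self.montage.n_channels, dtype=bool)
        else:
            self.usable = np.asarray(self.usable, dtype=bool)
            if self.usable.shape != (self.montage.n_channels,):
                raise ValueError("usable mask must have one entry per channel")

    @property
    def n_samples(self) -> int:
        return self.ohb.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def chromophore(self, name: str) -> np.ndarray:
        try:
            return {"OHb": self.ohb, "DHb": self.dhb, "THb": self.thb}[name]
        except KeyError:
            raise ValueError(f"unknown chromophore {name!r}") from None


def hb_from_ohb_dhb(
    sampling_rate: float,
    ohb: np.ndarray,
    dhb: np.ndarray,
    montage: MontageLayout,
    schedule: EventSchedule,
    usable: np.ndarray | None = None,
) -> HbRecording:
    """Build an HbRecording with THb computed exactly as OHb + DHb."""
    ohb = np.atleast_2d(np.asarray(ohb, dtype=float))
    dhb = np.atleast_2d(np.asarray(dhb, dtype=float))
    return HbRecording(
        sampling_rate=sampling_rate,
        ohb=ohb,
        dhb=dhb,
        thb=ohb + dhb,
        montage=montage,
        schedule=schedule,
        usable=usable,
    )
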