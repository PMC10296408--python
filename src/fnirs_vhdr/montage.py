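"""Optode montage geometry for the occipital fNIRS array.

A channel is a source–detector pair; its signal reflects the cortex between
the two optodes.  The default montage mimics a dual-wavelength continuous-wave
system with eight sources and seven detectors forming 22 channels over the
occipital cortex, laid out as a symmetric two-row grid so that every
left-hemisphere channel has a mirror partner on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

LEFT = "left"
RIGHT = "right"
MIDLINE = "midline"

DEFAULT_WAVELENGTHS_NM = (760.0, 850.0)

#: nominal source–detector separation assigned to every default channel, cm
DEFAULT_SD_DISTANCE_CM = 3.0


@dataclass(frozen=True)
class Channel:
    """A source–detector pair with a hemisphere label."""

    channel_id: str
    source_id: str
    detector_id: str
    hemisphere: str

    def __post_init__(self):
        if self.hemisphere not in (LEFT, RIGHT, MIDLINE):
            raise ValueError(f"unknown hemisphere label {self.hemisphere!r}")


@dataclass
class MontageLayout:
    """Optode/channel geometry with hemisphere labels and wavelength pair.

    Positions are 2-D scalp coordinates in arbitrary units with the head
    midline at x = 0 (negative x = left hemisphere).  The hemisphere of a
    channel is determined by the sign of the x-coordinate of the
    source–detector midpoint.
    """

    sources: list[tuple[str, tuple[float, float]]]
    detectors: list[tuple[str, tuple[float, float]]]
    channels: list[Channel]
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    source_detector_distance_cm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_ids(self) -> list[str]:
        return [c.channel_id for c in self.channels]

    def hemisphere_labels(self) -> list[str]:
        return [c.hemisphere for c in self.channels]

    def channel_indices(self, hemisphere: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.hemisphere == hemisphere]

    def distances_cm(self) -> list[float]:
        return [self.source_detector_distance_cm[c.channel_id] for c in self.channels]

    def source_pos(self, source_id: str) -> tuple[float, float]:
        return dict(self.sources)[source_id]

    def detector_pos(self, detector_id: str) -> tuple[float, float]:
        return dict(self.detectors)[detector_id]

    def channel_midpoint(self, channel: Channel) -> tuple[float, float]:
        sx, sy = self.source_pos(channel.source_id)
        dx, dy = self.detector_pos(channel.detector_id)
        return ((sx + dx) / 2.0, (sy + dy) / 2.0)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        source_ids = {s for s, _ in self.sources}
        detector_ids = {d for d, _ in self.detectors}
        if len(source_ids) != len(self.sources):
            raise ValueError("duplicate source ids")
        if len(detector_ids) != len(self.detectors):
            raise ValueError("duplicate detector ids")
        seen = set()
        for ch in self.channels:
            if ch.source_id not in source_ids:
                raise ValueError(f"channel {ch.channel_id} references unknown source {ch.source_id}")
            if ch.detector_id not in detector_ids:
                raise ValueError(f"channel {ch.channel_id} references unknown detector {ch.detector_id}")
            if ch.channel_id in seen:
                raise ValueError(f"duplicate channel id {ch.channel_id}")
            seen.add(ch.channel_id)
            if ch.channel_id not in self.source_detector_distance_cm:
                raise ValueError(f"missing source–detector distance for {ch.channel_id}")
        if len(self.wavelengths) != 2 or self.wavelengths[0] == self.wavelengths[1]:
            raise ValueError("exactly two distinct wavelengths are required")


def hemisphere_from_midpoint(x: float, tol: float = 1e-9) -> str:
    if x < -tol:
        return LEFT
    if x > tol:
        return RIGHT
    return MIDLINE


# Default grid: two rows of optodes (y = 0 lower, y = 1 upper) with an extra
# detector on the midline between the rows.  Units are arbitrary; hemisphere
# labels follow the sign of the channel-midpoint x-coordinate.
_SOURCE_POS = {
    "S1": (-3.0, 0.0), "S2": (-1.0, 0.0), "S3": (1.0, 0.0), "S4": (3.0, 0.0),
    "S5": (-3.0, 1.0), "S6": (-1.0, 1.0), "S7": (1.0, 1.0), "S8": (3.0, 1.0),
}
_DETECTOR_POS = {
    "D1": (-2.0, 0.0), "D2": (0.0, 0.0), "D3": (2.0, 0.0),
    "D4": (-2.0, 1.0), "D5": (0.0, 1.0), "D6": (2.0, 1.0),
    "D7": (0.0, 0.5),
}
_CHANNEL_PAIRS = [
    # lower row
    ("S1", "D1"), ("S2", "D1"), ("S2", "D2"), ("S3", "D2"), ("S3", "D3"), ("S4", "D3"),
    # upper row
    ("S5", "D4"), ("S6", "D4"), ("S6", "D5"), ("S7", "D5"), ("S7", "D6"), ("S8", "D6"),
    # cross-row pairs
    ("S1", "D4"), ("S5", "D1"), ("S4", "D6"), ("S8", "D3"), ("S2", "D4"), ("S3", "D6"),
    # pairs with the inter-row midline detector
    ("S2", "D7"), ("S6", "D7"), ("S3", "D7"), ("S7", "D7"),
]


def make_default_montage() -> MontageLayout:
    """Build the default 8-source / 7-detector / 22-channel occipital montage.

    The layout is mirror-symmetric about the midline, giving 11 left and 11
    right channels and no midline channels; all channels are assigned the
    nominal 3 cm source–detector separation.
    """
    sources = sorted(_SOURCE_POS.items())
    detectors = sorted(_DETECTOR_POS.items())
    channels = []
    distances = {}
    for s, d in _CHANNEL_PAIRS:
        mid_x = (_SOURCE_POS[s][0] + _DETECTOR_POS[d][0]) / 2.0
        cid = f"{s}_{d}"
        channels.append(Channel(cid, s, d, hemisphere_from_midpoint(mid_x)))
        distances[cid] = DEFAULT_SD_DISTANCE_CM
    return MontageLayout(
        sources=sources,
        detectors=detectors,
        channels=channels,
        wavelengths=DEFAULT_WAVELENGTHS_NM,
        source_detector_distance_cm=distances,
    )
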