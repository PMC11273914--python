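"""Channel layout, region definitions and analysis-window constants.

The pipeline assumes a 32-channel actiCAP-style cap labelled per the
international 10-20 system, recorded together with bipolar horizontal and
vertical electro-oculogram channels.  Two scalp regions drive the theory:
a bilateral temporal set whose alpha power is read as cortical inhibition
of non-motor areas, and a central-frontal set over sensorimotor cortex
whose alpha release accompanies motor execution.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Standard 32-channel actiCAP layout (10-20 labels).
EEG_CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

#: Ocular channels appended to the scalp montage by the simulator/reader.
EOG_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG")

#: Default mastoid labels used for the linked-mastoid re-reference.
MASTOID_CHANNELS: tuple[str, str] = ("TP9", "TP10")

#: Bilateral temporal sites: alpha surge here indexes inhibition of
#: non-motor interference around response onset.
TEMPORAL_CHANNELS: tuple[str, ...] = ("T7", "F7", "CP5", "T8", "F8", "CP6")

#: Central-frontal (frontal + central) sites over motor regions.
CENTRAL_FRONTAL_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4", "C3", "CP1", "C4", "CP2",
)

#: Pre-response analysis window for temporal alpha, milliseconds.
PRE_RESPONSE_WINDOW_MS: tuple[float, float] = (-65.0, 0.0)

#: Post-response analysis window for central-frontal alpha, milliseconds.
POST_RESPONSE_WINDOW_MS: tuple[float, float] = (0.0, 127.0)

#: Alpha frequency band, Hz.
ALPHA_BAND: tuple[float, float] = (8.0, 12.0)


@dataclass(frozen=True)
class RegionDefinition:
    """A named scalp region given by its 10-20 channel labels."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"duplicate channels in region {self.name!r}")


TEMPORAL_REGION = RegionDefinition("temporal", TEMPORAL_CHANNELS)
CENTRAL_FRONTAL_REGION = RegionDefinition(
    "central_frontal", CENTRAL_FRONTAL_CHANNELS
)

REGIONS: dict[str, RegionDefinition] = {
    "temporal": TEMPORAL_REGION,
    "central_frontal": CENTRAL_FRONTAL_REGION,
}

#: Convention for selecting response events: a "contralesional response"
#: is a key-press made by the hand contralateral to the lesioned
#: hemisphere (the paretic side).  Flip to False to select ipsilesional
#: responses instead.
CONTRALESIONAL_MEANS_HAND_OPPOSITE_LESION: bool = True


def hand_for_lesion_side(lesion_side: str) -> str:
    """Return the response hand selected for epoching given the lesion side.

    With the default convention a left-hemisphere lesion selects
    right-hand responses (the paretic hand) and vice versa.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(f"lesion_side must be 'left' or 'right', got {lesion_side!r}")
    opposite = {"left": "right", "right": "left"}
    if CONTRALESIONAL_MEANS_HAND_OPPOSITE_LESION:
        return opposite[lesion_side]
    return lesion_side
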