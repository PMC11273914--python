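"""Readers and writers for the pipeline's interchange formats.

* BrainVision triplet (.vhdr / .vmrk / .eeg, IEEE float32 multiplexed):
  written natively, read through MNE.
* Array container: .npy with a JSON sidecar carrying channel names,
  sampling rate and events.
* Clinical tables and result tables: CSV.
* Ground truth: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import RawRecording
from .synthetic import GroundTruth

CLINICAL_COLUMNS = [
    "subject_id", "group", "timepoint",
    "sis_adl", "fim", "neadl", "wmft_time", "wmft_strength",
]

#: Default mapping from BrainVision marker description to response hand.
DEFAULT_MARKER_MAP = {"R  1": "left", "R  2": "right"}
_HAND_TO_MARKER = {"left": "R  1", "right": "R  2"}


# ---------------------------------------------------------------------------
# BrainVision triplet


def write_brainvision(raw: RawRecording, basename: str | Path) -> Path:
    """Write a BrainVision triplet (float32 multiplexed). Returns .vhdr path."""
    base = Path(basename)
    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")
    eeg = base.with_suffix(".eeg")

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={raw.n_channels}",
        f"SamplingInterval={1e6 / raw.sampling_rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(raw.channel_names, start=1):
        header.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (sample, _label, hand) in enumerate(
        sorted(raw.events, key=lambda e: e[0]), start=2
    ):
        desc = _HAND_TO_MARKER.get(hand, "R  9")
        # BrainVision marker positions are 1-based
        markers.append(f"Mk{k}=Response,{desc},{int(sample) + 1},1,0")
    vmrk.write_text("\n".join(markers) + "\n", encoding="utf-8")

    raw.signal.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


def read_brainvision(
    vhdr_path: str | Path, marker_map: dict[str, str] | None = None
) -> RawRecording:
    """Read a BrainVision triplet into a RawRecording (microvolts)."""
    import mne

    marker_map = DEFAULT_MARKER_MAP if marker_map is None else marker_map
    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6  # MNE uses volts internally
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        # MNE encodes markers as "<type>/<description>"
        key = desc.split("/", 1)[-1]
        if key in marker_map:
            sample = int(round(onset * raw.info["sfreq"]))
            events.append((sample, key, marker_map[key]))
    return RawRecording(
        signal=signal_uv,
        channel_names=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# array container + JSON sidecar


def write_array_container(raw: RawRecording, basename: str | Path) -> Path:
    base = Path(basename)
    npy = base.with_suffix(".npy")
    sidecar = base.with_suffix(".json")
    np.save(npy, raw.signal)
    meta = dict(
        channel_names=list(raw.channel_names),
        sampling_rate=raw.sampling_rate,
        units="microvolts",
        reference_state=raw.reference_state,
        events=[
            dict(sample=int(s), label=lab, response_hand=hand)
            for s, lab, hand in raw.events
        ],
    )
    sidecar.write_text(json.dumps(meta, indent=2), encoding="utf-8")
    return npy


def read_array_container(basename: str | Path) -> RawRecording:
    base = Path(basename)
    signal = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text(encoding="utf-8"))
    events = [
        (int(e["sample"]), e.get("label", ""), e["response_hand"])
        for e in meta.get("events", [])
    ]
    return RawRecording(
        signal=signal,
        channel_names=list(meta["channel_names"]),
        sampling_rate=float(meta["sampling_rate"]),
        events=events,
        reference_state=meta.get("reference_state", "recording"),
    )


# ---------------------------------------------------------------------------
# tables & ground truth


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    clinical[CLINICAL_COLUMNS].to_csv(path, index=False)
    return path


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing columns: {sorted(missing)}")
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_json_dict(), indent=2), encoding="utf-8")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(**data)
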