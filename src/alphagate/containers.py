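"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class ConfigurationError(ValueError):
    """A container or operation was configured inconsistently."""


@dataclass
class RawRecording:
    """Continuous multichannel EEG with response events.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Microvolts.
    channel_names : list of str
        Unique 10-20 labels (plus EOG labels where present).
    sampling_rate : float
        Hz.
    events : list of (sample_index, label, response_hand)
        ``response_hand`` is ``"left"`` or ``"right"``.
    reference_state : str
        Free-form label of the current reference (e.g. ``"mastoid"``).
    """

    signal: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    events: list[tuple[int, str, str]] = field(default_factory=list)
    reference_state: str = "recording"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ConfigurationError("signal must be channels x samples")
        if self.signal.shape[0] != len(self.channel_names):
            raise ConfigurationError("channel count mismatch")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        n = self.signal.shape[1]
        for s, _label, _hand in self.events:
            if not (0 <= int(s) < n):
                raise ConfigurationError(f"event sample {s} outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not in recording") from None

    def copy_with(self, **kwargs) -> "RawRecording":
        out = replace(self, **kwargs)
        return out


@dataclass
class EpochSet:
    """Response-locked epochs for one subject x session.

    ``epochs`` has shape (n_epochs, n_channels, n_samples), microvolts.
    ``time_axis`` is seconds relative to response onset and must contain
    an exact t = 0 sample.  ``artifact_flags`` marks epochs to be dropped
    by the minimum-epoch gate.
    """

    subject_id: str
    session: str
    lesion_side: str
    epochs: np.ndarray
    time_axis: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    artifact_flags: np.ndarray | None = None
    reference_state: str = "recording"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.epochs.ndim != 3:
            raise ConfigurationError("epochs must be n_epochs x n_channels x n_samples")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ConfigurationError("channel count mismatch")
        if self.epochs.shape[2] != self.time_axis.size:
            raise ConfigurationError("time axis length mismatch")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ConfigurationError("time_axis must be strictly increasing")
        if not np.any(np.isclose(self.time_axis, 0.0, atol=1e-9)):
            raise ConfigurationError("time_axis must contain t = 0")
        if self.session not in ("pre", "post"):
            raise ConfigurationError(f"session must be pre/post, got {self.session!r}")
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.epochs.shape[0], dtype=bool)
        else:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if self.artifact_flags.size != self.epochs.shape[0]:
                raise ConfigurationError("artifact_flags length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_clean(self) -> int:
        return int((~self.artifact_flags).sum())

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.time_axis)))

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(f"channel {name!r} not in epochs") from None

    def channel_indices(self, names) -> np.ndarray:
        return np.array([self.channel_index(n) for n in names], dtype=int)

    def copy_with(self, **kwargs) -> "EpochSet":
        defaults = dict(
            subject_id=self.subject_id,
            session=self.session,
            lesion_side=self.lesion_side,
            epochs=self.epochs.copy(),
            time_axis=self.time_axis.copy(),
            channel_names=list(self.channel_names),
            sampling_rate=self.sampling_rate,
            artifact_flags=None if self.artifact_flags is None else self.artifact_flags.copy(),
            reference_state=self.reference_state,
        )
        defaults.update(kwargs)
        return EpochSet(**defaults)
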