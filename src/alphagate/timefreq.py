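"""Morlet-wavelet alpha power with participant-level median-scaled dB.

Power is estimated per channel and frequency by convolution with complex
Morlet wavelets (5 cycles by default, 1 Hz steps over 8-12 Hz), on
segments zero-padded to ``pad_ratio`` times their length.  Wavelet
amplitudes are doubled (one-sided spectrum convention, so a sinusoid of
amplitude A recovers power A^2), squared, and averaged over clean
epochs.  Absolute power is reported without baseline correction as
10*log10(power / median), the median taken over valid time samples per
channel x frequency within each participant-session, which centres every
participant's dB map near zero without assuming a quiet baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import ConfigurationError, EpochSet
from .montage import ALPHA_BAND

logger = logging.getLogger(__name__)

DEFAULT_N_CYCLES = 5.0
DEFAULT_PAD_RATIO = 4
#: floor substituted for nonpositive power before the log transform
POWER_FLOOR = 1e-12


def morlet_wavelet(freq: float, sampling_rate: float, n_cycles: float = DEFAULT_N_CYCLES):
    """Complex Morlet wavelet, truncated at +-3.5 temporal SDs.

    Normalised in the frequency domain so the peak of its transfer
    function is 1: a unit-amplitude sinusoid at ``freq`` then yields
    coefficient magnitude 1/2 before the one-sided doubling.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    wav = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2 * sigma_t**2))
    # peak transfer gain at the centre frequency: sum of wav * e^{-i2pift}
    gain = np.abs(np.sum(wav * np.exp(-2j * np.pi * freq * t)))
    return wav / gain


def wavelet_half_width(freq: float, sampling_rate: float, n_cycles: float = DEFAULT_N_CYCLES) -> int:
    """Samples invalidated at each epoch edge by the wavelet support."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    return int(np.ceil(3.5 * sigma_t * sampling_rate))


def wavelet_power(
    epochs: EpochSet,
    freqs,
    *,
    n_cycles: float = DEFAULT_N_CYCLES,
    pad_ratio: int = DEFAULT_PAD_RATIO,
    channel_names=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged wavelet power, channels x freqs x time, in uV^2.

    Only artifact-free epochs contribute.  Returns ``(power, valid)``
    where ``valid`` is a boolean time mask marking samples unaffected by
    edge effects at every requested frequency.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    nyquist = epochs.sampling_rate / 2.0
    if np.any(freqs <= 0) or np.any(freqs >= nyquist):
        raise ConfigurationError(f"freqs must lie in (0, {nyquist}) Hz")
    clean = epochs.epochs[~epochs.artifact_flags]
    if clean.shape[0] == 0:
        raise ConfigurationError("no clean epochs to decompose")
    if channel_names is None:
        ch_idx = np.arange(len(epochs.channel_names))
    else:
        ch_idx = epochs.channel_indices(channel_names)
    data = clean[:, ch_idx, :]  # (n_ep, n_ch, n_samp)
    n_ep, n_ch, n_samp = data.shape
    n_fft = int(pad_ratio) * n_samp

    power = np.empty((n_ch, freqs.size, n_samp))
    valid = np.ones(n_samp, dtype=bool)
    flat = data.reshape(n_ep * n_ch, n_samp)
    spec = np.fft.fft(flat, n=n_fft, axis=1)
    for fi, f in enumerate(freqs):
        wav = morlet_wavelet(f, epochs.sampling_rate, n_cycles)
        half = (wav.size - 1) // 2
        if 2 * half >= n_samp:
            raise ConfigurationError(
                f"wavelet at {f} Hz ({wav.size} samples) longer than epoch"
            )
        kernel = np.zeros(n_fft, dtype=complex)
        kernel[: half + 1] = wav[half:]
        kernel[-half:] = wav[:half]  # centre of wavelet at lag 0
        wf = np.fft.fft(kernel)
        coef = np.fft.ifft(spec * wf[None, :], axis=1)[:, :n_samp]
        amp = 2.0 * np.abs(coef)  # one-sided doubling
        pw = (amp**2).reshape(n_ep, n_ch, n_samp).mean(axis=0)
        power[:, fi, :] = pw
        valid[:half] = False
        valid[n_samp - half:] = False
    return power, valid


def median_log_scale(power: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Median-scaled 10*log10 transform along the time axis (last axis).

    The median is taken per channel x frequency over the valid time
    samples of the participant-session, so the output is scale invariant
    (a gain applied to the raw signal cancels) and centred near 0 dB.
    Nonpositive values are floored before the log, with a logged count.
    """
    p = np.asarray(power, dtype=float)
    if valid is None:
        valid = np.ones(p.shape[-1], dtype=bool)
    n_bad = int((p <= 0).sum())
    if n_bad:
        logger.warning("median_log_scale: flooring %d nonpositive samples", n_bad)
        p = np.maximum(p, POWER_FLOOR)
    med = np.median(p[..., valid], axis=-1, keepdims=True)
    med = np.maximum(med, POWER_FLOOR)
    return 10.0 * np.log10(p / med)


def band_average(power: np.ndarray, freqs, band=ALPHA_BAND) -> np.ndarray:
    """Unweighted mean over frequencies inside the closed band.

    ``power`` is channels x freqs x time (any units, including dB).
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ConfigurationError(f"no frequencies inside band {band}")
    return np.asarray(power)[:, sel, :].mean(axis=1)


@dataclass
class AlphaPowerMap:
    """Per-channel alpha-band power time course in median-scaled dB."""

    subject_id: str
    session: str
    power_db: np.ndarray  # (n_channels, n_time)
    time_axis: np.ndarray
    channel_names: list[str]
    freq_band: tuple[float, float]
    n_epochs_used: int
    valid: np.ndarray

    def channel_indices(self, names) -> np.ndarray:
        idx = []
        for n in names:
            if n not in self.channel_names:
                raise ConfigurationError(f"channel {n!r} missing from power map")
            idx.append(self.channel_names.index(n))
        return np.asarray(idx, dtype=int)


def alpha_power_map(
    epochs: EpochSet,
    *,
    band=ALPHA_BAND,
    freq_step: float = 1.0,
    n_cycles: float = DEFAULT_N_CYCLES,
    pad_ratio: int = DEFAULT_PAD_RATIO,
    channel_names=None,
) -> AlphaPowerMap:
    """EpochSet -> median-scaled dB alpha power map (channels x time)."""
    freqs = np.arange(band[0], band[1] + 1e-9, freq_step)
    power, valid = wavelet_power(
        epochs, freqs, n_cycles=n_cycles, pad_ratio=pad_ratio,
        channel_names=channel_names,
    )
    db = median_log_scale(power, valid)
    band_db = band_average(db, freqs, band)
    names = list(epochs.channel_names) if channel_names is None else list(channel_names)
    return AlphaPowerMap(
        subject_id=epochs.subject_id,
        session=epochs.session,
        power_db=band_db,
        time_axis=epochs.time_axis.copy(),
        channel_names=names,
        freq_band=(float(band[0]), float(band[1])),
        n_epochs_used=epochs.n_clean,
        valid=valid,
    )
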