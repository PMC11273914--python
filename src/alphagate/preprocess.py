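"""Continuous EEG -> artifact-flagged, re-referenced, response-locked epochs.

Stage order (enforced by the pipeline): zero-phase band-pass filter,
line-noise removal, epoching around contralesional responses,
re-reference to linked mastoids, ocular-artifact removal, and the
minimum-clean-epoch qualification gate (default 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import ConfigurationError, EpochSet, RawRecording
from .montage import EOG_CHANNELS, MASTOID_CHANNELS, hand_for_lesion_side

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 40.0)
#: conventional epoch-rejection bound on peak-to-peak amplitude, uV
ARTIFACT_PTP_UV = 150.0
MIN_CLEAN_EPOCHS = 50
#: |r| between an unmixed component and any EOG channel above which the
#: component is removed
EOG_CORR_THRESHOLD = 0.7


class MinEpochsError(RuntimeError):
    """Subject excluded: fewer clean epochs than the qualification gate."""

    def __init__(self, subject_id: str, n_clean: int, minimum: int):
        self.subject_id = subject_id
        self.n_clean = n_clean
        self.minimum = minimum
        super().__init__(
            f"subject {subject_id}: only {n_clean} clean epochs (< {minimum})"
        )


class EmptyEpochSetError(RuntimeError):
    """No qualifying events to epoch."""


# ---------------------------------------------------------------------------
# filtering


def bandpass_filter(
    raw: RawRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    *,
    transition_hz: float = 0.5,
) -> RawRecording:
    """Zero-phase FIR band-pass (forward-backward), preserving latencies.

    The FIR length is set by the transition bandwidth at the low edge
    (default 0.5 Hz); a Hamming-window design gives > 20 dB attenuation
    at half the low cutoff and at twice the high cutoff.
    """
    nyq = raw.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ConfigurationError(f"invalid band ({low}, {high}) at fs={raw.sampling_rate}")
    numtaps = int(np.ceil(3.3 * raw.sampling_rate / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length, type-I linear phase
    if raw.n_samples <= 3 * numtaps:
        # short recording: shorten the filter rather than refuse
        numtaps = max((raw.n_samples // 3) | 1, 31)
    taps = sps.firwin(
        numtaps, [low, high], pass_zero=False, fs=raw.sampling_rate,
        window="hamming",
    )
    filtered = sps.filtfilt(taps, [1.0], raw.signal, axis=1, padtype="odd",
                            padlen=min(3 * numtaps, raw.n_samples - 1))
    return raw.copy_with(signal=filtered)


def remove_line_noise(
    raw: RawRecording,
    line_freq: float = 60.0,
    *,
    window_s: float = 4.0,
) -> RawRecording:
    """Sliding-window sinusoid regression at the line frequency.

    In each Hann-tapered window the 50/60 Hz sine and cosine are fit by
    least squares and the estimated line component is subtracted via
    overlap-add (hop = half window), tracking slow drifts of line
    amplitude/phase while leaving neighbouring frequencies intact.
    """
    if line_freq not in (50.0, 60.0, 50, 60):
        raise ConfigurationError("line_freq must be 50 or 60 Hz")
    fs = raw.sampling_rate
    n = raw.n_samples
    win = int(round(window_s * fs))
    win -= win % 2
    win = min(win, n)
    if win < int(fs):  # need at least ~1 s to separate from neighbours
        win = n
    hop = win // 2
    t = np.arange(n) / fs
    estimate = np.zeros_like(raw.signal)
    weight = np.zeros(n)
    hann = np.hanning(win)
    starts = list(range(0, max(n - win, 0) + 1, hop))
    if not starts or starts[-1] + win < n:
        starts.append(max(n - win, 0))
    for s0 in starts:
        sl = slice(s0, s0 + win)
        tt = t[sl]
        basis = np.column_stack([
            np.sin(2 * np.pi * line_freq * tt),
            np.cos(2 * np.pi * line_freq * tt),
        ])
        coef, *_ = np.linalg.lstsq(basis, raw.signal[:, sl].T, rcond=None)
        est = (basis @ coef).T
        estimate[:, sl] += est * hann[None, :]
        weight[sl] += hann
    weight[weight == 0] = 1.0
    cleaned = raw.signal - estimate / weight[None, :]
    return raw.copy_with(signal=cleaned)


# ---------------------------------------------------------------------------
# epoching & reference


def extract_epochs(
    raw: RawRecording,
    lesion_side: str,
    *,
    subject_id: str = "S00",
    session: str = "pre",
    window: tuple[float, float] = (-1.0, 1.0),
) -> EpochSet:
    """Epoch around responses made by the hand contralateral to the lesion.

    The window is half-open [lo, hi): at 500 Hz a (-1, 1) s window gives
    1000 samples with the t = 0 sample included.  Events too close to
    the recording edge are dropped with a warning.
    """
    hand = hand_for_lesion_side(lesion_side)
    fs = raw.sampling_rate
    lo, hi = window
    if not (lo < 0 < hi):
        raise ConfigurationError("window must span response onset")
    n_pre = int(round(-lo * fs))
    n_samp = int(round((hi - lo) * fs))
    time_axis = lo + np.arange(n_samp) / fs

    picked = []
    for sample, _label, resp_hand in sorted(raw.events, key=lambda e: e[0]):
        if resp_hand != hand:
            continue
        start = int(sample) - n_pre
        stop = start + n_samp
        if start < 0 or stop > raw.n_samples:
            logger.warning(
                "dropping event at sample %d: window outside recording", sample
            )
            continue
        picked.append(raw.signal[:, start:stop])
    if not picked:
        raise EmptyEpochSetError(
            f"no qualifying ({hand}-hand) events for lesion_side={lesion_side!r}"
        )
    return EpochSet(
        subject_id=subject_id,
        session=session,
        lesion_side=lesion_side,
        epochs=np.stack(picked),
        time_axis=time_axis,
        channel_names=list(raw.channel_names),
        sampling_rate=fs,
        reference_state=raw.reference_state,
    )


def rereference_linked_mastoids(
    epochs: EpochSet, mastoids: tuple[str, str] = MASTOID_CHANNELS
) -> EpochSet:
    """Subtract the mean of the two mastoid channels from every channel.

    EOG channels are left untouched.  Idempotent once the mastoids are
    zeroed by the subtraction.
    """
    try:
        m_idx = epochs.channel_indices(mastoids)
    except ConfigurationError as exc:
        raise ConfigurationError(f"mastoid channels missing: {exc}") from exc
    ref = epochs.epochs[:, m_idx, :].mean(axis=1, keepdims=True)
    out = epochs.copy_with(reference_state="linked_mastoids")
    eeg_rows = [i for i, n in enumerate(epochs.channel_names) if n not in EOG_CHANNELS]
    out.epochs[:, eeg_rows, :] -= ref
    return out


# ---------------------------------------------------------------------------
# ocular artifact removal


@dataclass
class OcularCleanResult:
    epochs: EpochSet
    n_components_removed: int
    backend: str


def _fastica_unmix(data: np.ndarray, n_components: int, seed: int):
    """Default decomposition backend (FastICA); returns (sources, mixing, mean)."""
    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed, max_iter=500,
                  whiten="unit-variance")
    sources = ica.fit_transform(data.T).T  # (n_comp, n_times)
    return sources, ica.mixing_, ica.mean_


def _regress_out_eog(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Least-squares EOG regression per EEG channel."""
    e = eog - eog.mean(axis=1, keepdims=True)
    x = eeg - eeg.mean(axis=1, keepdims=True)
    beta = np.linalg.lstsq(e.T, x.T, rcond=None)[0]  # (n_eog, n_eeg)
    return eeg - (beta.T @ e)


def remove_ocular_artifacts(
    epochs: EpochSet,
    eog_channels=EOG_CHANNELS,
    *,
    threshold: float = EOG_CORR_THRESHOLD,
    backend=None,
    n_components: int | None = None,
    seed: int = 0,
) -> tuple[EpochSet, int]:
    """Remove unmixed components correlated with the EOG channels.

    The decomposition backend is pluggable: any callable
    ``backend(data, n_components, seed) -> (sources, mixing, mean)``
    operating on (n_eeg_channels, n_times) data, or the string
    ``"regression"`` to use plain least-squares EOG regression.
    Components whose time-course correlation with any EOG channel
    exceeds ``threshold`` in magnitude are dropped before
    reconstruction.  On decomposition failure the EOG-regression
    fall-back is applied with a warning.
    """
    eog_present = [c for c in eog_channels if c in epochs.channel_names]
    if not eog_present:
        raise ConfigurationError("no EOG channels available for ocular removal")
    eeg_rows = [i for i, n in enumerate(epochs.channel_names) if n not in eog_channels]
    eog_rows = epochs.channel_indices(eog_present)

    n_ep, _n_ch, n_samp = epochs.epochs.shape
    eeg = epochs.epochs[:, eeg_rows, :].transpose(1, 0, 2).reshape(len(eeg_rows), -1)
    eog = epochs.epochs[:, eog_rows, :].transpose(1, 0, 2).reshape(len(eog_rows), -1)

    backend = _fastica_unmix if backend is None else backend
    if n_components is None:
        n_components = min(len(eeg_rows), 15)
    out = epochs.copy_with()
    if backend == "regression":
        cleaned = _regress_out_eog(eeg, eog)
        out.epochs[:, eeg_rows, :] = cleaned.reshape(
            len(eeg_rows), n_ep, n_samp
        ).transpose(1, 0, 2)
        return out, 0
    try:
        sources, mixing, mean = backend(eeg, n_components, seed)
        sc = sources - sources.mean(axis=1, keepdims=True)
        ec = eog - eog.mean(axis=1, keepdims=True)
        s_sd = sc.std(axis=1)
        e_sd = ec.std(axis=1)
        corr = np.zeros((sources.shape[0], len(eog_rows)))
        ok = np.outer(s_sd > 0, e_sd > 0)
        raw_corr = (sc @ ec.T) / n_samp / n_ep
        denom = np.outer(s_sd, e_sd)
        corr[ok] = (raw_corr / np.where(denom == 0, np.inf, denom))[ok]
        bad = np.flatnonzero(np.max(np.abs(corr), axis=1) > threshold)
        n_removed = int(bad.size)
        if n_removed:
            keep = np.setdiff1d(np.arange(sources.shape[0]), bad)
            cleaned = mixing[:, keep] @ sources[keep] + mean[:, None]
        else:
            cleaned = mixing @ sources + mean[:, None]
        backend_name = getattr(backend, "__name__", "custom")
    except Exception as exc:  # decomposition failure -> regression fall-back
        logger.warning("decomposition failed (%s); falling back to EOG regression", exc)
        cleaned = _regress_out_eog(eeg, eog)
        n_removed = 0
        backend_name = "eog_regression"
    out.epochs[:, eeg_rows, :] = cleaned.reshape(
        len(eeg_rows), n_ep, n_samp
    ).transpose(1, 0, 2)
    logger.info("ocular removal (%s): %d component(s) removed", backend_name, n_removed)
    return out, n_removed


# ---------------------------------------------------------------------------
# artifact flagging & qualification gate


def flag_artifacts(
    epochs: EpochSet, *, ptp_threshold_uv: float = ARTIFACT_PTP_UV
) -> EpochSet:
    """Flag epochs whose EEG peak-to-peak amplitude exceeds the bound."""
    eeg_rows = [i for i, n in enumerate(epochs.channel_names) if n not in EOG_CHANNELS]
    ptp = np.ptp(epochs.epochs[:, eeg_rows, :], axis=2).max(axis=1)
    flags = ptp > ptp_threshold_uv
    out = epochs.copy_with(artifact_flags=epochs.artifact_flags | flags)
    logger.info("flag_artifacts: %d/%d epochs flagged", int(flags.sum()), epochs.n_epochs)
    return out


def enforce_min_epochs(epochs: EpochSet, minimum: int = MIN_CLEAN_EPOCHS) -> EpochSet:
    """Keep only artifact-free epochs; refuse the subject below the gate."""
    clean_idx = np.flatnonzero(~epochs.artifact_flags)
    if clean_idx.size < minimum:
        raise MinEpochsError(epochs.subject_id, int(clean_idx.size), minimum)
    return epochs.copy_with(
        epochs=epochs.epochs[clean_idx],
        artifact_flags=np.zeros(clean_idx.size, dtype=bool),
    )


def preprocess_epochs(
    epochs: EpochSet,
    *,
    minimum_epochs: int = MIN_CLEAN_EPOCHS,
    ptp_threshold_uv: float = ARTIFACT_PTP_UV,
    ocular_backend=None,
    seed: int = 0,
) -> tuple[EpochSet, dict]:
    """Epoch-level tail of the pipeline: reference, ocular removal, gate."""
    ref = rereference_linked_mastoids(epochs)
    cleaned, n_removed = remove_ocular_artifacts(ref, backend=ocular_backend, seed=seed)
    flagged = flag_artifacts(cleaned, ptp_threshold_uv=ptp_threshold_uv)
    gated = enforce_min_epochs(flagged, minimum=minimum_epochs)
    log = dict(
        n_epochs_in=epochs.n_epochs,
        n_components_removed=n_removed,
        n_flagged=int(flagged.artifact_flags.sum()),
        n_clean=gated.n_epochs,
    )
    return gated, log
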