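"""Synthetic EEG cohorts with planted gating-by-inhibition structure.

The generator emulates the study conditions the pipeline targets: three
intervention groups (PMC, M1, Sham) of 12 stroke patients each, measured
pre and post training; 32-channel 10-20 EEG at 500 Hz (plus HEOG/VEOG),
epoched from -1 to +1 s around response onset; alpha-band (8-12 Hz)
activity with a temporal-region surge around response onset and
central-frontal suppression after it; and clinical scales (SIS-ADL, FIM,
NEADL, WMFT) anchored to published group means/SDs, with a planted
correlation between each subject's alpha-index change and outcome
change.

Signal model per epoch: 1/f background noise (exponent 1) plus
amplitude-modulated 8-12 Hz narrowband noise.  Temporal-region channels
have their alpha amplitude multiplied by a surge gain inside the surge
window; central-frontal channels are multiplied by a suppression gain
after onset.  Ocular artifacts are positive frontal-dominant transients
generated coherently on the VEOG channel.

Everything planted (latent index changes, correlations, outlier and
artifact indices) is returned in a :class:`GroundTruth` record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ConfigurationError, EpochSet
from .montage import (
    CENTRAL_FRONTAL_CHANNELS,
    EEG_CHANNELS_32,
    EOG_CHANNELS,
    MASTOID_CHANNELS,
    TEMPORAL_CHANNELS,
)

logger = logging.getLogger(__name__)

GROUPS = ("PMC", "M1", "Sham")
OUTCOMES = ("sis_adl", "fim", "neadl", "wmft_time", "wmft_strength")

#: Published group-level anchors: (pre_mean, pre_sd, post_mean, post_sd).
CLINICAL_ANCHORS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "sis_adl": {
        "PMC": (74.58, 14.88, 76.46, 13.79),
        "M1": (71.25, 17.21, 69.72, 19.47),
        "Sham": (68.96, 17.24, 72.92, 13.97),
    },
    "fim": {
        "PMC": (113.58, 9.48, 112.33, 12.78),
        "M1": (106.50, 9.47, 106.67, 12.22),
        "Sham": (106.50, 10.32, 109.42, 9.39),
    },
    "neadl": {
        "PMC": (36.92, 15.63, 42.75, 13.05),
        "M1": (33.67, 13.35, 37.33, 13.41),
        "Sham": (34.25, 13.07, 32.83, 12.22),
    },
    "wmft_time": {
        "PMC": (11.04, 6.48, 12.28, 7.42),
        "M1": (14.25, 5.22, 10.75, 4.82),
        "Sham": (9.72, 5.37, 10.56, 6.50),
    },
    "wmft_strength": {
        "PMC": (2.76, 0.67, 2.91, 0.58),
        "M1": (2.51, 0.61, 2.69, 0.65),
        "Sham": (3.06, 0.80, 3.23, 0.83),
    },
}

#: Instrument score ranges used for clipping after noise addition.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "sis_adl": (0.0, 100.0),
    "fim": (18.0, 126.0),
    "neadl": (0.0, 66.0),
    "wmft_time": (0.5, 120.0),
    "wmft_strength": (0.0, 6.0),
}

#: SD of the pre/post change as a fraction of the pre SD (not reported
#: in the anchor table; a moderate test-retest change spread).
CHANGE_SD_FRACTION = 0.4

#: dB of true temporal-index change per SD of the latent change score.
INDEX_CHANGE_DB_PER_SD = 1.5

#: SD (log scale) of the stable between-subject surge-depth trait.
SUBJECT_TRAIT_LOG_SD = 0.15

#: Displacement of planted outliers along the bivariate minor axis, in
#: robust-SD units (large enough that the box-plot rule should flag it).
OUTLIER_DISPLACEMENT = 4.5


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_per_group: int = 12
    groups: tuple[str, ...] = GROUPS
    sampling_rate: float = 500.0
    channel_names: tuple[str, ...] = EEG_CHANNELS_32 + EOG_CHANNELS
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    n_epochs_per_session: int = 60
    alpha_band: tuple[float, float] = (8.0, 12.0)
    temporal_surge_window_ms: tuple[float, float] = (-65.0, 127.0)
    surge_gain: float = 2.0
    cf_suppression_gain: float = 0.7
    planted_rho: dict = field(
        default_factory=lambda: {"PMC": 0.6, "M1": 0.0, "Sham": 0.0}
    )
    outlier_fraction: float = 0.0
    artifact_rate: float = 0.05
    background_rms_uv: float = 5.0
    alpha_rms_uv: float = 6.0
    eog_noise_rms_uv: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window
        if not (lo < 0.0 < hi):
            raise ConfigurationError("epoch_window must span response onset")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        required = set(TEMPORAL_CHANNELS) | set(CENTRAL_FRONTAL_CHANNELS) | set(
            MASTOID_CHANNELS
        )
        missing = required - set(self.channel_names)
        if missing:
            raise ConfigurationError(f"montage missing region channels: {sorted(missing)}")
        if not (0.0 <= self.outlier_fraction < 0.5):
            raise ConfigurationError("outlier_fraction must be in [0, 0.5)")
        if self.artifact_rate < 0:
            raise ConfigurationError("artifact_rate must be >= 0")
        if self.surge_gain < 1.0:
            raise ConfigurationError("surge_gain must be >= 1")
        if not (0.0 < self.cf_suppression_gain <= 1.0):
            raise ConfigurationError("cf_suppression_gain must be in (0, 1]")
        for g, rho in self._rho_map().items():
            for o, r in rho.items():
                if not (-1.0 <= r <= 1.0):
                    raise ConfigurationError(f"planted_rho[{g}][{o}] outside [-1, 1]")

    def _rho_map(self) -> dict[str, dict[str, float]]:
        """Normalise planted_rho to group -> outcome -> rho."""
        out: dict[str, dict[str, float]] = {}
        for g in self.groups:
            spec = self.planted_rho.get(g, 0.0)
            if isinstance(spec, dict):
                out[g] = {o: float(spec.get(o, 0.0)) for o in OUTCOMES}
            else:
                out[g] = {o: float(spec) for o in OUTCOMES}
        return out

    @property
    def n_samples(self) -> int:
        # half-open [lo, hi): the t = 0 sample is included exactly
        lo, hi = self.epoch_window
        return int(round((hi - lo) * self.sampling_rate))

    @property
    def time_axis(self) -> np.ndarray:
        lo, _hi = self.epoch_window
        return lo + np.arange(self.n_samples) / self.sampling_rate

    @property
    def eeg_channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c not in EOG_CHANNELS)


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream validation."""

    subjects: list[str]
    group_of: dict[str, str]
    lesion_side_of: dict[str, str]
    planted_rho: dict[str, dict[str, float]]
    latent_change: dict[str, float]  # standardised latent per subject
    true_index_change_db: dict[str, float]
    subject_trait: dict[str, float]
    session_log_gain: dict[str, dict[str, float]]  # subject -> session -> log gain mult
    outlier_subjects: list[str]
    artifact_epochs: dict[str, dict[str, list[int]]]  # subject -> session -> indices

    def to_json_dict(self) -> dict:
        return asdict(self)


def _rng_for(config: SimulationConfig, *key: int) -> np.random.Generator:
    """Deterministic, order-independent per-entity random stream."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *key]))


def _colored_noise(rng, n_samples: int, fs: float, *, exponent: float = 1.0,
                   f_lo: float = 0.5, f_hi: float = 40.0) -> np.ndarray:
    """Band-limited 1/f^exponent noise, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    band = (freqs >= f_lo) & (freqs <= f_hi)
    amp[band] = freqs[band] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_alpha(rng, n_samples: int, fs: float, band=(8.0, 12.0)) -> np.ndarray:
    """Unit-RMS narrowband noise with raised-cosine band edges (1 Hz)."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    lo, hi = band
    roll = 1.0
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    mask[inside] = 1.0
    lo_edge = (freqs >= lo - roll) & (freqs < lo)
    mask[lo_edge] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[lo_edge]) / roll))
    hi_edge = (freqs > hi) & (freqs <= hi + roll)
    mask[hi_edge] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_edge] - hi) / roll))
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    x = np.fft.irfft(mask * np.exp(1j * phases), n=n_samples)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_envelope(rng, n_samples: int, fs: float) -> np.ndarray:
    """Positive amplitude envelope, mean ~1, fluctuating below ~1 Hz."""
    slow = _colored_noise(rng, n_samples, fs, exponent=0.0, f_lo=0.1, f_hi=1.0)
    return np.clip(1.0 + 0.4 * slow, 0.25, 1.6)


def simulate_subject_epochs(
    config: SimulationConfig,
    subject_effect: float,
    session: str,
    rng: np.random.Generator,
    *,
    subject_id: str = "S00",
    lesion_side: str = "left",
    n_epochs: int | None = None,
) -> EpochSet:
    """One subject-session's response-locked epochs.

    ``subject_effect`` shifts that subject-session's temporal surge gain
    on the log scale: effective gain = surge_gain * exp(subject_effect).
    """
    n_epochs = config.n_epochs_per_session if n_epochs is None else n_epochs
    n_samp = config.n_samples
    t = config.time_axis
    fs = config.sampling_rate
    names = list(config.channel_names)
    n_ch = len(names)
    g_surge = config.surge_gain * float(np.exp(subject_effect))

    surge_lo, surge_hi = (v / 1000.0 for v in config.temporal_surge_window_ms)
    in_surge = (t >= surge_lo) & (t <= surge_hi)
    post_onset = t >= 0.0

    temporal = set(TEMPORAL_CHANNELS)
    central_frontal = set(CENTRAL_FRONTAL_CHANNELS)
    eog = set(EOG_CHANNELS)

    epochs = np.empty((n_epochs, n_ch, n_samp))
    for ep in range(n_epochs):
        for ci, name in enumerate(names):
            if name in eog:
                epochs[ep, ci] = config.eog_noise_rms_uv * _colored_noise(
                    rng, n_samp, fs, exponent=1.0, f_lo=0.1, f_hi=10.0
                )
                continue
            bg = config.background_rms_uv * _colored_noise(rng, n_samp, fs)
            alpha = _narrowband_alpha(rng, n_samp, fs, config.alpha_band)
            env = _slow_envelope(rng, n_samp, fs)
            gain = np.ones(n_samp)
            if name in temporal:
                gain[in_surge] = g_surge
            elif name in central_frontal:
                gain[post_onset] = config.cf_suppression_gain
            epochs[ep, ci] = bg + config.alpha_rms_uv * env * gain * alpha
    return EpochSet(
        subject_id=subject_id,
        session=session,
        lesion_side=lesion_side,
        epochs=epochs,
        time_axis=t,
        channel_names=names,
        sampling_rate=fs,
        reference_state="recording",
    )


def inject_artifacts(
    epochs: EpochSet,
    rate: float,
    rng: np.random.Generator,
) -> tuple[EpochSet, list[int]]:
    """Add blink-like frontal transients to a Bernoulli(rate) epoch subset.

    The blink is a ~300 ms positive half-cosine, largest on VEOG, with a
    frontal-dominant scalp topography.  Returns the contaminated copy
    and the injected epoch indices.
    """
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    out = epochs.copy_with()
    if rate == 0:
        return out, []
    topography = {"Fp1": 0.6, "Fp2": 0.6, "F7": 0.35, "F3": 0.35, "Fz": 0.35,
                  "F4": 0.35, "F8": 0.35, "FC5": 0.15, "FC1": 0.15, "FC2": 0.15,
                  "FC6": 0.15, "VEOG": 1.0, "HEOG": 0.15}
    fs = epochs.sampling_rate
    n_samp = epochs.time_axis.size
    width = int(round(0.3 * fs))
    injected = []
    for ep in range(out.n_epochs):
        if rng.random() >= rate:
            continue
        injected.append(ep)
        amp = rng.normal(300.0, 40.0)
        center = rng.integers(width, n_samp - width)
        window = np.zeros(n_samp)
        idx = np.arange(center - width // 2, center + width // 2)
        window[idx] = 0.5 * (1 - np.cos(2 * np.pi * np.arange(idx.size) / idx.size))
        for ci, name in enumerate(out.channel_names):
            w = topography.get(name, 0.03)
            out.epochs[ep, ci] += amp * w * window
    return out, injected


@dataclass
class Cohort:
    """A simulated study: epochs (optional), clinical table, ground truth."""

    config: SimulationConfig
    clinical: pd.DataFrame
    truth: GroundTruth
    epoch_sets: dict[tuple[str, str], EpochSet] | None = None


def _subject_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    ids = []
    i = 1
    for g in config.groups:
        for _ in range(config.n_per_group):
            ids.append((f"S{i:02d}", g))
            i += 1
    return ids


def subject_session_effect(truth: GroundTruth, subject: str, session: str) -> float:
    return truth.session_log_gain[subject][session]


def simulate_cohort(config: SimulationConfig, *, include_epochs: bool = True) -> Cohort:
    """Simulate the full cohort: EEG, clinical scores and ground truth.

    Each subject carries a standardised latent change score z; clinical
    outcome changes are drawn with the planted group-level correlation
    against z, and the post-session EEG surge gain is shifted by z so
    the recovered temporal-alpha change tracks it.  A fraction of
    subjects per group may be replaced by bivariate outliers displaced
    along the minor axis of the planted distribution.
    """
    if config.n_per_group < 4:
        raise ConfigurationError("n_per_group must be >= 4 (MCD undefined below)")
    rho_map = config._rho_map()
    ids = _subject_ids(config)
    rng_clin = _rng_for(config, 0)

    subjects = [s for s, _g in ids]
    group_of = {s: g for s, g in ids}
    lesion_side_of = {s: ("left" if i % 2 == 0 else "right") for i, s in enumerate(subjects)}

    latent = {s: float(rng_clin.standard_normal()) for s in subjects}
    trait = {s: float(rng_clin.normal(0.0, SUBJECT_TRAIT_LOG_SD)) for s in subjects}

    # planted outliers, per group
    outliers: list[str] = []
    for g in config.groups:
        members = [s for s in subjects if group_of[s] == g]
        k = int(round(config.outlier_fraction * len(members)))
        if k:
            chosen = list(rng_clin.choice(members, size=k, replace=False))
            outliers.extend(chosen)

    # outcome changes with planted correlation against z
    clinical_rows = []
    w_values: dict[str, dict[str, float]] = {s: {} for s in subjects}
    for s in subjects:
        g = group_of[s]
        z = latent[s]
        if s in outliers:
            z = z + OUTLIER_DISPLACEMENT / np.sqrt(2.0)
            latent[s] = float(z)
        for o in OUTCOMES:
            rho = rho_map[g][o]
            eps = rng_clin.standard_normal()
            w = rho * z + np.sqrt(max(1.0 - rho * rho, 0.0)) * eps
            if s in outliers:
                w = w - np.sign(rho if rho != 0 else 1.0) * OUTLIER_DISPLACEMENT / np.sqrt(2.0)
            w_values[s][o] = float(w)

    for s in subjects:
        g = group_of[s]
        row_pre = dict(subject_id=s, group=g, timepoint="pre")
        row_post = dict(subject_id=s, group=g, timepoint="post")
        for o in OUTCOMES:
            pre_m, pre_sd, post_m, _post_sd = CLINICAL_ANCHORS[o][g]
            lo, hi = INSTRUMENT_RANGES[o]
            pre = np.clip(rng_clin.normal(pre_m, pre_sd), lo, hi)
            change = (post_m - pre_m) + CHANGE_SD_FRACTION * pre_sd * w_values[s][o]
            post = np.clip(pre + change, lo, hi)
            row_pre[o] = float(pre)
            row_post[o] = float(post)
        clinical_rows.extend([row_pre, row_post])
    clinical = pd.DataFrame(clinical_rows)

    # session-level log-gain offsets: pre = trait, post = trait + coupled shift
    db_to_log = np.log(10.0) / 20.0
    session_log_gain = {}
    true_index_change = {}
    for s in subjects:
        delta_db = INDEX_CHANGE_DB_PER_SD * latent[s]
        session_log_gain[s] = {
            "pre": trait[s],
            "post": trait[s] + delta_db * db_to_log,
        }
        true_index_change[s] = float(delta_db)

    truth = GroundTruth(
        subjects=subjects,
        group_of=group_of,
        lesion_side_of=lesion_side_of,
        planted_rho=rho_map,
        latent_change=latent,
        true_index_change_db=true_index_change,
        subject_trait=trait,
        session_log_gain=session_log_gain,
        outlier_subjects=sorted(outliers),
        artifact_epochs={s: {"pre": [], "post": []} for s in subjects},
    )

    epoch_sets = None
    if include_epochs:
        epoch_sets = {}
        for s in subjects:
            for session in ("pre", "post"):
                epoch_sets[(s, session)] = make_subject_session(config, truth, s, session)
    return Cohort(config=config, clinical=clinical, truth=truth, epoch_sets=epoch_sets)


def index_change_table(
    cohort: Cohort,
    rng: np.random.Generator,
    *,
    measurement_noise_db: float = 0.5,
) -> pd.DataFrame:
    """Table-level EEG index changes without running the signal chain.

    Emulates what the wavelet pipeline would recover per subject: the
    temporal index change equals the planted true change plus Gaussian
    measurement noise, while the central-frontal and ratio index changes
    carry no planted coupling (pure measurement noise).  Used for
    statistical calibration of the correlation battery at scale; the
    full signal chain is validated separately.
    """
    truth = cohort.truth
    sd = INDEX_CHANGE_DB_PER_SD
    rows = []
    for s in truth.subjects:
        rows.append(
            dict(
                subject_id=s,
                group=truth.group_of[s],
                temporal=truth.true_index_change_db[s]
                + measurement_noise_db * rng.standard_normal(),
                central_frontal=sd * rng.standard_normal()
                + measurement_noise_db * rng.standard_normal(),
                ratio=sd * rng.standard_normal()
                + measurement_noise_db * rng.standard_normal(),
            )
        )
    return pd.DataFrame(rows)


def make_subject_session(
    config: SimulationConfig,
    truth: GroundTruth,
    subject: str,
    session: str,
    *,
    n_epochs: int | None = None,
) -> EpochSet:
    """(Re)generate one subject-session deterministically from the truth.

    Artifact indices are recorded in ``truth.artifact_epochs``.
    """
    sess_code = 0 if session == "pre" else 1
    sidx = truth.subjects.index(subject)
    rng = _rng_for(config, 1, sidx, sess_code)
    eset = simulate_subject_epochs(
        config,
        truth.session_log_gain[subject][session],
        session,
        rng,
        subject_id=subject,
        lesion_side=truth.lesion_side_of[subject],
        n_epochs=n_epochs,
    )
    if config.artifact_rate > 0:
        rng_art = _rng_for(config, 2, sidx, sess_code)
        eset, injected = inject_artifacts(eset, config.artifact_rate, rng_art)
        truth.artifact_epochs[subject][session] = list(map(int, injected))
    return eset
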