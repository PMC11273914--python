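"""End-to-end orchestration: simulate/load -> preprocess -> alpha power ->
indexes -> windows -> robust correlations -> mixed ANOVA.

A single declarative :class:`PipelineConfig` (YAML round-trippable)
parameterises every stage; ``run_pipeline`` executes them in order and
writes the interchange tables, a cluster JSON and a run manifest with
seeds and per-subject exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import mixed_anova
from .cluster import DEFAULT_WINDOWS_MS, cluster_permutation_test, windows_from_clusters
from .containers import ConfigurationError
from .indexes import change_scores, compute_indexes
from .montage import CENTRAL_FRONTAL_REGION, TEMPORAL_REGION
from .preprocess import (
    MinEpochsError,
    bandpass_filter,
    enforce_min_epochs,
    extract_epochs,
    flag_artifacts,
    remove_line_noise,
    remove_ocular_artifacts,
    rereference_linked_mastoids,
)
from .robust import correlation_battery
from .synthetic import OUTCOMES, SimulationConfig, make_subject_session, simulate_cohort
from .timefreq import alpha_power_map

logger = logging.getLogger(__name__)

EEG_INDEX_NAMES = ("temporal", "central_frontal", "ratio")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full pipeline run."""

    input_mode: str = "synthetic"  # "synthetic" | "files"
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    subjects: list = field(default_factory=list)  # files mode: per-subject dicts
    filter_band: tuple[float, float] = (0.5, 40.0)
    line_freq: float = 60.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    minimum_epochs: int = 50
    ptp_threshold_uv: float = 150.0
    ocular_method: str = "ica"  # "ica" | "regression" | "none"
    wavelet_cycles: float = 5.0
    pad_ratio: int = 4
    analysis_windows_ms: object = "default"  # "default" | "derive" | list of 2 windows
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    seed: int = 0
    output_dir: str = "alphagate_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self)), encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cfg = cls(**data)
        return cfg

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ConfigurationError("input_mode must be 'synthetic' or 'files'")
        if self.ocular_method not in ("ica", "regression", "none"):
            raise ConfigurationError("ocular_method must be ica/regression/none")
        self.filter_band = tuple(self.filter_band)
        self.epoch_window = tuple(self.epoch_window)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("epoch_window", self.epoch_window)
        return SimulationConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _preprocess_tail(epochs, config: PipelineConfig, seed: int):
    """Reference -> ocular removal -> flag -> gate, per configured method."""
    eset = rereference_linked_mastoids(epochs)
    n_removed = 0
    if config.ocular_method == "ica":
        eset, n_removed = remove_ocular_artifacts(eset, seed=seed)
    elif config.ocular_method == "regression":
        eset, n_removed = remove_ocular_artifacts(
            eset, backend="regression", seed=seed
        )
    eset = flag_artifacts(eset, ptp_threshold_uv=config.ptp_threshold_uv)
    eset = enforce_min_epochs(eset, minimum=config.minimum_epochs)
    return eset, n_removed


def _iter_sessions(config: PipelineConfig):
    """Yield (subject_id, group, session, EpochSet) for the configured input."""
    if config.input_mode == "synthetic":
        sim = config.simulation_config()
        cohort = simulate_cohort(sim, include_epochs=False)
        for sid in cohort.truth.subjects:
            for session in ("pre", "post"):
                eset = make_subject_session(sim, cohort.truth, sid, session)
                yield sid, cohort.truth.group_of[sid], session, eset
        return cohort
    else:
        from .io import read_array_container, read_brainvision

        for entry in config.subjects:
            sid = entry["subject_id"]
            for session in ("pre", "post"):
                path = Path(entry[f"{session}_path"])
                if path.suffix == ".vhdr":
                    raw = read_brainvision(path, entry.get("marker_map"))
                else:
                    raw = read_array_container(path.with_suffix(""))
                raw = bandpass_filter(raw, *config.filter_band)
                raw = remove_line_noise(raw, config.line_freq)
                eset = extract_epochs(
                    raw,
                    entry["lesion_side"],
                    subject_id=sid,
                    session=session,
                    window=config.epoch_window,
                )
                yield sid, entry["group"], session, eset
        return None


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages and write result tables; returns the manifest."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_ocular, seed_cluster, seed_boot = (int(s) for s in ss.generate_state(3))

    regions = tuple(TEMPORAL_REGION.channels) + tuple(CENTRAL_FRONTAL_REGION.channels)

    gen = _iter_sessions(config)
    index_rows = []
    exclusions = []
    session_logs = []
    temporal_courses = {"pre": {}, "post": {}}
    cohort = None
    windows = _resolve_windows(config)  # may be None when deriving

    # -- stage 1-3: per-session preprocessing, power and time courses
    while True:
        try:
            sid, group, session, eset = next(gen)
        except StopIteration as stop:
            cohort = stop.value
            break
        try:
            eset, n_removed = _preprocess_tail(eset, config, seed_ocular)
        except MinEpochsError as exc:
            exclusions.append(
                dict(subject_id=sid, session=session, n_clean=exc.n_clean,
                     minimum=exc.minimum)
            )
            logger.warning("excluding %s (%s): %s", sid, session, exc)
            continue
        pmap = alpha_power_map(
            eset,
            n_cycles=config.wavelet_cycles,
            pad_ratio=config.pad_ratio,
            channel_names=regions,
        )
        t_idx = pmap.channel_indices(TEMPORAL_REGION.channels)
        temporal_courses[session][sid] = pmap.power_db[t_idx].mean(axis=0)
        session_logs.append(
            dict(subject_id=sid, session=session, group=group,
                 n_clean=eset.n_epochs, n_components_removed=n_removed)
        )
        index_rows.append((sid, group, session, pmap))

    # -- stage 4: analysis windows (configured or derived by permutation)
    cluster_payload = {"mode": "default", "windows_ms": list(map(list, DEFAULT_WINDOWS_MS))}
    if windows is None:
        windows, cluster_payload = _derive_windows(
            config, temporal_courses, index_rows, seed_cluster
        )
    (out / "clusters.json").write_text(json.dumps(cluster_payload, indent=2))

    if not index_rows:
        raise RuntimeError(
            "all subject-sessions excluded by the minimum-epoch gate; "
            f"see {out / 'exclusions.csv'}"
        )

    temporal_win, cf_win = windows
    indexes = pd.DataFrame(
        [
            dict(
                subject_id=sid, group=group, session=session,
                **{
                    k: v
                    for k, v in compute_indexes(
                        pmap,
                        temporal_window_ms=temporal_win,
                        central_frontal_window_ms=cf_win,
                    ).as_row().items()
                    if k not in ("subject_id", "session")
                },
            )
            for sid, group, session, pmap in index_rows
        ]
    )
    indexes.to_csv(out / "indexes.csv", index=False)

    # -- stage 5: change scores (EEG indexes + clinical)
    excluded_ids = {e["subject_id"] for e in exclusions}
    eeg_changes = change_scores(
        indexes.drop(columns=["ratio_flagged"]), EEG_INDEX_NAMES
    )
    eeg_changes = eeg_changes[~eeg_changes["subject_id"].isin(excluded_ids)]

    if config.input_mode == "synthetic" and cohort is not None:
        clinical = cohort.clinical
        from .io import write_clinical_csv, write_ground_truth

        write_clinical_csv(clinical, out / "clinical.csv")
        write_ground_truth(cohort.truth, out / "ground_truth.json")
    else:
        clinical = _load_clinical(config)
    clin_changes = change_scores(clinical, OUTCOMES)
    changes = eeg_changes.merge(
        clin_changes.drop(columns=[c for c in ("group",) if c in clin_changes]),
        on="subject_id",
        how="inner",
    )
    changes.to_csv(out / "change_scores.csv", index=False)

    # -- stage 6: robust correlation battery (45 cells)
    battery = correlation_battery(
        changes, n_bootstrap=config.n_bootstrap, seed=seed_boot
    )
    battery.to_csv(out / "correlations.csv", index=False)

    # -- stage 7: mixed ANOVA per measure
    anova_rows = []
    long_clin = clinical.melt(
        id_vars=["subject_id", "group", "timepoint"],
        value_vars=list(OUTCOMES), var_name="measure",
    )
    long_eeg = indexes.rename(columns={"session": "timepoint"}).melt(
        id_vars=["subject_id", "group", "timepoint"],
        value_vars=list(EEG_INDEX_NAMES), var_name="measure",
    )
    for measure, sub in pd.concat([long_clin, long_eeg]).groupby("measure"):
        sub = sub[~sub["subject_id"].isin(excluded_ids)]
        try:
            res = mixed_anova(sub)
        except Exception as exc:
            logger.warning("ANOVA failed for %s: %s", measure, exc)
            continue
        for effect, vals in res.effects.items():
            anova_rows.append(dict(measure=measure, effect=effect, **vals))
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)

    pd.DataFrame(
        exclusions, columns=["subject_id", "session", "n_clean", "minimum"]
    ).to_csv(out / "exclusions.csv", index=False)

    manifest = dict(
        version=__version__,
        config=dataclasses.asdict(config),
        config_hash=_config_hash(config),
        seeds=dict(master=config.seed, ocular=seed_ocular,
                   cluster=seed_cluster, bootstrap=seed_boot),
        n_subjects=int(indexes["subject_id"].nunique()),
        n_sessions=len(session_logs),
        exclusions=exclusions,
        windows_ms=dict(temporal=list(temporal_win), central_frontal=list(cf_win)),
        n_correlation_cells=int(len(battery)),
        session_logs=session_logs,
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _resolve_windows(config: PipelineConfig):
    spec = config.analysis_windows_ms
    if spec == "default":
        return DEFAULT_WINDOWS_MS
    if spec == "derive":
        return None
    wins = [tuple(map(float, w)) for w in spec]
    if len(wins) != 2:
        raise ConfigurationError("analysis_windows_ms needs exactly two windows")
    return tuple(wins)


def _derive_windows(config, temporal_courses, index_rows, seed):
    """Paired pre-vs-post cluster test on the temporal-region time course."""
    common = sorted(set(temporal_courses["pre"]) & set(temporal_courses["post"]))
    if len(common) < 4:
        logger.warning("too few paired subjects to derive windows; using defaults")
        return DEFAULT_WINDOWS_MS, {"mode": "fallback",
                                    "windows_ms": list(map(list, DEFAULT_WINDOWS_MS))}
    pmap = index_rows[0][3]
    valid = np.flatnonzero(pmap.valid)
    t_ms = pmap.time_axis[valid] * 1000.0
    pre = np.stack([temporal_courses["pre"][s][valid] for s in common])
    post = np.stack([temporal_courses["post"][s][valid] for s in common])
    result = cluster_permutation_test(
        post, pre, t_ms, paired=True, n_perm=config.n_permutations, seed=seed
    )
    wins = windows_from_clusters(result, fallback=DEFAULT_WINDOWS_MS)
    payload = {
        "mode": "derived",
        "n_permutations": result.n_permutations,
        "threshold_t": result.cluster_forming_threshold,
        "clusters": [
            dict(start_ms=c.start_ms, end_ms=c.end_ms, mass=c.mass, p=c.p_value)
            for c in result.clusters
        ],
        "windows_ms": [list(w) for w in wins[:2]] if len(wins) >= 2
        else list(map(list, DEFAULT_WINDOWS_MS)),
    }
    if len(wins) >= 2:
        return (tuple(wins[0]), tuple(wins[-1])), payload
    logger.warning("cluster derivation yielded %d window(s); using defaults", len(wins))
    return DEFAULT_WINDOWS_MS, payload


def _load_clinical(config: PipelineConfig):
    from .io import read_clinical_csv

    paths = {e.get("clinical_path") for e in config.subjects if e.get("clinical_path")}
    if len(paths) != 1:
        raise ConfigurationError("files mode needs one clinical_path shared by subjects")
    return read_clinical_csv(paths.pop())
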