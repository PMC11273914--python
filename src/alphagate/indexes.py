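"""Theory-driven alpha indexes and pre/post change scores.

Three indexes summarise each participant-session:

* ``temporal``        — mean dB over the bilateral temporal sites in the
                        pre-response window (default -65 to 0 ms);
* ``central_frontal`` — mean dB over the central-frontal sites in the
                        post-response window (default 0 to 127 ms);
* ``ratio``           — temporal / central_frontal on the dB scale, a
                        composite whose higher values read as better
                        psychomotor efficiency under the
                        gating-by-inhibition account.

dB values are median-centred and can approach zero, so the ratio is
guarded by a denominator floor (default 0.1 dB) with a flag rather than
an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError
from .montage import (
    POST_RESPONSE_WINDOW_MS,
    PRE_RESPONSE_WINDOW_MS,
    RegionDefinition,
    CENTRAL_FRONTAL_REGION,
    TEMPORAL_REGION,
)
from .timefreq import AlphaPowerMap

logger = logging.getLogger(__name__)

RATIO_DENOMINATOR_FLOOR_DB = 0.1


def region_window_mean(
    power: AlphaPowerMap, region: RegionDefinition, window_ms
) -> float:
    """Mean dB over a region's channels and a closed time window (ms)."""
    idx = power.channel_indices(region.channels)
    lo, hi = (window_ms[0] / 1000.0, window_ms[1] / 1000.0)
    t = power.time_axis
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not sel.any():
        raise ConfigurationError(f"window {window_ms} ms selects no samples")
    if not power.valid[sel].all():
        raise ConfigurationError(
            f"window {window_ms} ms overlaps wavelet edge artefacts"
        )
    return float(power.power_db[np.ix_(idx, np.flatnonzero(sel))].mean())


def alpha_ratio(
    temporal_db: float,
    central_frontal_db: float,
    *,
    floor: float = RATIO_DENOMINATOR_FLOOR_DB,
) -> tuple[float, bool]:
    """Temporal / central-frontal ratio on dB values, with guard.

    Returns ``(ratio, flagged)``; when |denominator| < floor the ratio
    is computed against the floor (sign preserved) and flagged.
    """
    denom = central_frontal_db
    if abs(denom) < floor:
        flagged = True
        denom = floor if denom >= 0 else -floor
        logger.warning(
            "alpha_ratio: denominator %.4f dB below floor %.2f dB; substituted",
            central_frontal_db, floor,
        )
    else:
        flagged = False
    return float(temporal_db / denom), flagged


@dataclass
class AlphaIndexes:
    """The three alpha indexes for one subject x session."""

    subject_id: str
    session: str
    temporal: float
    central_frontal: float
    ratio: float
    ratio_flagged: bool
    temporal_window_ms: tuple[float, float]
    central_frontal_window_ms: tuple[float, float]

    def as_row(self) -> dict:
        return dict(
            subject_id=self.subject_id,
            session=self.session,
            temporal=self.temporal,
            central_frontal=self.central_frontal,
            ratio=self.ratio,
            ratio_flagged=self.ratio_flagged,
        )


def compute_indexes(
    power: AlphaPowerMap,
    *,
    temporal_region: RegionDefinition = TEMPORAL_REGION,
    central_frontal_region: RegionDefinition = CENTRAL_FRONTAL_REGION,
    temporal_window_ms=PRE_RESPONSE_WINDOW_MS,
    central_frontal_window_ms=POST_RESPONSE_WINDOW_MS,
) -> AlphaIndexes:
    """Reduce a power map to the three indexes."""
    t_db = region_window_mean(power, temporal_region, temporal_window_ms)
    cf_db = region_window_mean(power, central_frontal_region, central_frontal_window_ms)
    ratio, flagged = alpha_ratio(t_db, cf_db)
    return AlphaIndexes(
        subject_id=power.subject_id,
        session=power.session,
        temporal=t_db,
        central_frontal=cf_db,
        ratio=ratio,
        ratio_flagged=flagged,
        temporal_window_ms=tuple(temporal_window_ms),
        central_frontal_window_ms=tuple(central_frontal_window_ms),
    )


def change_scores(table: pd.DataFrame, metrics, *, on: str = "subject_id") -> pd.DataFrame:
    """Post-minus-pre deltas per subject for the listed metric columns.

    ``table`` holds one row per subject x session with a ``session`` (or
    ``timepoint``) column; subjects missing either session are dropped
    with a logged exclusion.  Non-metric columns that are constant
    within subject (e.g. ``group``) are carried through.
    """
    tab = table.copy()
    sess_col = "session" if "session" in tab.columns else "timepoint"
    if sess_col not in tab.columns:
        raise ConfigurationError("table needs a session/timepoint column")
    pre = tab[tab[sess_col] == "pre"].set_index(on)
    post = tab[tab[sess_col] == "post"].set_index(on)
    common = pre.index.intersection(post.index)
    dropped = set(pre.index).symmetric_difference(post.index)
    if dropped:
        logger.warning("change_scores: dropped subjects missing a session: %s",
                       sorted(dropped))
    rows = []
    carry = [c for c in tab.columns if c not in set(metrics) | {on, sess_col}]
    for sid in common:
        row = {on: sid}
        for c in carry:
            row[c] = pre.loc[sid, c]
        for m in metrics:
            row[m] = float(post.loc[sid, m]) - float(pre.loc[sid, m])
        rows.append(row)
    return pd.DataFrame(rows)
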