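"""Cluster-based nonparametric permutation test over time.

Controls the family-wise error of a pointwise t-test across a time axis
by clustering adjacent supra-threshold samples and referring each
cluster's summed t ("mass") to the permutation null distribution of the
maximum absolute cluster mass.  Paired designs permute by sign flips of
the within-subject differences; independent designs shuffle the group
labels.  For small paired samples the full set of 2^n sign patterns can
be enumerated, making the p-values exact.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    start_index: int
    end_index: int  # inclusive
    start_ms: float
    end_ms: float
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_forming_threshold: float
    threshold_p: float
    seed: int | None
    exact: bool = False
    t_observed: np.ndarray | None = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Pointwise paired t over subjects (axis 0); zero-variance -> t = 0."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    n_degen = int((~ok).sum())
    if n_degen:
        logger.warning("paired t: %d timepoint(s) with zero variance set to 0", n_degen)
    return t


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1 / na + 1 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    t = np.zeros_like(diff)
    ok = denom > 0
    t[ok] = diff[ok] / denom[ok]
    return t


def _find_clusters(t: np.ndarray, thresh: float):
    """Runs of adjacent samples with |t| > thresh and consistent sign."""
    sign = np.where(t > thresh, 1, np.where(t < -thresh, -1, 0))
    clusters = []
    start = None
    cur = 0
    for i, s in enumerate(sign):
        if s != 0 and s == cur:
            continue
        if start is not None and cur != 0:
            clusters.append((start, i - 1))
        start = i if s != 0 else None
        cur = s
    if start is not None and cur != 0:
        clusters.append((start, len(sign) - 1))
    return clusters


def _max_cluster_mass(t: np.ndarray, thresh: float) -> float:
    clusters = _find_clusters(t, thresh)
    if not clusters:
        return 0.0
    return max(abs(t[a : b + 1].sum()) for a, b in clusters)


def _max_cluster_mass_batch(t_rows: np.ndarray, thresh: float) -> np.ndarray:
    """Max |cluster mass| per row of a (n_rows, n_time) t matrix.

    Rows are separated by an interleaved zero column so supra-threshold
    runs never span rows; one reduceat pass then sums every run.
    """
    n_rows, n_time = t_rows.shape
    padded = np.concatenate(
        [t_rows, np.zeros((n_rows, 1))], axis=1
    ).ravel()
    sign = np.where(padded > thresh, 1, np.where(padded < -thresh, -1, 0))
    change = np.flatnonzero(np.diff(sign) != 0) + 1
    starts = np.concatenate([[0], change])
    masses = np.add.reduceat(padded, starts)
    seg_sign = sign[starts]
    seg_row = starts // (n_time + 1)
    out = np.zeros(n_rows)
    active = seg_sign != 0
    np.maximum.at(out, seg_row[active], np.abs(masses[active]))
    return out


def cluster_permutation_test(
    condition_a: np.ndarray,
    condition_b: np.ndarray,
    time_axis_ms: np.ndarray,
    *,
    paired: bool = True,
    n_perm: int = 1000,
    threshold_p: float = 0.05,
    seed: int | None = None,
    exact: bool = False,
) -> ClusterTestResult:
    """Cluster permutation test between two conditions (subjects x time).

    Parameters
    ----------
    condition_a, condition_b : ndarray (n_subjects, n_time)
        Matched time axes; for ``paired`` the subject rows correspond.
    threshold_p : float
        Two-sided pointwise p defining the cluster-forming t threshold.
    exact : bool
        For paired designs with <= 16 subjects, enumerate all 2^n sign
        patterns instead of Monte-Carlo sampling.
    """
    a = np.asarray(condition_a, dtype=float)
    b = np.asarray(condition_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("conditions must be subjects x time with equal time axes")
    time_axis_ms = np.asarray(time_axis_ms, dtype=float)
    if time_axis_ms.size != a.shape[1]:
        raise ValueError("time axis length mismatch")
    if paired and a.shape[0] != b.shape[0]:
        raise ValueError("paired test needs equal subject counts")
    if n_perm < 100 and not exact:
        raise ValueError("n_perm must be >= 100")

    if paired:
        diffs = a - b
        n = diffs.shape[0]
        df = n - 1
        thresh = float(stats.t.ppf(1 - threshold_p / 2, df))
        t_obs = _paired_t(diffs)
        # Sufficient statistics are invariant under sign flips:
        # sum(d_i^2) per timepoint is fixed, only the signed mean moves.
        sumsq = (diffs**2).sum(axis=0)
        if exact:
            if n > 16:
                raise ValueError("exact enumeration limited to n <= 16")
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
            n_eff = signs.shape[0]
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice((1.0, -1.0), size=(n_perm, n))
            n_eff = n_perm
        means = signs @ diffs / n  # (n_perm, n_time)
        var = (sumsq[None, :] - n * means**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_null = np.where(var > 0, means / np.sqrt(var / n), 0.0)
        null_max = _max_cluster_mass_batch(t_null, thresh)
    else:
        na, nb = a.shape[0], b.shape[0]
        df = na + nb - 2
        thresh = float(stats.t.ppf(1 - threshold_p / 2, df))
        t_obs = _independent_t(a, b)
        pooled = np.vstack([a, b])
        rng = np.random.default_rng(seed)
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(na + nb)
            t_p = _independent_t(pooled[perm[:na]], pooled[perm[na:]])
            null_max[i] = _max_cluster_mass(t_p, thresh)
        n_eff = n_perm

    clusters = []
    for a_i, b_i in _find_clusters(t_obs, thresh):
        mass = float(t_obs[a_i : b_i + 1].sum())
        if exact:
            p = float((null_max >= abs(mass)).mean())
            p = max(p, 1.0 / n_eff)
        else:
            p = float((1 + (null_max >= abs(mass)).sum()) / (1 + n_eff))
        clusters.append(
            Cluster(
                start_index=a_i,
                end_index=b_i,
                start_ms=float(time_axis_ms[a_i]),
                end_ms=float(time_axis_ms[b_i]),
                mass=mass,
                p_value=p,
            )
        )
    clusters.sort(key=lambda c: c.start_index)
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_eff,
        cluster_forming_threshold=thresh,
        threshold_p=threshold_p,
        seed=seed,
        exact=exact,
        t_observed=t_obs,
    )


#: Fall-back analysis windows (ms) used when no cluster reaches
#: significance: the pre-response and post-response intervals the
#: pipeline was designed around.
DEFAULT_WINDOWS_MS: tuple[tuple[float, float], ...] = ((-65.0, 0.0), (0.0, 127.0))


def windows_from_clusters(
    result: ClusterTestResult,
    alpha: float = 0.05,
    *,
    fallback=None,
) -> list[tuple[float, float]]:
    """Time windows (ms) of clusters significant at ``alpha``.

    Returns ``fallback`` (if given) when no cluster survives, letting
    downstream index extraction proceed with configured defaults.
    """
    wins = [(c.start_ms, c.end_ms) for c in result.significant(alpha)]
    if not wins and fallback is not None:
        return [tuple(w) for w in fallback]
    return wins
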