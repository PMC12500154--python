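"""Cluster-based sign-flip permutation test for paired participant series.

For a participants × time matrix of paired differences, a pointwise
one-sample t-test is thresholded at a two-sided alpha; maximal runs of
adjacent supra-threshold samples with a common t-sign form clusters
scored by their mass (sum of t values).  The null distribution of the
maximum absolute cluster mass is built by flipping the sign of each
participant's whole series independently (the participant-level
condition swap for a paired design), and each observed cluster's
p-value is the proportion of permutations whose maximum mass reaches
it.  A 2D (frequency × time) variant uses 4-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats
from scipy.ndimage import label as ndi_label

from . import defaults

log = logging.getLogger(__name__)


@dataclass
class Cluster:
    start: int  # first sample index (1D) — for 2D clusters see `indices`
    stop: int  # last sample index, inclusive
    mass: float  # sum of t values in the cluster
    sign: int
    p_value: float | None = None
    indices: np.ndarray | None = None  # 2D clusters: flat indices

    @property
    def p_str(self) -> str:
        if self.p_value is None:
            return "n/a"
        return f"{self.p_value:.4g}" if self.p_value > 0 else "< 1/n_perm"


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray
    n_permutations: int
    alpha: float
    t_obs: np.ndarray
    exhaustive: bool = False

    @property
    def min_p(self) -> float | None:
        return min((c.p_value for c in self.clusters), default=None)


def _t_onesample(data: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t across axis 0; zero-variance points → 0.

    Zero-variance points have no defined t statistic; they are treated
    as non-significant (and logged) rather than erred on.
    """
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    bad = ~np.isfinite(t)
    if bad.any():
        log.info("t statistic undefined at %d points (zero variance); set non-significant",
                 int(bad.sum()))
        t[bad] = 0.0
    return t


def find_clusters(
    participant_series: np.ndarray, alpha: float = defaults.CLUSTER_ALPHA
) -> tuple[list[Cluster], np.ndarray]:
    """Observed clusters of a participants × time matrix.

    Returns (clusters, pointwise t).  Requires ≥ 2 participants.
    """
    data = np.asarray(participant_series, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2D participants × time array with ≥ 2 participants")
    n = data.shape[0]
    t = _t_onesample(data)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    code = np.where(t > tcrit, 1, np.where(t < -tcrit, -1, 0))
    clusters: list[Cluster] = []
    start = None
    for i in range(code.size + 1):
        c = code[i] if i < code.size else 0
        if start is not None and (i == code.size or c != code[start]):
            clusters.append(
                Cluster(start=start, stop=i - 1, mass=float(t[start:i].sum()),
                        sign=int(code[start]))
            )
            start = None
        if c != 0 and start is None:
            start = i
    return clusters, t


def _max_cluster_mass_rows(t: np.ndarray, tcrit: float) -> np.ndarray:
    """Max |cluster mass| per row of a permutations × time t matrix.

    Vectorized run detection: rows are padded with a zero column and
    flattened so that every same-signed supra-threshold run lies within
    one row; masses are cumulative-sum differences over run boundaries.
    """
    n_perm, n_time = t.shape
    code = np.where(t > tcrit, 1, np.where(t < -tcrit, -1, 0)).astype(np.int8)
    code = np.concatenate([code, np.zeros((n_perm, 1), np.int8)], axis=1).ravel()
    tv = np.concatenate([t, np.zeros((n_perm, 1))], axis=1).ravel()
    change = np.flatnonzero(np.diff(code) != 0) + 1
    bounds = np.concatenate(([0], change, [code.size]))
    run_vals = code[bounds[:-1]]
    csum = np.concatenate(([0.0], np.cumsum(tv)))
    masses = csum[bounds[1:]] - csum[bounds[:-1]]
    keep = run_vals != 0
    rows = bounds[:-1][keep] // (n_time + 1)
    out = np.zeros(n_perm)
    np.maximum.at(out, rows, np.abs(masses[keep]))
    return out


def permutation_test(
    participant_series: np.ndarray,
    n_perm: int = defaults.N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    alpha: float = defaults.CLUSTER_ALPHA,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Sign-flip cluster permutation test on participants × time data.

    Each permutation multiplies every participant's series by an
    independent ±1 before recomputing the pointwise t statistic and the
    maximum absolute cluster mass.  Cluster p = proportion of
    permutations whose max |mass| ≥ the observed cluster's |mass| (the
    literal proportion rule, so p = 0 is possible and rendered as
    "< 1/n_perm").  With ``exhaustive=True`` all 2**n sign patterns are
    enumerated instead (n ≤ 20).
    """
    data = np.asarray(participant_series, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2D participants × time array with ≥ 2 participants")
    n, n_time = data.shape
    if not exhaustive and n_perm < 100:
        log.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    clusters, t_obs = find_clusters(data, alpha)
    tcrit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 1))

    ssq = np.sum(data**2, axis=0)  # invariant under sign flips
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to ≤ 20 participants")
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        n_perm = signs.shape[0]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))

    null_max = np.empty(n_perm)
    chunk = max(1, 5_000_000 // max(1, n_time))  # ~5M elements per block
    for a in range(0, n_perm, chunk):
        s = signs[a : a + chunk]
        mean = s @ data / n
        with np.errstate(divide="ignore", invalid="ignore"):
            var = (ssq - n * mean**2) / (n - 1)
            var = np.maximum(var, 0.0)
            t_perm = mean / np.sqrt(var / n)
        t_perm[~np.isfinite(t_perm)] = 0.0
        null_max[a : a + s.shape[0]] = _max_cluster_mass_rows(t_perm, tcrit)

    for c in clusters:
        c.p_value = float(np.mean(null_max >= abs(c.mass)))
    return ClusterTestResult(
        clusters=clusters, null_max_mass=null_max, n_permutations=n_perm,
        alpha=alpha, t_obs=t_obs, exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# 2D (frequency × time) variant for time-frequency maps


def find_clusters_2d(
    participant_maps: np.ndarray, alpha: float = defaults.CLUSTER_ALPHA
) -> tuple[list[Cluster], np.ndarray]:
    """Clusters over a participants × freq × time stack, 4-connectivity."""
    data = np.asarray(participant_maps, dtype=float)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need participants × freq × time with ≥ 2 participants")
    n = data.shape[0]
    t = _t_onesample(data.reshape(n, -1)).reshape(data.shape[1:])
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    clusters: list[Cluster] = []
    for sign, mask in ((1, t > tcrit), (-1, t < -tcrit)):
        labels, n_lab = ndi_label(mask, structure=structure)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(labels.ravel() == k)
            clusters.append(Cluster(start=int(idx.min()), stop=int(idx.max()),
                                    mass=float(t.ravel()[idx].sum()), sign=sign, indices=idx))
    return clusters, t


def permutation_test_2d(
    participant_maps: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = defaults.CLUSTER_ALPHA,
) -> ClusterTestResult:
    """Sign-flip cluster test on participants × freq × time maps."""
    data = np.asarray(participant_maps, dtype=float)
    clusters, t_obs = find_clusters_2d(data, alpha)
    n = data.shape[0]
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        s = rng.choice((1.0, -1.0), size=(n, 1, 1))
        t = _t_onesample((data * s).reshape(n, -1)).reshape(data.shape[1:])
        best = 0.0
        for sign, mask in ((1, t > tcrit), (-1, t < -tcrit)):
            labels, n_lab = ndi_label(mask, structure=structure)
            if n_lab:
                sums = np.abs(np.bincount(labels.ravel(), weights=t.ravel())[1:])
                best = max(best, float(sums.max()))
        null_max[i] = best
    for c in clusters:
        c.p_value = float(np.mean(null_max >= abs(c.mass)))
    return ClusterTestResult(clusters=clusters, null_max_mass=null_max,
                             n_permutations=n_perm, alpha=alpha, t_obs=t_obs)
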