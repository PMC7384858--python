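"""Cross-condition epoch correlations with shuffle nulls, and the
cross-temporal correlation matrix.

Epoch vectors pair each neuron x grasp entry of the execution population
with its observation counterpart (length N x C, C = 2 grasps); the shuffle
null permutes the observation vector to destroy within-unit relationships.
The cross-temporal matrix correlates unsmoothed 50 ms-binned PSTHs across
neurons at every pair of timepoints and is symmetrized by averaging with
its transpose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class EpochCorrelation:
    epoch: str
    r: float | None  # None when undefined (zero variance)
    p_parametric: float | None
    null: np.ndarray | None = None
    null_95: float | None = None
    p_permutation: float | None = None

    @property
    def significant_vs_null(self) -> bool | None:
        if self.r is None or self.null_95 is None:
            return None
        return self.r > self.null_95


@dataclass
class CrossTemporalMatrix:
    values: np.ndarray  # (T, T), NaN where undefined
    time_axis: np.ndarray
    bin_width: float
    symmetrized: bool = True


def pearson(x: np.ndarray, y: np.ndarray, method: str = "pearson"):
    """r and two-sided p; (None, None) when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return None, None
    if method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def epoch_corr(
    exe_vector: np.ndarray,
    obs_vector: np.ndarray,
    epoch: str = "",
    method: str = "pearson",
) -> EpochCorrelation:
    r, p = pearson(exe_vector, obs_vector, method)
    return EpochCorrelation(epoch=epoch, r=r, p_parametric=p)


def shuffle_null(
    exe_vector: np.ndarray,
    obs_vector: np.ndarray,
    n_shuffles: int = 1000,
    seed=0,
    within_grasp_blocks: int | None = None,
    method: str = "pearson",
) -> tuple[np.ndarray, float]:
    """Null r distribution from permutations of the observation vector.

    By default the full N*C vector is permuted; pass
    ``within_grasp_blocks=C`` to permute within equal-length grasp blocks
    instead.  Returns (null values, 95th percentile).  Undefined null draws
    (zero variance) are impossible since permutation preserves the value
    multiset.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exe_vector = np.asarray(exe_vector, dtype=float)
    obs_vector = np.asarray(obs_vector, dtype=float)
    n = obs_vector.size
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        if within_grasp_blocks:
            blocks = np.split(np.arange(n), within_grasp_blocks)
            perm = np.concatenate([rng.permutation(b) for b in blocks])
        else:
            perm = rng.permutation(n)
        r, _ = pearson(exe_vector, obs_vector[perm], method)
        null[i] = r if r is not None else np.nan
    return null, float(np.nanpercentile(null, 95))


def epoch_corr_with_null(
    exe_vector, obs_vector, epoch: str = "", n_shuffles: int = 1000, seed=0,
    method: str = "pearson",
) -> EpochCorrelation:
    res = epoch_corr(exe_vector, obs_vector, epoch, method)
    if res.r is None:
        return res
    null, thr = shuffle_null(exe_vector, obs_vector, n_shuffles, seed, method=method)
    res.null = null
    res.null_95 = thr
    res.p_permutation = float(np.mean(null >= res.r))
    return res


def cross_temporal(
    exe_psth: np.ndarray,
    obs_psth: np.ndarray,
    time_axis: np.ndarray | None = None,
    bin_width: float = 50.0,
) -> CrossTemporalMatrix:
    """T x T cross-condition correlation matrix.

    entry (t1, t2) = Pearson r across neurons between execution activity at
    t1 and observation activity at t2, averaged with the transposed order.
    Inputs are N x T and must be unsmoothed (e.g. 50 ms non-overlapping
    bins) to avoid kernel-induced correlations.  Zero-variance timepoints
    yield NaN entries.
    """
    x = np.asarray(exe_psth, dtype=float)
    y = np.asarray(obs_psth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("PSTHs must share shape (neurons x time)")
    n, t = x.shape
    xc = x - x.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    xs = x.std(axis=0)
    ys = y.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = (xc.T @ yc) / n / np.outer(xs, ys)
    m[:, ys == 0] = np.nan
    m[xs == 0, :] = np.nan
    sym = 0.5 * (m + m.T)
    if time_axis is None:
        time_axis = np.arange(t) * bin_width
    return CrossTemporalMatrix(values=sym, time_axis=np.asarray(time_axis),
                               bin_width=bin_width)
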