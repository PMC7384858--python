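"""PCA subspace fitting, the alignment index, and its null distributions.

The alignment index of target activity ``X`` (T x N, mean-centred per
neuron) against a reference orthonormal basis ``V_ref`` (N x k) is

    a = tr(V_ref' cov(X) V_ref) / tr(V_tgt' cov(X) V_tgt)

where ``V_tgt`` holds the top-k eigenvectors of ``cov(X)``; the denominator
equals the sum of the top-k eigenvalues, i.e. the maximum variance k axes
could capture.  ``a`` is bounded in [0, 1], equals 1 when target and
reference data overlap perfectly and 0 when they are fully orthogonal, and
is invariant to global scaling and to the covariance normalization (T vs
T-1), which cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: subspace fitting windows (ms relative to canonical events)
MOVEMENT_WINDOW = ("HPR", -50.0, "HO", 500.0)  # HPR-50 -> HO+500
OBSERVATION_WINDOW = ("GoNogo", 100.0, "GoNogo", 400.0)  # Go+100 -> Go+400


@dataclass
class SubspaceModel:
    basis: np.ndarray  # (N, k), orthonormal columns
    k: int
    mean: np.ndarray  # (N,) per-neuron time-mean used for centering
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    variance_fractions: np.ndarray  # (k,)
    window: str = ""
    grasp: str = ""
    condition: str = ""

    @property
    def captured_variance(self) -> float:
        return float(self.variance_fractions.sum())


@dataclass
class AlignmentResult:
    a: float
    numerator: float
    denominator: float
    null: np.ndarray | None = None
    p: float | None = None


@dataclass
class CrossGraspBootstrap:
    alignments: dict[str, np.ndarray]  # condition -> (n_draws,)
    p: float  # proportion of execution draws > paired observation draws
    n_discarded: int = 0


def _center_cols(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


def time_covariance(x: np.ndarray) -> np.ndarray:
    """(N, N) covariance across time of a T x N matrix (T-1 denominator)."""
    xc = _center_cols(x)
    return xc.T @ xc / max(x.shape[0] - 1, 1)


def fit_subspace(x: np.ndarray, k: int = 3, **meta) -> SubspaceModel:
    """Top-k principal axes of a T x N activity matrix.

    Column signs are fixed so each axis's largest-magnitude coordinate is
    positive, making the decomposition deterministic up to eigenvalue ties.
    """
    x = np.asarray(x, dtype=float)
    t, n = x.shape
    if t <= k:
        raise ValueError(f"need more timepoints than k={k}, got T={t}")
    cov = time_covariance(x)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    rank = int((evals > evals[0] * 1e-12).sum()) if evals[0] > 0 else 0
    if rank < k:
        raise ValueError(f"data rank {rank} < requested k={k}")
    v = evecs[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    total = evals.sum()
    return SubspaceModel(
        basis=v,
        k=k,
        mean=x.mean(axis=0),
        eigenvalues=evals,
        variance_fractions=evals[:k] / total,
        **meta,
    )


def alignment_index(
    x_target: np.ndarray, reference: SubspaceModel | np.ndarray, k: int | None = None
) -> AlignmentResult:
    """Alignment of target activity (T x N) with a reference basis."""
    v_ref = reference.basis if isinstance(reference, SubspaceModel) else reference
    v_ref = np.asarray(v_ref, dtype=float)
    x_target = np.asarray(x_target, dtype=float)
    if x_target.shape[1] != v_ref.shape[0]:
        raise ValueError(
            f"neuron mismatch: target has {x_target.shape[1]}, "
            f"reference basis {v_ref.shape[0]}"
        )
    if k is None:
        k = v_ref.shape[1]
    cov = time_covariance(x_target)
    return _alignment_from_cov(cov, v_ref, k)


def _alignment_from_cov(cov, v_ref, k) -> AlignmentResult:
    num = float(np.trace(v_ref.T @ cov @ v_ref))
    evals = np.linalg.eigvalsh(cov)
    den = float(np.sort(evals)[::-1][:k].sum())
    if den <= 0:
        raise ValueError("target covariance has no variance in top-k axes")
    a = num / den
    return AlignmentResult(a=float(np.clip(a, 0.0, 1.0)), numerator=num,
                           denominator=den)


def haar_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Haar-uniform random N x k orthonormal frame (QR with sign fix)."""
    g = rng.standard_normal((n, k))
    q, r = np.linalg.qr(g)
    return q * np.sign(np.diag(r))


def random_orthonormal_null(
    x_target: np.ndarray,
    k: int,
    n_draws: int = 10_000,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null alignment distribution from Haar-random orthonormal subspaces.

    Each draw orthonormalizes an N x k standard-Gaussian matrix and computes
    the alignment of the target data with it.  The p-value is the proportion
    of null values strictly greater than *observed* (resolution 1/n_draws).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_target = np.asarray(x_target, dtype=float)
    n = x_target.shape[1]
    if n < k:
        raise ValueError("need at least k neurons")
    cov = time_covariance(x_target)
    evals = np.linalg.eigvalsh(cov)
    den = float(np.sort(evals)[::-1][:k].sum())
    null = np.empty(n_draws)
    for i in range(n_draws):
        v = haar_orthonormal(rng, n, k)
        null[i] = np.trace(v.T @ cov @ v) / den
    p = None if observed is None else float(np.mean(null > observed))
    return null, p


def aligned_with_null(
    x_target: np.ndarray,
    reference: SubspaceModel,
    n_draws: int = 10_000,
    seed=0,
) -> AlignmentResult:
    """Alignment index plus its random-orthonormal null and p-value."""
    res = alignment_index(x_target, reference)
    null, p = random_orthonormal_null(
        x_target, reference.k, n_draws=n_draws, seed=seed, observed=res.a
    )
    res.null = null
    res.p = p
    return res


def bootstrap_cross_grasp(
    rates: dict,
    conditions: tuple[str, str] = ("execution", "observation"),
    grasp_fit: str = "PG",
    grasp_target: str = "WHG",
    k: int = 3,
    fraction: float = 0.5,
    n_draws: int = 1000,
    seed=0,
) -> CrossGraspBootstrap:
    """Cross-grasp alignment distributions from neuron subsampling.

    ``rates[(condition, grasp)]`` are T x N matrices over identical neurons.
    Per draw, the same random neuron subset is used in both conditions
    (draws are paired); the one-sided p is the proportion of execution draws
    strictly greater than their paired observation draws.  Rank-deficient
    draws are discarded and resampled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rates[(conditions[0], grasp_fit)].shape[1]
    m = int(np.floor(n * fraction))
    if m < k:
        raise ValueError("subsample too small to support k axes")
    out = {c: np.empty(n_draws) for c in conditions}
    discarded = 0
    for d in range(n_draws):
        while True:
            idx = (np.arange(n) if m == n
                   else rng.choice(n, size=m, replace=False))
            try:
                for c in conditions:
                    ref = fit_subspace(rates[(c, grasp_fit)][:, idx], k)
                    out[c][d] = alignment_index(
                        rates[(c, grasp_target)][:, idx], ref
                    ).a
            except ValueError:
                discarded += 1
                continue
            break
    a, b = conditions
    p = float(np.mean(out[a] > out[b]))
    return CrossGraspBootstrap(alignments=out, p=p, n_discarded=discarded)


# ---------------------------------------------------------------------------
# Full per-population suite
# ---------------------------------------------------------------------------

@dataclass
class ProjectionSuiteResult:
    """Per-grasp movement- and observation-subspace analyses."""

    movement: dict = field(default_factory=dict)  # grasp -> AlignmentResult (obs)
    observation: dict = field(default_factory=dict)  # grasp -> {cond: AlignmentResult}
    models: dict = field(default_factory=dict)
    trajectories: dict = field(default_factory=dict)  # (label, grasp) -> (T, k)


def _slice_window(tensor, spec):
    ev0, off0, ev1, off1 = spec
    t0 = tensor.canonical_events[ev0] + off0
    t1 = tensor.canonical_events[ev1] + off1
    return tensor.window(t0, t1)


def condition_projection_suite(
    tensors: dict,
    k: int = 3,
    n_draws: int = 10_000,
    seed: int = 0,
    grasps: tuple[str, ...] = ("PG", "WHG"),
    min_nogo_trials_ok: bool = True,
) -> ProjectionSuiteResult:
    """Movement- and observation-subspace analyses for one population.

    ``tensors`` maps (condition, grasp) to multi-aligned, soft-normalized
    RateTensors with canonical event metadata.  For each grasp:

    - movement analysis: fit the execution subspace on the peri-movement
      window, project observation activity, null + p;
    - observation analysis: fit the observation subspace on the 100-400 ms
      post-Go window, project execution and NoGo activity, each with its own
      null.
    """
    rng = np.random.default_rng(seed)
    res = ProjectionSuiteResult()
    for grasp in grasps:
        exe = tensors[("execution", grasp)]
        obs = tensors[("observation", grasp)]
        x_exe_mov = _slice_window(exe, MOVEMENT_WINDOW).values.T
        x_obs_mov = _slice_window(obs, MOVEMENT_WINDOW).values.T
        ref_mov = fit_subspace(x_exe_mov, k, window="movement",
                               grasp=grasp, condition="execution")
        res.models[("movement", grasp)] = ref_mov
        res.movement[grasp] = aligned_with_null(
            x_obs_mov, ref_mov, n_draws=n_draws, seed=rng
        )
        res.trajectories[("execution-movement", grasp)] = (
            _center_cols(x_exe_mov) @ ref_mov.basis
        )
        res.trajectories[("observation-movement", grasp)] = (
            _center_cols(x_obs_mov) @ ref_mov.basis
        )

        x_obs_win = _slice_window(obs, OBSERVATION_WINDOW).values.T
        ref_obs = fit_subspace(x_obs_win, k, window="observation",
                               grasp=grasp, condition="observation")
        res.models[("observation", grasp)] = ref_obs
        proj = {}
        x_exe_win = _slice_window(exe, OBSERVATION_WINDOW).values.T
        proj["execution"] = aligned_with_null(
            x_exe_win, ref_obs, n_draws=n_draws, seed=rng
        )
        if min_nogo_trials_ok and ("nogo", grasp) in tensors:
            x_nogo_win = _slice_window(
                tensors[("nogo", grasp)], OBSERVATION_WINDOW
            ).values.T
            proj["nogo"] = aligned_with_null(
                x_nogo_win, ref_obs, n_draws=n_draws, seed=rng
            )
            res.trajectories[("nogo-observation", grasp)] = (
                _center_cols(x_nogo_win) @ ref_obs.basis
            )
        res.observation[grasp] = proj
        res.trajectories[("observation-observation", grasp)] = (
            _center_cols(x_obs_win) @ ref_obs.basis
        )
        res.trajectories[("execution-observation", grasp)] = (
            _center_cols(x_exe_win) @ ref_obs.basis
        )
    return res
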