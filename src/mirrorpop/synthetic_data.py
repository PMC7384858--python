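"""Seeded synthetic sessions with recorded ground truth.

The generator plants:

- smooth latent trajectories (sums of Gaussian bumps anchored to the
  Go/HPR/DO/HO events) driving an inhomogeneous-Poisson population;
- a controllable degree of subspace sharing between conditions: the
  observation loading basis is ``cos(theta) W_exe Q + sin(theta) W_perp Q``
  with ``theta = arccos(sqrt(rho))``, so every principal angle between the
  execution and observation loading subspaces equals ``theta`` exactly;
- condition amplitude gains (observation ~ 1/3.5 of execution by default);
- lognormal event-time distributions (monkey vs human actor);
- EMG bursts confined to execution trials, with optional injected
  contamination of passive trials for exclusion-procedure tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mirrorpop.dataio import EmgBlock, NeuronMeta, SessionBundle, TrialRecord


class ConfigError(ValueError):
    pass


#: (mean, sd) in ms for lognormal inter-event intervals, by actor
DEFAULT_INTERVALS = {
    "monkey": {"RT": (310.0, 25.0), "MT": (306.0, 20.0), "DO_HO": (100.0, 10.0),
               "HOFF_HPN": (400.0, 30.0)},
    "human": {"RT": (450.0, 40.0), "MT": (430.0, 35.0), "DO_HO": (120.0, 12.0),
              "HOFF_HPN": (450.0, 40.0)},
}

HOLD_MS = 1000.0  # HO -> HOFF
LCD_TO_OBJCUE = 250.0
OBJCUE_TO_GO = 800.0
PRE_LCD = 700.0  # recorded span before LCDon
POST_LAST = 600.0  # recorded span after the last event
NOGO_POST = 1000.0  # NoGo trial length after the cue


@dataclass
class GroundTruthConfig:
    n_neurons: int = 40
    k_latent: int = 3
    rho_exe_obs: float = 0.8  # subspace overlap, execution <-> observation
    rho_obs_nogo: float = 0.5  # subspace overlap, observation <-> nogo
    gain_exe: float = 1.0
    gain_obs: float = 1.0 / 3.5
    gain_nogo: float = 0.3
    baseline_lo: float = 5.0  # spikes/s
    baseline_hi: float = 20.0
    latent_scale: float = 30.0  # spikes/s per unit loading at bump peak
    trials_per_condition: int = 20  # per condition x grasp
    intervals: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                     DEFAULT_INTERVALS.items()})
    emg: bool = True
    n_muscles: int = 12
    emg_rate: float = 1000.0  # Hz
    emg_noise_sd: float = 1.0
    emg_burst_gain: float = 8.0
    dead_muscles: tuple[int, ...] = ()  # planted noisy channels (no burst)
    area: str = "M1"
    identity: str = "PTN"
    session_id: str = "synthetic"
    conditions: tuple[str, ...] = ("execution", "observation", "nogo")
    grasps: tuple[str, ...] = ("PG", "WHG")

    def validate(self) -> None:
        if not (0.0 <= self.rho_exe_obs <= 1.0 and 0.0 <= self.rho_obs_nogo <= 1.0):
            raise ConfigError("rho must lie in [0, 1]")
        if min(self.gain_exe, self.gain_obs, self.gain_nogo) < 0:
            raise ConfigError("condition gains must be >= 0")
        if self.baseline_lo <= 0 or self.baseline_hi < self.baseline_lo:
            raise ConfigError("baseline rates must be positive")
        if self.trials_per_condition < 1:
            raise ConfigError("need at least one trial per condition")
        if not 1 <= self.k_latent <= self.n_neurons:
            raise ConfigError("k_latent must be in [1, n_neurons]")
        if 3 * self.k_latent > self.n_neurons:
            raise ConfigError("n_neurons too small to plant three subspaces")


@dataclass
class GroundTruthRecord:
    loadings: dict[str, np.ndarray]  # condition -> (N, k) orthonormal
    baselines: np.ndarray  # (N,)
    bump_params: dict  # per grasp: list of (event, delay_ms, sd_ms, (k,) amps)
    planted_angles: dict[str, float]  # radians, e.g. "exe_obs"
    event_times: dict[int, dict[str, float]]  # per trial
    spike_counts: dict[int, np.ndarray]  # per trial, (N,) generator tally
    config: GroundTruthConfig = None


def _lognormal_ms(rng, mean, sd, size):
    """Lognormal draws with the requested arithmetic mean/SD (ms)."""
    if sd == 0:
        return np.full(size, float(mean))
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def sample_event_times(
    config: GroundTruthConfig, condition: str, n_trials: int, seed
) -> list[dict[str, float]]:
    """Per-trial event maps (ms, trial-local clock with LCDon at PRE_LCD).

    Execution draws monkey intervals, observation human ones; NoGo trials
    carry only LCDon/ObjCue/GoNogo.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    actor = "human" if condition == "observation" else "monkey"
    iv = config.intervals[actor]
    out = []
    for i in range(n_trials):
        ev = {"LCDon": PRE_LCD}
        ev["ObjCue"] = ev["LCDon"] + LCD_TO_OBJCUE
        ev["GoNogo"] = ev["ObjCue"] + OBJCUE_TO_GO
        if condition != "nogo":
            rt = float(_lognormal_ms(rng, *iv["RT"], 1)[0])
            mt = float(_lognormal_ms(rng, *iv["MT"], 1)[0])
            ev["HPR"] = ev["GoNogo"] + rt
            ev["DO"] = ev["HPR"] + mt
            ev["HO"] = ev["DO"] + float(_lognormal_ms(rng, *iv["DO_HO"], 1)[0])
            ev["HOFF"] = ev["HO"] + HOLD_MS
            ev["HPN"] = ev["HOFF"] + float(_lognormal_ms(rng, *iv["HOFF_HPN"], 1)[0])
        out.append(ev)
    return out


def _haar_orthonormal(rng, n, k):
    g = rng.standard_normal((n, k))
    q, r = np.linalg.qr(g)
    return q * np.sign(np.diag(r))


def _rotated_basis(rng, w_ref, w_perp, rho):
    """Basis sharing fraction *rho* of its subspace with w_ref.

    Every principal angle between span(result) and span(w_ref) equals
    arccos(sqrt(rho)).
    """
    theta = np.arccos(np.sqrt(rho))
    k = w_ref.shape[1]
    q = _haar_orthonormal(rng, k, k)
    return (np.cos(theta) * w_ref + np.sin(theta) * w_perp) @ q


def make_loadings(rng, config: GroundTruthConfig):
    """Orthonormal loading bases per condition with planted principal angles."""
    n, k = config.n_neurons, config.k_latent
    big = _haar_orthonormal(rng, n, 3 * k)
    w_exe = big[:, :k]
    w_perp_obs = big[:, k:2 * k]  # orthogonal to w_exe
    w_obs = _rotated_basis(rng, w_exe, w_perp_obs, config.rho_exe_obs)
    # complement of span(w_exe, w_obs) so nogo<->exe overlap stays incidental
    w_perp_nogo = big[:, 2 * k:3 * k]
    w_nogo = _rotated_basis(rng, w_obs, w_perp_nogo, config.rho_obs_nogo)
    angles = {
        "exe_obs": float(np.arccos(np.sqrt(config.rho_exe_obs))),
        "obs_nogo": float(np.arccos(np.sqrt(config.rho_obs_nogo))),
    }
    return {"execution": w_exe, "observation": w_obs, "nogo": w_nogo}, angles


def principal_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Principal angles (radians) between the column spans of two bases."""
    qa, _ = np.linalg.qr(a)
    qb, _ = np.linalg.qr(b)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.arccos(np.clip(s, -1.0, 1.0))


def _draw_bumps(rng, k):
    """Latent bump parameters: per event, per-component delays/widths/amps.

    Each latent component gets its own delay and width so the k latent time
    courses stay linearly independent within any task window; amplitudes
    differ across grasps and may be negative (suppression-type neurons then
    arise from the signs of the loadings).
    """
    bumps = []
    for event, delay_span in (("GoNogo", (80.0, 280.0)), ("HPR", (-50.0, 80.0)),
                              ("DO", (-30.0, 100.0)), ("HO", (50.0, 300.0))):
        delays = rng.uniform(*delay_span, size=k)
        sds = rng.uniform(50.0, 140.0, size=k)
        # magnitudes bounded away from zero so every component carries signal
        amps = rng.uniform(0.6, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
        bumps.append((event, delays, sds, amps))
    return bumps


def latent_trajectory(bumps, events: dict[str, float], t: np.ndarray, k: int):
    """(k, len(t)) latent time course on the trial-local clock."""
    z = np.zeros((k, t.size))
    for event, delays, sds, amps in bumps:
        if event not in events:
            continue
        centers = events[event] + delays
        g = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / sds[:, None]) ** 2)
        z += amps[:, None] * g
    return z


def generate_session(
    config: GroundTruthConfig, seed: int
) -> tuple[SessionBundle, GroundTruthRecord]:
    """Generate one synthetic session plus its ground-truth record.

    Rates are ``max(0, b_n + g_c * latent_scale * (W_c z)_n)`` evaluated on a
    1 ms grid; spikes are drawn as an inhomogeneous Poisson process (binwise
    thinning at 1 ms).  The same seed yields an identical bundle.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n, k = config.n_neurons, config.k_latent

    baselines = rng.uniform(config.baseline_lo, config.baseline_hi, size=n)
    loadings, angles = make_loadings(rng, config)
    bump_params = {g: _draw_bumps(rng, k) for g in ("PG", "WHG")}
    gains = {"execution": config.gain_exe, "observation": config.gain_obs,
             "nogo": config.gain_nogo}

    neurons = [
        NeuronMeta(f"n{j:03d}", config.area, config.identity, "synthetic")
        for j in range(n)
    ]
    ids = [nm.neuron_id for nm in neurons]

    trials: list[TrialRecord] = []
    emg_traces: dict[int, np.ndarray] = {}
    emg_t0: dict[int, float] = {}
    gt_events: dict[int, dict[str, float]] = {}
    gt_counts: dict[int, np.ndarray] = {}

    # fixed interleaving so trial indices are stable given the config
    plan = [
        (cond, grasp)
        for _ in range(config.trials_per_condition)
        for cond in config.conditions
        for grasp in config.grasps
    ]
    session_clock = 0.0
    for idx, (cond, grasp) in enumerate(plan):
        ev_local = sample_event_times(config, cond, 1, rng.integers(2**63))[0]
        last = max(ev_local.values())
        stop_local = (ev_local["GoNogo"] + NOGO_POST if cond == "nogo"
                      else last + POST_LAST)
        t_grid = np.arange(0.0, stop_local, 1.0)  # 1 ms rate grid
        z = latent_trajectory(bump_params[grasp], ev_local, t_grid, k)
        drive = loadings[cond] @ z  # (N, T)
        lam = np.maximum(
            0.0, baselines[:, None] + gains[cond] * config.latent_scale * drive
        )
        counts = rng.poisson(lam * 1e-3)  # per 1 ms bin
        spikes = {}
        tally = np.zeros(n)
        for j in range(n):
            nz = np.nonzero(counts[j])[0]
            if nz.size:
                times = np.repeat(t_grid[nz], counts[j][nz])
                times = times + rng.uniform(0.0, 1.0, size=times.size)
                times = np.minimum(times, stop_local - 1e-6)
                spikes[ids[j]] = np.sort(times) + session_clock
                tally[j] = times.size
            else:
                spikes[ids[j]] = np.empty(0)

        ev = {e: v + session_clock for e, v in ev_local.items()}
        tr = TrialRecord(
            index=idx, condition=cond, grasp=grasp, events=ev, spikes=spikes,
            outcome="correct", start=session_clock, stop=session_clock + stop_local,
        )
        trials.append(tr)
        gt_events[idx] = ev
        gt_counts[idx] = tally

        if config.emg:
            emg_traces[idx] = _emg_trial(rng, config, cond, ev_local, stop_local)
            emg_t0[idx] = session_clock
        session_clock += stop_local + 500.0  # inter-trial gap

    emg = None
    if config.emg:
        emg = EmgBlock(
            muscles=[f"m{j:02d}" for j in range(config.n_muscles)],
            traces=emg_traces, rate=config.emg_rate, t0=emg_t0,
        )
    bundle = SessionBundle(
        session_id=config.session_id, neurons=neurons, trials=trials, emg=emg
    )
    record = GroundTruthRecord(
        loadings=loadings, baselines=baselines, bump_params=bump_params,
        planted_angles=angles, event_times=gt_events, spike_counts=gt_counts,
        config=config,
    )
    return bundle, record


def canonical_events_from_config(config: GroundTruthConfig, condition: str):
    """Mean event times (ms, relative to GoNogo = 0) implied by the config."""
    actor = "human" if condition == "observation" else "monkey"
    iv = config.intervals[actor]
    ev = {"GoNogo": 0.0, "ObjCue": -OBJCUE_TO_GO,
          "LCDon": -OBJCUE_TO_GO - LCD_TO_OBJCUE}
    if condition != "nogo":
        ev["HPR"] = iv["RT"][0]
        ev["DO"] = ev["HPR"] + iv["MT"][0]
        ev["HO"] = ev["DO"] + iv["DO_HO"][0]
        ev["HOFF"] = ev["HO"] + HOLD_MS
        ev["HPN"] = ev["HOFF"] + iv["HOFF_HPN"][0]
    return ev


def planted_rate_tensors(
    record: GroundTruthRecord,
    window: tuple[float, float] = (-1400.0, 2400.0),
    bin_width: float = 10.0,
    subtract_baseline: bool = True,
) -> dict:
    """Noise-free rate tensors implied by the ground truth.

    Rates are evaluated analytically on a canonical timeline (events at
    their configured means, GoNogo = 0); no Poisson draw, no binning error.
    Used by planted-identity and parameter-recovery checks.  Returns a dict
    keyed (condition, grasp) of RateTensors.
    """
    from mirrorpop.preprocess import RateTensor

    config = record.config
    t = np.arange(window[0], window[1], bin_width)
    out = {}
    for cond in ("execution", "observation", "nogo"):
        gain = {"execution": config.gain_exe, "observation": config.gain_obs,
                "nogo": config.gain_nogo}[cond]
        ev = canonical_events_from_config(config, cond)
        for grasp in ("PG", "WHG"):
            z = latent_trajectory(record.bump_params[grasp], ev, t,
                                  config.k_latent)
            vals = np.maximum(
                0.0,
                record.baselines[:, None]
                + gain * config.latent_scale * (record.loadings[cond] @ z),
            )
            if subtract_baseline:
                vals = vals - record.baselines[:, None]
            canon = canonical_events_from_config(config, "execution")
            out[(cond, grasp)] = RateTensor(
                values=vals, time_axis=t, bin_width=bin_width,
                alignment="multi:(Go,HPR,DO)",
                neuron_ids=[f"n{j:03d}" for j in range(config.n_neurons)],
                canonical_events=canon,
            )
    return out


def _emg_trial(rng, config, cond, ev_local, stop_local):
    """Raw multichannel EMG for one trial: broadband noise, plus a burst
    (multiplicative envelope) spanning Go->DO on execution trials only.
    Planted dead muscles get noise but never a burst."""
    n_samp = int(stop_local * config.emg_rate / 1000.0)
    t = np.arange(n_samp) * 1000.0 / config.emg_rate
    x = rng.normal(0.0, config.emg_noise_sd, size=(config.n_muscles, n_samp))
    if cond == "execution":
        # EMG onset precedes homepad release; burst spans the reach
        center = ev_local["HPR"]
        width = max(ev_local["DO"] - ev_local["HPR"], 1.0) * 0.8
        env = np.exp(-0.5 * ((t - center) / width) ** 2)
        gain = 1.0 + config.emg_burst_gain * env
        for m in range(config.n_muscles):
            if m not in config.dead_muscles:
                x[m] *= gain
    # planted dead channels: essentially flat traces (broken electrode)
    for m in config.dead_muscles:
        x[m] *= 1e-4
    return x


def inject_emg_contamination(
    bundle: SessionBundle,
    trial_indices,
    amplitude: float,
    seed: int = 0,
    reaction_ms: float = 300.0,
) -> SessionBundle:
    """Raise Reaction-interval EMG on selected passive trials.

    *amplitude* is expressed in multiples of the within-trial baseline SD of
    the raw trace.  The contaminated trial list is recorded on the returned
    bundle as ground truth.  Targeting an execution trial is an error.
    """
    if bundle.emg is None:
        raise ValueError("bundle has no EMG block")
    rng = np.random.default_rng(seed)
    by_index = {t.index: t for t in bundle.trials}
    traces = {i: v.copy() for i, v in bundle.emg.traces.items()}
    for idx in trial_indices:
        tr = by_index[idx]
        if tr.condition == "execution":
            raise ValueError(f"trial {idx} is an execution trial")
        if amplitude == 0:
            continue
        x = traces[idx]
        rate = bundle.emg.rate
        t0 = bundle.emg.t0.get(idx, tr.start)
        go = tr.events["GoNogo"] - t0
        i0 = int(go * rate / 1000.0)
        i1 = min(int((go + reaction_ms) * rate / 1000.0), x.shape[1])
        t = np.arange(i1 - i0) * 1000.0 / rate
        env = np.exp(-0.5 * ((t - reaction_ms / 2) / (reaction_ms / 4)) ** 2)
        for m in range(x.shape[0]):
            sd = x[m].std()
            x[m, i0:i1] += amplitude * sd * env * rng.standard_normal(env.size)
        traces[idx] = x
    emg = EmgBlock(
        muscles=list(bundle.emg.muscles), traces=traces,
        rate=bundle.emg.rate, t0=dict(bundle.emg.t0),
    )
    contaminated = sorted(
        set(bundle.contaminated_trials)
        | ({int(i) for i in trial_indices} if amplitude != 0 else set())
    )
    return replace(bundle, emg=emg, contaminated_trials=contaminated)
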