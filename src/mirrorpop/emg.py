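"""EMG conditioning, baseline-referenced trial distances, the iterative
contaminated-trial exclusion procedure, and the EMG median split.

Quantification chain (interval means): rectify -> zero-phase 4th-order
Butterworth band-pass 0.5-30 Hz -> mean over the interval.  The separate
visualization chain (high-pass 30 Hz -> rectify -> low-pass 500 Hz ->
100 ms moving average) is provided only for plotting.

Intervals: Baseline = LCDon -> ObjCue.  Reaction = Go -> HPR for execution
and observation (the actor's homepad release), or a fixed 0-300 ms window
after the imperative cue for NoGo (and optionally for observation, via
``reaction_def="fixed300"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from mirrorpop.dataio import SessionBundle

log = logging.getLogger(__name__)

MIN_OBS_TRIALS = 10  # per grasp; below -> unit excluded from dataset
MIN_NOGO_TRIALS = 7  # per grasp; below -> unit excluded from NoGo analyses


@dataclass
class EmgTrialDistance:
    trial: int
    condition: str
    grasp: str
    interval: str  # "Baseline" | "Reaction"
    distance: float  # 2-norm across muscles, z-scored units


@dataclass
class ExclusionReport:
    condition: str
    removed: list[int] = field(default_factory=list)  # in removal order
    removed_magnitudes: list[float] = field(default_factory=list)
    iterations: int = 0
    p_values: list[float] = field(default_factory=list)  # min-p per iteration
    noisy_muscles: list[str] = field(default_factory=list)
    exhausted: bool = False  # stopped because trials ran out


def _bandpass(trace: np.ndarray, rate: float, lo=0.5, hi=30.0, order=4):
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, trace, axis=-1)


def envelope(trace: np.ndarray, rate: float) -> np.ndarray:
    """Rectified, band-passed (0.5-30 Hz, zero-phase 4th-order Butterworth)
    envelope of a raw trace; works on the last axis."""
    if rate <= 60.0:
        raise ValueError("EMG rate must exceed 60 Hz")
    return _bandpass(np.abs(np.asarray(trace, dtype=float)), rate)


def visualization_envelope(trace: np.ndarray, rate: float) -> np.ndarray:
    """Plot-only chain: 30 Hz high-pass -> rectify -> 500 Hz low-pass ->
    100 ms moving average."""
    x = np.asarray(trace, dtype=float)
    sos = signal.butter(2, 30.0, btype="highpass", fs=rate, output="sos")
    x = np.abs(signal.sosfiltfilt(sos, x, axis=-1))
    if rate > 1000.0:
        sos = signal.butter(2, 500.0, btype="lowpass", fs=rate, output="sos")
        x = signal.sosfiltfilt(sos, x, axis=-1)
    w = max(int(round(rate * 0.1)), 1)
    kernel = np.ones(w) / w
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), -1, x)


def _interval(trial, which: str, reaction_def: str = "hpr"):
    ev = trial.events
    if which == "Baseline":
        return ev["LCDon"], ev["ObjCue"]
    if which != "Reaction":
        raise ValueError(f"unknown interval {which!r}")
    if trial.condition == "nogo" or reaction_def == "fixed300":
        return ev["GoNogo"], ev["GoNogo"] + 300.0
    return ev["GoNogo"], ev["HPR"]


def envelope_quant(
    bundle: SessionBundle,
    intervals: tuple[str, ...] = ("Baseline", "Reaction"),
    reaction_def: str = "hpr",
) -> dict:
    """Mean envelope per (trial, muscle, interval).

    Returns ``{interval: {trial_index: (n_muscles,) means}}``.  Raises if an
    interval falls outside the recorded trace.
    """
    if bundle.emg is None:
        raise ValueError("bundle has no EMG block")
    emg = bundle.emg
    out = {iv: {} for iv in intervals}
    for t in bundle.select_trials():
        if t.index not in emg.traces:
            continue
        env = envelope(emg.traces[t.index], emg.rate)
        taxis = emg.time_axis(t.index)
        for iv in intervals:
            t0, t1 = _interval(t, iv, reaction_def)
            m = (taxis >= t0) & (taxis < t1)
            if not m.any() or t0 < taxis[0] or t1 > taxis[-1] + 1000.0 / emg.rate:
                raise ValueError(
                    f"trial {t.index}: interval {iv} outside recorded trace"
                )
            out[iv][t.index] = env[:, m].mean(axis=1)
    return out


def envelope_samples(
    bundle: SessionBundle,
    intervals: tuple[str, ...] = ("Baseline", "Reaction"),
    reaction_def: str = "hpr",
    decimate_hz: float = 250.0,
) -> dict:
    """Rectified EMG sample arrays per (trial, interval), for the exclusion
    t-test.

    Returns ``{interval: {trial_index: (n_muscles, n_samples)}}``.  The
    samples are the rectified raw trace (decimated to ~*decimate_hz*), not
    the 0.5-30 Hz envelope: the envelope's slow band is autocorrelated over
    seconds, which would wreck the calibration of a pooled two-sample test,
    whereas rectified raw samples are essentially independent.
    """
    if bundle.emg is None:
        raise ValueError("bundle has no EMG block")
    emg_block = bundle.emg
    step = max(int(round(emg_block.rate / decimate_hz)), 1)
    out = {iv: {} for iv in intervals}
    for t in bundle.select_trials():
        if t.index not in emg_block.traces:
            continue
        rect = np.abs(emg_block.traces[t.index])
        taxis = emg_block.time_axis(t.index)
        for iv in intervals:
            t0, t1 = _interval(t, iv, reaction_def)
            m = (taxis >= t0) & (taxis < t1)
            if not m.any():
                raise ValueError(
                    f"trial {t.index}: interval {iv} outside recorded trace"
                )
            out[iv][t.index] = rect[:, m][:, ::step]
    return out


def flag_noisy_channels(bundle: SessionBundle, envelopes: dict) -> list[str]:
    """Muscles whose mean execution Reaction envelope does not exceed the
    mean Baseline envelope are flagged noisy and dropped for the session.

    "Exceed" is taken with a small relative margin so that flat (broken)
    channels, whose two means differ only by numerical noise, are always
    flagged.
    """
    exe = [t.index for t in bundle.select_trials("execution")
           if t.index in envelopes["Reaction"]]
    if not exe:
        raise ValueError("need at least one execution trial")
    base = np.mean([envelopes["Baseline"][i] for i in exe], axis=0)
    reach = np.mean([envelopes["Reaction"][i] for i in exe], axis=0)
    diff = reach - base
    tol = max(1e-3 * diff.max(), 1e-12)
    muscles = bundle.emg.muscles
    flagged = [muscles[m] for m in range(len(muscles)) if diff[m] <= tol]
    if len(flagged) == len(muscles):
        log.warning("all EMG channels flagged noisy; distances unusable")
    return flagged


def _zscore_stats(bundle, envelopes, condition, keep_idx):
    """Per-muscle baseline mean/SD across this condition's trials."""
    trials = [t.index for t in bundle.select_trials(condition)
              if t.index in envelopes["Baseline"]]
    if len(trials) < 2:
        raise ValueError("need >=2 trials for baseline statistics")
    base = np.array([envelopes["Baseline"][i] for i in trials])  # (trials, muscles)
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    keep = list(keep_idx)
    dropped = [m for m in keep if sd[m] == 0]
    if dropped:
        log.warning("dropping %d zero-variance muscle(s)", len(dropped))
        keep = [m for m in keep if sd[m] > 0]
    return trials, mu, sd, keep


def trial_distances(
    bundle: SessionBundle,
    envelopes: dict,
    condition: str,
    interval: str = "Reaction",
    exclude_muscles: tuple[str, ...] = (),
) -> list[EmgTrialDistance]:
    """Per-trial Euclidean distance from the mean baseline EMG.

    Each muscle's interval-mean envelope is z-scored against the baseline
    mean/SD across this condition's trials, then the per-trial 2-norm is
    taken across the retained muscles.
    """
    muscles = bundle.emg.muscles
    keep_idx = [m for m, name in enumerate(muscles) if name not in exclude_muscles]
    trials, mu, sd, keep = _zscore_stats(bundle, envelopes, condition, keep_idx)
    by_index = {t.index: t for t in bundle.trials}
    out = []
    for i in trials:
        if i not in envelopes[interval]:
            continue
        z = (envelopes[interval][i][keep] - mu[keep]) / sd[keep]
        out.append(
            EmgTrialDistance(
                trial=i,
                condition=condition,
                grasp=by_index[i].grasp,
                interval=interval,
                distance=float(np.linalg.norm(z)),
            )
        )
    return out


def session_median_distance(distances: list[EmgTrialDistance]) -> float:
    return float(np.median([d.distance for d in distances]))


def iterative_exclusion(
    bundle: SessionBundle,
    samples: dict,
    condition: str,
    alpha: float = 0.05,
    exclude_muscles: tuple[str, ...] = (),
    max_iterations: int = 1000,
    z_gate: float | None = 3.0,
) -> ExclusionReport:
    """Iteratively remove passive trials whose EMG departs from baseline.

    *samples* comes from :func:`envelope_samples`.  Per muscle, a Welch
    (unequal-variance, unequal-n) t-test compares the pooled Baseline
    samples of the condition's remaining trials with the pooled Reaction
    samples; the two intervals have different durations, so the comparison
    is unbalanced by construction.  While any muscle shows a significant
    *elevation* at *alpha*, the single remaining trial with the largest
    mean Reaction magnitude on the most-significant muscle is removed and
    all muscles are re-tested.  Stops when no muscle is significant, when
    fewer than 3 trials remain (flagged ``exhausted``), or at
    *max_iterations*.

    *z_gate* (default 3): a trial is only removed if its Reaction magnitude
    also exceeds the across-trial baseline variability by this many SDs,
    i.e. it actually looks contaminated.  A pooled test over thousands of
    samples can stay marginally significant for many rounds after a chance
    trigger; without the gate the loop would then discard several perfectly
    ordinary trials.  Pass ``None`` for the ungated stopping rule.
    """
    if condition not in ("observation", "nogo"):
        raise ValueError("exclusion applies to observation or nogo trials")
    muscles = bundle.emg.muscles
    keep_idx = [m for m, name in enumerate(muscles) if name not in exclude_muscles]
    all_trials = [t.index for t in bundle.select_trials(condition)
                  if t.index in samples["Baseline"]
                  and t.index in samples["Reaction"]]
    if len(all_trials) < 3:
        raise ValueError("need >=3 trials for the exclusion procedure")
    report = ExclusionReport(condition=condition,
                             noisy_muscles=list(exclude_muscles))
    remaining = list(all_trials)
    for _ in range(max_iterations):
        if len(remaining) < 3:
            report.exhausted = True
            break
        base = np.concatenate([samples["Baseline"][i] for i in remaining],
                              axis=1)
        react = np.concatenate([samples["Reaction"][i] for i in remaining],
                               axis=1)
        pvals = np.ones(len(keep_idx))
        for j, m in enumerate(keep_idx):
            # two-sided test, but removal only makes sense for an elevation
            # (contamination can only raise Reaction EMG); suppressed
            # muscles never trigger a removal
            if react[m].mean() <= base[m].mean():
                continue
            res = stats.ttest_ind(react[m], base[m], equal_var=False)
            pvals[j] = res.pvalue if np.isfinite(res.pvalue) else 1.0
        report.iterations += 1
        j_min = int(np.argmin(pvals))
        report.p_values.append(float(pvals[j_min]))
        if pvals[j_min] >= alpha:
            break
        m = keep_idx[j_min]
        mags = np.array([samples["Reaction"][i][m].mean() for i in remaining])
        i_worst = remaining[int(np.argmax(mags))]
        if z_gate is not None:
            base_means = np.array(
                [samples["Baseline"][i][m].mean() for i in remaining])
            spread = base_means.std(ddof=1)
            if spread == 0 or (mags.max() - base_means.mean()) / spread <= z_gate:
                break  # significant pool difference but no outlying trial
        report.removed.append(i_worst)
        report.removed_magnitudes.append(float(mags.max()))
        remaining.remove(i_worst)
    return report


def apply_minimum_trial_rules(
    bundle: SessionBundle,
    reports: dict,
    min_obs: int = MIN_OBS_TRIALS,
    min_nogo: int = MIN_NOGO_TRIALS,
) -> dict:
    """Post-exclusion inclusion flags.

    Returns ``{"include_unit": bool, "include_nogo": bool, "counts": {...}}``:
    fewer than *min_obs* observation trials per grasp excludes the unit set
    entirely; fewer than *min_nogo* NoGo trials per grasp excludes it from
    NoGo analyses only.
    """
    removed = set()
    for rep in reports.values():
        removed.update(rep.removed)
    counts = {}
    for cond in ("observation", "nogo"):
        for grasp in ("PG", "WHG"):
            n = sum(
                1 for t in bundle.select_trials(cond, grasp)
                if t.index not in removed
            )
            counts[(cond, grasp)] = n
    include_unit = all(counts[("observation", g)] >= min_obs for g in ("PG", "WHG"))
    include_nogo = include_unit and all(
        counts[("nogo", g)] >= min_nogo for g in ("PG", "WHG")
    )
    return {"include_unit": include_unit, "include_nogo": include_nogo,
            "counts": counts}


def median_split(
    distances: list[EmgTrialDistance], by_grasp: bool = True
) -> tuple[list[int], list[int]]:
    """Split trials at the median Reaction-interval distance.

    Ties and the median element go to the low set (odd counts put the
    median trial in the low set); within each grasp separately when
    *by_grasp*.  Deterministic: stable sort by (distance, trial index).
    """
    if len(distances) < 4:
        raise ValueError("need >=4 trials for a median split")
    low, high = [], []
    groups: dict[str, list[EmgTrialDistance]] = {}
    for d in distances:
        groups.setdefault(d.grasp if by_grasp else "all", []).append(d)
    for ds in groups.values():
        ds = sorted(ds, key=lambda d: (d.distance, d.trial))
        n_low = (len(ds) + 1) // 2
        low.extend(d.trial for d in ds[:n_low])
        high.extend(d.trial for d in ds[n_low:])
    return sorted(low), sorted(high)
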