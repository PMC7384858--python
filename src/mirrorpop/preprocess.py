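"""Spikes -> aligned, smoothed, baseline-corrected, soft-normalized rates.

Conventions (fixed across the package):

- bins are half-open ``[t, t + width)``; an alignment event sits at ``t = 0``
  on a bin left edge;
- the Gaussian smoothing kernel is truncated at +/-4 SD and renormalized to
  unit sum; at the edges the kernel is renormalized over the valid support;
- trials missing a required event are skipped (warned), never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mirrorpop.dataio import SessionBundle, TrialRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationSpec:
    mode: str = "range_soft"  # "range_soft" | "absmax_soft"
    constant: float = 5.0  # spikes/s added to the denominator
    baseline_window: tuple[float, float] = (-250.0, 0.0)  # ms relative to LCDon

    def __post_init__(self):
        if self.constant <= 0:
            raise ValueError("normalization constant must be > 0")
        if self.mode not in ("range_soft", "absmax_soft"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")


@dataclass
class RateTensor:
    """Neurons x timepoints rate matrix with alignment/normalization metadata."""

    values: np.ndarray  # (N, T), spikes/s or normalized units
    time_axis: np.ndarray  # (T,) ms relative to canonical events
    bin_width: float  # ms
    alignment: str  # e.g. "single:GoNogo" or "multi:(Go,HPR,DO)"
    neuron_ids: list[str] = field(default_factory=list)
    normalization: NormalizationSpec | None = None
    canonical_events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.shape[-1] != self.time_axis.size:
            raise ValueError("time_axis length must match last axis of values")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def window(self, t0: float, t1: float) -> "RateTensor":
        """Slice to times in ``[t0, t1)``."""
        m = (self.time_axis >= t0) & (self.time_axis < t1)
        if not m.any():
            raise ValueError(f"window ({t0}, {t1}) outside tensor span")
        return replace(self, values=self.values[..., m], time_axis=self.time_axis[m])

    def value_at(self, t: float) -> np.ndarray:
        """Per-neuron value at the bin containing time ``t``."""
        i = int(np.searchsorted(self.time_axis, t, side="right")) - 1
        if i < 0 or i >= self.time_axis.size:
            raise ValueError(f"time {t} outside tensor span")
        return self.values[..., i]


@dataclass(frozen=True)
class EpochDefinition:
    """A task epoch, anchored to one event or spanning two.

    mode:
      - ``"offset"``: ``[anchor + offsets[0], anchor + offsets[1])``
      - ``"span"``: ``[events[0], events[1])``
      - ``"span_half"``: first/second half of ``[events[0], events[1])``
    """

    name: str
    mode: str
    events: tuple[str, ...]
    offsets: tuple[float, float] = (0.0, 0.0)
    half: int = 0  # for span_half: 0 = first half, 1 = second half

    def __post_init__(self):
        if self.mode not in ("offset", "span", "span_half"):
            raise ValueError(f"unknown epoch mode {self.mode!r}")
        if self.mode == "offset" and not self.offsets[0] < self.offsets[1]:
            raise ValueError(f"epoch {self.name}: offsets must be ordered")

    def resolve(self, events: dict[str, float]) -> tuple[float, float] | None:
        """Session-clock (start, stop) for one trial, or None if unresolvable."""
        if any(e not in events for e in self.events):
            return None
        if self.mode == "offset":
            a = events[self.events[0]]
            return (a + self.offsets[0], a + self.offsets[1])
        t0, t1 = events[self.events[0]], events[self.events[1]]
        if self.mode == "span":
            return (t0, t1)
        mid = 0.5 * (t0 + t1)
        return (t0, mid) if self.half == 0 else (mid, t1)


#: epochs used by the 2-way ANOVA unit classification
ANOVA_EPOCHS = (
    EpochDefinition("Baseline", "span", ("LCDon", "ObjCue")),
    EpochDefinition("Reach", "span", ("HPR", "DO")),
    EpochDefinition("GraspHold", "offset", ("HO",), (0.0, 700.0)),
)

#: the eight task periods of the cross-condition correlation analysis
CORRELATION_EPOCHS = (
    EpochDefinition("PreLCD", "offset", ("LCDon",), (-250.0, 0.0)),
    EpochDefinition("Pres", "span", ("LCDon", "ObjCue")),
    EpochDefinition("ObjectCue", "offset", ("GoNogo",), (-500.0, 0.0)),
    EpochDefinition("EarlyReact", "offset", ("GoNogo",), (0.0, 150.0)),
    EpochDefinition("LateReact", "offset", ("GoNogo",), (150.0, 300.0)),
    EpochDefinition("EarlyReach", "span_half", ("HPR", "DO"), half=0),
    EpochDefinition("LateReach", "span_half", ("HPR", "DO"), half=1),
    EpochDefinition("Hold", "offset", ("HO",), (0.0, 700.0)),
)


# ---------------------------------------------------------------------------
# Binning and smoothing
# ---------------------------------------------------------------------------

def bin_edges(window: tuple[float, float], bin_width: float) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t0, t1 = window
    n = int(np.ceil((t1 - t0) / bin_width - 1e-9))
    if n <= 0:
        raise ValueError(f"empty window {window}")
    return t0 + np.arange(n + 1) * bin_width


def bin_spikes(spikes, window: tuple[float, float], bin_width: float) -> np.ndarray:
    """Spike counts in half-open bins ``[t, t+width)`` covering *window*.

    A spike exactly at a bin boundary t is counted in the bin starting at t.
    """
    edges = bin_edges(window, bin_width)
    spikes = np.asarray(spikes, dtype=float)
    # np.histogram treats the last bin as closed; enforce half-open throughout
    counts, _ = np.histogram(spikes, bins=edges)
    if spikes.size:
        counts[-1] -= np.count_nonzero(spikes == edges[-1])
    return counts


def gaussian_kernel(sd_ms: float, bin_width: float) -> np.ndarray:
    """Unit-sum discrete Gaussian, truncated at +/-4 SD."""
    if sd_ms <= 0:
        raise ValueError("sd must be > 0")
    half = int(np.ceil(4.0 * sd_ms / bin_width))
    x = np.arange(-half, half + 1) * bin_width
    k = np.exp(-0.5 * (x / sd_ms) ** 2)
    return k / k.sum()


def smooth_gaussian(rates: np.ndarray, sd_ms: float, bin_width: float) -> np.ndarray:
    """Convolve per-bin rates with a unit-area Gaussian kernel.

    Edge handling: the kernel is renormalized over the valid support, so a
    constant input stays exactly constant and interior mass is conserved.
    Works on the last axis of 1-D or 2-D input.
    """
    rates = np.asarray(rates, dtype=float)
    k = gaussian_kernel(sd_ms, bin_width)
    if rates.ndim == 1:
        num = np.convolve(rates, k, mode="same")
        den = np.convolve(np.ones_like(rates), k, mode="same")
        return num / den
    den = np.convolve(np.ones(rates.shape[-1]), k, mode="same")
    out = np.empty_like(rates)
    for i in range(rates.shape[0]):
        out[i] = np.convolve(rates[i], k, mode="same") / den
    return out


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _trial_rates_aligned(
    trials: list[TrialRecord],
    neuron_ids: list[str],
    event: str,
    window: tuple[float, float],
    bin_width: float,
    smooth_sd: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial aligned rates.

    Returns (rates, valid): rates (n_trials, N, T) in spikes/s, valid
    (n_trials, T) boolean mask of bins fully inside the recorded trial span.
    Trials missing *event* are skipped with a warning.
    """
    edges = bin_edges(window, bin_width)
    centers_rel = edges[:-1]
    usable = [t for t in trials if event in t.events]
    skipped = len(trials) - len(usable)
    if skipped:
        log.warning("skipping %d trial(s) missing event %s", skipped, event)
    if not usable:
        raise ValueError(f"no trials carry event {event}")
    n_tr, n_nrn, n_t = len(usable), len(neuron_ids), centers_rel.size
    rates = np.zeros((n_tr, n_nrn, n_t))
    valid = np.zeros((n_tr, n_t), dtype=bool)
    for i, tr in enumerate(usable):
        t_ev = tr.events[event]
        abs_left = t_ev + edges[:-1]
        abs_right = t_ev + edges[1:]
        valid[i] = (abs_left >= tr.start) & (abs_right <= tr.stop)
        # vectorized across neurons: 2-D histogram over (neuron, time)
        all_t, all_j = [], []
        for j, nid in enumerate(neuron_ids):
            st = tr.spikes.get(nid)
            if st is None or len(st) == 0:
                continue
            st = np.asarray(st) - t_ev
            st = st[(st >= edges[0]) & (st < edges[-1])]
            if st.size:
                all_t.append(st)
                all_j.append(np.full(st.size, j))
        if all_t:
            counts, _, _ = np.histogram2d(
                np.concatenate(all_j), np.concatenate(all_t),
                bins=[np.arange(n_nrn + 1) - 0.5, edges],
            )
            rates[i] = counts * (1000.0 / bin_width)
        if smooth_sd is not None:
            rates[i] = smooth_gaussian(rates[i], smooth_sd, bin_width)
    return rates, valid


def psth_single(
    trials: list[TrialRecord],
    neuron_ids: list[str],
    event: str,
    window: tuple[float, float],
    bin_width: float = 10.0,
    smooth_sd: float | None = 50.0,
) -> RateTensor:
    """Trial-averaged PSTH aligned to one event."""
    rates, valid = _trial_rates_aligned(
        trials, neuron_ids, event, window, bin_width, smooth_sd
    )
    w = valid[:, None, :].astype(float)
    with np.errstate(invalid="ignore"):
        avg = (rates * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-12)
    edges = bin_edges(window, bin_width)
    return RateTensor(
        values=avg,
        time_axis=edges[:-1],
        bin_width=bin_width,
        alignment=f"single:{event}",
        neuron_ids=list(neuron_ids),
        canonical_events={event: 0.0},
    )


def canonical_event_times(
    trials: list[TrialRecord], events: tuple[str, ...] = ("GoNogo", "HPR", "DO", "HO")
) -> dict[str, float]:
    """Mean event times relative to Go/NoGo across the given trials."""
    out = {"GoNogo": 0.0}
    go = [t for t in trials if all(e in t.events for e in events)]
    if not go:
        raise ValueError("no trials carry all canonical events")
    for e in events:
        if e == "GoNogo":
            continue
        out[e] = float(np.mean([t.events[e] - t.events["GoNogo"] for t in go]))
    return out


def multi_align(
    trials: list[TrialRecord],
    neuron_ids: list[str],
    canonical: dict[str, float],
    window: tuple[float, float],
    bin_width: float = 10.0,
    smooth_sd: float | None = 50.0,
    blend_ms: float = 100.0,
) -> RateTensor:
    """Stitch Go-, HPR- and DO-aligned trial averages onto a common timeline.

    ``canonical`` gives the canonical event times relative to Go (= 0).  Each
    canonical segment is owned by its nearest event (boundaries at midpoints
    between canonical event times); segments are cross-blended linearly over
    ``blend_ms`` around each boundary so the stitched trace is continuous.
    """
    t_go, t_hpr, t_do = canonical["GoNogo"], canonical["HPR"], canonical["DO"]
    if not (t_go < t_hpr < t_do):
        raise ValueError("canonical event times must be ordered Go < HPR < DO")
    usable = [t for t in trials
              if all(e in t.events for e in ("GoNogo", "HPR", "DO"))]
    if len(usable) < len(trials):
        log.warning(
            "skipping %d trial(s) missing a required alignment event",
            len(trials) - len(usable),
        )
    if not usable:
        raise ValueError("no trials carry all of Go/HPR/DO")
    trials = usable
    edges = bin_edges(window, bin_width)
    tl = edges[:-1]  # canonical timeline (bin left edges)
    bounds = [0.5 * (t_go + t_hpr), 0.5 * (t_hpr + t_do)]
    anchors = [("GoNogo", t_go), ("HPR", t_hpr), ("DO", t_do)]

    segs = []
    for ev, t_c in anchors:
        # aligned support covering this event's owned span plus blend margin
        lo = tl[0] - t_c - blend_ms
        hi = tl[-1] + bin_width - t_c + blend_ms
        psth = psth_single(trials, neuron_ids, ev, (lo, hi), bin_width, smooth_sd)
        # resample onto the canonical timeline
        vals = np.vstack(
            [np.interp(tl - t_c, psth.time_axis, psth.values[j])
             for j in range(len(neuron_ids))]
        )
        segs.append(vals)

    # piecewise ownership with linear cross-blending at the two boundaries
    w = np.zeros((3, tl.size))
    w[0] = _blend_weight(tl, -np.inf, bounds[0], blend_ms)
    w[1] = _blend_weight(tl, bounds[0], bounds[1], blend_ms)
    w[2] = _blend_weight(tl, bounds[1], np.inf, blend_ms)
    w /= w.sum(axis=0, keepdims=True)
    values = sum(w[i][None, :] * segs[i] for i in range(3))
    return RateTensor(
        values=values,
        time_axis=tl,
        bin_width=bin_width,
        alignment="multi:(Go,HPR,DO)",
        neuron_ids=list(neuron_ids),
        canonical_events=dict(canonical),
    )


def _blend_weight(t, lo, hi, blend):
    """Trapezoidal ownership weight: 1 inside (lo, hi), linear rolloff of
    width *blend* centered on each finite boundary."""
    w = np.ones_like(t)
    if np.isfinite(lo):
        w = np.minimum(w, np.clip((t - lo) / blend + 0.5, 0.0, 1.0))
    if np.isfinite(hi):
        w = np.minimum(w, np.clip((hi - t) / blend + 0.5, 0.0, 1.0))
    return w


# ---------------------------------------------------------------------------
# Baseline correction and soft-normalization
# ---------------------------------------------------------------------------

def baseline_rates(
    bundle: SessionBundle,
    window: tuple[float, float] = (-250.0, 0.0),
    anchor: str = "LCDon",
) -> np.ndarray:
    """Per-neuron mean rate (spikes/s) in *window* relative to *anchor*,
    averaged across all correct trials of all conditions."""
    trials = bundle.select_trials()
    dur_s = (window[1] - window[0]) / 1000.0
    ids = bundle.neuron_ids
    counts = np.zeros(len(ids))
    n_used = 0
    for t in trials:
        if anchor not in t.events:
            continue
        t0 = t.events[anchor] + window[0]
        t1 = t.events[anchor] + window[1]
        if t0 < t.start or t1 > t.stop:
            raise ValueError(f"baseline window outside span on trial {t.index}")
        for j, nid in enumerate(ids):
            st = t.spikes.get(nid)
            if st is not None and len(st):
                st = np.asarray(st)
                counts[j] += np.count_nonzero((st >= t0) & (st < t1))
        n_used += 1
    if n_used == 0:
        raise ValueError("no trials available for baseline estimation")
    return counts / (n_used * dur_s)


def baseline_correct(
    tensors: dict, baseline: np.ndarray
) -> dict:
    """Subtract the per-neuron scalar baseline from every tensor.

    ``tensors`` maps condition keys to RateTensors over the same neurons.
    Negative output values are legal (suppression).
    """
    out = {}
    for key, t in tensors.items():
        out[key] = replace(t, values=t.values - baseline[:, None])
    return out


def soft_normalize(
    tensors: dict, spec: NormalizationSpec | None = None
) -> dict:
    """Divide each neuron's (baseline-corrected) rates by a soft denominator.

    range_soft: denominator = (rate range across all times and conditions
    + constant).  absmax_soft: denominator = (max absolute rate across all
    tensors + constant).  Output is strictly inside (-1, 1).
    """
    spec = spec or NormalizationSpec()
    stacked = np.concatenate([t.values.reshape(t.values.shape[0], -1)
                              for t in tensors.values()], axis=1)
    if spec.mode == "range_soft":
        denom = stacked.max(axis=1) - stacked.min(axis=1) + spec.constant
    else:
        denom = np.abs(stacked).max(axis=1) + spec.constant
    out = {}
    for key, t in tensors.items():
        out[key] = replace(
            t, values=t.values / denom[:, None], normalization=spec
        )
    return out


# ---------------------------------------------------------------------------
# Epoch averages and behaviour
# ---------------------------------------------------------------------------

def epoch_average(
    bundle: SessionBundle,
    epochs=ANOVA_EPOCHS,
    conditions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Trial-level mean firing rate per neuron x epoch.

    Rates are counts / epoch duration (spikes/s); trial-varying epochs
    (e.g. Reach halves) are resolved per trial before averaging.  Returns a
    long DataFrame: neuron_id, trial, condition, grasp, epoch, rate.
    Trials on which an epoch is unresolvable are omitted for that epoch.
    """
    rows = []
    ids = bundle.neuron_ids
    for t in bundle.select_trials():
        if conditions is not None and t.condition not in conditions:
            continue
        for ep in epochs:
            span = ep.resolve(t.events)
            if span is None:
                log.debug("trial %d: epoch %s unresolvable", t.index, ep.name)
                continue
            t0, t1 = span
            dur_s = (t1 - t0) / 1000.0
            if dur_s <= 0:
                continue
            for nid in ids:
                st = t.spikes.get(nid)
                n = 0
                if st is not None and len(st):
                    st = np.asarray(st)
                    n = int(np.count_nonzero((st >= t0) & (st < t1)))
                rows.append(
                    (nid, t.index, t.condition, t.grasp, ep.name, n / dur_s)
                )
    return pd.DataFrame(
        rows, columns=["neuron_id", "trial", "condition", "grasp", "epoch", "rate"]
    )


def compute_behaviour(bundle: SessionBundle) -> pd.DataFrame:
    """Per-trial RT (Go->HPR) and MT (HPR->DO) for correct Go trials.

    Returns a DataFrame with per-trial values; medians via
    :func:`behaviour_medians`.
    """
    rows = []
    for t in bundle.select_trials():
        if not t.is_go:
            continue
        if "HPR" not in t.events or "DO" not in t.events:
            continue
        rt = t.events["HPR"] - t.events["GoNogo"]
        mt = t.events["DO"] - t.events["HPR"]
        if rt <= 0 or mt <= 0:
            raise ValueError(f"trial {t.index}: non-positive RT/MT interval")
        rows.append((t.index, t.condition, t.grasp, rt, mt))
    return pd.DataFrame(rows, columns=["trial", "condition", "grasp", "RT", "MT"])


def behaviour_medians(table: pd.DataFrame) -> pd.DataFrame:
    return (
        table.groupby(["condition", "grasp"])[["RT", "MT"]].median().reset_index()
    )


# ---------------------------------------------------------------------------
# Population rate pipeline
# ---------------------------------------------------------------------------

def population_rates(
    bundle: SessionBundle,
    window: tuple[float, float] = (-1400.0, 2400.0),
    bin_width: float = 10.0,
    smooth_sd: float | None = 50.0,
    normalization: NormalizationSpec | None = None,
    conditions: tuple[str, ...] = ("execution", "observation", "nogo"),
    grasps: tuple[str, ...] = ("PG", "WHG"),
) -> dict:
    """Full preprocessing chain: multi-aligned PSTHs per condition x grasp,
    baseline-corrected and soft-normalized across all of them.

    Go conditions use the (Go, HPR, DO) multi-alignment; NoGo (which lacks
    movement events) is singly aligned to the Go/NoGo cue on the same
    canonical timeline.  Returns dict keyed ``(condition, grasp)``.
    """
    go_trials = bundle.select_trials("execution") + bundle.select_trials("observation")
    canonical = canonical_event_times(go_trials)
    tensors = {}
    for cond in conditions:
        for grasp in grasps:
            trials = bundle.select_trials(cond, grasp)
            if not trials:
                continue
            if cond == "nogo":
                # NoGo trials end early; restrict to the pre/peri-cue span
                stop = min(
                    min(t.stop - t.events["GoNogo"] for t in trials), window[1]
                )
                psth = psth_single(
                    trials, bundle.neuron_ids, "GoNogo",
                    (window[0], stop), bin_width, smooth_sd,
                )
                psth = replace(psth, canonical_events=dict(canonical))
                tensors[(cond, grasp)] = psth
            else:
                tensors[(cond, grasp)] = multi_align(
                    trials, bundle.neuron_ids, canonical, window,
                    bin_width, smooth_sd,
                )
    spec = normalization or NormalizationSpec()
    base = baseline_rates(bundle, spec.baseline_window)
    tensors = baseline_correct(tensors, base)
    return soft_normalize(tensors, spec)
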