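"""Session data model and HDF5/CSV I/O.

All times are in milliseconds on the session clock; alignment to task
events happens downstream (:mod:`mirrorpop.preprocess`).

HDF5 layout of a session file::

    /neurons                      JSON-encoded list of neuron metadata (attr)
    /trials/<i>/spikes/<neuron>   1-D float64 spike times (ms)
    /trials/<i>/events            attrs: event name -> time (ms)
    /trials/<i>                   attrs: condition, grasp, outcome, start, stop
    /emg/<i>                      (muscles, samples) float64 raw traces
    /emg                          attrs: muscles (list), rate (Hz), t0_<i>
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONDITIONS = ("execution", "observation", "nogo")
GRASPS = ("PG", "WHG")
EVENT_ORDER = ("LCDon", "ObjCue", "GoNogo", "HPR", "DO", "HO", "HOFF", "HPN")
#: events absent by design on NoGo trials
GO_ONLY_EVENTS = frozenset({"HPR", "DO", "HO", "HOFF", "HPN"})
SUBPOPULATIONS = ("M1-PTN", "M1-UID", "F5")


class SchemaError(Exception):
    """File does not conform to the expected session layout."""


class ValidationError(Exception):
    """A bundle violates a data-model invariant."""


class DepositNotFoundError(FileNotFoundError):
    """The externally deposited rate data is not present."""


class DepositAdapterError(Exception):
    """Deposited file present but its variable layout is unrecognized."""


@dataclass(frozen=True)
class NeuronMeta:
    neuron_id: str
    area: str  # "M1" | "F5"
    identity: str  # "PTN" | "UID"
    subject: str = ""

    @property
    def subpopulation(self) -> str:
        # F5 pools PTN and UID into one population
        if self.area == "F5":
            return "F5"
        return f"M1-{self.identity}"


@dataclass
class TrialRecord:
    index: int
    condition: str
    grasp: str
    events: dict[str, float]
    spikes: dict[str, np.ndarray]
    outcome: str = "correct"
    start: float = 0.0
    stop: float = 0.0

    @property
    def is_go(self) -> bool:
        return self.condition in ("execution", "observation")


@dataclass
class EmgBlock:
    muscles: list[str]
    traces: dict[int, np.ndarray]  # trial index -> (n_muscles, n_samples)
    rate: float  # Hz
    t0: dict[int, float] = field(default_factory=dict)  # session-clock ms of sample 0

    def time_axis(self, trial_index: int) -> np.ndarray:
        n = self.traces[trial_index].shape[1]
        start = self.t0.get(trial_index, 0.0)
        return start + np.arange(n) * 1000.0 / self.rate


@dataclass
class SessionBundle:
    session_id: str
    neurons: list[NeuronMeta]
    trials: list[TrialRecord]
    emg: EmgBlock | None = None
    spike_resolution_ms: float = 1.0
    #: ground-truth indices of trials with injected EMG contamination
    contaminated_trials: list[int] = field(default_factory=list)

    @property
    def neuron_ids(self) -> list[str]:
        return [n.neuron_id for n in self.neurons]

    def select_trials(
        self,
        condition: str | None = None,
        grasp: str | None = None,
        outcome: str | None = "correct",
    ) -> list[TrialRecord]:
        out = []
        for t in self.trials:
            if condition is not None and t.condition != condition:
                continue
            if grasp is not None and t.grasp != grasp:
                continue
            if outcome is not None and t.outcome != outcome:
                continue
            out.append(t)
        return out

    def drop_trials(self, indices) -> "SessionBundle":
        drop = set(indices)
        trials = [t for t in self.trials if t.index not in drop]
        emg = self.emg
        if emg is not None:
            emg = EmgBlock(
                muscles=list(emg.muscles),
                traces={i: v for i, v in emg.traces.items() if i not in drop},
                rate=emg.rate,
                t0={i: v for i, v in emg.t0.items() if i not in drop},
            )
        return replace(self, trials=trials, emg=emg)

    def validate(self) -> None:
        validate_bundle(self)


def validate_bundle(bundle: SessionBundle) -> None:
    """Check every data-model invariant; raise ValidationError on the first
    violation, naming the offending trial/neuron. No silent coercion."""
    ids = bundle.neuron_ids
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate neuron_id in neuron metadata")
    for n in bundle.neurons:
        if n.area not in ("M1", "F5"):
            raise ValidationError(f"neuron {n.neuron_id}: bad area {n.area!r}")
        if n.identity not in ("PTN", "UID"):
            raise ValidationError(f"neuron {n.neuron_id}: bad identity {n.identity!r}")

    seen = set()
    id_set = set(ids)
    for t in bundle.trials:
        if t.index in seen:
            raise ValidationError(f"duplicate trial index {t.index}")
        seen.add(t.index)
        if t.condition not in CONDITIONS:
            raise ValidationError(f"trial {t.index}: bad condition {t.condition!r}")
        if t.grasp not in GRASPS:
            raise ValidationError(f"trial {t.index}: bad grasp {t.grasp!r}")
        if t.outcome not in ("correct", "error"):
            raise ValidationError(f"trial {t.index}: bad outcome {t.outcome!r}")
        if t.condition == "nogo":
            bad = set(t.events) & GO_ONLY_EVENTS
            if bad:
                raise ValidationError(
                    f"trial {t.index}: NoGo trial carries movement events {sorted(bad)}"
                )
        present = [e for e in EVENT_ORDER if e in t.events]
        times = [t.events[e] for e in present]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"trial {t.index}: event times not strictly increasing in task order"
            )
        for nid, st in t.spikes.items():
            if nid not in id_set:
                raise ValidationError(f"trial {t.index}: spikes for unknown neuron {nid}")
            st = np.asarray(st)
            if st.size and (st.min() < t.start or st.max() > t.stop):
                raise ValidationError(
                    f"trial {t.index}: neuron {nid} spike outside trial span"
                )

    if bundle.emg is not None:
        m = len(bundle.emg.muscles)
        for i, tr in bundle.emg.traces.items():
            if i not in seen:
                raise ValidationError(f"EMG for unknown trial {i}")
            if tr.ndim != 2 or tr.shape[0] != m:
                raise ValidationError(
                    f"EMG trial {i}: trace shape {tr.shape} does not match "
                    f"{m} muscles"
                )
            if np.isnan(tr).any():
                raise ValidationError(f"EMG trial {i}: NaN samples")


# ---------------------------------------------------------------------------
# HDF5 session store
# ---------------------------------------------------------------------------

def write_session(bundle: SessionBundle, path) -> str:
    """Write a validated bundle to an HDF5 session file (deterministic layout)."""
    import h5py

    validate_bundle(bundle)
    path = str(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["session_id"] = bundle.session_id
        f.attrs["spike_resolution_ms"] = bundle.spike_resolution_ms
        f.attrs["neurons"] = json.dumps(
            [
                {"neuron_id": n.neuron_id, "area": n.area,
                 "identity": n.identity, "subject": n.subject}
                for n in bundle.neurons
            ]
        )
        f.attrs["contaminated_trials"] = json.dumps(sorted(bundle.contaminated_trials))
        g_tr = f.create_group("trials")
        for t in sorted(bundle.trials, key=lambda t: t.index):
            g = g_tr.create_group(str(t.index))
            g.attrs["condition"] = t.condition
            g.attrs["grasp"] = t.grasp
            g.attrs["outcome"] = t.outcome
            g.attrs["start"] = float(t.start)
            g.attrs["stop"] = float(t.stop)
            ge = g.create_group("events")
            for e in EVENT_ORDER:
                if e in t.events:
                    ge.attrs[e] = float(t.events[e])
            gs = g.create_group("spikes")
            for nid in sorted(t.spikes):
                gs.create_dataset(nid, data=np.asarray(t.spikes[nid], dtype=np.float64))
        if bundle.emg is not None:
            ge = f.create_group("emg")
            ge.attrs["muscles"] = json.dumps(list(bundle.emg.muscles))
            ge.attrs["rate"] = float(bundle.emg.rate)
            for i in sorted(bundle.emg.traces):
                d = ge.create_dataset(str(i), data=np.asarray(bundle.emg.traces[i],
                                                             dtype=np.float64))
                d.attrs["t0"] = float(bundle.emg.t0.get(i, 0.0))
    return path


def read_session(path) -> SessionBundle:
    """Read and validate a session file written by :func:`write_session`."""
    import h5py

    with h5py.File(str(path), "r") as f:
        for key in ("session_id", "neurons"):
            if key not in f.attrs:
                raise SchemaError(f"missing required attribute {key!r}")
        if "trials" not in f:
            raise SchemaError("missing required group /trials")
        neurons = [NeuronMeta(**d) for d in json.loads(f.attrs["neurons"])]
        trials = []
        for key in f["trials"]:
            g = f["trials"][key]
            events = {e: float(v) for e, v in g["events"].attrs.items()}
            spikes = {nid: np.asarray(g["spikes"][nid][()], dtype=np.float64)
                      for nid in g["spikes"]}
            trials.append(
                TrialRecord(
                    index=int(key),
                    condition=str(g.attrs["condition"]),
                    grasp=str(g.attrs["grasp"]),
                    events=events,
                    spikes=spikes,
                    outcome=str(g.attrs["outcome"]),
                    start=float(g.attrs["start"]),
                    stop=float(g.attrs["stop"]),
                )
            )
        trials.sort(key=lambda t: t.index)
        emg = None
        if "emg" in f:
            ge = f["emg"]
            traces, t0 = {}, {}
            for key in ge:
                traces[int(key)] = np.asarray(ge[key][()], dtype=np.float64)
                t0[int(key)] = float(ge[key].attrs.get("t0", 0.0))
            emg = EmgBlock(
                muscles=json.loads(ge.attrs["muscles"]),
                traces=traces,
                rate=float(ge.attrs["rate"]),
                t0=t0,
            )
        bundle = SessionBundle(
            session_id=str(f.attrs["session_id"]),
            neurons=neurons,
            trials=trials,
            emg=emg,
            spike_resolution_ms=float(f.attrs.get("spike_resolution_ms", 1.0)),
            contaminated_trials=json.loads(f.attrs.get("contaminated_trials", "[]")),
        )
    validate_bundle(bundle)
    return bundle


def events_table(bundle: SessionBundle) -> pd.DataFrame:
    """Per-trial event table (exportable as CSV)."""
    rows = []
    for t in bundle.trials:
        row = {
            "session_id": bundle.session_id,
            "trial": t.index,
            "condition": t.condition,
            "grasp": t.grasp,
        }
        for e in EVENT_ORDER:
            row[e] = t.events.get(e, np.nan)
        row["outcome"] = t.outcome
        rows.append(row)
    return pd.DataFrame(rows)


def write_events_csv(bundle: SessionBundle, path) -> str:
    events_table(bundle).to_csv(path, index=False)
    return str(path)


def write_neuron_sidecar(bundle: SessionBundle, path) -> str:
    with open(path, "w") as fh:
        json.dump(
            [
                {"neuron_id": n.neuron_id, "area": n.area,
                 "identity": n.identity, "subject": n.subject,
                 "subpopulation": n.subpopulation}
                for n in bundle.neurons
            ],
            fh,
            indent=2,
        )
    return str(path)


# ---------------------------------------------------------------------------
# Adapter for externally deposited trial-averaged rate matrices
# ---------------------------------------------------------------------------

def load_deposited_rates(path):
    """Load externally deposited per-population trial-averaged rate matrices.

    The deposit stores MATLAB structures of trial-averaged, already
    soft-normalized rates on a common multi-aligned timeline.  Returns a dict
    keyed ``(population, condition, grasp)`` of
    :class:`~mirrorpop.preprocess.RateTensor`, each flagged as
    pre-normalized.

    Raises
    ------
    DepositNotFoundError
        if *path* does not exist (callers are expected to fall back to
        synthetic mode).
    DepositAdapterError
        if the file exists but its variable layout is unrecognized; the
        error message lists the variable names actually found.
    """
    import os

    from mirrorpop.preprocess import NormalizationSpec, RateTensor

    path = str(path)
    if not os.path.exists(path):
        raise DepositNotFoundError(
            f"deposit not found at {path}; run in synthetic mode instead"
        )
    from scipy.io import loadmat

    try:
        mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    except Exception as exc:  # pragma: no cover - depends on external file
        raise DepositAdapterError(f"could not parse {path}: {exc}") from exc
    names = [k for k in mat if not k.startswith("__")]

    # Expected layout: variables named <pop>_<cond>_<grasp> holding T x N rate
    # matrices, plus a 'time' vector (ms) shared across all of them.
    if "time" not in mat:
        raise DepositAdapterError(
            f"unrecognized deposit layout; variables found: {sorted(names)}"
        )
    time_axis = np.asarray(mat["time"], dtype=float).ravel()
    out = {}
    for name in names:
        if name == "time":
            continue
        parts = name.split("_")
        if len(parts) != 3:
            continue
        pop, cond, grasp = parts
        values = np.asarray(mat[name], dtype=float)
        if values.ndim != 2:
            continue
        if values.shape[0] == time_axis.size:
            values = values.T  # store as neurons x time
        elif values.shape[1] != time_axis.size:
            raise DepositAdapterError(
                f"variable {name}: shape {values.shape} inconsistent with "
                f"time axis length {time_axis.size}"
            )
        bin_width = float(np.median(np.diff(time_axis))) if time_axis.size > 1 else 1.0
        out[(pop, cond, grasp)] = RateTensor(
            values=values,
            time_axis=time_axis,
            bin_width=bin_width,
            alignment="multi:(Go,HPR,DO)",
            neuron_ids=[f"{pop}-{i}" for i in range(values.shape[0])],
            normalization=NormalizationSpec(mode="range_soft"),
        )
    if not out:
        raise DepositAdapterError(
            f"unrecognized deposit layout; variables found: {sorted(names)}"
        )
    # per-population shape agreement across conditions
    by_pop: dict[str, set] = {}
    for (pop, _, _), t in out.items():
        by_pop.setdefault(pop, set()).add(t.values.shape)
    for pop, shapes in by_pop.items():
        if len(shapes) > 1:
            raise DepositAdapterError(
                f"population {pop}: inconsistent tensor shapes {sorted(shapes)}"
            )
    return out
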